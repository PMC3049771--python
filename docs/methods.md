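# Methods

## Model and procedure

The unit of analysis is a gene module: a set of identifiers with class
metadata (collection, namespace, disease/direction labels).  A module is
mapped onto a scaffold interactome — an undirected simple graph whose
edges may carry evidence-category tags — and induces its minimal
connected network (MCN).  Two constructions are supported:

- **base MCN**: the scaffold subgraph induced by the mapped members.
  Members with no surviving incident edge remain as singleton components;
  dropping them would silently overstate connectivity.
- **extended MCN**: every scaffold node outside the list that is adjacent
  to ≥2 distinct mapped members is admitted as a flagged *external*
  linker, and the subgraph induced by members ∪ linkers is used.  The
  rationale is that experimentally derived lists are incomplete; a single
  undetected protein may be the physical bridge between two halves of a
  real complex or pathway.

The phrase "minimal connected network" is sometimes read as a
Steiner-style object that imports arbitrary shortest-path intermediates.
We deliberately use the induced-subgraph reading: it is deterministic,
needs no tie-breaking among equal-length paths, and the one-external-node
extension covers the intended incomplete-list scenario exactly.  Shortest
paths enter only through betweenness.  Because the resampling null uses
the identical construction, the test is internally consistent under
either reading.

Per MCN we compute, with unit edge weights throughout (no interaction
confidence weighting is attempted):

- connection degree per node, within the MCN (not the whole scaffold);
- local clustering coefficient C(ν) = e_n / (n_ν(n_ν−1)/2), defined 0 for
  nodes with fewer than two neighbours;
- relative betweenness rC_B(ν): raw betweenness from shortest-path counts
  accumulated per connected component, normalised by (n−1)(n−2)/2 where n
  is the total MCN node count, and defined 0 when n < 3.  Shortest-path
  counting uses Brandes' algorithm (networkx); on unit weights it yields
  the same path counts a Dijkstra-based enumeration would.
- the number of connected components, singletons included.

External nodes are ordinary MCN nodes for all statistics, and their
values enter the observed samples; the null adds its own linkers
symmetrically, so neither side is favoured.

## The resampling null and the tests

For a module with N mapped members (N, not the raw list size, so that
observed and null networks are size-matched after mapping losses), the
null is built by R repetitions of: draw N distinct nodes uniformly from
the scaffold, build the MCN in the same external-node mode, record all
node-level parameter values and the component count.  Node-level values
are pooled across repetitions into one reference sample per parameter;
component counts are kept per repetition.  Uniform sampling is the
default; degree-proportional sampling is available as an off-by-default
sensitivity option (hub-rich nulls are stricter, since random hubs carry
high degree and betweenness).

Each of degree, betweenness and clustering is tested one-sided
("observed greater") with the two-sample Kolmogorov–Smirnov statistic
D₊ = sup_x [F_null(x) − F_obs(x)] and the asymptotic p-value
exp(−2·m·D₊²), m = |obs|·|null|/(|obs|+|null|), clipped to (0, 1].  The
component count is tested lower-tailed against the R null counts with an
add-one empirical p-value (1 + #{null ≤ obs})/(R+1), which cannot reach
zero.  Defaults: α = 0.05, R = 1,000 (raise to 10,000 for publication-
grade p-value resolution; runtime scales linearly), no multiple-testing
correction across the four parameters or across modules — raw p-values
are reported and any correction is left to the caller.  Modules with
fewer than 3 or more than 200 mapped members are skipped with an explicit
reason: below 3 the statistics are degenerate, far above 200 the
resampling null becomes both expensive and uninformative.

Nulls are cached in memory (and optionally on disk, versioned) keyed by
scaffold hash, N, mode, R and seed, so analysing a collection costs one
null per distinct mapped size.

### Known statistical limitation

The KS machinery treats the observed node values as an i.i.d. sample;
they are not — values within one network are mutually dependent, most
strongly for betweenness, which is a global statistic.  Measured on
uniform random lists (the null's own mechanism; N = 20, R = 1,000,
2,000-node scale-free scaffold with externals), the empirical type-I
rate at α = 0.05 is ≈0.08 for degree, ≈0.04 for clustering, ≈0.03 for
components, but ≈0.18 for betweenness.  Betweenness p-values should
therefore be read as a ranking/screening signal rather than as exactly
calibrated probabilities; the component-count test, being a per-network
empirical tail, is the best calibrated of the four.  This behaviour is a
property of the pooled-null KS approach itself, not of its
implementation (an i.i.d. sample drawn from the pooled null passes the
same code path at the nominal rate).

## Collection-level analyses

- **Percent significant** per parameter over non-skipped modules, overall
  or stratified by a module attribute (namespace, direction, disease).
- **Class comparisons**: node-level values pooled across all modules of a
  class, compared between classes by scipy's two-tailed two-sample KS;
  the reported direction (greater/less) is the significant median
  ordering.  Quartile tables summarise the pooled distributions.
- **Depth profiles**: for term-derived modules, statistics aggregated by
  ontology level, defined as the shortest parent-link distance from the
  term to its namespace root (depth conventions vary; shortest path is
  deterministic and the common choice).  Levels with <3 modules are
  flagged low-support.
- **ORA cross-classification**: term over-representation by one-sided
  Fisher exact test (hypergeometric upper tail) on true-path-propagated
  annotations with Benjamini–Hochberg correction; a module is
  net-significant when *any* of the four network parameters has p < α,
  ORA-significant when any term reaches q < α, giving the four-way
  only_net / only_go / net_and_go / nothing labels.  "Any parameter" is
  a permissive rule chosen to mirror how network evidence is used in
  screening practice.

## Synthetic data: what it emulates, and what it does not

The generators exist so that every stage is testable with known ground
truth:

- **scaffold**: Barabási–Albert preferential attachment by default
  (2,000 nodes, mean degree 8 — the order of magnitude of curated human
  interactomes, which run to ~9.5k proteins and ~37k interactions),
  Erdős–Rényi as an alternative for settings where the uniform-sampling
  null is exactly matched; evidence tags assigned so a configurable
  fraction (default 0.5) of edges survives the ≥2-evidence filter.
- **functional modules**: planted subgraphs (default size 20) topped up
  with random internal edges to a target induced density (default 0.3);
  planted edges carry two evidence tags so planting survives filtering.
- **signatures**: uniform random lists — by construction exactly the
  null's mechanism.
- **linker modules**: two cliques attached to one fresh non-member hub
  and to nothing else.  Fresh nodes are used (rather than reusing
  scaffold nodes) so the two-component base / one-component extended
  behaviour is guaranteed deterministically.
- **benchmark collections** bundle the above with a small term DAG whose
  leaf terms annotate exactly the planted modules' members, making ORA
  and the cross-classification testable against planted truth.

Real interactomes differ in ways the generators do not emulate: study
bias (well-studied proteins have inflated degree), false-positive and
false-negative interactions correlated with detection method, community
structure beyond what preferential attachment produces, and annotation
incompleteness.  Passing tests therefore demonstrate correctness of the
machinery and qualitative behaviour (power on cohesive modules, null
behaviour on random lists, linker rescue), not quantitative transfer of
any percentage to a particular interactome release.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; nulls are bit-reproducible and reruns of the CLI with
  equal config+seed are byte-identical (outputs contain no timestamps).
- KS p-values use the asymptotic one-sided formula; null pools are large
  by construction (R·N values), where the asymptotic regime is adequate.
  D₊ is evaluated at all sample points of both samples, which attains the
  supremum for right-continuous step ECDFs.
- Ties are handled naturally by the ECDF evaluation; heavily tied
  distributions (integer degrees, many zero clustering values) make the
  KS conservative, which is the safe direction for discovery.
- Self-interactions are dropped at load time: all statistics assume
  simple graphs.  Duplicate edge rows merge their evidence sets.
- Identifier translation (e.g. transcript→gene) is an optional
  two-column map applied at load; unmapped identifiers pass through
  unchanged, and the analysis is agnostic to identifier semantics.
- Study sizes used by the test suite and the acceptance script (200
  oracle graphs ≤30 nodes; 500 calibration lists; 100 power modules;
  20+20 class-separation benchmark; R = 1,000) were chosen as the
  smallest sizes at which the binomial/KS error bars are far narrower
  than the effects being checked.

## Limitations

- The enrichment test's betweenness branch is anti-conservative (see
  above); component counts and degree are the reliable primary signals.
- Base-mode MCNs of small modules on sparse scaffolds are mostly empty;
  one-sided KS tests on such degenerate samples have little power, which
  is precisely why the external-node extension exists.
- No degree-preserving permutation null is provided (uniform resampling
  is the specified null; degree-weighted sampling is a sensitivity
  option, not a calibrated alternative).
- Exact small-sample KS p-values and weighted/directed graphs are out of
  scope.
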