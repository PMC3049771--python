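# mcnet — PPI-network enrichment of gene modules

`mcnet` asks a simple question of any gene list: *do its members form a
real subnetwork of the protein–protein interaction (PPI) interactome, or
are they wired no better than a random draw of proteins?*  It is aimed at
systems biologists comparing conceptually different module definitions —
ontology terms, curated pathways, co-expression modules, differential
expression signatures — on a common network footing.

## The method

Given a scaffold interactome *G* (an undirected simple graph, optionally
filtered to interactions supported by ≥2 evidence categories) and a gene
list, the list is mapped onto *G* and induces its **minimal connected
network (MCN)**: the subgraph over the mapped members.  Because lists are
typically incomplete, an **extended MCN** additionally admits every
non-member protein adjacent to ≥2 mapped members as a flagged *external
linker node*.

Four statistics describe the MCN:

- connection degree *k(ν)* — edges incident to node ν within the MCN;
- clustering coefficient *C(ν) = e_n / (n_ν(n_ν−1)/2)*, where *e_n* is the
  number of edges among ν's *n_ν* neighbours;
- relative betweenness *rC_B(ν) = C_B(ν) / ((n−1)(n−2)/2)*, with
  *C_B(ν) = Σ_{s≠t≠ν} σ_st(ν)/σ_st* counted over shortest paths with unit
  edge weights and *n* the MCN node count;
- the number of connected components (singleton members included).

The **random expectation** for a list of *N* mapped members is built by
resampling: draw *N* nodes uniformly from *G* (*R* = 1,000 by default,
configurable), rebuild the MCN in the same mode, and pool the node-level
values over all repetitions.  The observed degree / betweenness /
clustering samples are tested against the pooled null with a one-sided
two-sample Kolmogorov–Smirnov test
(*p = exp(−2·m·D₊²)*, *m = |obs|·|null| / (|obs|+|null|)*,
*D₊ = sup_x [F_null − F_obs]*), and the observed component count with the
lower-tail empirical p-value *(1 + #{null ≤ obs}) / (R+1)*.  A module is
enriched when its parameters sit beyond random expectation at α = 0.05.

On top of the per-module test, the package summarises collections
(percent significant per parameter, stratified e.g. by ontology
namespace or depth), compares classes by two-tailed KS on pooled
parameter distributions, and cross-classifies modules by network
significance versus conventional term over-representation (Fisher exact
with Benjamini–Hochberg correction on true-path-propagated annotations).

## Worked example

```python
from mcnet import (SynthSpec, generate_scaffold, plant_module,
                   make_signature_list, analyze_module)

scaffold = generate_scaffold(SynthSpec(n_nodes=1000, mean_degree=6, seed=1))
planted, scaffold = plant_module(scaffold, size=20, internal_density=0.4, seed=2)
random_list = make_signature_list(scaffold, size=20, seed=3)

for module in (planted, random_list):
    r = analyze_module(module, scaffold, allow_external=True, reps=1000, seed=4)
    print(module.module_id, r.p_degree, r.p_components, r.n_components)
```

prints (see `examples/02_enrichment_of_one_module.py` for the full script):

```
planted (functional), 20 mapped members:
  p_degree      = 6.08e-11
  p_components  = 0.004  (observed 1 components)
signature (signature), 20 mapped members:
  p_degree      = 0.994
  p_components  = 0.542  (observed 8 components)
```

The planted cohesive module forms a single component whose degrees sit
far above the resampling null (tiny p-values); the equally sized uniform
random list scatters into 8 components and is indistinguishable from
random expectation.  The `examples/` directory has one short script per
capability (MCN construction, single-module testing, collection
comparison, ORA cross-classification, and the shell pipeline via the
`mcnet` CLI: `simulate`, `analyze`, `compare`, `report`).

## Input formats

- scaffold: TSV `node_a TAB node_b [TAB evidence;evidence]`, `#` comments;
- modules: GMT (`id TAB description TAB member...`; the description may
  carry `key=value;...` attributes such as `class=`, `namespace=`);
- term systems: TSVs for the DAG (`child TAB parent`), annotations
  (`gene TAB term`) and namespaces (`term TAB namespace`);
- optional two-column identifier translation applied at load time.

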