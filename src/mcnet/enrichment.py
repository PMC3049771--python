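"""Empirical resampling nulls and per-module network-enrichment tests.

The null ("random expectation") for a list of N mapped members is built by
repeatedly drawing N scaffold nodes uniformly without replacement, inducing
their MCN with the same external-node mode as the observed analysis, and
pooling the node-level parameter values over all repetitions; component
counts are kept per repetition.  The observed node-level samples are then
compared against the pooled null with a one-sided two-sample
Kolmogorov-Smirnov test (alternative: observed stochastically greater),
and the observed component count against the null counts with a lower-tail
empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GeneModule, ScaffoldInteractome
from .network import PARAMETERS, UnmappableModuleError, build_mcn, node_params

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "EnrichmentResult",
    "NullCache",
    "null_cache_key",
    "sample_null",
    "ks_greater",
    "components_p",
    "analyze_module",
]

NODE_PARAMETERS = ("degree", "betweenness", "clustering")
CACHE_FORMAT = "mcnet-null-v1"


@dataclass
class NullDistribution:
    """Pooled node-level null samples and per-repetition component counts."""

    list_size: int
    allow_external: bool
    reps: int
    pooled: dict[str, np.ndarray]
    component_counts: np.ndarray
    seed: int

    def __eq__(self, other) -> bool:  # bit-for-bit, for determinism checks
        if not isinstance(other, NullDistribution):
            return NotImplemented
        return (
            (self.list_size, self.allow_external, self.reps, self.seed)
            == (other.list_size, other.allow_external, other.reps, other.seed)
            and all(np.array_equal(self.pooled[k], other.pooled[k]) for k in NODE_PARAMETERS)
            and np.array_equal(self.component_counts, other.component_counts)
        )


@dataclass
class EnrichmentResult:
    """Outcome of one module's network-enrichment analysis.

    All four p-values are one-sided: degree/betweenness/clustering test
    "greater than random expectation", components tests "fewer than random
    expectation".  ``skipped_reason`` is set (and p-values are None) when
    the module was not analysable (size window, no mapped members).
    """

    module_id: str
    collection: str = ""
    attrs: dict[str, str] = field(default_factory=dict)
    mapped_n: int = 0
    allow_external: bool = False
    p_degree: float | None = None
    p_betweenness: float | None = None
    p_clustering: float | None = None
    p_components: float | None = None
    significant: dict[str, bool] | None = None
    skipped_reason: str | None = None
    n_components: int | None = None
    # per-node observed values (node -> value), retained for pooled
    # class-vs-class comparisons; excluded from the per-module TSV
    node_values: dict[str, dict[str, float]] | None = None
    external_nodes: frozenset[str] = frozenset()
    unmapped_n: int = 0

    @property
    def p_values(self) -> dict[str, float] | None:
        if self.skipped_reason is not None:
            return None
        return {
            "degree": self.p_degree,
            "betweenness": self.p_betweenness,
            "clustering": self.p_clustering,
            "components": self.p_components,
        }


def sample_null(
    scaffold: ScaffoldInteractome,
    list_size: int,
    allow_external: bool,
    reps: int,
    seed: int,
    degree_matched: bool = False,
) -> NullDistribution:
    """Build the empirical null for lists of ``list_size`` mapped nodes.

    Each repetition draws ``list_size`` distinct nodes uniformly from the
    scaffold (or with probability proportional to scaffold degree when
    ``degree_matched`` — an off-by-default sensitivity option), induces the
    MCN with the requested external-node mode, and records the node-level
    parameters and the component count.  Bit-reproducible under ``seed``.
    """
    n_nodes = scaffold.n_nodes
    if not 1 <= list_size <= n_nodes:
        raise ValueError(f"list_size must be in [1, {n_nodes}], got {list_size}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = np.array(sorted(scaffold.graph.nodes))
    probs = None
    if degree_matched:
        deg = np.array([scaffold.graph.degree(n) for n in nodes], dtype=float)
        probs = deg / deg.sum()

    pooled: dict[str, list[np.ndarray]] = {p: [] for p in NODE_PARAMETERS}
    comp_counts = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        draw = rng.choice(nodes, size=list_size, replace=False, p=probs)
        mcn = build_mcn(set(draw.tolist()), scaffold, allow_external=allow_external)
        params = node_params(mcn)
        order = sorted(mcn.graph.nodes)
        pooled["degree"].append(np.array([params.degree[v] for v in order], dtype=float))
        pooled["betweenness"].append(
            np.array([params.rel_betweenness[v] for v in order], dtype=float)
        )
        pooled["clustering"].append(np.array([params.clustering[v] for v in order], dtype=float))
        comp_counts[r] = params.n_components
    return NullDistribution(
        list_size=list_size,
        allow_external=allow_external,
        reps=reps,
        pooled={p: np.concatenate(v) for p, v in pooled.items()},
        component_counts=comp_counts,
        seed=seed,
    )


def ks_greater(observed, null) -> float:
    """One-sided two-sample KS p-value, alternative "observed greater".

    D+ = sup_x [F_null(x) - F_obs(x)];  p = exp(-2 m D+^2) with
    m = |obs|*|null| / (|obs| + |null|), clipped to (0, 1].
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size == 0 or nul.size == 0:
        raise ValueError("ks_greater requires non-empty samples")
    obs_sorted = np.sort(obs)
    nul_sorted = np.sort(nul)
    xs = np.concatenate([obs_sorted, nul_sorted])
    f_obs = np.searchsorted(obs_sorted, xs, side="right") / obs.size
    f_nul = np.searchsorted(nul_sorted, xs, side="right") / nul.size
    d_plus = float(np.max(f_nul - f_obs))
    if d_plus <= 0:
        return 1.0
    m = obs.size * nul.size / (obs.size + nul.size)
    p = float(np.exp(-2.0 * m * d_plus**2))
    return float(min(1.0, max(p, np.finfo(float).tiny)))


def components_p(observed: int, null_counts) -> float:
    """Lower-tail empirical p for the component count, with add-one
    correction: p = (1 + #{null <= observed}) / (R + 1)."""
    counts = np.asarray(null_counts)
    if counts.size == 0:
        raise ValueError("components_p requires non-empty null counts")
    return float((1 + int(np.count_nonzero(counts <= observed))) / (counts.size + 1))


def null_cache_key(
    scaffold_hash: str, list_size: int, allow_external: bool, reps: int, seed: int
) -> str:
    """Deterministic cache key for one null configuration."""
    return f"{CACHE_FORMAT}_{scaffold_hash}_N{list_size}_ext{int(allow_external)}_R{reps}_s{seed}"


class NullCache:
    """Memoises null distributions by (scaffold, N, mode, reps, seed).

    In-memory always; persisted to ``directory`` as ``.npz`` when given,
    tagged with the cache format version.
    """

    def __init__(self, directory: str | Path | None = None):
        self.directory = Path(directory) if directory else None
        if self.directory:
            self.directory.mkdir(parents=True, exist_ok=True)
        self._mem: dict[str, NullDistribution] = {}
        self.hits = 0
        self.misses = 0

    def get_or_sample(
        self,
        scaffold: ScaffoldInteractome,
        list_size: int,
        allow_external: bool,
        reps: int,
        seed: int,
        degree_matched: bool = False,
    ) -> NullDistribution:
        key = null_cache_key(scaffold.content_hash(), list_size, allow_external, reps, seed)
        if degree_matched:
            key += "_degmatched"
        if key in self._mem:
            self.hits += 1
            logger.debug("null cache hit: %s", key)
            return self._mem[key]
        null = self._load(key, list_size, allow_external, reps, seed)
        if null is None:
            self.misses += 1
            null = sample_null(scaffold, list_size, allow_external, reps, seed, degree_matched)
            self._store(key, null)
        else:
            self.hits += 1
        self._mem[key] = null
        return null

    def _path(self, key: str) -> Path | None:
        return self.directory / f"{key}.npz" if self.directory else None

    def _load(self, key, list_size, allow_external, reps, seed) -> NullDistribution | None:
        path = self._path(key)
        if path is None or not path.exists():
            return None
        with np.load(path) as z:
            if str(z["format"]) != CACHE_FORMAT:
                return None
            return NullDistribution(
                list_size=list_size,
                allow_external=allow_external,
                reps=reps,
                pooled={p: z[p] for p in NODE_PARAMETERS},
                component_counts=z["component_counts"],
                seed=seed,
            )

    def _store(self, key: str, null: NullDistribution) -> None:
        path = self._path(key)
        if path is None:
            return
        np.savez(
            path,
            format=CACHE_FORMAT,
            component_counts=null.component_counts,
            **null.pooled,
        )


def analyze_module(
    module: GeneModule,
    scaffold: ScaffoldInteractome,
    allow_external: bool = True,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    size_min: int = 3,
    size_max: int = 200,
    cache: NullCache | None = None,
) -> EnrichmentResult:
    """Run the full network-enrichment test for one module.

    Modules whose mapped member count falls outside [size_min, size_max]
    are skipped (empirical nulls are unreliable outside this window), as
    are modules with no member on the scaffold.
    """
    base = dict(
        module_id=module.module_id,
        collection=module.collection,
        attrs=dict(module.attrs),
        allow_external=allow_external,
    )
    try:
        mcn = build_mcn(module.members, scaffold, allow_external=allow_external)
    except UnmappableModuleError:
        return EnrichmentResult(**base, skipped_reason="no members in scaffold")
    n = mcn.source_list_size
    if not size_min <= n <= size_max:
        return EnrichmentResult(
            **base,
            mapped_n=n,
            unmapped_n=len(mcn.unmapped),
            skipped_reason="size out of range",
        )
    params = node_params(mcn)
    if cache is not None:
        null = cache.get_or_sample(scaffold, n, allow_external, reps, seed)
    else:
        null = sample_null(scaffold, n, allow_external, reps, seed)

    obs = {
        "degree": np.array(list(params.degree.values()), dtype=float),
        "betweenness": np.array(list(params.rel_betweenness.values()), dtype=float),
        "clustering": np.array(list(params.clustering.values()), dtype=float),
    }
    p = {k: ks_greater(obs[k], null.pooled[k]) for k in NODE_PARAMETERS}
    p["components"] = components_p(params.n_components, null.component_counts)
    return EnrichmentResult(
        **base,
        mapped_n=n,
        unmapped_n=len(mcn.unmapped),
        p_degree=p["degree"],
        p_betweenness=p["betweenness"],
        p_clustering=p["clustering"],
        p_components=p["components"],
        significant={k: p[k] < alpha for k in PARAMETERS},
        n_components=params.n_components,
        node_values={
            "degree": {k: float(v) for k, v in params.degree.items()},
            "betweenness": dict(params.rel_betweenness),
            "clustering": dict(params.clustering),
        },
        external_nodes=mcn.external,
    )
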