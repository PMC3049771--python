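"""Batch analysis over module collections and cross-collection comparisons.

This layer reproduces the comparative questions asked of curated
functional modules (GO/KEGG/Biocarta-like), co-expression modules and
expression signatures: what fraction of each collection shows significant
network structure, how the pooled node-parameter distributions differ
between classes, how network significance relates to term
over-representation, and how properties vary with ontology depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import NODE_PARAMETERS, EnrichmentResult, NullCache, analyze_module
from .io import GeneModule, ScaffoldInteractome, TermAnnotation, term_level
from .network import PARAMETERS

logger = logging.getLogger(__name__)

__all__ = [
    "CollectionSummary",
    "ClassComparison",
    "analyze_collection",
    "summarize_collection",
    "pool_parameter",
    "compare_classes",
    "distribution_quartiles",
    "level_profile",
    "ora_fisher",
    "classify_modules",
]


@dataclass
class CollectionSummary:
    """Percent of analysed modules significant per parameter, Table-1-style."""

    collection: str
    n_analyzed: int
    n_skipped: int
    pct_significant: dict[str, float]  # NaN when n_analyzed == 0
    stratum: str | None = None


@dataclass
class ClassComparison:
    """Two-tailed KS comparison of pooled parameter values between classes."""

    class_a: str
    class_b: str
    parameter: str
    ks_p: float
    direction: str  # greater | less | none  (of class_a relative to class_b)


def analyze_collection(
    modules: list[GeneModule],
    scaffold: ScaffoldInteractome,
    allow_external: bool = True,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    size_min: int = 3,
    size_max: int = 200,
    cache: NullCache | None = None,
) -> list[EnrichmentResult]:
    """Analyse every module against a shared null cache (nulls are reused
    across modules with equal mapped size)."""
    cache = cache if cache is not None else NullCache()
    results = []
    for m in modules:
        r = analyze_module(
            m,
            scaffold,
            allow_external=allow_external,
            reps=reps,
            alpha=alpha,
            seed=seed,
            size_min=size_min,
            size_max=size_max,
            cache=cache,
        )
        results.append(r)
        logger.debug("analyzed %s: mapped_n=%d skipped=%s", m.module_id, r.mapped_n, r.skipped_reason)
    logger.info(
        "collection analysed: %d modules, %d null cache hits / %d misses",
        len(modules),
        cache.hits,
        cache.misses,
    )
    return results


def summarize_collection(
    results: list[EnrichmentResult],
    alpha: float = 0.05,
    stratify_by: str | None = None,
) -> list[CollectionSummary]:
    """Percent of non-skipped modules with p < alpha, per parameter,
    overall or per stratum of a module attribute."""
    collection = results[0].collection if results else ""

    def stratum_of(r: EnrichmentResult) -> str | None:
        if stratify_by is None:
            return None
        return r.attrs.get(stratify_by, "NA")

    strata = sorted({stratum_of(r) for r in results}, key=lambda s: (s is None, s))
    out = []
    for s in strata:
        rs = [r for r in results if stratum_of(r) == s]
        analyzed = [r for r in rs if r.skipped_reason is None]
        if analyzed:
            pct = {
                p: 100.0 * sum(r.p_values[p] < alpha for r in analyzed) / len(analyzed)
                for p in PARAMETERS
            }
        else:
            pct = {p: float("nan") for p in PARAMETERS}
        out.append(
            CollectionSummary(
                collection=collection,
                n_analyzed=len(analyzed),
                n_skipped=len(rs) - len(analyzed),
                pct_significant=pct,
                stratum=s,
            )
        )
    return out


def pool_parameter(results: list[EnrichmentResult], parameter: str) -> np.ndarray:
    """Concatenate node-level values of one parameter across all analysed
    modules of a class (``components`` pools the per-module counts)."""
    values: list[float] = []
    for r in results:
        if r.skipped_reason is not None:
            continue
        if parameter == "components":
            values.append(float(r.n_components))
        else:
            if r.node_values is None:
                raise ValueError(f"module {r.module_id}: node values not retained")
            values.extend(r.node_values[parameter].values())
    if not values:
        raise ValueError(f"no node-level values available for parameter {parameter!r}")
    return np.array(values, dtype=float)


def compare_classes(
    pool_a,
    pool_b,
    class_a: str = "a",
    class_b: str = "b",
    parameter: str = "",
    alpha: float = 0.05,
) -> ClassComparison:
    """Two-sample two-tailed KS between pooled distributions; the reported
    direction is where class_a's median sits relative to class_b's when
    the difference is significant."""
    a = np.asarray(pool_a, dtype=float)
    b = np.asarray(pool_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both pools must be non-empty")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    p = float(ks.pvalue)
    direction = "none"
    if p < alpha:
        med_a, med_b = np.median(a), np.median(b)
        if med_a > med_b:
            direction = "greater"
        elif med_a < med_b:
            direction = "less"
        else:  # medians tie on heavily discrete pools; fall back to means
            direction = "greater" if a.mean() > b.mean() else "less"
    return ClassComparison(class_a, class_b, parameter, p, direction)


def distribution_quartiles(pools: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Quartile table (boxplot-as-data) per class and parameter:
    ``pools[class][parameter] -> values``."""
    rows = []
    for cls, by_param in sorted(pools.items()):
        for param, vals in sorted(by_param.items()):
            v = np.asarray(vals, dtype=float)
            q1, q2, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "class": cls,
                    "parameter": param,
                    "n": v.size,
                    "min": v.min(),
                    "q1": q1,
                    "median": q2,
                    "q3": q3,
                    "max": v.max(),
                    "mean": v.mean(),
                }
            )
    return pd.DataFrame(rows)


def level_profile(
    results: list[EnrichmentResult],
    ann: TermAnnotation,
    alpha: float = 0.05,
    min_modules: int = 3,
) -> pd.DataFrame:
    """Aggregate network properties by ontology depth of the module's term.

    Each result's module_id must be a term in ``ann``.  Per level we report
    the mean node-level parameter values, the mean component count, and the
    percent of modules significant per parameter; levels supported by fewer
    than ``min_modules`` modules are flagged ``low_support``.
    """
    rows = []
    for r in results:
        if r.skipped_reason is not None:
            continue
        lvl = term_level(ann, r.module_id)
        row = {"level": lvl, "module_id": r.module_id, "components": r.n_components}
        for p in NODE_PARAMETERS:
            row[f"mean_{p}"] = float(np.mean(list(r.node_values[p].values())))
            row[f"sig_{p}"] = r.p_values[p] < alpha
        row["sig_components"] = r.p_values["components"] < alpha
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["level", "n_modules", "low_support"]
        )
    df = pd.DataFrame(rows)
    agg = {"module_id": ("module_id", "count"), "mean_components": ("components", "mean")}
    for p in NODE_PARAMETERS:
        agg[f"mean_{p}"] = (f"mean_{p}", "mean")
        agg[f"pct_sig_{p}"] = (f"sig_{p}", lambda s: 100.0 * s.mean())
    agg["pct_sig_components"] = ("sig_components", lambda s: 100.0 * s.mean())
    out = df.groupby("level").agg(**agg).rename(columns={"module_id": "n_modules"}).reset_index()
    out["low_support"] = out["n_modules"] < min_modules
    return out


def ora_fisher(
    members: set[str] | frozenset[str],
    term2genes: dict[str, set[str]],
    background: set[str],
) -> dict[str, tuple[float, float]]:
    """Term over-representation analysis on propagated annotations.

    One-sided Fisher exact p per term (hypergeometric upper tail on the
    2x2 table of module/term membership within the background universe),
    Benjamini-Hochberg q across the tested terms.  Terms with no annotated
    gene in the background are skipped.
    """
    members = set(members)
    if not members <= background:
        raise ValueError("module members must be a subset of the background universe")
    M = len(background)
    n = len(members)
    terms, pvals = [], []
    for term, genes in sorted(term2genes.items()):
        K = len(genes & background)
        if K == 0:
            continue
        k = len(members & genes)
        # P[X >= k], X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        terms.append(term)
        pvals.append(min(1.0, p))
    qvals = _benjamini_hochberg(np.array(pvals)) if pvals else np.array([])
    return {t: (p, float(q)) for t, p, q in zip(terms, pvals, qvals)}


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def classify_modules(
    net_results: list[EnrichmentResult],
    ora_results: dict[str, dict[str, tuple[float, float]]],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Cross-classify modules by network significance vs term
    over-representation: only_net / only_go / net_and_go / nothing.

    A module is net-significant when any of the four network parameters
    has p < alpha; go-significant when any term reaches q < alpha.
    """
    net_ids = {r.module_id for r in net_results}
    if net_ids != set(ora_results):
        missing = net_ids.symmetric_difference(ora_results)
        raise ValueError(f"module sets differ between inputs: {sorted(missing)[:5]}")
    labels: dict[str, str] = {}
    for r in net_results:
        net_sig = r.p_values is not None and any(p < alpha for p in r.p_values.values())
        go_sig = any(q < alpha for _, q in ora_results[r.module_id].values())
        if net_sig and go_sig:
            labels[r.module_id] = "net_and_go"
        elif net_sig:
            labels[r.module_id] = "only_net"
        elif go_sig:
            labels[r.module_id] = "only_go"
        else:
            labels[r.module_id] = "nothing"
    return labels
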