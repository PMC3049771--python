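import numpy as np
import pytest

from mcnet import (
    EnrichmentResult,
    TermAnnotation,
    classify_modules,
    compare_classes,
    distribution_quartiles,
    level_profile,
    ora_fisher,
    pool_parameter,
    summarize_collection,
)

from oracles import brute_ks_d, hypergeom_upper_tail


def result(
    module_id,
    p=0.5,
    collection="c",
    attrs=None,
    skipped=None,
    degrees=(1.0, 2.0),
    n_components=2,
):
    if skipped:
        return EnrichmentResult(
            module_id=module_id, collection=collection, attrs=attrs or {}, skipped_reason=skipped
        )
    return EnrichmentResult(
        module_id=module_id,
        collection=collection,
        attrs=attrs or {},
        mapped_n=len(degrees),
        p_degree=p,
        p_betweenness=p,
        p_clustering=p,
        p_components=p,
        significant={k: p < 0.05 for k in ("degree", "betweenness", "clustering", "components")},
        n_components=n_components,
        node_values={
            "degree": {f"n{i}": d for i, d in enumerate(degrees)},
            "betweenness": {f"n{i}": 0.0 for i in range(len(degrees))},
            "clustering": {f"n{i}": 0.0 for i in range(len(degrees))},
        },
    )


# --- summaries -------------------------------------------------------------


def test_percent_significant_arithmetic():
    rs = [result(f"m{i}", p=0.01 if i < 4 else 0.5) for i in range(10)]
    (s,) = summarize_collection(rs, alpha=0.05)
    assert s.n_analyzed == 10 and s.n_skipped == 0
    assert s.pct_significant["degree"] == pytest.approx(40.0)


def test_stratified_summary_rows():
    rs = [
        result(f"m{i}", p=0.01, attrs={"namespace": ns})
        for i, ns in enumerate(["BP", "MF", "CC", "BP"])
    ]
    out = summarize_collection(rs, alpha=0.05, stratify_by="namespace")
    assert [s.stratum for s in out] == ["BP", "CC", "MF"]
    assert [s.n_analyzed for s in out] == [2, 1, 1]


def test_all_skipped_gives_nan_percentages():
    rs = [result("m0", skipped="size out of range")]
    (s,) = summarize_collection(rs)
    assert s.n_analyzed == 0 and s.n_skipped == 1
    assert all(np.isnan(v) for v in s.pct_significant.values())


def test_skipped_modules_excluded_from_percentages():
    rs = [result("m0", p=0.01), result("m1", skipped="no members in scaffold")]
    (s,) = summarize_collection(rs)
    assert s.n_analyzed == 1 and s.n_skipped == 1
    assert s.pct_significant["degree"] == 100.0


# --- pooling and class comparison ------------------------------------------


def test_pool_concatenates_node_values():
    rs = [result("a", degrees=(1.0, 2.0)), result("b", degrees=(3.0,))]
    assert sorted(pool_parameter(rs, "degree")) == [1.0, 2.0, 3.0]
    assert pool_parameter([rs[0]], "degree").tolist() == [1.0, 2.0]
    assert pool_parameter(rs, "components").tolist() == [2.0, 2.0]


def test_pool_empty_class_errors():
    with pytest.raises(ValueError):
        pool_parameter([result("a", skipped="size out of range")], "degree")


def test_identical_pools_compare_as_none():
    x = np.arange(50.0)
    c = compare_classes(x, x, "a", "b", "degree")
    assert c.ks_p > 0.9999
    assert c.direction == "none"


def test_shifted_pool_compares_greater():
    x = np.arange(100.0)
    c = compare_classes(x + 200, x, "a", "b", "degree")  # disjoint supports: D = 1
    assert c.ks_p < 1e-6
    assert c.direction == "greater"
    assert compare_classes(x, x + 200, "a", "b", "degree").direction == "less"


def test_comparison_p_symmetric():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=60), rng.normal(0.4, size=45)
    assert compare_classes(a, b).ks_p == pytest.approx(compare_classes(b, a).ks_p, rel=1e-12)


def test_two_sided_d_matches_sweep_oracle():
    from scipy import stats

    a = [float(i) for i in range(1, 51)]
    b = [float(i) for i in range(26, 76)]
    d = stats.ks_2samp(a, b).statistic
    assert d == pytest.approx(brute_ks_d(a, b), abs=1e-12)
    assert brute_ks_d(a, b) == pytest.approx(0.5)


def test_quartile_table_shape():
    pools = {"functional": {"degree": np.arange(9.0)}, "signature": {"degree": np.zeros(5)}}
    df = distribution_quartiles(pools)
    assert set(df["class"]) == {"functional", "signature"}
    row = df[df["class"] == "functional"].iloc[0]
    assert row["median"] == 4.0 and row["q1"] == 2.0 and row["q3"] == 6.0


# --- level profile ---------------------------------------------------------


def make_ann():
    return TermAnnotation(
        dag_edges={("t1", "root"), ("t2", "root"), ("t3", "t1")},
        gene2terms={},
    )


def test_level_profile_groups_by_depth():
    rs = [
        result("t1", p=0.01, degrees=(2.0, 2.0)),
        result("t2", p=0.5, degrees=(4.0, 4.0)),
        result("t3", p=0.01, degrees=(6.0,)),
    ]
    df = level_profile(rs, make_ann(), alpha=0.05)
    assert df["level"].tolist() == [1, 2]
    lvl1 = df[df["level"] == 1].iloc[0]
    assert lvl1["n_modules"] == 2
    assert lvl1["mean_degree"] == pytest.approx(3.0)
    assert lvl1["pct_sig_degree"] == pytest.approx(50.0)
    assert bool(lvl1["low_support"])


def test_level_profile_identical_modules_at_two_levels_match():
    rs = [result("t1", p=0.01, degrees=(5.0, 5.0)), result("t3", p=0.01, degrees=(5.0, 5.0))]
    df = level_profile(rs, make_ann())
    cols = ["n_modules", "mean_degree", "pct_sig_degree", "mean_components"]
    assert df.loc[0, cols].tolist() == df.loc[1, cols].tolist()


def test_level_profile_empty_input():
    assert level_profile([], make_ann()).empty


# --- ORA and cross-classification ------------------------------------------


def test_ora_matches_hypergeometric_tail():
    background = {f"g{i}" for i in range(100)}
    term_genes = set(list(sorted(background))[:10])
    members = set(list(sorted(term_genes))[:5]) | {f"g{i}" for i in range(90, 95)}
    out = ora_fisher(members, {"T": term_genes}, background)
    p, q = out["T"]
    assert p == pytest.approx(hypergeom_upper_tail(5, 100, 10, 10), rel=1e-9)
    assert q == pytest.approx(p)  # single term: BH is identity


def test_ora_term_covering_background_is_one():
    background = {f"g{i}" for i in range(30)}
    out = ora_fisher(set(list(background)[:8]), {"T": set(background)}, background)
    assert out["T"][0] == pytest.approx(1.0)


def test_ora_module_exactly_matching_term_is_minimal_p():
    background = {f"g{i}" for i in range(50)}
    members = {f"g{i}" for i in range(10)}
    out = ora_fisher(members, {"T": set(members)}, background)
    assert out["T"][0] == pytest.approx(hypergeom_upper_tail(10, 50, 10, 10), rel=1e-9)


def test_ora_skips_terms_absent_from_background():
    background = {"a", "b", "c"}
    out = ora_fisher({"a"}, {"T": {"zz"}}, background)
    assert out == {}


def test_ora_requires_members_in_background():
    with pytest.raises(ValueError):
        ora_fisher({"outsider"}, {"T": {"a"}}, {"a", "b"})


def test_classification_four_way():
    net = [
        result("m_both", p=0.01),
        result("m_net", p=0.01),
        result("m_go", p=0.9),
        result("m_none", p=0.9),
        result("m_skip", skipped="size out of range"),
    ]
    ora = {
        "m_both": {"T": (0.001, 0.001)},
        "m_net": {"T": (0.9, 0.9)},
        "m_go": {"T": (0.001, 0.001)},
        "m_none": {"T": (0.9, 0.9)},
        "m_skip": {"T": (0.001, 0.001)},
    }
    labels = classify_modules(net, ora, alpha=0.05)
    assert labels == {
        "m_both": "net_and_go",
        "m_net": "only_net",
        "m_go": "only_go",
        "m_none": "nothing",
        "m_skip": "only_go",  # no network p-values: only the ORA verdict applies
    }


def test_classification_requires_matching_module_sets():
    with pytest.raises(ValueError):
        classify_modules([result("a")], {"b": {"T": (0.5, 0.5)}})
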