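import networkx as nx
import numpy as np
import pytest

from mcnet import (
    SynthSpec,
    build_mcn,
    generate_benchmark_collection,
    generate_scaffold,
    load_modules,
    make_linker_module,
    make_signature_list,
    plant_module,
    propagate_annotations,
    write_benchmark,
    write_modules,
)


def spec(**kw):
    defaults = dict(n_nodes=100, mean_degree=4.0, seed=0)
    defaults.update(kw)
    return SynthSpec(**defaults)


# --- scaffold generation ---------------------------------------------------


def test_scaffold_edge_count_near_expectation():
    for model in ("preferential_attachment", "erdos_renyi"):
        counts = [
            generate_scaffold(spec(model=model, seed=s)).n_edges for s in range(20)
        ]
        assert abs(np.mean(counts) - 200) <= 20  # within 10% of n*d/2


def test_scaffold_deterministic_under_seed():
    a = generate_scaffold(spec(seed=3))
    b = generate_scaffold(spec(seed=3))
    assert a.content_hash() == b.content_hash()
    assert {frozenset(e): a.evidence(*e) for e in a.edges()} == {
        frozenset(e): b.evidence(*e) for e in b.edges()
    }
    assert generate_scaffold(spec(seed=4)).content_hash() != a.content_hash()


def test_preferential_attachment_is_heavier_tailed_than_er():
    def degvar(model):
        return np.mean(
            [
                np.var([d for _, d in generate_scaffold(spec(model=model, seed=s)).graph.degree()])
                for s in range(10)
            ]
        )

    assert degvar("preferential_attachment") > degvar("erdos_renyi")


def test_evidence_fraction_controls_filter_survival():
    sc = generate_scaffold(spec(n_nodes=300, high_evidence_fraction=0.5, seed=1))
    n_high = sum(1 for u, v in sc.edges() if len(sc.evidence(u, v)) >= 2)
    frac = n_high / sc.n_edges
    assert 0.35 < frac < 0.65


def test_infeasible_spec_rejected():
    with pytest.raises(ValueError):
        generate_scaffold(spec(mean_degree=200))
    with pytest.raises(ValueError):
        SynthSpec(internal_density=0.0).validate()
    with pytest.raises(ValueError):
        SynthSpec(module_size=2).validate()


# --- planted modules -------------------------------------------------------


def test_full_density_plants_a_clique():
    sc = generate_scaffold(spec(seed=2))
    mod, sc = plant_module(sc, 10, 1.0, seed=5)
    sub = sc.graph.subgraph(mod.members)
    assert sub.number_of_edges() == 45
    assert mod.collection == "functional"


def test_planting_at_existing_density_adds_nothing():
    sc = generate_scaffold(spec(seed=2))
    mod, sc = plant_module(sc, 10, 1.0, seed=5)
    before = sc.n_edges
    _, sc = plant_module(sc, 10, 1.0, seed=99, members=set(mod.members))
    assert sc.n_edges == before


def test_planted_edges_survive_evidence_filter():
    sc = generate_scaffold(spec(seed=2))
    mod, sc = plant_module(sc, 8, 1.0, seed=5)
    for u, v in sc.graph.subgraph(mod.members).edges():
        assert len(sc.evidence(u, v)) >= 2


def test_planted_internal_degree_exceeds_scaffold_mean():
    sc = generate_scaffold(spec(n_nodes=500, mean_degree=4, seed=8))
    mod, sc = plant_module(sc, 20, 0.5, seed=9)
    internal = sc.graph.subgraph(mod.members)
    mean_internal = 2 * internal.number_of_edges() / 20
    assert mean_internal > 4  # density*(size-1) = 9.5 >> scaffold mean degree


def test_planted_denser_than_signatures_on_average():
    dens_f, dens_s = [], []
    for s in range(50):
        sc = generate_scaffold(spec(n_nodes=200, seed=s))
        mod, sc = plant_module(sc, 12, 0.3, seed=1000 + s)
        sig = make_signature_list(sc, 12, seed=2000 + s)
        for members, acc in ((mod.members, dens_f), (sig.members, dens_s)):
            sub = sc.graph.subgraph(members)
            acc.append(sub.number_of_edges() / 66)
    assert np.mean(dens_f) > np.mean(dens_s)


# --- signatures ------------------------------------------------------------


def test_signature_sampling_contracts():
    sc = generate_scaffold(spec(seed=1))
    full = make_signature_list(sc, 100, seed=0)
    assert full.members == sc.nodes
    a = make_signature_list(sc, 10, seed=1)
    assert a.members == make_signature_list(sc, 10, seed=1).members
    different = sum(
        make_signature_list(sc, 10, seed=i).members != a.members for i in range(2, 12)
    )
    assert different == 10  # collision probability is negligible


# --- linker modules --------------------------------------------------------


def test_linker_module_rescued_only_by_its_hub():
    sc = generate_scaffold(spec(seed=6))
    mod = make_linker_module(sc, clique_size=6, module_id="L")
    hub = mod.attrs["linker"]
    base = build_mcn(mod.members, sc, allow_external=False)
    assert base.n_components == 2
    ext = build_mcn(mod.members, sc, allow_external=True)
    assert ext.n_components == 1
    assert ext.external == {hub}
    sc.graph.remove_node(hub)
    again = build_mcn(mod.members, sc, allow_external=True)
    assert again.n_components == 2


# --- benchmark collection --------------------------------------------------


def test_benchmark_collection_contracts(small_benchmark):
    bench = small_benchmark
    classes = [m.attrs["class"] for m in bench.modules]
    assert classes.count("functional") == 5
    assert classes.count("signature") == 5
    assert classes.count("linker") == 1
    assert len({m.module_id for m in bench.modules}) == len(bench.modules)
    # every functional module's term contains its members after propagation
    term2genes = propagate_annotations(bench.annotation)
    for m in bench.modules:
        if m.collection == "functional":
            assert m.members <= term2genes[f"T:{m.module_id}"]
            assert m.members <= term2genes["T:root"]


def test_benchmark_requested_counts():
    bench = generate_benchmark_collection(
        SynthSpec(n_nodes=200, mean_degree=4, module_size=8, n_modules_per_class=20, seed=3)
    )
    assert len(bench.modules) == 40


def test_benchmark_reproducible():
    s = SynthSpec(n_nodes=150, mean_degree=4, module_size=6, n_modules_per_class=3, seed=11)
    a = generate_benchmark_collection(s)
    b = generate_benchmark_collection(s)
    assert a.scaffold.content_hash() == b.scaffold.content_hash()
    assert [(m.module_id, m.members) for m in a.modules] == [
        (m.module_id, m.members) for m in b.modules
    ]


def test_class_labels_roundtrip_through_gmt(tmp_path, small_benchmark):
    path = tmp_path / "mods.gmt"
    write_modules(small_benchmark.modules, path)
    back = load_modules(path)
    assert [(m.module_id, m.members, m.attrs["class"]) for m in back] == [
        (m.module_id, m.members, m.attrs["class"]) for m in small_benchmark.modules
    ]


def test_benchmark_files_parse_back(tmp_path, small_benchmark):
    from mcnet import load_interactome, load_term_annotations

    paths = write_benchmark(small_benchmark, tmp_path)
    sc = load_interactome(paths["scaffold"])
    assert sc.content_hash() == small_benchmark.scaffold.content_hash()
    mods = load_modules(paths["modules"])
    assert len(mods) == len(small_benchmark.modules)
    ann = load_term_annotations(paths["dag"], paths["annotations"], paths["namespaces"])
    assert ann.roots == {"T:root"}
    assert ann.dag_edges == small_benchmark.annotation.dag_edges
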