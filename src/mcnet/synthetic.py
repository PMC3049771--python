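"""Synthetic scaffolds and module collections with known ground truth.

Real interactome releases and module databases drift; every pipeline
stage is therefore exercised on generated data that emulates their
statistical structure: a sparse heavy-tailed scaffold (preferential
attachment by default; Erdos-Renyi for calibration settings where the
uniform null is exact), cohesive "functional" modules planted with
elevated internal edge density, unstructured uniform "signature" lists,
and modules whose two halves are reconnectable only through one
non-member hub (the external-linker scenario).

Defaults mirror a genome-scale PPI scaffold at desk scale: 2,000 nodes
with mean degree 8 (the order of magnitude of curated human interactomes,
~9.5k proteins / ~37k interactions), half of the edges carrying two
evidence categories so a filtered scaffold remains usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    GeneModule,
    ScaffoldInteractome,
    TermAnnotation,
    write_interactome,
    write_modules,
)

__all__ = [
    "SynthSpec",
    "Benchmark",
    "generate_scaffold",
    "plant_module",
    "make_signature_list",
    "make_linker_module",
    "generate_benchmark_collection",
    "write_benchmark",
]

EVIDENCE_CATEGORIES = ("y2h", "coip", "in_vitro", "in_vivo", "ms", "xray")


@dataclass
class SynthSpec:
    """Parameters of one synthetic benchmark.

    mean_degree is the target average scaffold degree (edges ~ n*d/2);
    internal_density is the planted modules' induced edge density in
    (0, 1]; high_evidence_fraction is the fraction of scaffold edges
    tagged with two evidence categories (the rest get one), controlling
    how much survives the filtered-scaffold rule.
    """

    n_nodes: int = 2000
    mean_degree: float = 8.0
    model: str = "preferential_attachment"  # or "erdos_renyi"
    module_size: int = 20
    internal_density: float = 0.3
    n_modules_per_class: int = 20
    n_linker_modules: int = 0
    linker_clique_size: int = 6
    high_evidence_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if not 1 <= self.mean_degree < self.n_nodes:
            raise ValueError("mean_degree must be in [1, n_nodes)")
        if self.model not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown scaffold model: {self.model!r}")
        if not 0 < self.internal_density <= 1:
            raise ValueError("internal_density must be in (0, 1]")
        if self.module_size < 3:
            raise ValueError("module_size must be >= 3")
        if not 0 <= self.high_evidence_fraction <= 1:
            raise ValueError("high_evidence_fraction must be in [0, 1]")


@dataclass
class Benchmark:
    """A scaffold plus labelled modules and an aligned term system."""

    scaffold: ScaffoldInteractome
    modules: list[GeneModule]
    annotation: TermAnnotation
    spec: SynthSpec = field(default_factory=SynthSpec)


def _node_name(i: int) -> str:
    return f"g{i:05d}"


def generate_scaffold(spec: SynthSpec) -> ScaffoldInteractome:
    """Generate a simple scaffold of the requested size and model, with
    evidence tags; deterministic under ``spec.seed``."""
    spec.validate()
    m = max(1, round(spec.mean_degree / 2))
    if spec.model == "preferential_attachment":
        g0 = nx.barabasi_albert_graph(spec.n_nodes, m, seed=spec.seed)
    else:
        n_edges = round(spec.n_nodes * spec.mean_degree / 2)
        g0 = nx.gnm_random_graph(spec.n_nodes, n_edges, seed=spec.seed)
    g = nx.relabel_nodes(g0, {i: _node_name(i) for i in g0.nodes})

    rng = np.random.default_rng(spec.seed)
    cats = np.array(EVIDENCE_CATEGORIES)
    for u, v in sorted(g.edges()):
        if rng.random() < spec.high_evidence_fraction:
            ev = frozenset(rng.choice(cats, size=2, replace=False).tolist())
        else:
            ev = frozenset([str(rng.choice(cats))])
        g.edges[u, v]["evidence"] = ev
    return ScaffoldInteractome(g, filtered=False)


def plant_module(
    scaffold: ScaffoldInteractome,
    size: int,
    internal_density: float,
    seed: int,
    module_id: str = "planted",
    members: set[str] | None = None,
) -> tuple[GeneModule, ScaffoldInteractome]:
    """Plant a cohesive module: choose ``size`` nodes and add internal
    edges (two evidence tags each, so they survive filtering) until the
    induced density reaches the target.  Modifies the scaffold in place
    and returns it alongside the module.
    """
    g = scaffold.graph
    if size > g.number_of_nodes():
        raise ValueError("module size exceeds scaffold size")
    rng = np.random.default_rng(seed)
    if members is None:
        chosen = sorted(rng.choice(sorted(g.nodes), size=size, replace=False).tolist())
    else:
        chosen = sorted(members)
    n_pairs = size * (size - 1) // 2
    target = ceil(internal_density * n_pairs)
    if target > n_pairs:
        raise ValueError("internal density target unreachable")
    missing = [
        (a, b)
        for i, a in enumerate(chosen)
        for b in chosen[i + 1 :]
        if not g.has_edge(a, b)
    ]
    existing = n_pairs - len(missing)
    if existing < target:
        idx = rng.choice(len(missing), size=target - existing, replace=False)
        cats = np.array(EVIDENCE_CATEGORIES)
        for i in idx:
            a, b = missing[i]
            ev = frozenset(rng.choice(cats, size=2, replace=False).tolist())
            g.add_edge(a, b, evidence=ev)
    module = GeneModule(
        module_id=module_id,
        members=frozenset(chosen),
        collection="functional",
        attrs={"class": "functional"},
    )
    return module, scaffold


def make_signature_list(
    scaffold: ScaffoldInteractome, size: int, seed: int, module_id: str = "signature"
) -> GeneModule:
    """A uniform random gene list — the unstructured, signature-like class."""
    g = scaffold.graph
    if size > g.number_of_nodes():
        raise ValueError("signature size exceeds scaffold size")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sorted(g.nodes), size=size, replace=False).tolist()
    return GeneModule(
        module_id=module_id,
        members=frozenset(chosen),
        collection="signature",
        attrs={"class": "signature"},
    )


def make_linker_module(
    scaffold: ScaffoldInteractome,
    clique_size: int,
    seed: int = 0,
    module_id: str = "linker",
) -> GeneModule:
    """A module whose connectivity is restored only by one external node.

    Adds 2*clique_size fresh member nodes plus one fresh hub to the
    scaffold: two cliques with no edge between them, each attached to the
    hub.  The module lists the clique members only, so its base MCN has
    exactly two components while the extended MCN is one component with
    the hub flagged external.  The ground-truth hub is recorded in attrs.
    """
    del seed  # construction is fully deterministic; kept for API symmetry
    g = scaffold.graph
    cats = (EVIDENCE_CATEGORIES[0], EVIDENCE_CATEGORIES[1])
    cliques = []
    hub = f"{module_id}_hub"
    for side in ("a", "b"):
        nodes = [f"{module_id}_{side}{i}" for i in range(clique_size)]
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                g.add_edge(u, v, evidence=frozenset(cats))
        g.add_edge(hub, nodes[0], evidence=frozenset(cats))
        cliques.append(nodes)
    return GeneModule(
        module_id=module_id,
        members=frozenset(cliques[0] + cliques[1]),
        collection="linker",
        attrs={"class": "linker", "linker": hub},
    )


def generate_benchmark_collection(spec: SynthSpec) -> Benchmark:
    """Scaffold + mixed labelled collection + aligned GO-like term system.

    Functional modules are planted dense subgraphs; each gets a term
    (child of a class term, grandchild of the root) whose direct
    annotations are the module's members, so ORA and the network/ORA
    cross-classification are testable against planted truth.
    """
    spec.validate()
    scaffold = generate_scaffold(spec)
    seed_rng = np.random.default_rng(spec.seed)
    seeds = seed_rng.integers(0, 2**31, size=2 * spec.n_modules_per_class + 1)

    modules: list[GeneModule] = []
    dag_edges = {("T:functional", "T:root")}
    gene2terms: dict[str, set[str]] = {}
    namespaces = {"T:root": "biological_process", "T:functional": "biological_process"}
    for i in range(spec.n_modules_per_class):
        mod, _ = plant_module(
            scaffold,
            spec.module_size,
            spec.internal_density,
            seed=int(seeds[i]),
            module_id=f"func{i:03d}",
        )
        term = f"T:{mod.module_id}"
        dag_edges.add((term, "T:functional"))
        namespaces[term] = "biological_process"
        for gene in mod.members:
            gene2terms.setdefault(gene, set()).add(term)
        modules.append(mod)
    for i in range(spec.n_modules_per_class):
        modules.append(
            make_signature_list(
                scaffold,
                spec.module_size,
                seed=int(seeds[spec.n_modules_per_class + i]),
                module_id=f"sig{i:03d}",
            )
        )
    for i in range(spec.n_linker_modules):
        modules.append(
            make_linker_module(
                scaffold, spec.linker_clique_size, module_id=f"link{i:03d}"
            )
        )
    ann = TermAnnotation(dag_edges, gene2terms, namespaces)
    return Benchmark(scaffold=scaffold, modules=modules, annotation=ann, spec=spec)


def write_benchmark(bench: Benchmark, directory: str | Path) -> dict[str, Path]:
    """Serialise a benchmark to the formats the loaders read back."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "scaffold": d / "scaffold.tsv",
        "modules": d / "modules.gmt",
        "dag": d / "dag.tsv",
        "annotations": d / "annotations.tsv",
        "namespaces": d / "namespaces.tsv",
    }
    write_interactome(bench.scaffold, paths["scaffold"])
    write_modules(bench.modules, paths["modules"])
    with open(paths["dag"], "w", encoding="utf-8") as fh:
        for child, parent in sorted(bench.annotation.dag_edges):
            fh.write(f"{child}\t{parent}\n")
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        for gene in sorted(bench.annotation.gene2terms):
            for term in sorted(bench.annotation.gene2terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(paths["namespaces"], "w", encoding="utf-8") as fh:
        for term in sorted(bench.annotation.namespaces):
            fh.write(f"{term}\t{bench.annotation.namespaces[term]}\n")
    return paths
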