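"""Minimal connected networks and the four node/graph statistics.

A gene list is mapped onto the scaffold interactome and induces its
minimal connected network (MCN): the scaffold subgraph over the mapped
members.  The extended MCN additionally admits *external* (linker) nodes —
scaffold proteins outside the list that are adjacent to at least two
mapped members — to compensate for incomplete lists.

Per node we measure connection degree, local clustering coefficient
C(v) = e_n / (n_v (n_v - 1) / 2) and relative betweenness centrality
rC_B(v) = C_B(v) / ((n-1)(n-2)/2) with unit edge weights, where n is the
total number of MCN nodes; per graph we count connected components
(singleton members included).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io import ScaffoldInteractome

__all__ = [
    "UnmappableModuleError",
    "MinimalConnectedNetwork",
    "NodeParams",
    "build_mcn",
    "connection_degree",
    "clustering_coefficient",
    "betweenness",
    "count_components",
    "node_params",
]

PARAMETERS = ("degree", "betweenness", "clustering", "components")


class UnmappableModuleError(ValueError):
    """No module member maps onto the scaffold."""


@dataclass
class MinimalConnectedNetwork:
    graph: nx.Graph
    external: frozenset[str] = frozenset()
    source_list_size: int = 0  # mapped member count N
    unmapped: frozenset[str] = frozenset()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def members(self) -> set[str]:
        return set(self.graph.nodes) - self.external

    @property
    def n_components(self) -> int:
        return count_components(self)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "MinimalConnectedNetwork":
        """Wrap an arbitrary simple graph (no externals) for direct use of
        the statistics functions."""
        return cls(graph=graph, source_list_size=graph.number_of_nodes())


@dataclass
class NodeParams:
    """The three per-node maps (identical key sets) plus the component count."""

    degree: dict[str, int]
    clustering: dict[str, float]
    rel_betweenness: dict[str, float]
    n_components: int

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            "degree": self.degree,
            "clustering": self.clustering,
            "betweenness": self.rel_betweenness,
        }


def build_mcn(
    members: set[str] | frozenset[str],
    scaffold: ScaffoldInteractome,
    allow_external: bool = False,
) -> MinimalConnectedNetwork:
    """Map ``members`` onto the scaffold and induce their MCN.

    Base mode: the subgraph induced by the mapped members (isolated
    members stay as singleton components).  Extended mode: every scaffold
    node outside the list adjacent to >=2 distinct mapped members is added
    as a flagged external linker, and the subgraph induced by
    members+linkers is returned.
    """
    if not members:
        raise ValueError("empty member set")
    g = scaffold.graph
    mapped = {m for m in members if m in g}
    if not mapped:
        raise UnmappableModuleError("no members map onto the scaffold")
    unmapped = frozenset(set(members) - mapped)

    external: set[str] = set()
    if allow_external:
        counts: dict[str, int] = {}
        for m in mapped:
            for nb in g.adj[m]:
                if nb not in mapped:
                    counts[nb] = counts.get(nb, 0) + 1
        external = {n for n, c in counts.items() if c >= 2}

    sub = g.subgraph(mapped | external).copy()
    # strip evidence payloads; the MCN is pure topology
    for _, _, d in sub.edges(data=True):
        d.clear()
    return MinimalConnectedNetwork(
        graph=sub,
        external=frozenset(external),
        source_list_size=len(mapped),
        unmapped=unmapped,
    )


def connection_degree(mcn: MinimalConnectedNetwork) -> dict[str, int]:
    """Edge count per node, within the MCN subgraph."""
    return dict(mcn.graph.degree())


def clustering_coefficient(mcn: MinimalConnectedNetwork) -> dict[str, float]:
    """C(v): fraction of realised edges among v's neighbours; 0 when v has
    fewer than two neighbours."""
    return {n: float(c) for n, c in nx.clustering(mcn.graph).items()}


def betweenness(mcn: MinimalConnectedNetwork) -> dict[str, float]:
    """Relative betweenness rC_B(v).

    Shortest-path counts are accumulated per connected component with unit
    edge weights; C_B is normalised by (n-1)(n-2)/2 over the total node
    count n of the MCN (0 by convention when n < 3).
    """
    g = mcn.graph
    n = g.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in g}
    return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=True).items()}


def count_components(mcn: MinimalConnectedNetwork) -> int:
    return nx.number_connected_components(mcn.graph)


def node_params(mcn: MinimalConnectedNetwork) -> NodeParams:
    """Bundle all four statistics for one MCN."""
    return NodeParams(
        degree=connection_degree(mcn),
        clustering=clustering_coefficient(mcn),
        rel_betweenness=betweenness(mcn),
        n_components=count_components(mcn),
    )
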