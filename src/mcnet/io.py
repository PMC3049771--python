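"""Reading, validating and writing the pipeline's file formats.

The scaffold interactome is a plain undirected edge list in TSV
(``node_a TAB node_b [TAB evidence;evidence;...]``), gene modules come in
as GMT, and GO-style term systems as three small TSVs (DAG child/parent,
gene->term annotations, term->namespace).  Identifiers are opaque strings;
an optional two-column translation table can be applied at load time for
users whose lists and scaffold use different identifier spaces.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "EmptyScaffoldError",
    "CyclicOntologyError",
    "LoadReport",
    "ScaffoldInteractome",
    "GeneModule",
    "TermAnnotation",
    "load_id_map",
    "load_interactome",
    "write_interactome",
    "load_modules",
    "write_modules",
    "load_term_annotations",
    "propagate_annotations",
    "term_level",
    "write_results_tsv",
    "write_node_values_tsv",
    "write_summaries_tsv",
    "write_comparisons_tsv",
    "write_classification_tsv",
    "write_run_metadata",
    "write_mcn_sif",
]


class ParseError(ValueError):
    """A malformed data row; the message names the offending line number."""


class EmptyScaffoldError(ValueError):
    """No edges survived loading/filtering."""


class CyclicOntologyError(ValueError):
    """The term DAG contains a cycle; the message lists one."""


@dataclass
class LoadReport:
    """Bookkeeping from one interactome load."""

    rows_read: int = 0
    self_edges_dropped: int = 0
    duplicate_rows_merged: int = 0
    edges_removed_by_filter: int = 0


@dataclass
class ScaffoldInteractome:
    """Undirected simple PPI graph with per-edge evidence-category tags.

    ``filtered`` records whether the at-least-two-evidence-categories rule
    was applied, i.e. whether this is the confident scaffold or the
    all-interactions one.
    """

    graph: nx.Graph
    filtered: bool = False
    report: LoadReport | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str]]:
        return self.graph.edges()

    def evidence(self, u: str, v: str) -> frozenset[str]:
        return self.graph.edges[u, v].get("evidence", frozenset())

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def copy(self) -> "ScaffoldInteractome":
        return ScaffoldInteractome(self.graph.copy(), self.filtered, self.report)

    def content_hash(self) -> str:
        """Stable hash of the topology; keys the on-disk null cache."""
        h = hashlib.sha256()
        for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges()):
            h.update(u.encode())
            h.update(b"\t")
            h.update(v.encode())
            h.update(b"\n")
        for n in sorted(self.graph.nodes):
            h.update(n.encode())
            h.update(b"\n")
        return h.hexdigest()[:16]


@dataclass
class GeneModule:
    """A labelled gene/protein list: a GO term, pathway, signature, ..."""

    module_id: str
    members: frozenset[str]
    collection: str = ""
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"module {self.module_id!r} has no members")


@dataclass
class TermAnnotation:
    """A term DAG plus direct gene->term annotations.

    ``roots`` are the terms with no parent (one per namespace in GO-style
    inputs).  Terms mentioned only in annotations are treated as roots of
    their own (degenerate single-node DAGs).
    """

    dag_edges: set[tuple[str, str]]  # (child, parent)
    gene2terms: dict[str, set[str]]
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._parents: dict[str, set[str]] = {}
        terms: set[str] = set()
        for child, parent in self.dag_edges:
            terms.add(child)
            terms.add(parent)
            self._parents.setdefault(child, set()).add(parent)
        for ts in self.gene2terms.values():
            terms.update(ts)
        self.terms = terms
        self.roots = {t for t in terms if not self._parents.get(t)}

    def parents(self, term: str) -> set[str]:
        return self._parents.get(term, set())

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via parent links (excl. itself)."""
        seen: set[str] = set()
        stack = list(self.parents(term))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents(t))
        return seen


# ---------------------------------------------------------------------------
# loading


def load_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``source TAB target``; later rows win on conflicts."""
    mapping: dict[str, str] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
        mapping[fields[0]] = fields[1]
    return mapping


def _tsv_rows(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_interactome(
    path: str | Path,
    min_evidence: int = 0,
    id_map: Mapping[str, str] | None = None,
) -> ScaffoldInteractome:
    """Read an edge-list TSV into a :class:`ScaffoldInteractome`.

    Self-edges are dropped, duplicate rows are merged with evidence-set
    union, and when ``min_evidence >= 1`` edges supported by fewer than
    that many distinct evidence categories are removed.  Nodes exist only
    through surviving edges.  ``filtered`` is set iff ``min_evidence >= 2``.
    """
    if min_evidence < 0:
        raise ValueError("min_evidence must be non-negative")
    report = LoadReport()
    edges: dict[tuple[str, str], set[str]] = {}
    for lineno, fields in _tsv_rows(path):
        if len(fields) not in (2, 3):
            raise ParseError(
                f"{path}: line {lineno}: expected 2 or 3 tab-separated columns, got {len(fields)}"
            )
        report.rows_read += 1
        a, b = fields[0], fields[1]
        if id_map:
            a = id_map.get(a, a)
            b = id_map.get(b, b)
        if a == b:
            report.self_edges_dropped += 1
            continue
        ev = {c for c in fields[2].split(";") if c} if len(fields) == 3 else set()
        key = (a, b) if a < b else (b, a)
        if key in edges:
            report.duplicate_rows_merged += 1
            edges[key] |= ev
        else:
            edges[key] = ev

    g = nx.Graph()
    for (a, b), ev in edges.items():
        if min_evidence >= 1 and len(ev) < min_evidence:
            report.edges_removed_by_filter += 1
            continue
        g.add_edge(a, b, evidence=frozenset(ev))
    if g.number_of_edges() == 0:
        raise EmptyScaffoldError(
            f"{path}: empty scaffold after loading (min_evidence={min_evidence})"
        )
    return ScaffoldInteractome(g, filtered=min_evidence >= 2, report=report)


def write_interactome(scaffold: ScaffoldInteractome, path: str | Path) -> None:
    """Write back to edge-list TSV; round-trips with :func:`load_interactome`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#node_a\tnode_b\tevidence\n")
        for u, v in sorted(tuple(sorted(e)) for e in scaffold.graph.edges()):
            ev = ";".join(sorted(scaffold.evidence(u, v)))
            fh.write(f"{u}\t{v}\t{ev}\n")


def _parse_description(desc: str) -> dict[str, str]:
    chunks = [c for c in desc.split(";") if c]
    if chunks and all("=" in c for c in chunks):
        return dict(c.split("=", 1) for c in chunks)
    return {"description": desc}


def load_modules(
    path: str | Path,
    collection: str = "",
    id_map: Mapping[str, str] | None = None,
) -> list[GeneModule]:
    """Read a GMT file (``id TAB description TAB member...``).

    The description field is parsed into attrs when it follows the
    ``key=value;key=value`` convention, else stored verbatim under
    ``description``.
    """
    modules: list[GeneModule] = []
    for lineno, fields in _tsv_rows(path):
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: GMT row needs >=3 fields, got {len(fields)}")
        module_id, desc = fields[0], fields[1]
        members = [id_map.get(m, m) if id_map else m for m in fields[2:] if m]
        modules.append(
            GeneModule(
                module_id=module_id,
                members=frozenset(members),
                collection=collection,
                attrs=_parse_description(desc),
            )
        )
    if not modules:
        logger.warning("%s: empty module file", path)
    return modules


def write_modules(modules: Iterable[GeneModule], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in modules:
            if set(m.attrs) == {"description"}:
                desc = m.attrs["description"]
            else:
                desc = ";".join(f"{k}={v}" for k, v in sorted(m.attrs.items()))
            desc = desc or "-"
            fh.write("\t".join([m.module_id, desc, *sorted(m.members)]) + "\n")


def load_term_annotations(
    dag_path: str | Path,
    annotations_path: str | Path,
    namespaces_path: str | Path | None = None,
) -> TermAnnotation:
    """Load the three term-system TSVs (DAG, gene->term, term->namespace)."""
    dag_edges: set[tuple[str, str]] = set()
    for lineno, fields in _tsv_rows(dag_path):
        if len(fields) != 2:
            raise ParseError(f"{dag_path}: line {lineno}: expected child TAB parent")
        dag_edges.add((fields[0], fields[1]))
    gene2terms: dict[str, set[str]] = {}
    for lineno, fields in _tsv_rows(annotations_path):
        if len(fields) != 2:
            raise ParseError(f"{annotations_path}: line {lineno}: expected gene TAB term")
        gene2terms.setdefault(fields[0], set()).add(fields[1])
    namespaces: dict[str, str] = {}
    if namespaces_path is not None:
        for lineno, fields in _tsv_rows(namespaces_path):
            if len(fields) != 2:
                raise ParseError(f"{namespaces_path}: line {lineno}: expected term TAB namespace")
            namespaces[fields[0]] = fields[1]
    ann = TermAnnotation(dag_edges, gene2terms, namespaces)
    _check_acyclic(ann)
    return ann


def _check_acyclic(ann: TermAnnotation) -> None:
    dg = nx.DiGraph(list(ann.dag_edges))
    if not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        pretty = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
        raise CyclicOntologyError(f"term DAG contains a cycle: {pretty}")


def propagate_annotations(ann: TermAnnotation) -> dict[str, set[str]]:
    """True-path propagation: a gene annotated to a term is a member of
    every ancestor term as well.  Returns term -> full member set."""
    _check_acyclic(ann)
    term2genes: dict[str, set[str]] = {t: set() for t in ann.terms}
    for gene, terms in ann.gene2terms.items():
        for t in terms:
            term2genes.setdefault(t, set()).add(gene)
            for anc in ann.ancestors(t):
                term2genes[anc].add(gene)
    return term2genes


def term_level(ann: TermAnnotation, term: str) -> int:
    """Depth of a term: shortest parent-link distance to its namespace root
    (root itself is level 0)."""
    if term not in ann.terms:
        raise KeyError(f"unknown term: {term!r}")
    ns = ann.namespaces.get(term)
    q: deque[tuple[str, int]] = deque([(term, 0)])
    seen = {term}
    while q:
        t, d = q.popleft()
        if t in ann.roots and (ns is None or ann.namespaces.get(t, ns) == ns):
            return d
        for p in ann.parents(t):
            if p not in seen:
                seen.add(p)
                q.append((p, d + 1))
    raise KeyError(f"term {term!r} has no reachable namespace root")


# ---------------------------------------------------------------------------
# report writers (duck-typed over the result/summary dataclasses so this
# module stays import-independent of the analysis layers)

_RESULT_COLUMNS = [
    "module_id",
    "collection",
    "class",
    "mapped_n",
    "allow_external",
    "p_degree",
    "p_betweenness",
    "p_clustering",
    "p_components",
    "sig_degree",
    "sig_betweenness",
    "sig_clustering",
    "sig_components",
    "n_components",
    "skipped_reason",
]


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def write_results_tsv(results, path: str | Path) -> None:
    """One row per analysed (or skipped) module."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for r in results:
            sig = r.significant or {}
            row = [
                r.module_id,
                r.collection,
                r.attrs.get("class", r.collection) if r.attrs else r.collection,
                r.mapped_n,
                r.allow_external,
                r.p_degree,
                r.p_betweenness,
                r.p_clustering,
                r.p_components,
                sig.get("degree"),
                sig.get("betweenness"),
                sig.get("clustering"),
                sig.get("components"),
                r.n_components,
                r.skipped_reason or "",
            ]
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def write_node_values_tsv(results, path: str | Path) -> None:
    """Per-node parameter values of every observed MCN (for pooled
    class-vs-class comparisons downstream)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module_id\tcollection\tclass\tnode\texternal\tdegree\tbetweenness\tclustering\n")
        for r in results:
            if r.node_values is None:
                continue
            ext = r.external_nodes or frozenset()
            cls = r.attrs.get("class", r.collection) if r.attrs else r.collection
            for node in sorted(r.node_values["degree"]):
                fh.write(
                    "\t".join(
                        [
                            r.module_id,
                            r.collection,
                            cls,
                            node,
                            str(int(node in ext)),
                            _fmt(r.node_values["degree"][node]),
                            _fmt(r.node_values["betweenness"][node]),
                            _fmt(r.node_values["clustering"][node]),
                        ]
                    )
                    + "\n"
                )


def write_summaries_tsv(summaries, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "collection\tstratum\tn_analyzed\tn_skipped\t"
            "pct_degree\tpct_betweenness\tpct_clustering\tpct_components\n"
        )
        for s in summaries:
            pct = s.pct_significant
            fh.write(
                "\t".join(
                    [
                        s.collection,
                        s.stratum or "all",
                        str(s.n_analyzed),
                        str(s.n_skipped),
                        _fmt(pct.get("degree")),
                        _fmt(pct.get("betweenness")),
                        _fmt(pct.get("clustering")),
                        _fmt(pct.get("components")),
                    ]
                )
                + "\n"
            )


def write_comparisons_tsv(comparisons, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("class_a\tclass_b\tparameter\tks_p\tdirection\n")
        for c in comparisons:
            fh.write(
                f"{c.class_a}\t{c.class_b}\t{c.parameter}\t{_fmt(c.ks_p)}\t{c.direction}\n"
            )


def write_classification_tsv(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module_id\tlabel\n")
        for module_id in sorted(labels):
            fh.write(f"{module_id}\t{labels[module_id]}\n")


def write_run_metadata(path: str | Path, **fields) -> None:
    """Reproducibility sidecar: config, seed, input hashes.  Deliberately
    contains no timestamps so identical runs are byte-identical."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_mcn_sif(mcn, path: str | Path, flags_path: str | Path | None = None) -> None:
    """SIF export (``node_a pp node_b``) with an optional sidecar TSV
    flagging external (linker) nodes."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in mcn.graph.edges()):
            fh.write(f"{u}\tpp\t{v}\n")
    if flags_path is not None:
        with open(flags_path, "w", encoding="utf-8") as fh:
            fh.write("node\texternal\n")
            for n in sorted(mcn.graph.nodes):
                fh.write(f"{n}\t{int(n in mcn.external)}\n")
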