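"""Directed binary-adjacency citation graph over a paper corpus.

The graph ``G = (V, E)`` has one vertex per paper and a directed edge
i -> j whenever paper i cites paper j.  Adjacency is binary: multiple
citation records between the same ordered pair collapse to one edge.
Vertex order is fixed by sorted id so adjacency matrices and exports
are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .corpus import CitationRecord, Paper

__all__ = [
    "CitationGraph",
    "DegreeVector",
    "SubgraphSpec",
    "GraphBuildError",
    "build_graph",
    "in_degrees",
    "out_degrees",
    "extract_claim_subgraph",
]

ALL_SCOPE = "all"


class GraphBuildError(ValueError):
    """Raised when the supplied corpus cannot form a valid graph."""


@dataclass(frozen=True)
class SubgraphSpec:
    """Selects the claim sub-graph for one review class.

    The edge restriction is fixed: only edges from the selected reviews
    to primary studies survive.  ``review_class="all"`` keeps every
    review (used for whole-network utilisation measures).
    """

    review_class: str


@dataclass(frozen=True)
class DegreeVector:
    """Per-vertex in- and out-degree, aligned with the graph's vertex order."""

    ids: tuple[str, ...]
    in_degree: tuple[int, ...]
    out_degree: tuple[int, ...]

    def in_of(self, paper_id: str) -> int:
        return self.in_degree[self.ids.index(paper_id)]

    def out_of(self, paper_id: str) -> int:
        return self.out_degree[self.ids.index(paper_id)]

    def as_dicts(self) -> tuple[dict[str, int], dict[str, int]]:
        return dict(zip(self.ids, self.in_degree)), dict(zip(self.ids, self.out_degree))


class CitationGraph:
    """Immutable directed citation graph with binary adjacency.

    Vertices are :class:`~claimcite.corpus.Paper` records sorted by id;
    ``G[i, j] = 1`` means vertex i cites vertex j.
    """

    def __init__(self, papers: Iterable[Paper], edges: Iterable[tuple[str, str]]):
        self._papers: tuple[Paper, ...] = tuple(sorted(papers, key=lambda p: p.id))
        self._index: dict[str, int] = {p.id: i for i, p in enumerate(self._papers)}
        if len(self._index) != len(self._papers):
            raise GraphBuildError("duplicate paper ids in vertex set")
        edge_set: set[tuple[str, str]] = set()
        for citing, cited in edges:
            if citing == cited:
                raise GraphBuildError(f"self-citation on {citing!r}")
            if citing not in self._index:
                raise GraphBuildError(f"edge endpoint {citing!r} is not in the corpus")
            if cited not in self._index:
                raise GraphBuildError(f"edge endpoint {cited!r} is not in the corpus")
            edge_set.add((citing, cited))
        self._edges: tuple[tuple[str, str], ...] = tuple(sorted(edge_set))

    # -- basic accessors -------------------------------------------------
    @property
    def papers(self) -> tuple[Paper, ...]:
        return self._papers

    @property
    def vertex_index(self) -> Mapping[str, int]:
        return dict(self._index)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return self._edges

    @property
    def n(self) -> int:
        return len(self._papers)

    @property
    def m(self) -> int:
        return len(self._edges)

    def paper(self, paper_id: str) -> Paper:
        return self._papers[self._index[paper_id]]

    @property
    def primaries(self) -> tuple[Paper, ...]:
        return tuple(p for p in self._papers if p.is_primary)

    @property
    def reviews(self) -> tuple[Paper, ...]:
        return tuple(p for p in self._papers if p.is_review)

    def reviews_of_class(self, review_class: str) -> tuple[Paper, ...]:
        if review_class == ALL_SCOPE:
            return self.reviews
        return tuple(p for p in self.reviews if p.classification == review_class)

    @property
    def stance_set(self) -> frozenset[str]:
        return frozenset(p.classification for p in self._papers)

    def review_primary_edges(
        self, review_class: str = ALL_SCOPE
    ) -> tuple[tuple[str, str], ...]:
        """Edges from reviews of the given class to primary studies."""
        wanted = {p.id for p in self.reviews_of_class(review_class)}
        prim = {p.id for p in self.primaries}
        return tuple(e for e in self._edges if e[0] in wanted and e[1] in prim)

    # -- representations -------------------------------------------------
    def adjacency_matrix(self) -> np.ndarray:
        """Binary adjacency with rows/columns in sorted-id vertex order."""
        a = np.zeros((self.n, self.n), dtype=np.int_)
        for citing, cited in self._edges:
            a[self._index[citing], self._index[cited]] = 1
        return a

    def to_networkx(self) -> nx.DiGraph:
        """A :class:`networkx.DiGraph` carrying the vertex attributes."""
        g = nx.DiGraph()
        in_deg, _ = in_degrees(self).as_dicts()
        for p in self._papers:
            g.add_node(
                p.id,
                label=p.label or p.id,
                paper_type=p.paper_type,
                classification=p.classification,
                year=p.year,
                in_degree=in_deg[p.id],
            )
        g.add_edges_from(self._edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CitationGraph):
            return NotImplemented
        return self._papers == other._papers and self._edges == other._edges

    def __repr__(self) -> str:
        return f"CitationGraph(n={self.n}, m={self.m})"


def build_graph(
    papers: Sequence[Paper],
    edges: Sequence[CitationRecord],
    alias_map: Mapping[str, str] | None = None,
) -> CitationGraph:
    """Build the binary citation graph, optionally collapsing id aliases.

    ``alias_map`` maps alternative ids onto a canonical id; all papers
    sharing a canonical id merge into a single vertex (the record whose
    own id equals the canonical id is kept as representative, otherwise
    the earliest publication).  Parallel edges created by the collapse
    merge into one, and citations between merged aliases vanish — they
    would be self-loops of the merged vertex.
    """
    alias_map = dict(alias_map or {})

    def canon(pid: str) -> str:
        return alias_map.get(pid, pid)

    groups: dict[str, list[Paper]] = {}
    for p in papers:
        groups.setdefault(canon(p.id), []).append(p)
    merged: list[Paper] = []
    for cid, members in groups.items():
        rep = next(
            (p for p in members if p.id == cid),
            min(members, key=lambda p: (p.year, p.id)),
        )
        if rep.id != cid:
            rep = Paper(
                id=cid,
                paper_type=rep.paper_type,
                classification=rep.classification,
                year=rep.year,
                label=rep.label,
                extra=rep.extra,
            )
        merged.append(rep)

    known = {p.id for p in merged}
    edge_pairs: list[tuple[str, str]] = []
    for rec in edges:
        citing, cited = canon(rec.citing_id), canon(rec.cited_id)
        if citing == cited:
            if rec.citing_id == rec.cited_id:
                raise GraphBuildError(f"self-citation on {rec.citing_id!r}")
            continue  # alias-induced self-loop: internal to the merged vertex
        for endpoint in (citing, cited):
            if endpoint not in known:
                raise GraphBuildError(
                    f"edge endpoint {endpoint!r} is not in the corpus"
                )
        edge_pairs.append((citing, cited))
    return CitationGraph(merged, edge_pairs)


def in_degrees(graph: CitationGraph) -> DegreeVector:
    """Degree vector whose in-degrees are the adjacency column sums."""
    return _degrees(graph)


def out_degrees(graph: CitationGraph) -> DegreeVector:
    """Degree vector whose out-degrees are the adjacency row sums."""
    return _degrees(graph)


def _degrees(graph: CitationGraph) -> DegreeVector:
    n = graph.n
    ins = [0] * n
    outs = [0] * n
    idx = graph.vertex_index
    for citing, cited in graph.edges:
        outs[idx[citing]] += 1
        ins[idx[cited]] += 1
    return DegreeVector(
        ids=tuple(p.id for p in graph.papers),
        in_degree=tuple(ins),
        out_degree=tuple(outs),
    )


def extract_claim_subgraph(graph: CitationGraph, spec: SubgraphSpec) -> CitationGraph:
    """Claim sub-graph for one review class.

    Keeps every primary study (cited or not) plus the reviews of the
    requested class, and only the edges from those reviews to primaries.
    """
    cls = spec.review_class
    if cls != ALL_SCOPE and cls not in {p.classification for p in graph.reviews}:
        raise ValueError(
            f"unknown review class {cls!r}; corpus has "
            f"{sorted({p.classification for p in graph.reviews})}"
        )
    vertices = list(graph.primaries) + list(graph.reviews_of_class(cls))
    return CitationGraph(vertices, graph.review_primary_edges(cls))
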