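"""Writers for standard network-exchange formats (GEXF, GraphML, DOT, edge CSV).

Graphs are exported for external visualisation; layout is left to the
consuming tool.  Vertex attributes classification, paper_type, year and
in_degree are emitted; edge direction is preserved.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import IO

import networkx as nx

from .corpus import Paper
from .graph import CitationGraph

__all__ = ["FORMATS", "export_graph", "import_graph"]

FORMATS = ("gexf", "graphml", "dot", "edge-csv")


def _dot_escape(value: object) -> str:
    return str(value).replace("\\", "\\\\").replace('"', '\\"')


def _write_dot(graph: CitationGraph, sink: IO[str]) -> None:
    # Plain textual DOT; attributes carried so Graphviz can style on them.
    sink.write("digraph citations {\n")
    for p in graph.papers:
        attrs = (
            f'label="{_dot_escape(p.label or p.id)}", '
            f'paper_type="{p.paper_type}", '
            f'classification="{p.classification}", '
            f"year={p.year}"
        )
        sink.write(f'  "{_dot_escape(p.id)}" [{attrs}];\n')
    for citing, cited in graph.edges:
        sink.write(f'  "{_dot_escape(citing)}" -> "{_dot_escape(cited)}";\n')
    sink.write("}\n")


def export_graph(graph: CitationGraph, fmt: str, path: str | Path) -> None:
    """Write ``graph`` to ``path`` in one of :data:`FORMATS`.

    Raises
    ------
    ValueError
        If ``fmt`` is not a supported format name.
    """
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unsupported export format {fmt!r}; choose from {FORMATS}")
    path = Path(path)
    if fmt == "gexf":
        nx.write_gexf(graph.to_networkx(), path, version="1.2draft")
    elif fmt == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif fmt == "dot":
        with path.open("w", encoding="utf-8") as fh:
            _write_dot(graph, fh)
    else:  # edge-csv
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["citing_id", "cited_id"])
            writer.writerows(graph.edges)


def import_graph(fmt: str, path: str | Path) -> CitationGraph:
    """Re-read a previously exported GEXF or GraphML file.

    Provided for round-trip checks; edge CSV and DOT carry no vertex
    attributes and are export-only.
    """
    fmt = fmt.lower()
    if fmt == "gexf":
        g = nx.read_gexf(str(path))
    elif fmt == "graphml":
        g = nx.read_graphml(str(path))
    else:
        raise ValueError(f"unsupported import format {fmt!r}; use gexf or graphml")
    papers = [
        Paper(
            id=str(node),
            paper_type=data["paper_type"],
            classification=data["classification"],
            year=int(data["year"]),
            label=data.get("label", ""),
        )
        for node, data in g.nodes(data=True)
    ]
    return CitationGraph(papers, [(str(u), str(v)) for u, v in g.edges()])
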