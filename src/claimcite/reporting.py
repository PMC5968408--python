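"""One-call analysis runner producing a reproducible structured report.

The report mirrors the analysis sequence: validate the corpus, build
the graph, compute whole-network and per-class utilisation metrics,
tabulate citations by review class and trial, and test the association
with a Pearson chi-square.  Serialisation uses stable key order and
carries input digests, so identical inputs give byte-identical JSON.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._version import __version__ as _pkg_version
from .corpus import (
    DEFAULT_STANCES,
    CitationRecord,
    CorpusError,
    Paper,
    ValidationReport,
    read_edge_list,
    read_node_list,
    validate_corpus,
)
from .graph import ALL_SCOPE, CitationGraph, SubgraphSpec, build_graph, extract_claim_subgraph, in_degrees
from .inference import DegenerateTableError, pearson_chi_square
from .metrics import (
    UndefinedDensityError,
    bias_flags_to_dict,
    bipartite_density,
    citation_bias_flags,
    citation_totals_by_primary_class,
    contingency_table,
    density_to_dict,
    utilization_distribution,
)

__all__ = ["AnalysisReport", "run_analysis", "analyze_corpus"]


@dataclass(frozen=True)
class AnalysisReport:
    """Structured analysis results plus provenance; ``body`` is JSON-ready."""

    body: dict
    graph: CitationGraph
    validation: ValidationReport

    def to_dict(self) -> dict:
        return self.body


def _file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _scope_block(graph: CitationGraph, scope: str) -> dict:
    sub = extract_claim_subgraph(graph, SubgraphSpec(scope))
    try:
        density = density_to_dict(bipartite_density(graph, scope))
    except UndefinedDensityError as exc:
        density = {"error": str(exc)}
    flags = citation_bias_flags(graph, scope)
    util = utilization_distribution(graph, scope)
    return {
        "n": sub.n,
        "m": sub.m,
        "density": density,
        "bias": bias_flags_to_dict(flags),
        "utilization_histogram": {str(k): v for k, v in util.histogram.items()},
    }


def analyze_corpus(
    papers: Sequence[Paper],
    records: Sequence[CitationRecord],
    *,
    alias_map: Mapping[str, str] | None = None,
    strict_years: bool = False,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the full pipeline on an in-memory corpus."""
    validation = validate_corpus(papers, records, strict_years=strict_years)
    graph = build_graph(papers, records, alias_map=alias_map)
    degrees = in_degrees(graph)
    in_deg, out_deg = degrees.as_dicts()
    classes = sorted({p.classification for p in graph.reviews})

    table = contingency_table(graph)
    try:
        chi = pearson_chi_square(table)
        chi_block = {
            "statistic": chi.statistic,
            "df": chi.df,
            "p_value": chi.p_value,
            "validity": {
                "fraction_expected_gt5": chi.validity.fraction_expected_gt5,
                "min_expected": chi.validity.min_expected,
                "conditions_met": chi.validity.conditions_met,
            },
        }
    except DegenerateTableError as exc:
        chi_block = {"error": str(exc)}

    body = {
        "package": "claimcite",
        "version": _pkg_version,
        "provenance": provenance or {},
        "validation": {
            "n_papers": validation.n_papers,
            "n_edges_raw": validation.n_edges_raw,
            "n_edges_deduplicated": validation.n_edges_deduplicated,
            "is_valid": validation.is_valid,
            "violations": [
                {"rule": v.rule, "ids": list(v.ids), "message": v.message}
                for v in validation.violations
            ],
        },
        "corpus": {
            "n_papers": graph.n,
            "n_primaries": len(graph.primaries),
            "n_reviews": len(graph.reviews),
            "reviews_by_class": {
                c: len(graph.reviews_of_class(c)) for c in classes
            },
            "primaries_by_class": {
                c: sum(p.classification == c for p in graph.primaries)
                for c in sorted({p.classification for p in graph.primaries})
            },
        },
        "network": {
            "n": graph.n,
            "m": graph.m,
            "primary_in_degrees": {p.id: in_deg[p.id] for p in graph.primaries},
            "review_out_degrees": {p.id: out_deg[p.id] for p in graph.reviews},
            "citation_totals_by_primary_class": citation_totals_by_primary_class(graph),
        },
        "scopes": {scope: _scope_block(graph, scope) for scope in [ALL_SCOPE, *classes]},
        "contingency_table": {
            "rows": list(table.row_labels),
            "columns": list(table.col_labels),
            "observed": table.observed.tolist(),
            "row_totals": table.row_totals.tolist(),
            "column_totals": table.column_totals.tolist(),
            "N": table.N,
        },
        "chi_square": chi_block,
    }
    return AnalysisReport(body=body, graph=graph, validation=validation)


def run_analysis(
    node_path: str | Path,
    edge_path: str | Path,
    *,
    stance_set: Iterable[str] = DEFAULT_STANCES,
    alias_map: Mapping[str, str] | None = None,
    strict_years: bool = False,
    strict: bool = False,
) -> AnalysisReport:
    """Read a node/edge list pair and run the full analysis.

    With ``strict`` a corpus failing validation raises
    :class:`~claimcite.corpus.CorpusError` instead of reporting.
    """
    node_path, edge_path = Path(node_path), Path(edge_path)
    with node_path.open(encoding="utf-8") as fh:
        papers = read_node_list(fh, stance_set=stance_set)
    with edge_path.open(encoding="utf-8") as fh:
        records = read_edge_list(fh)
    report = analyze_corpus(
        papers,
        records,
        alias_map=alias_map,
        strict_years=strict_years,
        provenance={
            "nodes": {"path": str(node_path), "sha256": _file_digest(node_path)},
            "edges": {"path": str(edge_path), "sha256": _file_digest(edge_path)},
        },
    )
    if strict and not report.validation.is_valid:
        first = report.validation.violations[0]
        raise CorpusError(
            f"corpus failed validation with {len(report.validation.violations)} "
            f"violation(s); first: {first.message}"
        )
    return report
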