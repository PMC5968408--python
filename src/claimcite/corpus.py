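"""Reading, validating and writing citation corpora.

A corpus is a node list of papers (primary studies and reviews, each
carrying a stance classification and a publication year) plus an edge
list of citations (citing id, cited id).  Files are comma-separated
UTF-8 text with a mandatory header row; column names are configurable
so differently-labelled supplements can be ingested without editing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "DEFAULT_STANCES",
    "Paper",
    "CitationRecord",
    "Violation",
    "ValidationReport",
    "CorpusError",
    "read_node_list",
    "read_edge_list",
    "write_node_list",
    "write_edge_list",
    "validate_corpus",
]

#: Stance labels used by the secondary-prevention diet-trial corpus; any
#: other label set can be passed to :func:`read_node_list`.
DEFAULT_STANCES: frozenset[str] = frozenset({"supportive", "neutral", "unsupportive"})

PRIMARY = "primary"
REVIEW = "review"

#: Accepted spellings for the two paper types.  The study's supplement
#: labels primaries "RCT"; both map onto the canonical names.
_TYPE_ALIASES = {
    "primary": PRIMARY,
    "rct": PRIMARY,
    "trial": PRIMARY,
    "review": REVIEW,
}


class CorpusError(ValueError):
    """Raised when a node or edge list cannot be interpreted as a corpus."""


@dataclass(frozen=True)
class Paper:
    """A vertex of the citation network.

    Parameters
    ----------
    id:
        Opaque non-empty identifier, unique within a corpus.
    paper_type:
        ``"primary"`` (a trial) or ``"review"``.
    classification:
        Stance label from the corpus stance set.
    year:
        Calendar year of publication.
    label:
        Free-text display name.
    extra:
        Any further column values, preserved verbatim.
    """

    id: str
    paper_type: str
    classification: str
    year: int
    label: str = ""
    extra: Mapping[str, str] = field(default_factory=dict)

    @property
    def is_primary(self) -> bool:
        return self.paper_type == PRIMARY

    @property
    def is_review(self) -> bool:
        return self.paper_type == REVIEW


@dataclass(frozen=True)
class CitationRecord:
    """One directed citation: ``citing_id`` cites ``cited_id``."""

    citing_id: str
    cited_id: str


@dataclass(frozen=True)
class Violation:
    """A single validation failure: rule name, offending ids, message."""

    rule: str
    ids: tuple[str, ...]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    n_papers: int
    n_edges_raw: int
    n_edges_deduplicated: int
    violations: tuple[Violation, ...]

    @property
    def is_valid(self) -> bool:
        return not self.violations


def _normalise_type(raw: str, row: int) -> str:
    key = raw.strip().lower()
    if key not in _TYPE_ALIASES:
        raise CorpusError(
            f"row {row}: unknown paper type {raw!r} (expected primary/RCT or review)"
        )
    return _TYPE_ALIASES[key]


def read_node_list(
    source: IO[str],
    stance_set: Iterable[str] = DEFAULT_STANCES,
    *,
    case_insensitive: bool = True,
    id_col: str = "id",
    type_col: str = "paper_type",
    class_col: str = "classification",
    year_col: str = "year",
    label_col: str = "label",
    year_range: tuple[int, int] = (1900, 2100),
) -> list[Paper]:
    """Read a node list from delimited text.

    The header must name at least the id, type, classification and year
    columns.  Unknown columns are preserved in :attr:`Paper.extra`.
    Classification labels are checked against ``stance_set``; with
    ``case_insensitive`` (the default) labels are matched and stored
    lower-cased.

    Raises
    ------
    CorpusError
        On a duplicate id, an unknown classification label, an
        unparseable or implausible year, or a missing required column.
    """
    stances = {s.lower() if case_insensitive else s for s in stance_set}
    reader = csv.DictReader(source)
    header = reader.fieldnames or []
    required = [id_col, type_col, class_col, year_col]
    missing = [c for c in required if c not in header]
    if missing:
        raise CorpusError(f"node list is missing required column(s): {missing}")

    papers: list[Paper] = []
    seen: set[str] = set()
    known = set(required) | {label_col}
    for row_no, row in enumerate(reader, start=2):
        pid = (row.get(id_col) or "").strip()
        if not pid:
            raise CorpusError(f"row {row_no}: empty paper id")
        if pid in seen:
            raise CorpusError(f"duplicate paper id {pid!r} (row {row_no})")
        seen.add(pid)
        ptype = _normalise_type(row.get(type_col) or "", row_no)
        raw_class = (row.get(class_col) or "").strip()
        cls = raw_class.lower() if case_insensitive else raw_class
        if cls not in stances:
            raise CorpusError(
                f"row {row_no}: unknown classification {raw_class!r} for {pid!r}; "
                f"expected one of {sorted(stances)}"
            )
        raw_year = (row.get(year_col) or "").strip()
        try:
            year = int(raw_year)
        except ValueError:
            raise CorpusError(
                f"row {row_no}: unparseable year {raw_year!r} for {pid!r}"
            ) from None
        lo, hi = year_range
        if not lo <= year <= hi:
            raise CorpusError(
                f"row {row_no}: year {year} for {pid!r} outside plausible range "
                f"{lo}-{hi}"
            )
        extra = {
            k: v for k, v in row.items() if k is not None and k not in known and v
        }
        papers.append(
            Paper(
                id=pid,
                paper_type=ptype,
                classification=cls,
                year=year,
                label=(row.get(label_col) or "").strip(),
                extra=extra,
            )
        )
    return papers


def read_edge_list(
    source: IO[str],
    *,
    citing_col: str = "citing_id",
    cited_col: str = "cited_id",
) -> list[CitationRecord]:
    """Read an edge list from delimited text, order preserved.

    No deduplication happens here; duplicate rows collapse to a single
    edge only when the binary-adjacency graph is built.  Self-citation
    rows are kept as records so that :func:`validate_corpus` can report
    them; they are rejected at graph build.
    """
    reader = csv.DictReader(source)
    header = reader.fieldnames or []
    missing = [c for c in (citing_col, cited_col) if c not in header]
    if missing:
        raise CorpusError(f"edge list is missing required column(s): {missing}")
    records: list[CitationRecord] = []
    for row_no, row in enumerate(reader, start=2):
        citing = (row.get(citing_col) or "").strip()
        cited = (row.get(cited_col) or "").strip()
        if not citing or not cited:
            raise CorpusError(f"row {row_no}: empty citation endpoint")
        records.append(CitationRecord(citing_id=citing, cited_id=cited))
    return records


def write_node_list(papers: Sequence[Paper], sink: IO[str]) -> None:
    """Write papers in the canonical CSV schema (extra columns appended)."""
    extra_cols = sorted({k for p in papers for k in p.extra})
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(["id", "paper_type", "classification", "year", "label", *extra_cols])
    for p in papers:
        writer.writerow(
            [p.id, p.paper_type, p.classification, p.year, p.label]
            + [p.extra.get(k, "") for k in extra_cols]
        )


def write_edge_list(edges: Sequence[CitationRecord], sink: IO[str]) -> None:
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(["citing_id", "cited_id"])
    for e in edges:
        writer.writerow([e.citing_id, e.cited_id])


def validate_corpus(
    papers: Sequence[Paper],
    edges: Sequence[CitationRecord],
    *,
    strict_years: bool = False,
) -> ValidationReport:
    """Check corpus-level invariants, reporting (never raising) problems.

    Citations must point at papers present in the corpus, must not be
    self-citations, and must respect publication order: a paper can only
    cite earlier literature.  By default a citation between two papers
    of the same year is allowed (publication lag within a year is
    common); ``strict_years`` forbids same-year citations too.

    The function is pure: identical inputs give identical reports.
    """
    index = {p.id: p for p in papers}
    violations: list[Violation] = []
    for rec in edges:
        if rec.citing_id == rec.cited_id:
            violations.append(
                Violation(
                    "self_citation",
                    (rec.citing_id,),
                    f"paper {rec.citing_id!r} cites itself",
                )
            )
            continue
        dangling = [i for i in (rec.citing_id, rec.cited_id) if i not in index]
        if dangling:
            violations.append(
                Violation(
                    "dangling_endpoint",
                    tuple(dangling),
                    f"citation {rec.citing_id!r} -> {rec.cited_id!r} references "
                    f"unknown paper(s) {dangling}",
                )
            )
            continue
        citing, cited = index[rec.citing_id], index[rec.cited_id]
        future = (
            citing.year < cited.year
            if not strict_years
            else citing.year <= cited.year
        )
        if future:
            violations.append(
                Violation(
                    "future_citation",
                    (rec.citing_id, rec.cited_id),
                    f"{rec.citing_id!r} ({citing.year}) cites {rec.cited_id!r} "
                    f"({cited.year}), which is not earlier literature",
                )
            )
    dedup = {(e.citing_id, e.cited_id) for e in edges if e.citing_id != e.cited_id}
    return ValidationReport(
        n_papers=len(papers),
        n_edges_raw=len(edges),
        n_edges_deduplicated=len(dedup),
        violations=tuple(violations),
    )
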