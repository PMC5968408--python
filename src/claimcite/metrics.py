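"""Evidence-utilisation and citation-bias measures on the citation graph.

Four outcome measures:

* **bipartite density** ``D = E / (|S| x |P|)`` — the number of
  review->primary citations as a proportion of the maximum possible,
  comparing how fully different classes of review use the primary
  evidence;
* **citation-bias flags** — a review is biased when every primary it
  cites shares one stance classification (the extreme of selective
  citation);
* **utilisation distribution** — histogram of how many distinct
  primaries each review cites (underutilisation: citing fewer than all
  the available studies);
* **contingency table** — citation counts, review stance classes by
  primary study, the input to the chi-square test of independence.

All measures count only review->primary edges, whatever other edges the
supplied graph carries.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .graph import ALL_SCOPE, CitationGraph

__all__ = [
    "DensityResult",
    "BiasFlag",
    "UtilizationDistribution",
    "ContingencyTable",
    "UndefinedDensityError",
    "bipartite_density",
    "citation_bias_flags",
    "utilization_distribution",
    "contingency_table",
    "citation_totals_by_primary_class",
    "write_contingency_csv",
    "write_report_json",
]


class UndefinedDensityError(ValueError):
    """Density is undefined when the review or primary set is empty."""


@dataclass(frozen=True)
class DensityResult:
    """The density statistic with its numerator/denominator provenance."""

    E: int
    n_reviews: int
    n_primaries: int
    scope_label: str

    @property
    def D(self) -> float:
        return self.E / (self.n_reviews * self.n_primaries)

    @property
    def exact(self) -> Fraction:
        """D as an exact ratio (densities are reported rounded to 2 dp)."""
        return Fraction(self.E, self.n_reviews * self.n_primaries)

    @property
    def rounded(self) -> float:
        return round(self.D, 2)


@dataclass(frozen=True)
class BiasFlag:
    """Citation-bias verdict for one review.

    ``is_biased`` is true iff the review cites at least one primary and
    every cited primary shares one stance label; ``biased_toward`` then
    names that label.  The review's own stance never enters the verdict:
    an unsupportive review citing only the supportive trial is biased
    toward *supportive*.  A review citing zero primaries violates the
    corpus inclusion assumption; it is reported with
    ``cites_no_primary=True`` rather than raising.
    """

    review_id: str
    n_primaries_cited: int
    cited_class_profile: tuple[str, ...]
    is_biased: bool
    biased_toward: str | None

    @property
    def cites_no_primary(self) -> bool:
        return self.n_primaries_cited == 0


@dataclass(frozen=True)
class UtilizationDistribution:
    """Reviews binned by the number of distinct primaries they cite."""

    histogram: dict[int, int]
    scope_label: str

    @property
    def n_reviews(self) -> int:
        return sum(self.histogram.values())

    @property
    def n_edges(self) -> int:
        return sum(k * v for k, v in self.histogram.items())


@dataclass(frozen=True)
class ContingencyTable:
    """Observed citation counts: review stance classes x primary studies."""

    observed: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=np.int_)
        if obs.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("observed shape does not match labels")
        if (obs < 0).any():
            raise ValueError("contingency cells must be non-negative")
        object.__setattr__(self, "observed", obs)

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.observed.sum())

    def row(self, label: str) -> np.ndarray:
        return self.observed[self.row_labels.index(label)]


def bipartite_density(
    graph: CitationGraph, review_class: str = ALL_SCOPE
) -> DensityResult:
    """Density of the review->primary bipartite relation for one scope.

    ``E`` counts distinct review->primary citations from reviews of the
    given class (``"all"`` for every review); the denominator is the
    maximum possible, |reviews in scope| x |primaries|.
    """
    reviews = graph.reviews_of_class(review_class)
    primaries = graph.primaries
    if not reviews or not primaries:
        raise UndefinedDensityError(
            f"density undefined for scope {review_class!r}: "
            f"{len(reviews)} reviews, {len(primaries)} primaries"
        )
    e = len(graph.review_primary_edges(review_class))
    return DensityResult(
        E=e,
        n_reviews=len(reviews),
        n_primaries=len(primaries),
        scope_label=review_class,
    )


def _cited_primaries_by_review(
    graph: CitationGraph, review_class: str
) -> dict[str, list[str]]:
    cited: dict[str, list[str]] = {p.id: [] for p in graph.reviews_of_class(review_class)}
    for citing, cited_id in graph.review_primary_edges(review_class):
        cited[citing].append(cited_id)
    return cited


def citation_bias_flags(
    graph: CitationGraph, review_class: str = ALL_SCOPE
) -> list[BiasFlag]:
    """One bias flag per review in scope, in sorted-id order."""
    flags = []
    for review_id, prim_ids in sorted(
        _cited_primaries_by_review(graph, review_class).items()
    ):
        profile = tuple(sorted(graph.paper(p).classification for p in prim_ids))
        classes = set(profile)
        biased = len(prim_ids) >= 1 and len(classes) == 1
        flags.append(
            BiasFlag(
                review_id=review_id,
                n_primaries_cited=len(prim_ids),
                cited_class_profile=profile,
                is_biased=biased,
                biased_toward=next(iter(classes)) if biased else None,
            )
        )
    return flags


def utilization_distribution(
    graph: CitationGraph, review_class: str = ALL_SCOPE
) -> UtilizationDistribution:
    """Histogram of distinct primaries cited per review in scope."""
    counts = Counter(
        len(v) for v in _cited_primaries_by_review(graph, review_class).values()
    )
    return UtilizationDistribution(
        histogram=dict(sorted(counts.items())), scope_label=review_class
    )


def contingency_table(graph: CitationGraph) -> ContingencyTable:
    """Citation counts by review class (rows) and primary study (columns).

    Cell (c, p) is the number of class-c reviews citing primary p; with
    binary adjacency no cell can exceed the number of reviews in its
    class.  Rows are stance labels in sorted order, columns primary ids
    in sorted order.
    """
    classes = tuple(sorted({p.classification for p in graph.reviews}))
    primaries = tuple(p.id for p in graph.primaries)  # already id-sorted
    obs = np.zeros((len(classes), len(primaries)), dtype=np.int_)
    col_index = {p: j for j, p in enumerate(primaries)}
    row_index = {c: i for i, c in enumerate(classes)}
    for citing, cited in graph.review_primary_edges(ALL_SCOPE):
        obs[row_index[graph.paper(citing).classification], col_index[cited]] += 1
    return ContingencyTable(observed=obs, row_labels=classes, col_labels=primaries)


def citation_totals_by_primary_class(graph: CitationGraph) -> dict[str, int]:
    """Total citations received, grouped by the cited primaries' stance."""
    totals: Counter[str] = Counter()
    for _, cited in graph.review_primary_edges(ALL_SCOPE):
        totals[graph.paper(cited).classification] += 1
    return dict(sorted(totals.items()))


# -- report writers ------------------------------------------------------


def write_contingency_csv(table: ContingencyTable, sink: IO[str]) -> None:
    """Emit the table with marginals: class rows, study columns."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(["classification", *table.col_labels, "row_total"])
    for i, cls in enumerate(table.row_labels):
        writer.writerow([cls, *table.observed[i].tolist(), int(table.row_totals[i])])
    writer.writerow(["column_total", *table.column_totals.tolist(), table.N])


def density_to_dict(result: DensityResult) -> dict:
    return {
        "scope": result.scope_label,
        "D": result.D,
        "D_rounded": result.rounded,
        "E": result.E,
        "n_reviews": result.n_reviews,
        "n_primaries": result.n_primaries,
    }


def bias_flags_to_dict(flags: Sequence[BiasFlag]) -> dict:
    toward: Counter[str] = Counter(
        f.biased_toward for f in flags if f.biased_toward is not None
    )
    return {
        "n_reviews": len(flags),
        "n_biased": sum(f.is_biased for f in flags),
        "biased_toward": dict(sorted(toward.items())),
        "reviews": [
            {
                "review_id": f.review_id,
                "n_primaries_cited": f.n_primaries_cited,
                "cited_class_profile": list(f.cited_class_profile),
                "is_biased": f.is_biased,
                "biased_toward": f.biased_toward,
            }
            for f in flags
        ],
    }


def write_report_json(report: dict, path: str | Path) -> None:
    """Serialise an analysis report with stable key order."""
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=False) + "\n", encoding="utf-8"
    )
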