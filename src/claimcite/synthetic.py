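"""Synthetic stance-labelled citation corpora with controlled homophily.

Two generators:

* :func:`generate_corpus` draws a random bipartite citation structure —
  each review cites each primary independently with a probability that
  depends only on the (review class, primary class) pair, like a
  stochastic block model restricted to review->primary edges.  A
  minimum-citation floor mirrors the usual inclusion criterion that
  every review cites at least one primary.
* :func:`build_fixture_from_marginals` realises a corpus whose per-class
  out-degree histograms and per-primary citation counts match a given
  profile exactly, choosing the actual review->primary incidence
  seeded-randomly among the valid 0/1 completions (Gale-Ryser
  feasibility, greedy realisation, checkerboard-swap mixing).

Independence across review-primary pairs is assumed; reference-copying
cascades between reviews are deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import PRIMARY, REVIEW, CitationRecord, Paper
from .graph import build_graph
from .inference import DegenerateTableError, pearson_chi_square
from .metrics import contingency_table

__all__ = [
    "SyntheticConfig",
    "PrimarySpec",
    "ClassMarginals",
    "MarginalProfile",
    "ConfigError",
    "FeasibilityError",
    "generate_corpus",
    "estimate_citation_probs",
    "build_fixture_from_marginals",
    "power_simulation",
]


class ConfigError(ValueError):
    """Raised for an invalid or infeasible generator configuration."""


class FeasibilityError(ValueError):
    """Raised when no 0/1 incidence realises the requested marginals."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the random homophilous citation generator.

    ``citation_prob[review_class][primary_class]`` is the probability
    that a review of one class cites a primary of the other, applied
    independently per pair.  Reviews left below
    ``min_citations_per_review`` draw additional distinct primaries
    uniformly until the floor is met (set the floor to 0 to disable).
    """

    primaries_per_class: Mapping[str, int]
    reviews_per_class: Mapping[str, int]
    citation_prob: Mapping[str, Mapping[str, float]]
    min_citations_per_review: int = 1
    year_range: tuple[int, int] = (1965, 1984)
    seed: int = 0

    def validate(self) -> None:
        n_prim = sum(self.primaries_per_class.values())
        n_rev = sum(self.reviews_per_class.values())
        if n_prim < 1 or n_rev < 1:
            raise ConfigError("need at least one primary and one review")
        if any(v < 0 for v in self.primaries_per_class.values()) or any(
            v < 0 for v in self.reviews_per_class.values()
        ):
            raise ConfigError("class sizes must be non-negative")
        if self.min_citations_per_review < 0:
            raise ConfigError("min_citations_per_review must be >= 0")
        if self.min_citations_per_review > n_prim:
            raise ConfigError(
                f"min_citations_per_review={self.min_citations_per_review} "
                f"exceeds the {n_prim} available primaries"
            )
        for rc, row in self.citation_prob.items():
            for pc, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"citation_prob[{rc!r}][{pc!r}]={p} outside [0, 1]"
                    )
        for rc in self.reviews_per_class:
            if rc not in self.citation_prob:
                raise ConfigError(f"no citation_prob row for review class {rc!r}")
            for pc in self.primaries_per_class:
                if pc not in self.citation_prob[rc]:
                    raise ConfigError(
                        f"no citation_prob entry for pair ({rc!r}, {pc!r})"
                    )
        if self.year_range[1] <= self.year_range[0]:
            raise ConfigError("year_range must span at least two years")


def _make_primaries(per_class: Mapping[str, int], year: int) -> list[Paper]:
    papers = []
    for cls in sorted(per_class):
        for i in range(per_class[cls]):
            papers.append(
                Paper(
                    id=f"P-{cls}-{i:03d}",
                    paper_type=PRIMARY,
                    classification=cls,
                    year=year,
                    label=f"{cls} trial {i}",
                )
            )
    return papers


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[Paper], list[CitationRecord]]:
    """Draw a corpus from the class-conditional citation model.

    Primaries are published at the start of ``year_range``; reviews in
    the later years.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    start, end = config.year_range
    primaries = _make_primaries(config.primaries_per_class, start)
    papers = list(primaries)
    records: list[CitationRecord] = []
    n_prim = len(primaries)
    for cls in sorted(config.reviews_per_class):
        probs = np.array(
            [config.citation_prob[cls][p.classification] for p in primaries]
        )
        for i in range(config.reviews_per_class[cls]):
            rid = f"R-{cls}-{i:04d}"
            papers.append(
                Paper(
                    id=rid,
                    paper_type=REVIEW,
                    classification=cls,
                    year=int(rng.integers(start + 1, end + 1)),
                    label=f"{cls} review {i}",
                )
            )
            cited = rng.random(n_prim) < probs
            shortfall = config.min_citations_per_review - int(cited.sum())
            if shortfall > 0:
                uncited = np.flatnonzero(~cited)
                extra = rng.choice(uncited, size=shortfall, replace=False)
                cited[extra] = True
            records.extend(
                CitationRecord(rid, primaries[j].id) for j in np.flatnonzero(cited)
            )
    return papers, records


def estimate_citation_probs(
    papers: Sequence[Paper], edges: Sequence[CitationRecord]
) -> dict[str, dict[str, dict]]:
    """Class-pair citation densities, the MLE of the generator's matrix.

    ``result[review_class][primary_class]`` holds the edge ``count``,
    the number of review-primary ``pairs``, and their ratio as
    ``estimate`` (``None`` where a class is empty) — the same statistic
    as the bipartite density restricted to one class pair.
    """
    by_id = {p.id: p for p in papers}
    review_classes = sorted({p.classification for p in papers if p.is_review})
    primary_classes = sorted({p.classification for p in papers if p.is_primary})
    n_rev = {
        c: sum(p.is_review and p.classification == c for p in papers)
        for c in review_classes
    }
    n_prim = {
        c: sum(p.is_primary and p.classification == c for p in papers)
        for c in primary_classes
    }
    counts = {rc: {pc: 0 for pc in primary_classes} for rc in review_classes}
    for e in edges:
        citing, cited = by_id[e.citing_id], by_id[e.cited_id]
        if citing.is_review and cited.is_primary:
            counts[citing.classification][cited.classification] += 1
    out: dict[str, dict[str, dict]] = {}
    for rc in review_classes:
        out[rc] = {}
        for pc in primary_classes:
            pairs = n_rev[rc] * n_prim[pc]
            out[rc][pc] = {
                "count": counts[rc][pc],
                "pairs": pairs,
                "estimate": counts[rc][pc] / pairs if pairs else None,
            }
    return out


# -- marginal-constrained fixtures ---------------------------------------


@dataclass(frozen=True)
class PrimarySpec:
    """Identity, stance and year of one primary study in a profile."""

    id: str
    classification: str
    year: int


@dataclass(frozen=True)
class ClassMarginals:
    """Printed marginals for one review class.

    ``out_degree_hist`` maps k (distinct primaries cited) to the number
    of reviews; ``column_counts`` maps primary id to the citations it
    receives from this class.  ``singleton_allocation`` optionally pins
    which primary each single-citing review cites (primary id -> count
    of degree-1 reviews), for when the source states this explicitly.
    """

    out_degree_hist: Mapping[int, int]
    column_counts: Mapping[str, int]
    singleton_allocation: Mapping[str, int] | None = None

    @property
    def n_reviews(self) -> int:
        return sum(self.out_degree_hist.values())

    @property
    def n_edges(self) -> int:
        return sum(k * v for k, v in self.out_degree_hist.items())


@dataclass(frozen=True)
class MarginalProfile:
    """Complete marginal description of a stance-labelled corpus."""

    primaries: tuple[PrimarySpec, ...]
    classes: Mapping[str, ClassMarginals]
    review_year_range: tuple[int, int] = (1969, 1984)

    def to_dict(self) -> dict:
        return {
            "primaries": [
                {"id": p.id, "classification": p.classification, "year": p.year}
                for p in self.primaries
            ],
            "review_year_range": list(self.review_year_range),
            "classes": {
                cls: {
                    "out_degree_hist": {str(k): v for k, v in m.out_degree_hist.items()},
                    "column_counts": dict(m.column_counts),
                    "singleton_allocation": (
                        dict(m.singleton_allocation)
                        if m.singleton_allocation is not None
                        else None
                    ),
                }
                for cls, m in self.classes.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MarginalProfile":
        return cls(
            primaries=tuple(
                PrimarySpec(p["id"], p["classification"], int(p["year"]))
                for p in data["primaries"]
            ),
            classes={
                name: ClassMarginals(
                    out_degree_hist={
                        int(k): int(v) for k, v in m["out_degree_hist"].items()
                    },
                    column_counts={k: int(v) for k, v in m["column_counts"].items()},
                    singleton_allocation=(
                        {k: int(v) for k, v in m["singleton_allocation"].items()}
                        if m.get("singleton_allocation")
                        else None
                    ),
                )
                for name, m in data["classes"].items()
            },
            review_year_range=tuple(data.get("review_year_range", (1969, 1984))),
        )


def gale_ryser_feasible(degrees: Sequence[int], column_sums: Sequence[int]) -> bool:
    """Whether a 0/1 matrix exists with the given row and column sums.

    Gale-Ryser: with row sums d sorted descending, for every k,
    sum_{i<=k} d_i <= sum_j min(c_j, k), with equal totals.
    """
    d = sorted(degrees, reverse=True)
    c = list(column_sums)
    if sum(d) != sum(c):
        return False
    if any(x < 0 for x in d + c):
        return False
    if d and d[0] > len(c):
        return False
    for k in range(1, len(d) + 1):
        if sum(d[:k]) > sum(min(cj, k) for cj in c):
            return False
    return True


def _realise_block(
    degrees: list[int],
    columns: dict[str, int],
    rng: np.random.Generator,
    cls: str,
) -> list[set[str]]:
    """Greedy Gale-Ryser realisation: largest row first, fullest columns first."""
    remaining = dict(columns)
    col_ids = sorted(remaining)
    rows: list[tuple[int, int]] = sorted(
        enumerate(degrees), key=lambda t: -t[1]
    )  # (original position, degree), largest degree first
    out: list[set[str]] = [set() for _ in degrees]
    for pos, k in rows:
        order = list(rng.permutation(len(col_ids)))
        ranked = sorted(order, key=lambda j: -remaining[col_ids[j]])
        chosen = [col_ids[j] for j in ranked[:k]]
        if any(remaining[c] <= 0 for c in chosen):
            raise FeasibilityError(
                f"class {cls!r}: marginals admit no 0/1 completion"
            )
        for c in chosen:
            remaining[c] -= 1
        out[pos] = set(chosen)
    return out


def _mix_block(
    rows: list[set[str]],
    swappable: list[int],
    rng: np.random.Generator,
    n_trades: int,
) -> None:
    # Checkerboard swaps preserve every row degree and column sum.
    if len(swappable) < 2:
        return
    for _ in range(n_trades):
        i, j = rng.choice(swappable, size=2, replace=False)
        only_i = sorted(rows[i] - rows[j])
        only_j = sorted(rows[j] - rows[i])
        if not only_i or not only_j:
            continue
        a = only_i[rng.integers(len(only_i))]
        b = only_j[rng.integers(len(only_j))]
        rows[i].remove(a)
        rows[i].add(b)
        rows[j].remove(b)
        rows[j].add(a)


def build_fixture_from_marginals(
    profile: MarginalProfile, seed: int
) -> tuple[list[Paper], list[CitationRecord]]:
    """Realise a corpus matching a marginal profile exactly.

    The contingency table and per-class utilisation histograms of the
    result equal the profile; the review->primary incidence within those
    constraints is seeded-random among valid completions.

    Raises
    ------
    FeasibilityError
        If some class block admits no 0/1 incidence (checked by the
        Gale-Ryser condition before construction), or a singleton
        allocation is inconsistent with the marginals.
    """
    rng = np.random.default_rng(seed)
    prim_ids = {p.id for p in profile.primaries}
    papers: list[Paper] = [
        Paper(
            id=p.id,
            paper_type=PRIMARY,
            classification=p.classification,
            year=p.year,
            label=p.id,
        )
        for p in profile.primaries
    ]
    records: list[CitationRecord] = []
    start, end = profile.review_year_range

    for cls in sorted(profile.classes):
        marg = profile.classes[cls]
        if set(marg.column_counts) - prim_ids:
            raise FeasibilityError(
                f"class {cls!r}: column counts name unknown primaries "
                f"{sorted(set(marg.column_counts) - prim_ids)}"
            )
        columns = {p.id: marg.column_counts.get(p.id, 0) for p in profile.primaries}
        degrees = [k for k, cnt in sorted(marg.out_degree_hist.items()) for _ in range(cnt)]
        if any(k < 0 for k in degrees) or any(v < 0 for v in columns.values()):
            raise FeasibilityError(f"class {cls!r}: negative marginal")
        if marg.n_edges != sum(columns.values()):
            raise FeasibilityError(
                f"class {cls!r}: histogram edge total {marg.n_edges} != "
                f"column total {sum(columns.values())}"
            )
        if any(v > marg.n_reviews for v in columns.values()):
            raise FeasibilityError(
                f"class {cls!r}: a column count exceeds the {marg.n_reviews} "
                "reviews of the class (binary adjacency bound)"
            )
        if not gale_ryser_feasible(degrees, list(columns.values())):
            raise FeasibilityError(
                f"class {cls!r}: Gale-Ryser condition fails for the marginals"
            )

        # Pin the single-citing reviews first when the profile says where they go.
        alloc = dict(marg.singleton_allocation or {})
        n_singletons = sum(1 for k in degrees if k == 1)
        pinned_rows: list[set[str]] = []
        if alloc:
            if sum(alloc.values()) != n_singletons:
                raise FeasibilityError(
                    f"class {cls!r}: singleton allocation covers "
                    f"{sum(alloc.values())} reviews but the histogram has "
                    f"{n_singletons} single-citers"
                )
            for pid, cnt in sorted(alloc.items()):
                if columns.get(pid, 0) < cnt:
                    raise FeasibilityError(
                        f"class {cls!r}: singleton allocation to {pid!r} "
                        "exceeds its column count"
                    )
                columns[pid] -= cnt
                pinned_rows.extend({pid} for _ in range(cnt))
            degrees = [k for k in degrees if k != 1]
            if not gale_ryser_feasible(degrees, list(columns.values())):
                raise FeasibilityError(
                    f"class {cls!r}: marginals infeasible once the singleton "
                    "allocation is fixed"
                )

        free_rows = _realise_block(degrees, columns, rng, cls)
        _mix_block(free_rows, list(range(len(free_rows))), rng, 4 * max(1, marg.n_edges))
        all_rows = pinned_rows + free_rows
        years = rng.integers(start, end + 1, size=len(all_rows))
        order = rng.permutation(len(all_rows))
        for i, row_idx in enumerate(order):
            rid = f"R-{cls}-{i:04d}"
            papers.append(
                Paper(
                    id=rid,
                    paper_type=REVIEW,
                    classification=cls,
                    year=int(years[row_idx]),
                    label=f"{cls} review {i}",
                )
            )
            records.extend(
                CitationRecord(rid, pid) for pid in sorted(all_rows[row_idx])
            )
    return papers, records


# -- power / calibration simulation --------------------------------------


def _rejection_rate(
    config: SyntheticConfig, replicates: int, alpha: float
) -> tuple[float, int]:
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=replicates)
    rejections = 0
    degenerate = 0
    for s in seeds:
        papers, records = generate_corpus(dataclasses.replace(config, seed=int(s)))
        graph = build_graph(papers, records)
        try:
            result = pearson_chi_square(contingency_table(graph))
        except DegenerateTableError:
            degenerate += 1
            continue
        rejections += result.p_value < alpha
    usable = replicates - degenerate
    return (rejections / usable if usable else float("nan")), degenerate


def power_simulation(
    config_null: SyntheticConfig,
    config_alt: SyntheticConfig,
    replicates: int,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo size and power of the stance-citation chi-square test.

    Each replicate generates a corpus, builds its contingency table and
    applies the test; the rejection fraction under ``config_null``
    (no homophily) estimates the type-I error, under ``config_alt``
    (homophilous citation probabilities) the power.  Replicates whose
    table is degenerate (a zero marginal) are counted and excluded.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    if set(config_null.reviews_per_class) != set(config_alt.reviews_per_class) or set(
        config_null.primaries_per_class
    ) != set(config_alt.primaries_per_class):
        raise ConfigError("null and alternative configs must share class structure")
    type1, degen_null = _rejection_rate(config_null, replicates, alpha)
    power, degen_alt = _rejection_rate(config_alt, replicates, alpha)
    return {
        "type1_rate": type1,
        "power": power,
        "alpha": alpha,
        "replicates": replicates,
        "n_degenerate_null": degen_null,
        "n_degenerate_alt": degen_alt,
    }
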