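"""Published inputs of the diet-heart secondary-prevention citation study.

The study network links 62 reviews (28 supportive, 17 neutral, 17
unsupportive of dietary fat modification) to the four secondary-
prevention RCTs published 1965-1968: the Oslo Diet-Heart Study (the
only supportive trial), the MRC Soya-bean Oil Study, the Rose Corn Oil
Study and the Research Committee Low-Fat Study (all unsupportive).

This module records, as structured input data, what the study prints:
the citation contingency table (review class x trial), the per-class
out-degree histograms, and the allocation of the single-citing reviews.
Those marginals fully determine every aggregate statistic of the
network; :func:`load_study_corpus` realises a concrete corpus
consistent with them for end-to-end runs.
"""

from __future__ import annotations

import numpy as np

from .corpus import CitationRecord, Paper
from .metrics import ContingencyTable
from .synthetic import ClassMarginals, MarginalProfile, PrimarySpec, build_fixture_from_marginals

__all__ = [
    "TRIALS",
    "REVIEWS_PER_CLASS",
    "study_contingency_table",
    "study_profile",
    "load_study_corpus",
]

#: The four trials: id, stance, publication year.
TRIALS: tuple[PrimarySpec, ...] = (
    PrimarySpec("T1-oslo", "supportive", 1966),
    PrimarySpec("T2-mrc-soya", "unsupportive", 1968),
    PrimarySpec("T3-rose-corn", "unsupportive", 1965),
    PrimarySpec("T4-lowfat", "unsupportive", 1965),
)

REVIEWS_PER_CLASS = {"supportive": 28, "neutral": 17, "unsupportive": 17}

#: Citations received by each trial, per review class (the published
#: contingency table; columns ordered Oslo, MRC, Rose, Low-fat).
_CITATIONS = {
    "neutral": {"T1-oslo": 17, "T2-mrc-soya": 15, "T3-rose-corn": 7, "T4-lowfat": 7},
    "unsupportive": {"T1-oslo": 12, "T2-mrc-soya": 12, "T3-rose-corn": 6, "T4-lowfat": 8},
    "supportive": {"T1-oslo": 28, "T2-mrc-soya": 5, "T3-rose-corn": 2, "T4-lowfat": 2},
}

#: Out-degree histograms per review class: how many reviews cite k of
#: the four trials.
_OUT_DEGREE_HISTS = {
    "neutral": {1: 1, 2: 9, 3: 1, 4: 6},
    "unsupportive": {1: 3, 2: 9, 3: 3, 4: 2},
    "supportive": {1: 23, 2: 2, 3: 2, 4: 1},
}

#: All single-citing reviews cite the Oslo study: every neutral and
#: supportive review cites Oslo (its column equals the class size), and
#: the three unsupportive single-citers are stated to cite only the
#: supportive trial.
_SINGLETONS = {
    "neutral": {"T1-oslo": 1},
    "unsupportive": {"T1-oslo": 3},
    "supportive": {"T1-oslo": 23},
}


def study_contingency_table() -> ContingencyTable:
    """The published review-class x trial citation table, with marginals."""
    classes = tuple(sorted(_CITATIONS))
    cols = tuple(t.id for t in TRIALS)
    observed = np.array(
        [[_CITATIONS[c][t] for t in cols] for c in classes], dtype=np.int_
    )
    return ContingencyTable(observed=observed, row_labels=classes, col_labels=cols)


def study_profile() -> MarginalProfile:
    """Marginal profile of the study network (review years 1969-1984)."""
    return MarginalProfile(
        primaries=TRIALS,
        classes={
            cls: ClassMarginals(
                out_degree_hist=_OUT_DEGREE_HISTS[cls],
                column_counts=_CITATIONS[cls],
                singleton_allocation=_SINGLETONS[cls],
            )
            for cls in _CITATIONS
        },
        review_year_range=(1969, 1984),
    )


def load_study_corpus(seed: int = 0) -> tuple[list[Paper], list[CitationRecord]]:
    """A concrete corpus realising the study's published marginals.

    The 66 papers and 121 citations reproduce every aggregate the study
    reports (densities, degree totals, utilisation histograms, bias
    counts, the contingency table); the review-by-review incidence is a
    seeded-random valid completion, since only marginals are published.
    """
    return build_fixture_from_marginals(study_profile(), seed=seed)
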