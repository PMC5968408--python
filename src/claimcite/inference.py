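"""Pearson chi-square test of independence on the citation contingency table.

The statistic is the classic sum over cells of (O - E)^2 / E with
expected counts from the product of the marginals, no continuity
correction, and df = (rows - 1)(columns - 1).  The upper-tail p-value
is computed through the regularized incomplete gamma function,
P(X^2 > x | df) = Q(df/2, x/2), evaluated by a power series for
x < a + 1 and by a modified-Lentz continued fraction otherwise
(tolerance 1e-12 on the regularized value).

The textbook validity conditions — expected count above 5 in at least
80% of cells and at least 1 everywhere — are evaluated and attached to
the result; they are advisory, not blocking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import ContingencyTable

__all__ = [
    "ChiSquareResult",
    "ValidityRecord",
    "DegenerateTableError",
    "pearson_chi_square",
    "check_validity",
    "chi_square_sf",
    "regularized_gamma_q",
]

_TOL = 1e-12
_MAX_ITER = 10_000


class DegenerateTableError(ValueError):
    """Raised when a zero marginal makes an expected count zero."""


@dataclass(frozen=True)
class ValidityRecord:
    fraction_expected_gt5: float
    min_expected: float
    conditions_met: bool


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    validity: ValidityRecord


def _gamma_p_series(a: float, x: float) -> float:
    """Regularized lower incomplete gamma P(a, x) by power series (x < a + 1)."""
    if x <= 0.0:
        return 0.0
    term = 1.0 / a
    total = term
    ap = a
    for _ in range(_MAX_ITER):
        ap += 1.0
        term *= x / ap
        total += term
        if abs(term) < abs(total) * _TOL:
            break
    return total * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _gamma_q_contfrac(a: float, x: float) -> float:
    """Regularized upper incomplete gamma Q(a, x) by continued fraction (x >= a + 1).

    Modified Lentz evaluation of the standard continued fraction
    x^a e^-x / Gamma(a) * 1/(x+1-a- 1*(1-a)/(x+3-a- ...)).
    """
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, _MAX_ITER + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < _TOL:
            break
    return math.exp(-x + a * math.log(x) - math.lgamma(a)) * h


def regularized_gamma_q(a: float, x: float) -> float:
    """Q(a, x) = Gamma(a, x) / Gamma(a), the upper regularized incomplete gamma."""
    if a <= 0.0:
        raise ValueError("shape parameter a must be positive")
    if x < 0.0:
        raise ValueError("x must be non-negative")
    if x == 0.0:
        return 1.0
    if x < a + 1.0:
        return 1.0 - _gamma_p_series(a, x)
    return _gamma_q_contfrac(a, x)


def chi_square_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution with ``df`` dof."""
    if df < 1:
        raise ValueError("df must be a positive integer")
    if x < 0.0:
        raise ValueError("chi-square statistic cannot be negative")
    return regularized_gamma_q(df / 2.0, x / 2.0)


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence: row_i x col_j / N."""
    if table.N == 0:
        raise DegenerateTableError("empty table: N = 0")
    expected = np.outer(table.row_totals, table.column_totals) / table.N
    if (expected == 0.0).any():
        zero_rows = [
            table.row_labels[i] for i in np.flatnonzero(table.row_totals == 0)
        ]
        zero_cols = [
            table.col_labels[j] for j in np.flatnonzero(table.column_totals == 0)
        ]
        raise DegenerateTableError(
            f"zero marginal(s) give zero expected counts "
            f"(rows {zero_rows}, columns {zero_cols})"
        )
    return expected


def check_validity(table: ContingencyTable) -> ValidityRecord:
    """Advisory validity conditions for the chi-square approximation.

    Met when the expected count exceeds 5 in at least 80% of cells and
    no expected count falls below 1.
    """
    expected = expected_counts(table)
    fraction = float((expected > 5.0).mean())
    min_expected = float(expected.min())
    return ValidityRecord(
        fraction_expected_gt5=fraction,
        min_expected=min_expected,
        conditions_met=fraction >= 0.8 and min_expected >= 1.0,
    )


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction.

    Raises
    ------
    DegenerateTableError
        If any row or column marginal is zero, or the table is smaller
        than 2 x 2.
    """
    if len(table.row_labels) < 2 or len(table.col_labels) < 2:
        raise DegenerateTableError(
            "chi-square needs at least 2 rows and 2 columns"
        )
    expected = expected_counts(table)
    statistic = float(((table.observed - expected) ** 2 / expected).sum())
    df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        p_value=chi_square_sf(statistic, df),
        expected=expected,
        validity=check_validity(table),
    )
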