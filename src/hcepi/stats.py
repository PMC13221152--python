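"""Fourfold-table statistics: prevalence ratio, odds ratio, Fisher's exact
test, Wald proportion intervals and Bonferroni correction.

All association statistics in the pipeline reduce to a 2x2 table

    =============  ========  ==========
    group          factor +  factor -
    =============  ========  ==========
    exposed/index  a         b
    reference      c         d
    =============  ========  ==========

The prevalence ratio PR = (a/(a+b)) / (c/(c+d)) carries a Katz
log-interval; the odds ratio OR = ad/bc carries a Woolf log-interval; the
two-sided Fisher p-value sums hypergeometric probabilities of all tables
(fixed margins) no more probable than the observed one, computed with
exact integer weights so tie handling never depends on floating-point
rounding.  Confidence level is fixed at 95% (z = 1.96), matching the
convention for this kind of descriptive epidemiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "FourfoldTable",
    "RatioResult",
    "prevalence_ratio",
    "odds_ratio",
    "fisher_exact",
    "proportion_ci",
    "bonferroni",
]

_Z = 1.96


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 counts; rows are groups, columns factor present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def transpose(self) -> "FourfoldTable":
        return FourfoldTable(self.a, self.c, self.b, self.d)

    def swap_groups(self) -> "FourfoldTable":
        return FourfoldTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    zero_cell: bool = False

    def __iter__(self):
        return iter((self.estimate, self.ci_low, self.ci_high))


def prevalence_ratio(t: FourfoldTable, continuity: bool = False) -> RatioResult:
    """Prevalence ratio of row 1 vs. row 2 with a Katz 95% CI.

    With ``continuity=True`` a 0.5 correction is added to every cell when a
    numerator cell is zero, giving a finite interval; otherwise a zero
    numerator yields estimate/CI of 0 or inf flagged via ``zero_cell``.
    """
    n1, n2 = t.row_totals
    if n1 == 0 or n2 == 0:
        raise ValueError("both row totals must be positive for a prevalence ratio")
    a, b, c, d = t.a, t.b, t.c, t.d
    zero = a == 0 or c == 0
    if zero and continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    p1 = a / (a + b)
    p2 = c / (c + d)
    if p2 == 0:
        return RatioResult(math.inf, math.nan, math.nan, zero_cell=True)
    pr = p1 / p2
    if p1 == 0:
        return RatioResult(0.0, math.nan, math.nan, zero_cell=True)
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo = math.exp(math.log(pr) - _Z * se)
    hi = math.exp(math.log(pr) + _Z * se)
    return RatioResult(pr, lo, hi, zero_cell=zero)


def odds_ratio(t: FourfoldTable) -> RatioResult:
    """Odds ratio ad/bc with a Woolf 95% CI.

    A 0.5 continuity correction is applied to every cell iff any cell is
    zero.  Two zero cells on a diagonal leave the odds ratio undefined and
    return NaN.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return RatioResult(math.nan, math.nan, math.nan, zero_cell=True)
    zero = 0 in (a, b, c, d)
    if zero:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - _Z * se)
    hi = math.exp(math.log(orr) + _Z * se)
    return RatioResult(orr, lo, hi, zero_cell=zero)


def fisher_exact(t: FourfoldTable) -> float:
    """Two-sided Fisher's exact p-value.

    Enumerates the hypergeometric support with exact integer weights
    ``C(r1, k) * C(r2, c1 - k)`` and sums the probability of every table at
    most as probable as the observed one ("probability-mass" two-sided
    definition).  With a zero margin only one table is attainable and
    p = 1.
    """
    r1, r2 = t.row_totals
    c1, _ = t.col_totals
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    w_obs = math.comb(r1, t.a) * math.comb(r2, c1 - t.a)
    num = 0
    tot = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        tot += w
        if w <= w_obs:
            num += w
    return num / tot


def proportion_ci(successes: int, n: int) -> RatioResult:
    """Wald 95% interval for a binomial proportion, truncated to [0, 1].

    Degenerate at p-hat of exactly 0 or 1 (zero-width interval); flagged
    via ``zero_cell``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be between 0 and n")
    p = successes / n
    se = math.sqrt(p * (1 - p) / n)
    return RatioResult(
        p, max(0.0, p - _Z * se), min(1.0, p + _Z * se), zero_cell=(se == 0.0)
    )


def bonferroni(p_values: Sequence[float], m: int = 15) -> list[float]:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value out of range: {p!r}")
        out.append(min(1.0, m * p))
    return out
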