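"""Statistical tests and descriptive conventions used throughout the pipeline.

Every test is two-tailed and every summary statistic states its SD convention
explicitly, so any number the analysis modules report can be reproduced by
hand.  The tests themselves are delegated to :mod:`scipy.stats`; this module
pins down the conventions (pooled-proportion z, Pearson chi-square without
continuity correction, Welch vs pooled t) and the degenerate-input behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _stats

__all__ = [
    "TestResult",
    "two_proportion_z",
    "chi_square",
    "paired_t",
    "independent_t",
    "descriptive",
    "round_half_away",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-tailed hypothesis test.

    ``p_value`` is ``None`` when the test is degenerate (e.g. a pooled
    proportion of 0 or 1, or a paired test with zero variance), in which case
    ``degenerate`` is set.
    """

    statistic: float
    p_value: float | None
    method: str
    df: float | None = None
    degenerate: bool = False


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero.

    This is the convention used when percentages and mm Hg values are printed
    to one decimal (so 56.35 -> 56.4, -0.25 -> -0.3), as opposed to Python's
    banker's rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-proportion z test with a two-tailed normal p-value.

    The statistic squares to the Pearson chi-square of the corresponding
    2x2 table (no continuity correction on either side).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside [0, {n}]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(0.0, None, "two_proportion_z", degenerate=True)
    p1, p2 = x1 / n1, x2 / n2
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * _stats.norm.sf(abs(z))
    return TestResult(z, p, "two_proportion_z")


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No Yates continuity correction is applied (so that on 2x2 tables the
    statistic equals the square of the pooled two-proportion z).  All
    expected counts must be strictly positive.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("chi_square requires an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total if total else np.zeros_like(counts)
    if (expected <= 0).any():
        raise ValueError("all expected counts must be > 0")
    stat, p, df, _ = _stats.chi2_contingency(counts, correction=False)
    return TestResult(float(stat), float(p), "chi_square", df=float(df))


def paired_t(differences) -> TestResult:
    """Two-tailed paired t test on pre-post difference scores."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("paired_t needs at least 2 differences")
    if np.ptp(d) == 0.0:
        return TestResult(float("nan"), None, "paired_t", df=float(d.size - 1), degenerate=True)
    res = _stats.ttest_1samp(d, 0.0)
    return TestResult(float(res.statistic), float(res.pvalue), "paired_t", df=float(d.size - 1))


def independent_t(a, b, welch: bool = True) -> TestResult:
    """Two-tailed independent-samples t test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("independent_t needs at least 2 observations per group")
    res = _stats.ttest_ind(a, b, equal_var=not welch)
    method = "independent_t_welch" if welch else "independent_t_pooled"
    df = float(res.df) if hasattr(res, "df") else None
    if np.isnan(res.statistic):
        return TestResult(float("nan"), None, method, df=df, degenerate=True)
    return TestResult(float(res.statistic), float(res.pvalue), method, df=df)


def descriptive(values, sd_convention: str = "sample") -> tuple[float, float]:
    """Mean and SD of ``values`` under an explicit SD convention.

    ``"population"`` divides by n (the convention behind the weekday-adherence
    summary rows); ``"sample"`` divides by n-1 (the convention behind the
    blood-pressure tables, consistent with t statistics).  A single value has
    SD 0 under the population convention and is rejected under the sample one.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("descriptive needs at least one value")
    if sd_convention == "population":
        ddof = 0
    elif sd_convention == "sample":
        if v.size < 2:
            raise ValueError("sample SD needs at least two values")
        ddof = 1
    else:
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    return float(v.mean()), float(v.std(ddof=ddof))
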