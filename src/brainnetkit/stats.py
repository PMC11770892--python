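"""Two-group statistics: t-tests from summaries or raw data, 2x2 chi-square,
Pearson correlation with p-values, and Benjamini-Hochberg FDR.

The two-sample t-test defaults to the Welch (unequal-variance) form with
Satterthwaite degrees of freedom; a pooled-variance variant is available by
flag.  All p-values are two-sided.  The minimum representable p is floored at
1e-300 so downstream log transforms never divide by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryStats",
    "TestResult",
    "welch_t_from_summary",
    "welch_t",
    "chi_square_2x2",
    "pearson_with_p",
    "pearson_p_from_r",
    "fdr_bh",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class SummaryStats:
    """Group summary (n, mean, sd) as printed in a demographics table."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("sd must be finite and >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    effect_direction: int  # sign of (group1 - group2) effect, 0 if none

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _floor_p(p: float) -> float:
    return float(min(max(p, P_FLOOR), 1.0))


def welch_t_from_summary(
    g1: SummaryStats, g2: SummaryStats, pooled: bool = False
) -> TestResult:
    """Two-sample t-test from (n, mean, sd) summaries.

    Welch by default: t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2) on Satterthwaite
    degrees of freedom.  ``pooled=True`` uses the classical equal-variance
    form on n1+n2-2 df.
    """
    d = g1.mean - g2.mean
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if g1.sd == 0 and g2.sd == 0:
        if d == 0:
            return TestResult(0.0, float(g1.n + g2.n - 2), 1.0, 0)
        return TestResult(np.sign(d) * np.inf, float(g1.n + g2.n - 2), P_FLOOR, int(np.sign(d)))
    if pooled:
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        se = np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    else:
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
        se = np.sqrt(v1 + v2)
    t = d / se
    p = _floor_p(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, int(np.sign(d)))


def welch_t(x, y, pooled: bool = False) -> TestResult:
    """Raw-data two-sample t-test; agrees with the summary form exactly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_summary(
        SummaryStats(len(x), x.mean(), x.std(ddof=1)),
        SummaryStats(len(y), y.mean(), y.std(ddof=1)),
        pooled=pooled,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> TestResult:
    """Chi-square test of independence on a 2x2 table [[a, b], [c, d]].

    chi2 = n(|ad - bc| - corr)^2 / ((a+b)(c+d)(a+c)(b+d)) with corr = n/2
    under the Yates continuity correction, else 0; p from chi2 on 1 df.
    """
    if min(a, b, c, d) < 0 or a + b + c + d == 0:
        raise ValueError("counts must be >= 0 with a positive total")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("chi-square undefined with a zero marginal")
    corr = n / 2 if yates else 0.0
    num = max(abs(a * d - b * c) - corr, 0.0) ** 2 * n
    chi2 = num / np.prod([float(m) for m in margins])
    p = _floor_p(sps.chi2.sf(chi2, 1))
    return TestResult(float(chi2), 1.0, p, int(np.sign(a * d - b * c)))


def pearson_p_from_r(r: float, n: int) -> TestResult:
    """Two-sided p for a Pearson r given the sample size.

    Uses the exact t transform t = r*sqrt((n-2)/(1-r^2)) on n-2 df, which is
    how printed (r, n) pairs convert to p-values.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must lie in [-1, 1]")
    df = n - 2
    if abs(r) == 1.0:
        return TestResult(np.sign(r) * np.inf, float(df), P_FLOOR, int(np.sign(r)))
    t = r * np.sqrt(df / (1 - r**2))
    p = _floor_p(2 * sps.t.sf(abs(t), df))
    return TestResult(float(r), float(df), p, int(np.sign(r)))


def pearson_with_p(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples of length >= 3 required")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return pearson_p_from_r(r, len(x))


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask) at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
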