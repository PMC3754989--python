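"""Group-level statistics for cohort comparisons.

Chi-square tests of case-frequency tables (with Yates continuity
correction for 2x2 tables), the exact two-tailed binomial test behind the
solver criterion, two-sample t-tests computable from printed summary
statistics (pooled or Welch), and Pearson/Spearman correlations.  All
p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float


def _as_table(table) -> np.ndarray:
    arr = np.asarray(
        table.to_numpy() if isinstance(table, pd.DataFrame) else table, dtype=float
    )
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return arr


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the margins; with ``yates`` (2x2 tables
    only) each |O - E| is shrunk by 0.5, floored at zero, before squaring.
    """
    arr = _as_table(table)
    if yates and arr.shape != (2, 2):
        raise ValueError("Yates correction applies only to 2x2 tables")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    statistic, p, df, _ = sps.chi2_contingency(arr, correction=yates)
    return TestResult(statistic=float(statistic), df=float(df), p=float(p))


def exact_binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-tailed binomial p-value by tail doubling.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Binomial(n, p0);
    for p0 = 0.5 this equals the symmetric sum of outcomes at least as
    extreme as k.
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def two_sample_t_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-sample t-test from group summary statistics.

    ``pooled`` assumes equal variances (df = n1 + n2 - 2); ``welch`` uses
    the Satterthwaite approximation, giving possibly fractional df.
    Usable directly on the rounded means/SDs printed in reports.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        df = n1 + n2 - 2
        pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p))


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d sequences of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison alpha: alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
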