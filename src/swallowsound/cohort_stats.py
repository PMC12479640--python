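"""Cohort-level descriptive and inferential statistics.

Covers the statistical toolkit of the profiling study: mean/SD summaries of
the acoustic parameters, a Shapiro-Wilk normality gate, Pearson correlation
with Fisher-z confidence intervals, Spearman rank correlation, and the
correlation-based power calculation used to plan the cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "summarize",
    "shapiro_wilk_gate",
    "pearson_with_ci",
    "spearman",
    "sample_size_correlation",
    "correlation_report",
]


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]  # 25th and 75th percentiles
    min: float
    max: float
    n: int


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD (n-1), median, IQR (linear-interpolation quantiles)."""
    x = np.asarray(values, dtype=np.float64)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, q75 = np.percentile(x, [25, 75])
    return SummaryStats(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        iqr=(float(q25), float(q75)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        n=int(x.size),
    )


def shapiro_wilk_gate(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Shapiro-Wilk test as a normality gate: (W, p, is_normal at alpha)."""
    x = np.asarray(values, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p > alpha)


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval.

    CI = tanh(atanh(r) +- z_{(1+conf)/2} / sqrt(n - 3)).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    half = stats.norm.ppf((1 + confidence) / 2) / math.sqrt(x.size - 3)
    return r, math.tanh(z - half), math.tanh(z + half)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (average ties)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def sample_size_correlation(
    rho: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Sample size to detect a correlation of magnitude ``rho``.

    Fisher-z approximation with ceiling rounding:
    n = ceil(((z_{1-alpha/2} + z_power) / atanh(rho))^2 + 3).
    """
    if not 0 < rho < 1:
        raise ValueError("effect size rho must be in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    z_power = stats.norm.ppf(power)
    return math.ceil(((z_alpha + z_power) / math.atanh(rho)) ** 2 + 3)


def correlation_report(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Pearson + Spearman estimates for named column pairs of a cohort table.

    Rows with a missing value in either column are dropped pairwise.
    Output columns: pair, method, estimate, ci_low, ci_high, n (Spearman
    rows carry NaN CIs).
    """
    rows = []
    for a, b in pairs:
        sub = cohort[[a, b]].dropna()
        r, lo, hi = pearson_with_ci(sub[a], sub[b], confidence)
        rows.append({"pair": f"{a}~{b}", "method": "pearson",
                     "estimate": r, "ci_low": lo, "ci_high": hi,
                     "n": len(sub)})
        rows.append({"pair": f"{a}~{b}", "method": "spearman",
                     "estimate": spearman(sub[a], sub[b]),
                     "ci_low": float("nan"), "ci_high": float("nan"),
                     "n": len(sub)})
    return pd.DataFrame(rows)
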