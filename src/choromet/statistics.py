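"""Normality-gated paired comparisons, correlations and Bland-Altman analysis.

The battery mirrors standard small-cohort ophthalmic practice: Shapiro-Wilk
decides between the parametric and rank test for each endpoint (paired t vs
Wilcoxon signed-rank for within-subject changes; Pearson vs Spearman for
associations), and within-session repeatability is summarized by Bland-Altman
limits of agreement (mean difference +/- 1.96 sample SD).  No multiple-testing
correction is applied; each endpoint is tested at its own alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "CorrelationResult",
    "BlandAltmanResult",
    "paired_compare",
    "correlate",
    "bland_altman",
    "bland_altman_from_summary",
    "paired_t_from_summary",
]


@dataclass
class PairedComparison:
    """One endpoint's paired baseline/condition comparison."""

    parameter: str
    baseline: np.ndarray
    condition: np.ndarray
    differences: np.ndarray
    shapiro_p: float
    test_used: str  # "t" | "wilcoxon"
    statistic: float
    p_value: float
    degenerate: bool = False

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.differences))

    @property
    def sd_difference(self) -> float:
        return float(np.std(self.differences, ddof=1))


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    normality_p: tuple[float, float]


@dataclass
class BlandAltmanResult:
    """Mean difference, sample SD and 95% limits of agreement (mean +/- 1.96 SD)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def paired_compare(
    baseline,
    condition,
    alpha: float = 0.05,
    parameter: str = "",
) -> PairedComparison:
    """Paired comparison with a Shapiro-Wilk gate on the differences.

    The paired t-test is used when the differences pass normality at ``alpha``,
    otherwise the Wilcoxon signed-rank test (zero differences excluded, exact
    null distribution for n <= 25, normal approximation beyond).  Identical
    vectors are a degenerate case reported with p = 1.
    """
    b = np.asarray(baseline, dtype=np.float64)
    c = np.asarray(condition, dtype=np.float64)
    if b.shape != c.shape:
        raise ValueError("baseline and condition must have equal length")
    ok = np.isfinite(b) & np.isfinite(c)
    b, c = b[ok], c[ok]
    if b.size < 3:
        raise ValueError("need at least 3 complete pairs")
    d = c - b
    if np.all(d == 0):
        return PairedComparison(parameter, b, c, d, 1.0, "t", 0.0, 1.0, degenerate=True)
    shapiro_p = float(sps.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        res = sps.ttest_rel(c, b)
        return PairedComparison(
            parameter, b, c, d, shapiro_p, "t", float(res.statistic), float(res.pvalue)
        )
    nz = d[d != 0]
    if nz.size == 0:
        return PairedComparison(parameter, b, c, d, shapiro_p, "wilcoxon", 0.0, 1.0, degenerate=True)
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", method=method)
    return PairedComparison(
        parameter, b, c, d, shapiro_p, "wilcoxon", float(res.statistic), float(res.pvalue)
    )


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson when both variables pass Shapiro-Wilk at ``alpha``, else Spearman."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a variable")
    px = float(sps.shapiro(x).pvalue)
    py = float(sps.shapiro(y).pvalue)
    if px >= alpha and py >= alpha:
        r, p = sps.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p), (px, py))
    r, p = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(r), float(p), (px, py))


def bland_altman(scan1, scan2) -> BlandAltmanResult:
    """Bland-Altman repeatability of two same-session measurements.

    Differences are taken scan2 - scan1; limits of agreement are the
    conventional mean +/- 1.96 x sample SD (ddof=1).
    """
    a = np.asarray(scan1, dtype=np.float64)
    b = np.asarray(scan2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bland_altman_from_summary(mean, sd, int(d.size))


def bland_altman_from_summary(mean_diff: float, sd_diff: float, n: int = 0) -> BlandAltmanResult:
    """Limits of agreement from a printed mean/SD summary (summary-input mode)."""
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        n=n,
    )


def paired_t_from_summary(mean_diff: float, sd_diff: float, n: int) -> tuple[float, float]:
    """Two-sided one-sample t on a difference summary: returns (t, p)."""
    if n < 2 or sd_diff <= 0:
        raise ValueError("need n >= 2 and positive SD")
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
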