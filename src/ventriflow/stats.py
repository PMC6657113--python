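"""Normality-gated paired rest-stress statistics.

The pipeline mirrors standard small-cohort hemodynamics practice:
Shapiro-Wilk decides between parametric and non-parametric branches at
alpha = 0.05. Paired rest-stress differences are tested with the paired
t-test when the differences look normal and the Wilcoxon signed-rank
test otherwise; associations use Pearson's r when both variables look
normal and Spearman's rank correlation otherwise. Descriptives follow
the same gate: mean +- SD (sample SD, n-1) under normality, median
[interquartile range] otherwise. All tests are two-sided; correlation
strength is classified on |r| as poor < 0.5 <= moderate <= 0.70 < good
<= 0.85 < strong <= 0.95 < excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05

#: upper edges of the |r| classification bands; ties fall to the weaker band
_STRENGTH_BANDS = (
    (0.5, "poor"),        # [0, 0.5)
    (0.70, "moderate"),   # [0.5, 0.70]
    (0.85, "good"),       # (0.70, 0.85]
    (0.95, "strong"),     # (0.85, 0.95]
    (1.0, "excellent"),   # (0.95, 1]
)


@dataclass(frozen=True)
class DescriptiveSummary:
    """Dual-form descriptive: mean +- SD when normal, median [IQR] otherwise."""

    n: int
    normal: bool
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]

    def __str__(self) -> str:
        if self.normal:
            return f"{self.mean:.3g} ± {self.sd:.3g}"
        return f"{self.median:.3g} [{self.iqr[0]:.3g}-{self.iqr[1]:.3g}]"


@dataclass(frozen=True)
class ComparisonResult:
    """Paired rest-vs-stress comparison of one metric."""

    n: int
    diff: DescriptiveSummary
    relative_diff: DescriptiveSummary
    p_value: float
    test_used: str  # "paired_t" | "wilcoxon_signed_rank"
    normality_p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    method: str  # "pearson" | "spearman"
    strength: str
    n: int


def relative_difference(rest, stress):
    """Percent change from rest to stress: (stress - rest)/rest * 100.

    Element-wise on arrays; entries with rest == 0 are returned as NaN
    (undefined, flagged missing) with a warning.
    """
    rest = np.asarray(rest, dtype=float)
    stress = np.asarray(stress, dtype=float)
    zero = rest == 0
    if np.any(zero):
        warnings.warn("relative difference undefined where rest == 0; set to NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, (stress - rest) / np.where(zero, 1.0, rest) * 100.0)
    return float(out) if out.ndim == 0 else out


def normality_test(values, alpha: float = ALPHA) -> tuple[float, bool]:
    """Shapiro-Wilk p-value and the gate decision p >= alpha.

    A (near-)constant vector is degenerate: Shapiro-Wilk is undefined,
    and we conservatively report non-normal with p = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) < 1e-12 * max(1.0, np.max(np.abs(x))):
        return 0.0, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.shapiro(x).pvalue)
    return p, p >= alpha


def describe(values, alpha: float = ALPHA) -> DescriptiveSummary:
    """Gated descriptive summary; n < 3 defaults to the median form."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot describe an empty sample")
    normal = False
    if x.size >= 3:
        _, normal = normality_test(x, alpha)
    q1, q3 = np.percentile(x, [25, 75])
    return DescriptiveSummary(
        n=int(x.size),
        normal=bool(normal),
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        iqr=(float(q1), float(q3)),
    )


def _wilcoxon_p(d: np.ndarray) -> float:
    # exact null distribution for small n (no ties/zeros), otherwise
    # normal approximation with continuity correction
    nonzero = d[d != 0]
    method = "exact" if (nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.wilcoxon(d, correction=True, method=method).pvalue)


def paired_compare(rest, stress, alpha: float = ALPHA) -> ComparisonResult:
    """Paired comparison of stress vs rest for one metric.

    Shapiro-Wilk on the differences d = stress - rest gates the paired
    t-test (normal) against the Wilcoxon signed-rank test (not). When
    every difference is zero the comparison is vacuous: p = 1.
    """
    rest = np.asarray(rest, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if rest.shape != stress.shape:
        raise ValueError("rest and stress must be paired")
    keep = ~(np.isnan(rest) | np.isnan(stress))
    rest, stress = rest[keep], stress[keep]
    n = rest.size
    if n < 3:
        raise ValueError("paired comparison needs n >= 3 complete pairs")
    d = stress - rest
    norm_p, is_normal = normality_test(d, alpha)
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; comparison is vacuous")
        p, test = 1.0, "wilcoxon_signed_rank"
    elif is_normal:
        p = float(sps.ttest_rel(stress, rest).pvalue)
        test = "paired_t"
    else:
        p = _wilcoxon_p(d)
        test = "wilcoxon_signed_rank"
    return ComparisonResult(
        n=n,
        diff=describe(d, alpha),
        relative_diff=describe(relative_difference(rest, stress), alpha),
        p_value=p,
        test_used=test,
        normality_p=norm_p,
    )


def classify_correlation(r: float) -> str:
    """Strength label for |r|; boundary ties go to the weaker band."""
    a = abs(float(r))
    if a > 1.0:
        raise ValueError("|r| cannot exceed 1")
    if a < 0.5:
        return "poor"
    if a <= 0.70:
        return "moderate"
    if a <= 0.85:
        return "good"
    if a <= 0.95:
        return "strong"
    return "excellent"


def correlate(x, y, alpha: float = ALPHA) -> CorrelationResult:
    """Association between two paired variables with a normality gate.

    Pearson's r when BOTH variables pass Shapiro-Wilk, Spearman's rank
    correlation otherwise; two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation needs n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    _, xn = normality_test(x, alpha)
    _, yn = normality_test(y, alpha)
    if xn and yn:
        res = sps.pearsonr(x, y)
        method = "pearson"
    else:
        res = sps.spearmanr(x, y)
        method = "spearman"
    r = float(res.statistic if hasattr(res, "statistic") else res.correlation)
    return CorrelationResult(
        r=r, p_value=float(res.pvalue), method=method,
        strength=classify_correlation(r), n=int(x.size),
    )
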