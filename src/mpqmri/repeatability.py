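"""Double-baseline Bland-Altman repeatability on the log scale.

For paired baseline measurements x_i1, x_i2 the within-subject SD of the
natural-log values is

    s_W = sqrt( sum_i d_i^2 / (2 N) ),   d_i = ln(x_i2) - ln(x_i1),

from which the test-retest coefficient of variation and 95% limits of
agreement on a percentage scale follow as

    CoV  = 100 * sqrt(exp(s_W^2) - 1)
    LoA± = 100 * (exp(±1.96 * sqrt(2) * s_W) - 1).

Summary statistics that can be negative (skew, kurtosis) use an
untransformed (absolute-scale) Bland-Altman path instead.  Confidence
intervals use a chi-squared pivot on the within-subject variance
(N * s_W^2 / sigma_W^2 ~ chi2(N) for a duplicate design), propagated
through the monotone CoV/LoA transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

__all__ = [
    "RepeatabilityResult",
    "ChangeClass",
    "repeatability_metrics",
    "bland_altman_points",
    "classify_individual_change",
    "cov_from_sw",
    "sw_from_cov",
    "loa_from_sw",
]

LOA_FACTOR = 1.96 * math.sqrt(2.0)


def cov_from_sw(s_w: float) -> float:
    """Percent CoV from the within-subject log-SD."""
    return 100.0 * math.sqrt(math.expm1(s_w**2))


def sw_from_cov(cov_pct: float) -> float:
    """Within-subject log-SD implied by a percent CoV (inverse of cov_from_sw)."""
    return math.sqrt(math.log1p((cov_pct / 100.0) ** 2))


def loa_from_sw(s_w: float) -> tuple[float, float]:
    """(upper, lower) 95% limits of agreement in percent."""
    return (
        100.0 * math.expm1(LOA_FACTOR * s_w),
        100.0 * math.expm1(-LOA_FACTOR * s_w),
    )


class ChangeClass(str, Enum):
    SIGNIFICANT_INCREASE = "significant_increase"
    SIGNIFICANT_DECREASE = "significant_decrease"
    WITHIN_LOA = "within_LoA"


@dataclass
class RepeatabilityResult:
    """Repeatability of one summary statistic across a double-baseline cohort.

    On the ``log_percent`` scale CoV and LoA are percentages; on the
    ``absolute`` scale the LoA fields hold raw-difference limits
    (mean(d) ± 1.96 SD(d)) and CoV/s_W are NaN.
    """

    statistic: str
    n: int
    s_w: float
    cov_pct: float
    loa_upper_pct: float
    loa_lower_pct: float
    ci_cov: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    scale: str


def repeatability_metrics(
    baseline1,
    baseline2,
    scale: str = "log_percent",
    statistic: str = "",
    conf: float = 0.95,
) -> RepeatabilityResult:
    """Bland-Altman repeatability metrics for paired baselines."""
    x1 = np.asarray(baseline1, dtype=float)
    x2 = np.asarray(baseline2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("baseline1 and baseline2 must be 1D and paired")
    n = len(x1)
    if n < 2:
        raise ValueError("need at least two pairs")
    alpha = 1.0 - conf

    if scale == "log_percent":
        bad = np.flatnonzero((x1 <= 0) | (x2 <= 0))
        if bad.size:
            raise ValueError(
                f"non-positive measurement for pair index {bad[0]} on the log scale"
            )
        d = np.log(x2) - np.log(x1)
        s_w = math.sqrt(float(np.sum(d**2)) / (2 * n))
        cov = cov_from_sw(s_w)
        loa_up, loa_lo = loa_from_sw(s_w)
        # chi-squared pivot: N s_W^2 / sigma_W^2 ~ chi2(N)
        q_lo, q_hi = chi2.ppf([alpha / 2, 1 - alpha / 2], df=n)
        sw_lo = math.sqrt(n * s_w**2 / q_hi)
        sw_hi = math.sqrt(n * s_w**2 / q_lo)
        ci_cov = (cov_from_sw(sw_lo), cov_from_sw(sw_hi))
        ci_up = (loa_from_sw(sw_lo)[0], loa_from_sw(sw_hi)[0])
        # the lower LoA decreases as s_W grows
        ci_lo = (loa_from_sw(sw_hi)[1], loa_from_sw(sw_lo)[1])
        return RepeatabilityResult(
            statistic=statistic, n=n, s_w=s_w, cov_pct=cov,
            loa_upper_pct=loa_up, loa_lower_pct=loa_lo,
            ci_cov=ci_cov, ci_loa_upper=ci_up, ci_loa_lower=ci_lo,
            scale="log_percent",
        )

    if scale == "absolute":
        d = x2 - x1
        mean_d = float(np.mean(d))
        sd_d = float(np.std(d, ddof=1))
        z = norm.ppf(1 - alpha / 2)
        loa_up = mean_d + z * sd_d
        loa_lo = mean_d - z * sd_d
        # standard large-sample variance of a Bland-Altman limit
        se_loa = sd_d * math.sqrt(1.0 / n + z**2 / (2 * (n - 1)))
        return RepeatabilityResult(
            statistic=statistic, n=n, s_w=float("nan"), cov_pct=float("nan"),
            loa_upper_pct=loa_up, loa_lower_pct=loa_lo,
            ci_cov=(float("nan"), float("nan")),
            ci_loa_upper=(loa_up - z * se_loa, loa_up + z * se_loa),
            ci_loa_lower=(loa_lo - z * se_loa, loa_lo + z * se_loa),
            scale="absolute",
        )

    raise ValueError(f"unknown scale {scale!r}")


def bland_altman_points(baseline1, baseline2, patient_ids=None) -> pd.DataFrame:
    """Bland-Altman plot data: percentage difference vs geometric mean.

    pct_difference = 100 * (x2 - x1) / sqrt(x1 * x2).
    """
    x1 = np.asarray(baseline1, dtype=float)
    x2 = np.asarray(baseline2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("baselines must be 1D and paired")
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("Bland-Altman points require positive measurements")
    gmean = np.sqrt(x1 * x2)
    if patient_ids is None:
        patient_ids = np.arange(1, len(x1) + 1)
    return pd.DataFrame(
        {
            "patient": patient_ids,
            "pct_difference": 100.0 * (x2 - x1) / gmean,
            "geometric_mean": gmean,
        }
    )


def classify_individual_change(
    pct_change: float, loa: RepeatabilityResult
) -> ChangeClass:
    """Classify a post-treatment percent change against baseline 95% LoA."""
    if pct_change > loa.loa_upper_pct:
        return ChangeClass.SIGNIFICANT_INCREASE
    if pct_change < loa.loa_lower_pct:
        return ChangeClass.SIGNIFICANT_DECREASE
    return ChangeClass.WITHIN_LOA
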