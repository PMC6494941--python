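"""Imaging-histopathology association.

Spearman rank correlations with Fisher-z confidence intervals, Wilcoxon
rank-sum group comparisons (exact permutation null for small samples), and
exclusion of fat-dominant ROIs from diffusion/R2* analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpearmanResult",
    "RankSumResult",
    "FatFilterResult",
    "filter_fat_rois",
    "spearman_ci",
    "rank_sum_test",
]

#: imaging parameters invalidated by >80%-fat ROIs (fat suppression)
DIFFUSION_PARAMS = ("ADC", "D", "f", "Dstar", "R2star")


class FatFilterResult(NamedTuple):
    diffusion: pd.DataFrame  # for ADC / D / f / D* / R2* analyses
    fat: pd.DataFrame  # full table, kept for FF analysis


def filter_fat_rois(records: pd.DataFrame, threshold: float = 0.80) -> FatFilterResult:
    """Drop ROIs with histology fat fraction > threshold from diffusion analyses.

    The full table is returned unchanged for fat-fraction analysis.  Emits a
    warning when nothing survives for the diffusion set.
    """
    if "histo_fat_fraction" not in records.columns:
        raise ValueError("records must have a histo_fat_fraction column")
    keep = records["histo_fat_fraction"] <= threshold
    diffusion = records[keep].copy()
    if diffusion.empty:
        warnings.warn(
            "all ROIs exceed the fat threshold; diffusion analysis set is empty",
            stacklevel=2,
        )
    return FatFilterResult(diffusion=diffusion, fat=records.copy())


@dataclass
class SpearmanResult:
    rho: float
    pvalue: float
    ci_low: float
    ci_high: float
    n: int
    method: str  # "exact-permutation" | "t-approx"


EXACT_PERM_N_MAX = 9


def spearman_ci(x, y, conf: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation with p-value and Fisher-z CI.

    Average ranks are used for ties.  The p-value is an exact full-permutation
    p for n <= 9 and the t-approximation otherwise.  The CI applies the
    Fisher z transform with variance 1.06 / (n - 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D samples")
    n = len(x)
    if n < 4:
        raise ValueError("need at least four pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation is undefined for constant input")

    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)

    if n <= EXACT_PERM_N_MAX:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        denom_x = math.sqrt(float(np.sum(rx_c**2)))
        perms = np.array(list(permutations(ry)))
        perms_c = perms - perms.mean(axis=1, keepdims=True)
        denom_y = np.sqrt((perms_c**2).sum(axis=1))
        rhos = perms_c @ rx_c / (denom_x * denom_y)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact-permutation"
    else:
        p = float(p_t)
        method = "t-approx"

    z = math.atanh(min(max(rho, -1 + 1e-15), 1 - 1e-15))
    se = math.sqrt(1.06 / (n - 3))
    zq = stats.norm.ppf(1 - (1 - conf) / 2)
    ci_low, ci_high = math.tanh(z - zq * se), math.tanh(z + zq * se)
    return SpearmanResult(rho=rho, pvalue=p, ci_low=ci_low, ci_high=ci_high, n=n, method=method)


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first group
    pvalue: float
    n_a: int
    n_b: int
    method: str  # "exact" | "approx"


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by subset-count dynamic programming.

    Equivalent to enumerating all C(n_a + n_b, n_a) group assignments of
    the pooled midranks (doubled to integers to accommodate ties).
    """
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r2 = np.rint(2 * ranks).astype(int)
    w2 = int(np.rint(2 * ranks[:n_a].sum()))
    total = int(r2.sum())
    # count[k][s]: subsets of size k with doubled-rank sum s
    count = np.zeros((n_a + 1, total + 1))
    count[0, 0] = 1.0
    for r in r2:
        for k in range(n_a, 0, -1):
            count[k, r:] += count[k - 1, : total + 1 - r]
    dist = count[n_a]
    n_total = dist.sum()
    cdf = float(dist[: w2 + 1].sum() / n_total)
    sf = float(dist[w2:].sum() / n_total)
    p = min(1.0, 2.0 * min(cdf, sf))
    return float(ranks[:n_a].sum()), p


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test between two independent groups.

    Exact permutation null when min(n_a, n_b) <= 10 and n_a + n_b <= 20
    (ties handled by midranks); tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    if min(n_a, n_b) <= 10 and n_a + n_b <= 20:
        w, p = _exact_rank_sum_p(a, b)
        return RankSumResult(statistic=w, pvalue=p, n_a=n_a, n_b=n_b, method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    ranks = stats.rankdata(np.concatenate([a, b]))
    return RankSumResult(
        statistic=float(ranks[:n_a].sum()),
        pvalue=float(res.pvalue),
        n_a=n_a,
        n_b=n_b,
        method="approx",
    )
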