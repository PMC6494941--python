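"""Cohort-level pre/post-radiotherapy comparison and per-patient change calls.

Cohort changes are tested with two-sided Wilcoxon signed-rank tests (exact
permutation null for small samples, normal approximation with tie
correction otherwise); individual patients are classified against the
baseline 95% limits of agreement.  Volume changes are reported as a
non-RECIST surrogate (RECIST 1.1 requires radiologist diameter readings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import spearman_ci
from .repeatability import RepeatabilityResult, classify_individual_change

__all__ = ["SignedRankResult", "ResponseReport", "signed_rank_test", "cohort_response_table"]

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25


@dataclass
class SignedRankResult:
    statistic: float  # sum of positive ranks W+
    pvalue: float
    n_informative: int
    method: str  # "exact" | "approx" | "degenerate"
    all_zero: bool = False


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by shift-polynomial enumeration.

    Equivalent to enumerating all 2^n sign assignments of the absolute-value
    midranks (ties allowed: midranks are doubled to integers).  Returns
    (W+, p) with p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)
    w2 = int(np.rint(2 * ranks[d > 0].sum()))
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    p = min(1.0, 2.0 * min(cdf, sf))
    return ranks[d > 0].sum(), p


def signed_rank_test(x, y=None) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired values or differences.

    Zero differences are dropped before ranking; if every difference is
    zero, p = 1 is returned with ``all_zero`` set.  The null distribution
    is exact (full sign-assignment enumeration) for up to 25 informative
    pairs and a tie-corrected normal approximation beyond that.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        d = y - x
    else:
        d = x
    d = d[np.isfinite(d)]
    d_inf = d[d != 0]
    n = len(d_inf)
    if n == 0:
        return SignedRankResult(0.0, 1.0, 0, "degenerate", all_zero=True)
    if n <= EXACT_N_MAX:
        w_plus, p = _exact_signed_rank_p(d_inf)
        return SignedRankResult(float(w_plus), p, n, "exact")
    res = stats.wilcoxon(
        d_inf, zero_method="wilcox", alternative="two-sided",
        correction=False, method="approx",
    )
    # report the sum of positive ranks regardless of scipy's statistic form
    ranks = stats.rankdata(np.abs(d_inf))
    w_plus = float(ranks[d_inf > 0].sum())
    return SignedRankResult(w_plus, float(res.pvalue), n, "approx")


@dataclass
class ResponseReport:
    patient_table: pd.DataFrame
    cohort_table: pd.DataFrame
    volume_summary: dict


def cohort_response_table(
    records: pd.DataFrame,
    loa: Mapping[str, RepeatabilityResult] | None = None,
    volume_statistic: str = "volume_cm3",
) -> ResponseReport:
    """Per-patient percent changes, LoA-based calls, and cohort p-values.

    ``records`` is tidy with columns patient, statistic, baseline1,
    baseline2 (nullable) and post_rt.  The pre-treatment reference is the
    mean of the available baselines.  Rows without a post-treatment value
    are skipped with a log entry.  Returns per-patient changes (classified
    against ``loa`` where provided), a per-statistic cohort table with
    signed-rank p-values, and a volume-change summary including the rank
    correlation between volume change and each parameter change.
    """
    required = {"patient", "statistic", "baseline1", "post_rt"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    loa = loa or {}

    rows = []
    for _, rec in records.iterrows():
        if pd.isna(rec["post_rt"]) or pd.isna(rec["baseline1"]):
            logger.info(
                "skipping patient %s statistic %s: missing pre/post pairing",
                rec["patient"], rec["statistic"],
            )
            continue
        baselines = [rec["baseline1"]]
        if "baseline2" in records.columns and not pd.isna(rec.get("baseline2")):
            baselines.append(rec["baseline2"])
        pre = float(np.mean(baselines))
        if pre == 0:
            logger.info("skipping patient %s: zero baseline", rec["patient"])
            continue
        pct = 100.0 * (float(rec["post_rt"]) - pre) / pre
        stat = rec["statistic"]
        call = (
            classify_individual_change(pct, loa[stat]).value
            if stat in loa
            else "no_LoA"
        )
        rows.append(
            {
                "patient": rec["patient"],
                "statistic": stat,
                "pre": pre,
                "post": float(rec["post_rt"]),
                "pct_change": pct,
                "classification": call,
            }
        )
    patient_table = pd.DataFrame(rows)
    if patient_table.empty:
        raise ValueError("no matched pre/post records")

    cohort_rows = []
    for stat, grp in patient_table.groupby("statistic", sort=True):
        test = signed_rank_test(grp["pre"].to_numpy(), grp["post"].to_numpy())
        cohort_rows.append(
            {
                "statistic": stat,
                "n": len(grp),
                "median_pct_change": float(grp["pct_change"].median()),
                "signed_rank_statistic": test.statistic,
                "pvalue": test.pvalue,
                "method": test.method,
                "significant": test.pvalue < 0.05,
                "n_significant_increase": int(
                    (grp["classification"] == "significant_increase").sum()
                ),
                "n_significant_decrease": int(
                    (grp["classification"] == "significant_decrease").sum()
                ),
            }
        )
    cohort_table = pd.DataFrame(cohort_rows)

    volume_summary: dict = {}
    vol = patient_table[patient_table["statistic"] == volume_statistic]
    if not vol.empty:
        vc = vol.set_index("patient")["pct_change"]
        volume_summary = {
            "n": int(len(vc)),
            "n_increased": int((vc > 0).sum()),
            "median_volume_change_pct": float(vc.median()),
            "range_volume_change_pct": (float(vc.min()), float(vc.max())),
            "rank_correlation_with": {},
        }
        for stat, grp in patient_table.groupby("statistic"):
            if stat == volume_statistic:
                continue
            merged = grp.set_index("patient")["pct_change"].to_frame("param").join(
                vc.to_frame("vol"), how="inner"
            )
            if len(merged) >= 4 and merged.nunique().min() > 1:
                res = spearman_ci(merged["vol"].to_numpy(), merged["param"].to_numpy())
                volume_summary["rank_correlation_with"][stat] = {
                    "rho": res.rho,
                    "pvalue": res.pvalue,
                }
    return ResponseReport(
        patient_table=patient_table,
        cohort_table=cohort_table,
        volume_summary=volume_summary,
    )
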