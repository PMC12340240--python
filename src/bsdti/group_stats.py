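"""Nonparametric group statistics and the ROI discrimination criterion.

The comparison machinery mirrors a two-cohort DTI study: Mann-Whitney U for
between-group contrasts (healthy controls vs patients), Wilcoxon signed-rank
for within-subject contrasts between processing approaches, a Yates-corrected
chi-square for 2x2 categorical tables, Benjamini-Hochberg FDR adjustment
across comparisons, and the rank-test effect size r = |Z| / sqrt(N) with the
conventional medium (0.3) and large (0.5) thresholds.  Normality is assessed
with Shapiro-Wilk and logged, but the pipeline always proceeds
nonparametrically.

The discrimination criterion asks, per parcel, whether at least one of the
four metrics (FA, MD, AD, RD) separates the groups at p < 0.005 with an
effect size above the threshold; its report gives the percentage of parcels
meeting the criterion per metric and for "ANY" metric, at both thresholds.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney",
    "wilcoxon_paired",
    "chi_square_2x2",
    "bh_fdr",
    "compare_groups",
    "discrimination_report",
    "group_size_curve",
    "METRICS",
]

METRICS = ("FA", "MD", "AD", "RD")


def mann_whitney(group_a, group_b) -> tuple[float, float, float, float]:
    """Two-sided Mann-Whitney U with tie-corrected normal approximation.

    Returns ``(U, Z, p, r)`` where U counts pairs won by group A, Z is the
    continuity-corrected standardized statistic and ``r = |Z| / sqrt(N)``.
    Degenerate input (every value identical) yields p = 1, r = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = ranks[:na].sum() - na * (na + 1) / 2.0
    n = na + nb
    mu = na * nb / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u_a), 0.0, 1.0, 0.0
    diff = u_a - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0   # continuity correction
    z = (diff - cc) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    p = min(p, 1.0)
    r = abs(z) / np.sqrt(n)
    return float(u_a), float(z), float(p), float(r)


def wilcoxon_paired(x, y) -> tuple[float, float, float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (and their count logged); p comes from the
    tie-corrected normal approximation and ``r = |Z| / sqrt(n_effective)``.
    All-zero differences yield p = 1, r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return 0.0, 0.0, 1.0, 0.0
    if n < x.size:
        logger.debug("wilcoxon_paired: dropped %d zero differences",
                     x.size - n)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return w_plus, 0.0, 1.0, 0.0
    z = (w_plus - mu) / np.sqrt(var)
    p = min(2.0 * stats.norm.sf(abs(z)), 1.0)
    r = abs(z) / np.sqrt(n)
    return w_plus, float(z), float(p), float(r)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(chi2), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _normality_gate(values_by_cell: dict) -> None:
    """Shapiro-Wilk check, logged only; the analysis stays nonparametric."""
    n_nonnormal = 0
    n_total = 0
    for key, vals in values_by_cell.items():
        v = np.asarray(vals)
        if v.size < 3 or np.ptp(v) == 0:
            continue
        n_total += 1
        if stats.shapiro(v).pvalue < 0.05:
            n_nonnormal += 1
    if n_total:
        logger.info("normality gate: %d/%d cells deviate from normality "
                    "(Shapiro-Wilk p < 0.05); proceeding nonparametrically",
                    n_nonnormal, n_total)


def compare_groups(summary: pd.DataFrame, group_order: Sequence[str] = ("HC", "MS"),
                   numeric_rois_only: bool = True) -> pd.DataFrame:
    """Per-(ROI, metric) Mann-Whitney comparison of the two groups.

    ``summary`` is tidy with columns (subject, group, roi, metric, mean).
    Returns one row per (roi, metric) with group sizes, means, SDs, U, Z,
    raw p, BH-adjusted p (across all rows of the table) and effect size r.
    """
    required = {"subject", "group", "roi", "metric", "mean"}
    if not required.issubset(summary.columns):
        raise ValueError(f"summary must have columns {sorted(required)}")
    ga, gb = group_order
    df = summary
    if numeric_rois_only:
        df = df[df["roi"].astype(str).str.isdigit()]
    cells = {}
    rows = []
    for (roi, metric), sub in df.groupby(["roi", "metric"], sort=True):
        va = sub.loc[sub["group"] == ga, "mean"].to_numpy(dtype=float)
        vb = sub.loc[sub["group"] == gb, "mean"].to_numpy(dtype=float)
        va = va[~np.isnan(va)]
        vb = vb[~np.isnan(vb)]
        cells[(roi, metric, ga)] = va
        cells[(roi, metric, gb)] = vb
        u, z, p, r = mann_whitney(va, vb)
        rows.append({
            "roi": roi, "metric": metric,
            f"n_{ga}": va.size, f"n_{gb}": vb.size,
            f"mean_{ga}": va.mean(), f"sd_{ga}": va.std(ddof=1),
            f"mean_{gb}": vb.mean(), f"sd_{gb}": vb.std(ddof=1),
            "U": u, "Z": z, "p": p, "r": r,
        })
    _normality_gate(cells)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def discrimination_report(summary: pd.DataFrame, alpha: float = 0.005,
                          thresholds: Sequence[float] = (0.3, 0.5),
                          group_order: Sequence[str] = ("HC", "MS"),
                          stats_table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Percentage of parcels discriminating the groups, per metric and ANY.

    A parcel qualifies under a metric when the raw Mann-Whitney p is below
    ``alpha`` and the effect size r exceeds the threshold; ANY counts parcels
    qualifying under at least one of the four metrics.  One row per
    threshold with columns ANY/MD/FA/AD/RD in percent of parcels.
    """
    if stats_table is None:
        stats_table = compare_groups(summary, group_order=group_order)
    present = set(stats_table["metric"].unique())
    missing = set(METRICS) - present
    if missing:
        raise ValueError(f"missing metric(s): {sorted(missing)}")
    wide_p = stats_table.pivot(index="roi", columns="metric", values="p")
    wide_r = stats_table.pivot(index="roi", columns="metric", values="r")
    n_roi = len(wide_p)
    rows = []
    for thr in thresholds:
        qual = (wide_p < alpha) & (wide_r > thr)
        row = {"threshold": thr,
               "ANY": 100.0 * qual.any(axis=1).mean()}
        for m in METRICS:
            row[m] = 100.0 * qual[m].mean()
        row["n_rois"] = n_roi
        rows.append(row)
    return pd.DataFrame(rows)


def group_size_curve(summary: pd.DataFrame, region: str, metric: str,
                     sizes: Sequence[int], n_resamples: int = 50,
                     seed: int = 0,
                     group_order: Sequence[str] = ("HC", "MS")) -> pd.DataFrame:
    """Mann-Whitney p as a function of per-group sample size.

    For each requested size n, subsamples n subjects per group without
    replacement ``n_resamples`` times and reports the median and IQR of the
    two-sided p-value for the given aggregate region and metric.
    """
    df = summary[(summary["roi"] == region) & (summary["metric"] == metric)]
    ga, gb = group_order
    va = df.loc[df["group"] == ga, "mean"].to_numpy(dtype=float)
    vb = df.loc[df["group"] == gb, "mean"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        if n > min(va.size, vb.size):
            raise ValueError(f"size {n} exceeds available subjects")
        ps = []
        for _ in range(n_resamples):
            ia = rng.choice(va.size, size=n, replace=False)
            ib = rng.choice(vb.size, size=n, replace=False)
            _, _, p, _ = mann_whitney(va[ia], vb[ib])
            ps.append(p)
        ps = np.asarray(ps)
        rows.append({"n": n, "p_median": float(np.median(ps)),
                     "p_q1": float(np.quantile(ps, 0.25)),
                     "p_q3": float(np.quantile(ps, 0.75)),
                     "n_resamples": n_resamples})
    return pd.DataFrame(rows)
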