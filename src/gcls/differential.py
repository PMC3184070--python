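"""Differential Pol II occupancy between two conditions.

Tag counts per region are compared between a treatment lane (e.g. LPS) and
a control lane.  Sequencing-depth differences are removed by an ordinary
least-squares regression of treatment on control counts; each region is then
tested with an exact two-sided binomial test of the treatment count against
Binomial(n_treat + n_ctrl_norm, 1/2), with Bonferroni control of the
family-wise error over all tested regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_counts",
    "binomial_test",
    "count_tags_in_regions",
    "run_differential",
]


def normalize_counts(counts_treat: np.ndarray, counts_ctrl: np.ndarray
                     ) -> tuple[float, float, np.ndarray]:
    """OLS fit of treatment on control counts; returns scaled control counts.

    The fitted line maps the control lane onto the treatment lane's depth
    scale: ``ctrl_norm = max(0, round(slope * ctrl + intercept))``, rounded
    to integers so the exact binomial test applies downstream.
    """
    t = np.asarray(counts_treat, dtype=float)
    c = np.asarray(counts_ctrl, dtype=float)
    if len(t) != len(c):
        raise ValueError("count vectors differ in length")
    if len(t) < 2:
        raise ValueError("need >= 2 regions to fit the normalization line")
    if not (t.any() or c.any()):
        raise ValueError("all counts are zero")
    slope, intercept = np.polyfit(c, t, 1)
    ctrl_norm = np.maximum(0, np.rint(slope * c + intercept)).astype(np.int64)
    return float(slope), float(intercept), ctrl_norm


def binomial_test(k: int, n: int) -> float:
    """Exact two-sided binomial test at p = 1/2.

    Doubles the smaller tail, capped at 1:
    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` for X ~ Binomial(n, 1/2).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def count_tags_in_regions(regions: pd.DataFrame, tags: pd.DataFrame) -> np.ndarray:
    """Tags whose 5' position falls inside each (disjoint) region."""
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom = {chrom: np.sort(grp["pos"].to_numpy(np.int64))
                for chrom, grp in tags.groupby("chrom", sort=False)}
    for i, row in enumerate(regions.itertuples(index=False)):
        pos = by_chrom.get(row.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start)
    return counts


def run_differential(regions: pd.DataFrame, tags_treat: pd.DataFrame,
                     tags_ctrl: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Normalize, test and call every region; Bonferroni-corrected calls.

    Returns a frame with raw and normalized counts, the exact two-sided
    p-value, its Bonferroni-corrected value (m = number of regions tested)
    and the call in {'up', 'down', 'unchanged'}.
    """
    if len(regions) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_treat", "n_ctrl",
                                     "n_ctrl_norm", "p_value", "p_bonferroni",
                                     "call"])
    n_treat = count_tags_in_regions(regions, tags_treat)
    n_ctrl = count_tags_in_regions(regions, tags_ctrl)
    _, _, n_ctrl_norm = normalize_counts(n_treat, n_ctrl)
    m = len(regions)
    p_values = np.ones(m)
    calls = np.full(m, "unchanged", dtype=object)
    for i in range(m):
        total = int(n_treat[i] + n_ctrl_norm[i])
        if total == 0:
            continue
        p = binomial_test(int(n_treat[i]), total)
        p_values[i] = p
        if p * m < alpha:
            frac = n_treat[i] / total
            if frac > 0.5:
                calls[i] = "up"
            elif frac < 0.5:
                calls[i] = "down"
    out = regions[["chrom", "start", "end"]].reset_index(drop=True).copy()
    out["n_treat"] = n_treat
    out["n_ctrl"] = n_ctrl
    out["n_ctrl_norm"] = n_ctrl_norm
    out["p_value"] = p_values
    out["p_bonferroni"] = np.minimum(1.0, p_values * m)
    out["call"] = calls
    return out
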