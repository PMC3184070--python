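"""Evaluation machinery: metagene coverage profiles, region/gene
concordance, a fixed-gap island-merging baseline, and unit-recovery scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import merge_intervals, sort_intervals

__all__ = [
    "MetageneProfile",
    "metagene_profile",
    "region_gene_concordance",
    "fixed_gap_merge",
    "unit_recovery_score",
]

N_BINS = 50  # per segment: upstream flank, gene body, downstream flank
FLANK_BP = 10_000


@dataclass
class MetageneProfile:
    """Mean binary coverage in 50 + 50 + 50 bins around the average gene.

    ``upstream``: 10 kb before the TSS in fixed 200-bp bins; ``body``:
    TSS->TES scaled to 50 equal bins; ``downstream``: 10 kb after the TES.
    All values are fractions of genes with any cluster overlap in the bin.
    """

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray

    def concat(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def _bin_edges(start: float, end: float, n: int) -> np.ndarray:
    return np.linspace(start, end, n + 1)


def _covered_bins(edges: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Binary per-bin coverage: does any [start, end) overlap the bin?"""
    covered = np.zeros(len(edges) - 1, dtype=bool)
    for s, e in zip(starts, ends):
        lo = np.searchsorted(edges, s, side="right") - 1
        hi = np.searchsorted(edges, e, side="left")
        covered[max(lo, 0):min(hi, len(covered))] = True
    return covered


def metagene_profile(clusters: pd.DataFrame, genes: pd.DataFrame) -> MetageneProfile:
    """Average binary cluster coverage over oriented genes.

    ``genes`` needs chrom/start/end plus a ``strand`` column; profiles are
    flipped for '-' genes so bin 0 of ``upstream`` is always 10 kb 5' of the
    TSS.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    up = np.zeros(N_BINS)
    body = np.zeros(N_BINS)
    down = np.zeros(N_BINS)
    by_chrom = {c: g for c, g in clusters.groupby("chrom", sort=False)}
    for row in genes.itertuples(index=False):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            starts = ends = np.array([], dtype=np.int64)
        else:
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
        strand = getattr(row, "strand", "+")
        left = _covered_bins(_bin_edges(row.start - FLANK_BP, row.start, N_BINS),
                             starts, ends)
        mid = _covered_bins(_bin_edges(row.start, row.end, N_BINS), starts, ends)
        right = _covered_bins(_bin_edges(row.end, row.end + FLANK_BP, N_BINS),
                              starts, ends)
        if strand == "-":
            left, mid, right = right[::-1], mid[::-1], left[::-1]
        up += left
        body += mid
        down += right
    n = len(genes)
    return MetageneProfile(upstream=up / n, body=body / n, downstream=down / n)


def region_gene_concordance(clusters: pd.DataFrame, genes: pd.DataFrame) -> dict:
    """How well predicted clusters line up with gene regions.

    A gene *region* is a maximal contig of overlapping genes.  Counts the
    regions, how many are hit by >= 1 cluster, how many detected regions
    contain exactly one gene, distinct genes hit, and summary statistics of
    clusters per detected region.
    """
    regions = merge_intervals(genes)
    n_genes_in_region = np.zeros(len(regions), dtype=int)
    for i, reg in enumerate(regions.itertuples(index=False)):
        mask = ((genes["chrom"] == reg.chrom) & (genes["start"] < reg.end)
                & (genes["end"] > reg.start))
        n_genes_in_region[i] = int(mask.sum())
    clusters_per_region = np.zeros(len(regions), dtype=int)
    genes_hit: set[int] = set()
    for i, reg in enumerate(regions.itertuples(index=False)):
        mask = ((clusters["chrom"] == reg.chrom) & (clusters["start"] < reg.end)
                & (clusters["end"] > reg.start))
        clusters_per_region[i] = int(mask.sum())
    for gi, gene in enumerate(genes.itertuples(index=False)):
        mask = ((clusters["chrom"] == gene.chrom) & (clusters["start"] < gene.end)
                & (clusters["end"] > gene.start))
        if mask.any():
            genes_hit.add(gi)
    detected = clusters_per_region > 0
    single = detected & (n_genes_in_region == 1)
    per_region = clusters_per_region[detected]
    return {
        "regions_total": int(len(regions)),
        "regions_detected": int(detected.sum()),
        "regions_single_gene": int(single.sum()),
        "genes_total": int(len(genes)),
        "genes_hit": len(genes_hit),
        "clusters_per_region_mean": float(per_region.mean()) if len(per_region) else 0.0,
        "clusters_per_region_max": int(per_region.max()) if len(per_region) else 0,
    }


def fixed_gap_merge(peaks: pd.DataFrame, gap: int) -> pd.DataFrame:
    """Merge successive peaks separated by <= ``gap`` bp (SICER-style
    island semantics, without the island-score machinery)."""
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if len(peaks) == 0:
        return peaks[["chrom", "start", "end"]].copy()
    rows = []
    for chrom, grp in sort_intervals(peaks).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _jaccard(a_start: int, a_end: int, b_start: np.ndarray, b_end: np.ndarray
             ) -> np.ndarray:
    inter = np.maximum(0, np.minimum(a_end, b_end) - np.maximum(a_start, b_start))
    union = (a_end - a_start) + (b_end - b_start) - inter
    return inter / union


def unit_recovery_score(predicted: pd.DataFrame, truth: pd.DataFrame,
                        jaccard_cutoff: float = 0.5) -> dict:
    """Best-match Jaccard of every truth unit against the predictions.

    Returns the mean best Jaccard, recall (truth units with best Jaccard >=
    ``jaccard_cutoff``) and precision (predictions whose best truth-match
    reaches the cutoff).
    """
    if len(truth) == 0:
        raise ValueError("empty truth set")
    pred_by_chrom = {c: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
                     for c, g in predicted.groupby("chrom", sort=False)}
    best_t = np.zeros(len(truth))
    for i, row in enumerate(truth.itertuples(index=False)):
        se = pred_by_chrom.get(row.chrom)
        if se is not None and len(se[0]):
            best_t[i] = _jaccard(row.start, row.end, se[0], se[1]).max()
    truth_by_chrom = {c: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
                      for c, g in truth.groupby("chrom", sort=False)}
    best_p = np.zeros(len(predicted))
    for i, row in enumerate(predicted.itertuples(index=False)):
        se = truth_by_chrom.get(row.chrom)
        if se is not None and len(se[0]):
            best_p[i] = _jaccard(row.start, row.end, se[0], se[1]).max()
    return {
        "mean_jaccard": float(best_t.mean()),
        "recall": float((best_t >= jaccard_cutoff).mean()),
        "precision": float((best_p >= jaccard_cutoff).mean()) if len(predicted) else 0.0,
    }
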