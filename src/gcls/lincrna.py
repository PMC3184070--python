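"""Putative lincRNA calls from Pol II and H3K4me3 transcription units.

A putative lincRNA is an intergenic Pol II unit of at least ``min_span`` bp
that overlaps at least one H3K4me3 unit.  Orientation and the transcription
start site are inferred from the position of the H3K4me3 mass relative to
the Pol II unit (the promoter mark sits at the 5' end), promoters are fixed
windows around the TSS, and each call is associated with its nearest
annotated gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeLayout, merge_intervals, overlaps_any, sort_intervals

__all__ = [
    "AnnotationConfig",
    "filter_intergenic",
    "call_lincrnas",
    "assign_orientation",
    "promoter_interval",
    "nearest_gene",
    "overlap_enrichment",
]


@dataclass
class AnnotationConfig:
    """lincRNA filtering and promoter geometry.

    min_span      minimum Pol II unit width (bp) for a positive call.
    promoter_up   promoter extent upstream of the TSS (bp).
    promoter_down promoter extent downstream of the TSS (bp).
    """

    min_span: int = 3000
    promoter_up: int = 3000
    promoter_down: int = 1000
    exclusion_sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.min_span, self.promoter_up, self.promoter_down) <= 0:
            raise ValueError("min_span and promoter extents must be positive")


def filter_intergenic(units: pd.DataFrame, exclusions: pd.DataFrame) -> pd.DataFrame:
    """Drop units overlapping any exclusion interval by >= 1 bp."""
    if len(units) == 0 or len(exclusions) == 0:
        return units.reset_index(drop=True)
    hit = overlaps_any(units, exclusions)
    return units[~hit].reset_index(drop=True)


def call_lincrnas(pol2_units: pd.DataFrame, k4_units: pd.DataFrame,
                  config: AnnotationConfig | None = None) -> pd.DataFrame:
    """Retain Pol II units of width >= min_span overlapping >= 1 K4 unit.

    Both inputs are expected to be intergenic-filtered already.  The result
    carries, per lincRNA, the list of overlapping K4 unit row indices in
    ``k4_indices``.
    """
    config = config or AnnotationConfig()
    units = sort_intervals(pol2_units)
    wide = (units["end"] - units["start"]) >= config.min_span
    units = units[wide].reset_index(drop=True)
    if len(units) == 0 or len(k4_units) == 0:
        return units.iloc[0:0].assign(k4_indices=None)
    k4 = k4_units.reset_index(drop=True)
    keep = []
    k4_idx_lists = []
    for _, row in units.iterrows():
        mask = ((k4["chrom"] == row["chrom"]) & (k4["start"] < row["end"])
                & (k4["end"] > row["start"]))
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx):
            keep.append(True)
            k4_idx_lists.append(list(idx))
        else:
            keep.append(False)
    out = units[np.asarray(keep, bool)].reset_index(drop=True)
    out["k4_indices"] = k4_idx_lists
    return out


def assign_orientation(unit: tuple[str, int, int], k4_clusters: pd.DataFrame,
                       k4_weights: np.ndarray | None = None) -> tuple[str, int]:
    """Infer strand and TSS from the H3K4me3 mass center.

    The promoter mark concentrates at the 5' end of a transcript, so a K4
    mass center in the left half of the Pol II unit implies transcription
    rightward ('+') with the TSS at the 3' edge of the leftmost K4 cluster;
    a center in the right half mirrors this.  ``k4_weights`` (e.g. tag
    counts) weight the per-cluster midpoints; widths are used otherwise.
    An exact-midpoint tie resolves to '+'.
    """
    if len(k4_clusters) == 0:
        raise ValueError("no H3K4me3 cluster attached to the unit")
    _, start, end = unit
    mids = (k4_clusters["start"].to_numpy(float)
            + k4_clusters["end"].to_numpy(float)) / 2.0
    if k4_weights is None:
        weights = (k4_clusters["end"] - k4_clusters["start"]).to_numpy(float)
    else:
        weights = np.asarray(k4_weights, dtype=float)
    center = float(np.average(mids, weights=weights))
    middle = (start + end) / 2.0
    if center <= middle:
        leftmost = k4_clusters.loc[k4_clusters["start"].idxmin()]
        return "+", int(leftmost["end"])
    rightmost = k4_clusters.loc[k4_clusters["end"].idxmax()]
    return "-", int(rightmost["start"])


def promoter_interval(tss: int, strand: str, chrom: str,
                      config: AnnotationConfig | None = None,
                      layout: GenomeLayout | None = None) -> tuple[str, int, int]:
    """Fixed window around the TSS: [-promoter_up, +promoter_down) on '+'."""
    config = config or AnnotationConfig()
    if strand == "+":
        start, end = tss - config.promoter_up, tss + config.promoter_down
    elif strand == "-":
        start, end = tss - config.promoter_down, tss + config.promoter_up
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if layout is not None:
        start, end = layout.clip(chrom, start, end)
    else:
        start = max(0, start)
    return chrom, start, end


def nearest_gene(linc: tuple[str, int, int], genes: pd.DataFrame) -> tuple[int, int]:
    """Nearest gene by edge-to-edge distance (0 when flanks touch/overlap).

    Returns ``(gene_row_index, distance)``.  Ties resolve to the 5' side
    (smaller coordinate), then to the smaller row index.
    """
    if len(genes) == 0:
        raise ValueError("empty gene set")
    chrom, start, end = linc
    same = genes[genes["chrom"] == chrom]
    if len(same) == 0:
        raise ValueError(f"no genes on chromosome {chrom!r}")
    gstart = same["start"].to_numpy(np.int64)
    gend = same["end"].to_numpy(np.int64)
    dist = np.maximum(0, np.maximum(gstart - end, start - gend))
    best = dist.min()
    cand = np.flatnonzero(dist == best)
    # prefer the 5'-side (upstream) gene, then positional order
    upstream = cand[gend[cand] <= start] if len(cand) > 1 else cand
    pick = upstream[0] if len(upstream) else cand[0]
    return int(same.index[pick]), int(best)


def overlap_enrichment(lincrnas: pd.DataFrame, markers: pd.DataFrame,
                       layout: GenomeLayout,
                       intergenic_space: pd.DataFrame) -> tuple[int, float, float]:
    """Enrichment of marker intervals (e.g. PU.1 & H3K4me1 enhancer
    signatures) inside lincRNAs.

    Counts lincRNAs containing >= 1 marker midpoint-overlap and tests the
    count against an upper-tail Binomial(n_lincrnas, p0) null, where p0 is
    the chance that a random intergenic window of the median lincRNA width
    hits a marker: the marker-covered fraction of the intergenic space after
    dilating markers by that width.

    Returns ``(n_overlapping, fraction, p_value)``.
    """
    n = len(lincrnas)
    if n == 0:
        return 0, 0.0, 1.0
    if len(markers) == 0:
        return 0, 0.0, 1.0
    merged = merge_intervals(markers)
    hit = overlaps_any(lincrnas, merged)
    k = int(hit.sum())
    median_width = float(np.median(lincrnas["end"] - lincrnas["start"]))
    dilated = merged.copy()
    dilated["start"] = (dilated["start"] - median_width).clip(lower=0).astype(np.int64)
    dilated = merge_intervals(dilated)
    inter_bp = float((intergenic_space["end"] - intergenic_space["start"]).sum())
    from .genome_io import intersect_intervals
    cover = intersect_intervals(dilated, intergenic_space)
    covered_bp = float((cover["end"] - cover["start"]).sum()) if len(cover) else 0.0
    p0 = min(1.0, covered_bp / max(inter_bp, 1.0))
    p_value = float(stats.binom.sf(k - 1, n, p0))
    return k, k / n, p_value
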