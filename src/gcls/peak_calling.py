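"""Diffuse ChIP-seq peak calling.

Tags are extended to the expected fragment length, de-duplicated, and piled
up; candidate regions (maximal stretches of depth >= 1) are then filtered in
two steps: a Poisson-null height threshold controlling the FDR, and a
fold-enrichment test against the sequenced input (no-antibody) lane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeLayout, sort_intervals

__all__ = [
    "PeakCallConfig",
    "extend_and_dedup",
    "pileup",
    "depth_tail_counts",
    "poisson_height_threshold",
    "call_peaks",
]

PEAK_COLUMNS = ["chrom", "start", "end", "height", "summit", "n_tags"]


@dataclass
class PeakCallConfig:
    """Parameters of the two-step peak filter.

    extension_length
        Expected sequenced-fragment length; every tag is extended to this
        many bp from its 5' end (default 150).
    fdr
        Target false discovery rate for the Poisson height threshold.
    input_fold
        Required fold enrichment of a peak's height over the depth-scaled
        input-lane pileup at the same locus.
    dedup
        Collapse tags with identical (chrom, pos, strand) to suppress PCR
        duplicates.
    fdr_method
        ``"ratio"``: FDR(h) = expected false bases under the Poisson null /
        observed bases at depth >= h.  ``"expected"``: per-bp null tail
        probability below ``fdr`` (no observed-data denominator).
    mappable_fraction
        Fraction of the genome considered mappable; scales G in the null.
    """

    extension_length: int = 150
    fdr: float = 0.001
    input_fold: float = 3.0
    dedup: bool = True
    fdr_method: str = "ratio"
    mappable_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.extension_length <= 0:
            raise ValueError("extension_length must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.input_fold < 1:
            raise ValueError("input_fold must be >= 1")
        if self.fdr_method not in ("ratio", "expected"):
            raise ValueError("fdr_method must be 'ratio' or 'expected'")
        if not 0 < self.mappable_fraction <= 1:
            raise ValueError("mappable_fraction must be in (0, 1]")


def extend_and_dedup(tags: pd.DataFrame, config: PeakCallConfig,
                     layout: GenomeLayout) -> pd.DataFrame:
    """Extend each tag to ``extension_length`` bp from its 5' end.

    Forward tags cover ``[pos, pos + L)``; reverse tags cover
    ``[pos - L + 1, pos + 1)``.  Duplicate tags (same chrom, pos, strand)
    collapse to one interval when ``config.dedup`` is set.  Intervals are
    clipped to the chromosome bounds.
    """
    if config.dedup:
        tags = tags.drop_duplicates(["chrom", "pos", "strand"])
    L = config.extension_length
    pos = tags["pos"].to_numpy(np.int64)
    fwd = (tags["strand"] == "+").to_numpy()
    start = np.where(fwd, pos, pos - L + 1)
    end = np.where(fwd, pos + L, pos + 1)
    out = pd.DataFrame({"chrom": tags["chrom"].to_numpy(), "start": start, "end": end})
    sizes = out["chrom"].map(layout.chrom_sizes)
    if sizes.isna().any():
        bad = out.loc[sizes.isna(), "chrom"].iloc[0]
        raise ValueError(f"unknown chromosome {bad!r}")
    out["start"] = out["start"].clip(lower=0)
    out["end"] = np.minimum(out["end"].to_numpy(), sizes.to_numpy(np.int64))
    return sort_intervals(out)


def _pileup_one_chrom(starts: np.ndarray, ends: np.ndarray) -> list[tuple[int, int, int, int, int]]:
    """Sweep-line pileup of sorted intervals on one chromosome.

    Returns ``(start, end, height, summit, n_tags)`` per maximal region of
    depth >= 1.  The summit is the leftmost position of maximal depth.
    """
    bounds = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(len(bounds), dtype=np.int64)
    np.add.at(delta, np.searchsorted(bounds, starts), 1)
    np.add.at(delta, np.searchsorted(bounds, ends), -1)
    depth = np.cumsum(delta)  # depth on [bounds[i], bounds[i+1])

    regions = []
    i = 0
    n = len(bounds) - 1
    while i < n:
        if depth[i] <= 0:
            i += 1
            continue
        j = i
        while j < n and depth[j] > 0:
            j += 1
        seg = depth[i:j]
        k = int(np.argmax(seg))
        height = int(seg[k])
        summit = int(bounds[i + k])
        region_start, region_end = int(bounds[i]), int(bounds[j])
        n_tags = int(np.count_nonzero((starts < region_end) & (ends > region_start)))
        regions.append((region_start, region_end, height, summit, n_tags))
        i = j
    return regions


def pileup(intervals: pd.DataFrame) -> pd.DataFrame:
    """Maximal regions of overlapping intervals with height, summit, n_tags."""
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        for start, end, height, summit, n_tags in _pileup_one_chrom(starts, ends):
            rows.append((chrom, start, end, height, summit, n_tags))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS).astype(
        {c: np.int64 for c in PEAK_COLUMNS[1:]})


def depth_tail_counts(intervals: pd.DataFrame, max_depth: int | None = None) -> np.ndarray:
    """``counts[h-1]`` = number of genomic positions with pileup depth >= h."""
    per_depth: dict[int, int] = {}
    for _, grp in intervals.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        bounds = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(len(bounds), dtype=np.int64)
        np.add.at(delta, np.searchsorted(bounds, starts), 1)
        np.add.at(delta, np.searchsorted(bounds, ends), -1)
        depth = np.cumsum(delta)[:-1]
        widths = np.diff(bounds)
        for d, w in zip(depth, widths):
            if d > 0:
                per_depth[int(d)] = per_depth.get(int(d), 0) + int(w)
    top = max(per_depth, default=0)
    if max_depth is not None:
        top = max(top, max_depth)
    counts = np.zeros(top, dtype=np.int64)
    for d, w in per_depth.items():
        counts[:d] += w
    return counts


def poisson_height_threshold(n_tags: int, config: PeakCallConfig, layout: GenomeLayout,
                             observed_tail: np.ndarray | None = None) -> int:
    """Smallest peak height h* with estimated FDR below ``config.fdr``.

    The null places ``n_tags`` extended tags uniformly on the genome, so the
    depth at a position is Poisson with rate
    ``lambda = n_tags * extension_length / G``.  With the default ``"ratio"``
    estimator, FDR(h) = G * P(Pois >= h) / max(1, observed bases at depth
    >= h); ``observed_tail`` is as returned by :func:`depth_tail_counts`.
    The ``"expected"`` estimator thresholds the per-bp tail probability
    P(Pois >= h) directly.
    """
    if n_tags <= 0:
        raise ValueError("n_tags must be positive")
    G = layout.genome_size * config.mappable_fraction
    lam = n_tags * config.extension_length / G
    if lam >= 1.0:
        import warnings
        warnings.warn(f"saturated coverage: Poisson rate {lam:.3g} >= 1 per bp")
    use_ratio = config.fdr_method == "ratio" and observed_tail is not None
    h = 1
    while True:
        tail = stats.poisson.sf(h - 1, lam)  # P(X >= h)
        if use_ratio:
            observed = observed_tail[h - 1] if h <= len(observed_tail) else 0
            fdr_h = G * tail / max(1, observed)
        else:
            fdr_h = tail
        if fdr_h < config.fdr:
            return h
        h += 1
        if h > max(1000, 10 * lam):
            return h  # pathological; never reached for sane inputs


def call_peaks(exp_tags: pd.DataFrame, input_tags: pd.DataFrame | None,
               config: PeakCallConfig, layout: GenomeLayout) -> pd.DataFrame:
    """Two-step peak caller: Poisson height filter then input-fold filter.

    A candidate region is retained iff its height reaches the Poisson-null
    threshold and is at least ``input_fold`` times the depth-normalized
    maximum input pileup over the same interval.  Passing ``input_tags=None``
    applies only the Poisson filter.
    """
    if len(exp_tags) == 0:
        raise ValueError("empty experiment lane")
    ext = extend_and_dedup(exp_tags, config, layout)
    peaks = pileup(ext)
    if len(peaks) == 0:
        return peaks
    tail = depth_tail_counts(ext)
    h_star = poisson_height_threshold(len(ext), config, layout, observed_tail=tail)
    peaks = peaks[peaks["height"] >= h_star].reset_index(drop=True)

    if input_tags is not None and len(input_tags) > 0 and len(peaks) > 0:
        input_ext = extend_and_dedup(input_tags, config, layout)
        scale = len(ext) / len(input_ext)
        profiles = {chrom: _depth_profile(grp["start"].to_numpy(np.int64),
                                          grp["end"].to_numpy(np.int64))
                    for chrom, grp in input_ext.groupby("chrom", sort=False)}
        keep = np.ones(len(peaks), dtype=bool)
        for i, row in enumerate(peaks.itertuples(index=False)):
            prof = profiles.get(row.chrom)
            if prof is None:
                continue
            input_height = _max_depth_in(prof, row.start, row.end) * scale
            if row.height < config.input_fold * input_height:
                keep[i] = False
        peaks = peaks[keep].reset_index(drop=True)
    return peaks


def _depth_profile(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step-function pileup depth: depth[i] holds on [bounds[i], bounds[i+1])."""
    bounds = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(len(bounds), dtype=np.int64)
    np.add.at(delta, np.searchsorted(bounds, starts), 1)
    np.add.at(delta, np.searchsorted(bounds, ends), -1)
    return bounds, np.cumsum(delta)[:-1]


def _max_depth_in(profile: tuple[np.ndarray, np.ndarray], start: int, end: int) -> int:
    bounds, depth = profile
    i0 = max(0, int(np.searchsorted(bounds, start, side="right")) - 1)
    i1 = int(np.searchsorted(bounds[:-1], end, side="left"))
    seg = depth[i0:i1]
    return int(seg.max()) if len(seg) else 0
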