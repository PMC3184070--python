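"""Reaction-diffusion simulation of Pol II occupancy, plus fixture generators.

The simulator follows a deliberately simple one-dimensional picture of a
limited pool of polymerase competing for gene loci: a signal array (one bin
per ``nbp`` base pairs, total mass 1) evolves by repeated rounds of (1)
random binding attempts that multiplicatively amplify short runs of signal
where a gene is present (or, with probability ``fp``, anywhere), (2)
renormalization of the total mass, and (3) diffusion following Fick's second
law.  Peaks extracted from the final signal reproduce the two-cluster
width/gap pattern seen in diffuse ChIP-seq data.

The remaining generators build synthetic inputs (gene layouts, tag lanes,
fragmented transcription units, two-condition counts) so that the whole
pipeline is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeLayout, sort_intervals

__all__ = [
    "SimConfig",
    "generate_gene_layout",
    "simulate_signal",
    "extract_signal_peaks",
    "generate_tags",
    "generate_fragmented_units",
    "generate_two_condition_counts",
]


@dataclass
class SimConfig:
    """Reaction-diffusion parameters.

    nbp     bp represented by one array bin.
    nb      binding attempts drawn per time step.
    fa      multiplicative amplification factor per binding event.
    fl      length of the amplified run, in bins.
    fp      probability that an off-gene attempt still reacts (noise).
    D       diffusion coefficient, bins^2 per step.
    fstd    extraction threshold: mean + fstd * std of the signal.
    steps   number of time steps.
    seed    RNG seed; same seed gives a bit-identical trajectory.
    """

    nbp: int = 100
    nb: int = 1000
    fa: float = 1.05
    fl: int = 7
    fp: float = 0.1
    D: float = 1.0
    fstd: float = 0.6
    steps: int = 80
    seed: int = 0
    diffusion: str = "gaussian"  # or "euler" (explicit sub-stepped Laplacian)

    def __post_init__(self) -> None:
        if min(self.nbp, self.fl, self.steps) <= 0 or self.nb < 0:
            raise ValueError("nbp, fl, steps must be positive; nb non-negative")
        if self.fa <= 0:
            raise ValueError("fa must be positive")
        if not 0 <= self.fp <= 1:
            raise ValueError("fp must be in [0, 1]")
        if self.D < 0 or self.fstd < 0:
            raise ValueError("D and fstd must be non-negative")
        if self.diffusion not in ("gaussian", "euler"):
            raise ValueError("diffusion must be 'gaussian' or 'euler'")


def generate_gene_layout(region_length: int, n_genes: int, seed: int = 0,
                         median_length: float = 20_000.0,
                         sigma_log: float = 0.8,
                         chrom: str = "chrSim") -> pd.DataFrame:
    """Non-overlapping gene intervals with log-normal lengths.

    Genes are placed uniformly at random by rejection; packing that cannot
    fit (after 200 * n_genes attempts) raises.
    """
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    lengths = np.maximum(
        1, rng.lognormal(np.log(median_length), sigma_log, n_genes).astype(np.int64))
    if lengths.sum() > region_length:
        raise ValueError("infeasible packing: gene lengths exceed the region")
    placed: list[tuple[int, int]] = []
    attempts = 0
    for L in sorted(lengths, reverse=True):
        L = int(min(L, region_length))
        while True:
            attempts += 1
            if attempts > 200 * n_genes:
                raise ValueError("infeasible packing: too many rejected placements")
            start = int(rng.integers(0, region_length - L + 1))
            end = start + L
            if all(end <= s or start >= e for s, e in placed):
                placed.append((start, end))
                break
    placed.sort()
    return pd.DataFrame({"chrom": chrom, "start": [s for s, _ in placed],
                         "end": [e for _, e in placed]})


def _gaussian_kernel(variance: float) -> np.ndarray:
    sigma = np.sqrt(variance)
    radius = max(1, int(np.ceil(4 * sigma)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-x * x / (2 * variance))
    return k / k.sum()


def _diffuse_gaussian(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # reflecting boundaries: pad, convolve, crop
    radius = (len(kernel) - 1) // 2
    padded = np.pad(values, radius, mode="reflect")
    return np.convolve(padded, kernel, mode="same")[radius:-radius]


def _diffuse_euler(values: np.ndarray, D: float, substeps: int = 4) -> np.ndarray:
    # explicit scheme du/dt = D d2u/dx2, sub-stepped for stability
    d = D / substeps
    v = values
    for _ in range(substeps):
        left = np.concatenate([v[:1], v[:-1]])
        right = np.concatenate([v[1:], v[-1:]])
        v = v + d * (left - 2 * v + right)
    return v


def simulate_signal(config: SimConfig, genes: pd.DataFrame, region_length: int,
                    return_trajectory: bool = False):
    """Evolve the Pol II signal array for ``config.steps`` time steps.

    Returns the final signal array (bins of ``nbp`` bp, summing to 1), or the
    full list of per-step arrays when ``return_trajectory`` is set.
    """
    rng = np.random.default_rng(config.seed)
    n_bins = int(np.ceil(region_length / config.nbp))
    values = np.full(n_bins, 1.0 / n_bins)

    on_gene = np.zeros(n_bins, dtype=bool)
    for row in genes.itertuples(index=False):
        b0 = int(row.start) // config.nbp
        b1 = int(np.ceil(int(row.end) / config.nbp))
        on_gene[b0:b1] = True

    kernel = _gaussian_kernel(2 * config.D) if config.D > 0 else None
    log_fa = np.log(config.fa)
    trajectory = []
    for _ in range(config.steps):
        if config.nb > 0:
            sites = rng.integers(0, n_bins, config.nb)
            noise = rng.random(config.nb) < config.fp
            react = on_gene[sites] | noise
            direction = rng.random(config.nb) < 0.5  # True: leftward run
            sites = sites[react]
            direction = direction[react]
            if len(sites):
                # multiplicative amplification of fl-bin runs, compounding
                # across overlapping events; computed additively in log space
                bump = np.zeros(n_bins + 1)
                lo = np.where(direction, sites - config.fl + 1, sites).clip(0, n_bins)
                hi = np.where(direction, sites + 1, sites + config.fl).clip(0, n_bins)
                np.add.at(bump, lo, log_fa)
                np.add.at(bump, hi, -log_fa)
                values = values * np.exp(np.cumsum(bump[:-1]))
            values /= values.sum()
        if config.D > 0:
            if config.diffusion == "gaussian":
                values = _diffuse_gaussian(values, kernel)
            else:
                values = _diffuse_euler(values, config.D)
            values /= values.sum()
        if return_trajectory:
            trajectory.append(values.copy())
    return trajectory if return_trajectory else values


def extract_signal_peaks(signal: np.ndarray, fstd: float, nbp: int = 100,
                         chrom: str = "chrSim") -> pd.DataFrame:
    """Maximal runs of bins above mean + fstd * std, as bp intervals."""
    threshold = signal.mean() + fstd * signal.std()
    above = signal > threshold
    rows = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    for b0, b1 in zip(edges[::2], edges[1::2]):
        rows.append((chrom, int(b0) * nbp, int(b1) * nbp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_tags(units: pd.DataFrame, layout: GenomeLayout,
                  unit_rate: float = 0.05, background_rate: float = 0.0005,
                  fragmentation: tuple[int, int] | None = (3, 12),
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson tag lanes: an experiment lane enriched in ``units``, and a
    uniform input lane.

    Rates are tags per bp.  Within each unit, tags concentrate in 3-12
    sub-peak bursts whose centers tile the unit with jitter, mimicking the
    broken-up pileup of diffuse occupancy along a transcript (set
    ``fragmentation=None`` for uniform placement).  Strands are
    Bernoulli(1/2).  Returns ``(experiment, input)`` tag frames.
    """
    if unit_rate < 0 or background_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)

    def _uniform_lane(rate: float) -> list[tuple[str, int]]:
        out = []
        for chrom, size in layout.chrom_sizes.items():
            n = rng.poisson(rate * size)
            out.extend((chrom, int(p)) for p in rng.integers(0, size, n))
        return out

    exp_rows = _uniform_lane(background_rate)
    for row in units.itertuples(index=False):
        width = int(row.end) - int(row.start)
        n = rng.poisson(unit_rate * width)
        if fragmentation is None:
            positions = rng.integers(row.start, row.end, n)
        else:
            k = int(rng.integers(fragmentation[0], fragmentation[1] + 1))
            spacing = width / k
            centers = (row.start + (np.arange(k) + 0.5) * spacing
                       + rng.normal(0, spacing / 8, k)).astype(np.int64)
            burst_sd = max(50, int(spacing) // 10)
            which = rng.integers(0, k, n)
            positions = (centers[which]
                         + rng.normal(0, burst_sd, n)).astype(np.int64)
            positions = positions.clip(int(row.start), int(row.end) - 1)
        exp_rows.extend((str(row.chrom), int(p)) for p in positions)

    def _frame(rows: list[tuple[str, int]]) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=["chrom", "pos"])
        df["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
        return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    return _frame(exp_rows), _frame(_uniform_lane(background_rate))


def generate_fragmented_units(n_units: int = 200, n_noise: int = 500,
                              unit_length: tuple[int, int] = (5_000, 40_000),
                              n_fragments: tuple[int, int] = (3, 12),
                              gap_fraction: float = 0.05,
                              noise_gap: int = 50_000,
                              noise_width: tuple[int, int] = (150, 600),
                              seed: int = 0,
                              chrom: str = "chrSim"
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peak-level fixture with known truth for unit-recovery benchmarks.

    Each true unit (length uniform in ``unit_length``) is tiled by 3-12
    sub-peaks separated by gaps of about ``gap_fraction`` of the unit
    length; isolated noise peaks sit at least ``noise_gap`` bp apart.  Units
    and noise peaks are interleaved along one synthetic chromosome.

    Returns ``(peaks, truth_units)``; ``peaks`` has the standard peak
    columns, truth units are plain intervals.
    """
    rng = np.random.default_rng(seed)
    peak_rows = []
    truth_rows = []
    cursor = noise_gap
    events = ["unit"] * n_units + ["noise"] * n_noise
    rng.shuffle(events)
    for ev in events:
        if ev == "noise":
            w = int(rng.integers(*noise_width))
            peak_rows.append((chrom, cursor, cursor + w, 1, cursor, 1))
            cursor += w + noise_gap + int(rng.integers(0, noise_gap))
        else:
            length = int(rng.integers(unit_length[0], unit_length[1] + 1))
            k = int(rng.integers(n_fragments[0], n_fragments[1] + 1))
            gap_scale = max(1, int(gap_fraction * length))
            gaps = np.maximum(1, rng.normal(gap_scale, gap_scale / 4, k - 1)).astype(int)
            frag_total = length - int(gaps.sum())
            if frag_total < k:  # degenerate draw; fall back to equal tiling
                gaps = np.full(k - 1, max(1, length // (3 * k)))
                frag_total = length - int(gaps.sum())
            cuts = np.sort(rng.choice(np.arange(1, frag_total), k - 1, replace=False)) \
                if k > 1 else np.array([], dtype=int)
            frag_widths = np.diff(np.concatenate([[0], cuts, [frag_total]]))
            start = cursor
            pos = start
            for fi, w in enumerate(frag_widths):
                w = int(max(1, w))
                peak_rows.append((chrom, pos, pos + w,
                                  int(rng.integers(5, 15)), pos, int(w // 50 + 1)))
                pos += w
                if fi < len(gaps):
                    pos += int(gaps[fi])
            truth_rows.append((chrom, start, pos))
            cursor = pos + noise_gap + int(rng.integers(0, noise_gap))
    peaks = pd.DataFrame(peak_rows,
                         columns=["chrom", "start", "end", "height", "summit",
                                  "n_tags"])
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end"])
    return sort_intervals(peaks).astype({"start": np.int64, "end": np.int64}), \
        sort_intervals(truth)


def generate_two_condition_counts(n_regions: int, fold_changes: np.ndarray | float = 1.0,
                                  mu: float = 100.0, depth_ratio: float = 1.0,
                                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Paired Poisson counts for a differential-test fixture.

    ``counts_a ~ Poisson(mu)``, ``counts_b ~ Poisson(mu * fold * depth_ratio)``.
    """
    rng = np.random.default_rng(seed)
    folds = np.broadcast_to(np.asarray(fold_changes, dtype=float), (n_regions,))
    if (folds <= 0).any():
        raise ValueError("fold changes must be positive")
    counts_a = rng.poisson(mu, n_regions)
    counts_b = rng.poisson(mu * folds * depth_ratio)
    return counts_a, counts_b
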