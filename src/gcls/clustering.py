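"""Global clustering over a linear separator (GCLS).

Diffuse Pol II / histone-mark peaks fall into two populations when plotted
as log10 peak width against log10 distance to the next peak center: peaks
belonging to one transcription unit (wide relative to their gap, "Type 1")
and unrelated, isolated peaks ("Type 2").  The classifier is a single
straight line in that plane, placed where the point density projected onto
the line's normal direction shows the deepest valley between two modes.
Type 1 peaks are merged with their nearest Type 1 neighbor, the separator is
re-estimated, and the procedure iterates until merging dries up; the
surviving merged intervals are the reconstructed transcription units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans

__all__ = [
    "GCLSConfig",
    "DensityProjection",
    "SeparatorModel",
    "peak_points",
    "projected_density",
    "find_separator",
    "classify_peaks",
    "merge_iteration",
    "run_gcls",
    "kmeans_cosine",
]


@dataclass
class GCLSConfig:
    """Tuning parameters of the separator search and the merge loop.

    angle_grid
        Number of candidate projection angles, evenly spaced over (0, pi).
    density_bins
        Histogram bins for the 1-D projected density.
    smoothing_bandwidth
        Gaussian smoothing sigma of the projected histogram, in bins.
    min_merges / min_merge_fraction
        An iteration that merges fewer than
        ``max(min_merges, min_merge_fraction * n_peaks)`` pairs is treated
        as converged (its merges are not applied).
    max_iterations
        Hard cap on merge iterations.
    min_mode_ratio / min_mode_fraction / bimodality_z
        A projection counts as bimodal only when the smaller of the two
        modes rises at least ``min_mode_ratio`` times above the valley,
        reaches ``min_mode_fraction`` of the global density maximum, and the
        mode-valley contrast exceeds ``bimodality_z`` standard deviations of
        the smoothed histogram's counting noise; wiggles of a single cloud
        fail these gates.
    """

    angle_grid: int = 180
    density_bins: int = 100
    smoothing_bandwidth: float = 2.0
    min_merges: int = 5
    min_merge_fraction: float = 0.005
    max_iterations: int = 50
    min_mode_ratio: float = 1.2
    min_mode_fraction: float = 0.05
    bimodality_z: float = 4.0

    def __post_init__(self) -> None:
        for name in ("angle_grid", "density_bins", "smoothing_bandwidth",
                     "min_merges", "min_merge_fraction", "max_iterations",
                     "min_mode_ratio", "min_mode_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DensityProjection:
    """Point density projected onto the normal of a candidate separator.

    ``u = log_w * cos(theta) - log_d * sin(theta)`` is the (signed) offset of
    a point from lines of slope tan(theta).  The histogram is taken on the
    z-scored projection ``(u - mu) / sigma`` over a fixed (-4, 4) range so
    that mode heights are comparable across angles; ``grid`` and the
    locations ``u_M1 < u_m < u_M2`` are therefore in z units (raw
    ``u = mu + sigma * z``).  M1/M2 are the two modes bracketing the deepest
    admissible valley m.
    """

    theta: float
    grid: np.ndarray
    density: np.ndarray
    bimodal: bool
    mu: float = np.nan
    sigma: float = np.nan
    M1: float = np.nan
    M2: float = np.nan
    m: float = np.nan
    u_M1: float = np.nan
    u_M2: float = np.nan
    u_m: float = np.nan

    @property
    def objective(self) -> float:
        """Peak-to-valley difference min(M1, M2) - m (nan if unimodal)."""
        return min(self.M1, self.M2) - self.m if self.bimodal else np.nan


@dataclass
class SeparatorModel:
    """The fitted line ``log_w = slope * log_d + intercept``."""

    slope: float
    intercept: float
    theta_star: float
    objective: float
    projection: DensityProjection = field(repr=False)


def peak_points(peaks: pd.DataFrame) -> pd.DataFrame:
    """(log10 gap, log10 width) coordinates, one point per peak.

    The gap d_i of peak i is the center-to-center distance to the next peak
    on the same chromosome; the last peak of a chromosome reuses its
    preceding gap.  Chromosomes holding a single peak contribute no point
    (such peaks are classified Type 2 by default).

    Returns a frame with columns ``peak_index`` (integer position in
    ``peaks``), ``log_d`` and ``log_w``.
    """
    rows = []
    for _, grp in peaks.groupby("chrom", sort=False):
        if len(grp) < 2:
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        centers = (starts + ends) // 2
        widths = ends - starts
        gaps = np.diff(centers)
        d = np.concatenate([gaps, gaps[-1:]])  # last peak: preceding gap
        d = np.maximum(d, 1)
        w = np.maximum(widths, 1)
        rows.append(pd.DataFrame({
            "peak_index": grp.index.to_numpy(),
            "log_d": np.log10(d),
            "log_w": np.log10(w),
        }))
    if not rows:
        raise ValueError("insufficient peaks: need >= 2 peaks on some chromosome")
    return pd.concat(rows, ignore_index=True)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1-D curve."""
    n = len(y)
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i == 0 or y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            idx.append((i + j) // 2)
        i = j + 1
    return np.asarray(idx, dtype=int)


def projected_density(points: pd.DataFrame, theta: float,
                      config: GCLSConfig | None = None) -> DensityProjection:
    """Smoothed 1-D density of the points projected at angle ``theta``."""
    config = config or GCLSConfig()
    x = points["log_d"].to_numpy(float)
    y = points["log_w"].to_numpy(float)
    if len(x) < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0):
        raise ValueError("degenerate point set")
    u = y * np.cos(theta) - x * np.sin(theta)
    mu, sigma = float(u.mean()), float(u.std())
    if sigma == 0:
        raise ValueError("degenerate projection: all points identical along u")
    z = (u - mu) / sigma
    counts, edges = np.histogram(z, bins=config.density_bins, range=(-4.0, 4.0))
    width = edges[1] - edges[0]
    smoothed = gaussian_filter1d(counts.astype(float), config.smoothing_bandwidth,
                                 mode="constant")
    density = smoothed / (smoothed.sum() * width)
    grid = 0.5 * (edges[:-1] + edges[1:])
    # counting-noise scale of a smoothed bin: var ~= count * sum(kernel^2)
    kappa = 1.0 / (2.0 * config.smoothing_bandwidth * np.sqrt(np.pi))

    maxima = _local_maxima(density)
    proj = DensityProjection(theta=theta, grid=grid, density=density,
                             bimodal=False, mu=mu, sigma=sigma)
    if len(maxima) < 2:
        return proj
    # choose the pair of modes with the largest peak-to-valley difference;
    # both modes must clear the significance gate or the scan stays unimodal
    floor = config.min_mode_fraction * density.max()
    best = None
    for a in range(len(maxima)):
        for b in range(a + 1, len(maxima)):
            i, j = maxima[a], maxima[b]
            k = i + int(np.argmin(density[i:j + 1]))
            valley = density[k]
            lower_mode = min(density[i], density[j])
            if lower_mode < floor or lower_mode < config.min_mode_ratio * valley:
                continue
            c_mode = min(smoothed[i], smoothed[j])
            c_valley = smoothed[k]
            noise = np.sqrt(kappa * (c_mode + c_valley))
            if c_mode - c_valley < config.bimodality_z * noise:
                continue
            obj = lower_mode - valley
            if best is None or obj > best[0]:
                best = (obj, i, j, k)
    if best is None:
        return proj
    obj, i, j, k = best
    if obj <= 0:
        return proj
    proj.bimodal = True
    proj.M1, proj.M2, proj.m = float(density[i]), float(density[j]), float(density[k])
    proj.u_M1, proj.u_M2, proj.u_m = float(grid[i]), float(grid[j]), float(grid[k])
    return proj


def find_separator(points: pd.DataFrame, config: GCLSConfig | None = None) -> SeparatorModel:
    """Scan projection angles for the largest peak-to-valley difference.

    The optimizing angle theta* is the slope angle of the separator; the
    line passes through the valley of the projected density:
    ``log_w * cos(theta*) - log_d * sin(theta*) = u_m``.
    """
    config = config or GCLSConfig()
    x = points["log_d"].to_numpy(float)
    y = points["log_w"].to_numpy(float)
    best: DensityProjection | None = None
    for k in range(config.angle_grid):
        theta = np.pi * (k + 0.5) / config.angle_grid
        cos_t = np.cos(theta)
        if abs(cos_t) < 1e-9:  # vertical line: slope undefined
            continue
        proj = projected_density(points, theta, config)
        if not proj.bimodal:
            continue
        if best is not None and proj.objective <= best.objective:
            continue
        # orientation guard: Type 1 (above the line) must be the small-gap
        # mode, else the same partition at the mirrored angle is preferred
        u_m_raw = proj.mu + proj.sigma * proj.u_m
        above = y - (np.tan(theta) * x + u_m_raw / cos_t) > 0
        if not above.any() or above.all():
            continue
        if x[above].mean() >= x[~above].mean():
            continue
        best = proj
    if best is None:
        raise ValueError("no bimodality detected at any projection angle")
    cos_t = np.cos(best.theta)
    slope = np.tan(best.theta)
    intercept = (best.mu + best.sigma * best.u_m) / cos_t
    return SeparatorModel(slope=float(slope), intercept=float(intercept),
                          theta_star=float(best.theta),
                          objective=float(best.objective), projection=best)


def classify_points(points: pd.DataFrame, separator: SeparatorModel) -> np.ndarray:
    """True where a point is Type 1 (strictly above the separator line)."""
    resid = points["log_w"].to_numpy(float) - (
        separator.slope * points["log_d"].to_numpy(float) + separator.intercept)
    return resid > 0


def classify_peaks(peaks: pd.DataFrame, points: pd.DataFrame,
                   separator: SeparatorModel) -> np.ndarray:
    """Per-peak Type 1 flags; peaks without a point are Type 2."""
    labels = np.zeros(len(peaks), dtype=bool)
    type1 = classify_points(points, separator)
    labels[points["peak_index"].to_numpy()[type1]] = True
    return labels


def merge_iteration(peaks: pd.DataFrame, labels: np.ndarray) -> tuple[pd.DataFrame, int]:
    """One greedy left-to-right pass merging adjacent Type 1 pairs.

    A Type 1 peak merges with its nearest neighbor (by center distance,
    same chromosome) when that neighbor is also Type 1 and not already
    consumed in this pass.  The merged peak spans both; height is the max,
    tag counts add.
    """
    merged_rows = []
    n_merges = 0
    for chrom, grp in peaks.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        heights = grp["height"].to_numpy(np.int64)
        summits = grp["summit"].to_numpy(np.int64)
        n_tags = grp["n_tags"].to_numpy(np.int64)
        lab = labels[grp.index.to_numpy()]
        centers = (starts + ends) // 2
        n = len(grp)
        rows: list[tuple] = []  # emitted rows for this chromosome
        merged_last = False  # last emitted row is a pair merged this pass
        i = 0
        while i < n:
            if lab[i] and n > 1:
                d_prev = centers[i] - centers[i - 1] if i > 0 else np.inf
                d_next = centers[i + 1] - centers[i] if i < n - 1 else np.inf
                nearest = i - 1 if d_prev <= d_next else i + 1
                if nearest == i + 1 and lab[i + 1]:
                    hi = max(heights[i], heights[i + 1])
                    summit = summits[i] if heights[i] >= heights[i + 1] else summits[i + 1]
                    rows.append((chrom, starts[i], ends[i + 1], hi, summit,
                                 n_tags[i] + n_tags[i + 1]))
                    merged_last = True
                    n_merges += 1
                    i += 2
                    continue
                if nearest == i - 1 and lab[i - 1] and rows and not merged_last:
                    _, s0, _, h0, sm0, t0 = rows.pop()
                    hi = max(h0, heights[i])
                    summit = sm0 if h0 >= heights[i] else summits[i]
                    rows.append((chrom, s0, ends[i], hi, summit, t0 + n_tags[i]))
                    merged_last = True
                    n_merges += 1
                    i += 1
                    continue
            rows.append((chrom, starts[i], ends[i], heights[i], summits[i],
                         n_tags[i]))
            merged_last = False
            i += 1
        merged_rows.extend(rows)
    out = pd.DataFrame(merged_rows, columns=list(peaks.columns))
    out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out, n_merges


def run_gcls(peaks: pd.DataFrame, config: GCLSConfig | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterate separator fitting and Type 1 merging to convergence.

    Returns ``(units, log)`` where ``units`` are the final merged intervals
    (same columns as ``peaks``) and ``log`` records, per iteration, the
    separator parameters, the objective, the Type 1 count and the merge
    count.  Iterations stop when no bimodal projection exists, when a pass
    would merge fewer than ``max(min_merges, min_merge_fraction * n)`` pairs
    (that pass is discarded, making the procedure idempotent), or at
    ``max_iterations``.
    """
    config = config or GCLSConfig()
    current = peaks.reset_index(drop=True).copy()
    log_rows = []
    for iteration in range(1, config.max_iterations + 1):
        try:
            points = peak_points(current)
            separator = find_separator(points, config=config)
        except ValueError:
            break
        labels = classify_peaks(current, points, separator)
        candidate, n_merges = merge_iteration(current, labels)
        threshold = max(config.min_merges, config.min_merge_fraction * len(current))
        log_rows.append((iteration, separator.slope, separator.intercept,
                         separator.objective, int(labels.sum()), n_merges,
                         len(current)))
        if n_merges < threshold:
            break
        current = candidate
    log = pd.DataFrame(log_rows, columns=["iteration", "slope", "intercept",
                                          "objective", "n_type1", "n_merges",
                                          "n_peaks"])
    return current, log


def bimodality_ratio(points: pd.DataFrame, config: GCLSConfig | None = None) -> float:
    """Largest peak-to-valley ratio min(M1, M2) / m over the angle grid.

    Diagnostic for how strongly two-clustered a width/gap scatter is; 1.0
    means no bimodal projection exists.
    """
    config = config or GCLSConfig()
    best = 1.0
    for k in range(config.angle_grid):
        theta = np.pi * (k + 0.5) / config.angle_grid
        proj = projected_density(points, theta, config)
        if proj.bimodal and proj.m > 0:
            best = max(best, min(proj.M1, proj.M2) / proj.m)
    return best


def kmeans_cosine(points: pd.DataFrame, k: int = 2, seed: int = 0) -> np.ndarray:
    """K-means on unit-normalized (log_d, log_w) points (cosine metric).

    Cross-check for the separator classification, not part of the pipeline:
    Euclidean k-means on L2-normalized vectors is equivalent to clustering
    by cosine dissimilarity.
    """
    X = points[["log_d", "log_w"]].to_numpy(float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of points {len(X)}")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero vector cannot be normalized for the cosine metric")
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
    return km.fit_predict(X / norms[:, None])
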