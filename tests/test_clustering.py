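import numpy as np
import pandas as pd
import pytest

from gcls.clustering import (GCLSConfig, bimodality_ratio, classify_points,
                             find_separator, kmeans_cosine, merge_iteration,
                             peak_points, projected_density, run_gcls)
from gcls.simulator import generate_fragmented_units

from conftest import two_gaussian_points


def make_peaks(pairs, chrom="chr1", labels=None):
    df = pd.DataFrame({"chrom": chrom,
                       "start": [p[0] for p in pairs],
                       "end": [p[1] for p in pairs]})
    df["height"] = 5
    df["summit"] = df["start"]
    df["n_tags"] = 10
    return df


class TestPeakPoints:
    def test_gap_and_width_logs(self):
        points = peak_points(make_peaks([(0, 100), (200, 300)]))
        assert np.isclose(points.iloc[0]["log_d"], np.log10(200))
        assert np.isclose(points.iloc[0]["log_w"], 2.0)

    def test_last_peak_reuses_preceding_gap(self):
        points = peak_points(make_peaks([(0, 100), (200, 300), (1000, 1100)]))
        # last point: gap to previous center (1050 - 250 = 800)
        assert np.isclose(points.iloc[2]["log_d"], np.log10(800))

    def test_single_peak_chromosome_excluded(self):
        peaks = pd.concat([make_peaks([(0, 100), (300, 400)], "chr1"),
                           make_peaks([(0, 50)], "chr2")], ignore_index=True)
        points = peak_points(peaks)
        assert set(points["peak_index"]) == {0, 1}

    def test_fewer_than_two_peaks_everywhere_errors(self):
        with pytest.raises(ValueError, match="insufficient peaks"):
            peak_points(make_peaks([(0, 100)]))


class TestProjectedDensity:
    def test_theta_zero_is_width_axis(self):
        points, _ = two_gaussian_points(500, seed=0)
        proj = projected_density(points, 0.0)
        u = points["log_w"].to_numpy()
        assert np.isclose(proj.mu, u.mean())
        assert np.isclose(proj.sigma, u.std())

    def test_symmetric_mixture_valley_at_midpoint(self):
        rng = np.random.default_rng(0)
        n = 2000
        u = np.r_[rng.normal(-1, 0.2, n), rng.normal(1, 0.2, n)]
        # embed the 1-D mixture along log_w at theta=0
        points = pd.DataFrame({"peak_index": np.arange(2 * n),
                               "log_d": np.zeros(2 * n), "log_w": u})
        proj = projected_density(points, 0.0)
        assert proj.bimodal
        assert abs(proj.mu + proj.sigma * proj.u_m) < 0.1
        assert proj.u_M1 < proj.u_m < proj.u_M2
        assert proj.m <= min(proj.M1, proj.M2)

    def test_density_normalized(self):
        points, _ = two_gaussian_points(1000, seed=1)
        proj = projected_density(points, 0.7)
        width = proj.grid[1] - proj.grid[0]
        assert np.isclose(proj.density.sum() * width, 1.0)

    def test_unimodal_cloud_flagged(self):
        rng = np.random.default_rng(2)
        points = pd.DataFrame({"peak_index": np.arange(2000),
                               "log_d": rng.normal(3, 0.2, 2000),
                               "log_w": rng.normal(2, 0.2, 2000)})
        proj = projected_density(points, 0.3)
        assert not proj.bimodal

    def test_degenerate_points_error(self):
        points = pd.DataFrame({"peak_index": [0, 1], "log_d": [1.0, 1.0],
                               "log_w": [2.0, 2.0]})
        with pytest.raises(ValueError, match="degenerate"):
            projected_density(points, 0.5)


class TestFindSeparator:
    def test_two_cluster_recovery_vs_labels(self):
        points, truth = two_gaussian_points(2500, seed=3)
        sep = find_separator(points)
        labels = classify_points(points, sep)
        assert (labels == truth).mean() >= 0.95

    def test_objective_is_grid_maximum(self):
        """theta* beats every other admissible angle: bimodal projections
        whose above-the-line class is the small-gap population."""
        points, _ = two_gaussian_points(1500, seed=4)
        config = GCLSConfig(angle_grid=60)
        sep = find_separator(points, config)
        x = points["log_d"].to_numpy()
        y = points["log_w"].to_numpy()
        for k in range(config.angle_grid):
            theta = np.pi * (k + 0.5) / config.angle_grid
            if abs(np.cos(theta)) < 1e-9:
                continue
            proj = projected_density(points, theta, config)
            if not proj.bimodal:
                continue
            u_m_raw = proj.mu + proj.sigma * proj.u_m
            above = y - (np.tan(theta) * x + u_m_raw / np.cos(theta)) > 0
            if not above.any() or above.all():
                continue
            if x[above].mean() >= x[~above].mean():
                continue
            assert sep.objective >= proj.objective - 1e-12

    def test_mirror_symmetric_clusters_give_unit_slope(self):
        rng = np.random.default_rng(5)
        n = 2500
        # clusters mirrored about y = x -> separator is that diagonal
        points = pd.DataFrame({
            "peak_index": np.arange(2 * n),
            "log_d": np.r_[rng.normal(2.0, 0.2, n), rng.normal(3.0, 0.2, n)],
            "log_w": np.r_[rng.normal(3.0, 0.2, n), rng.normal(2.0, 0.2, n)]})
        sep = find_separator(points)
        assert abs(sep.slope - 1.0) < 0.1

    def test_single_cluster_errors(self):
        rng = np.random.default_rng(6)
        points = pd.DataFrame({"peak_index": np.arange(3000),
                               "log_d": rng.normal(3, 0.15, 3000),
                               "log_w": rng.normal(2, 0.15, 3000)})
        with pytest.raises(ValueError, match="bimodality"):
            find_separator(points)


class TestClassify:
    def test_above_line_is_type1_on_line_is_type2(self):
        points, _ = two_gaussian_points(100, seed=7)
        sep = find_separator(points)
        probe = pd.DataFrame({
            "peak_index": [0, 1],
            "log_d": [2.0, 2.0],
            "log_w": [sep.slope * 2.0 + sep.intercept + 0.5,
                      sep.slope * 2.0 + sep.intercept]})
        lab = classify_points(probe, sep)
        assert lab[0] and not lab[1]


class TestMergeIteration:
    def test_adjacent_type1_pair_merges(self):
        peaks = make_peaks([(0, 100), (200, 300)])
        merged, n = merge_iteration(peaks, np.array([True, True]))
        assert n == 1
        assert (merged.iloc[0]["start"], merged.iloc[0]["end"]) == (0, 300)

    def test_type2_neighbor_blocks_merge(self):
        peaks = make_peaks([(0, 100), (200, 300)])
        merged, n = merge_iteration(peaks, np.array([True, False]))
        assert n == 0
        assert len(merged) == 2

    def test_chain_merges_pairwise_per_pass(self):
        peaks = make_peaks([(0, 100), (200, 300), (400, 500)])
        merged, n = merge_iteration(peaks, np.ones(3, bool))
        assert n == 1  # (A,B) merge; C waits for the next iteration
        assert len(merged) == 2

    def test_nearest_type2_blocks_even_if_other_side_type1(self):
        # B's nearest neighbor is C (Type 2): no merge, even though A exists.
        peaks = make_peaks([(0, 100), (1000, 1100), (1400, 1500), (1600, 1700)])
        labels = np.array([False, True, False, True])
        merged, n = merge_iteration(peaks, labels)
        assert n == 0  # B blocked by C; D's nearest is also C

    def test_leftward_merge_with_unconsumed_neighbor(self):
        # B (Type 1) is blocked by its nearest neighbor A (Type 2) and is
        # emitted unmerged; C (Type 1) then merges leftward with B.
        peaks = make_peaks([(0, 100), (160, 260), (600, 700)])
        labels = np.array([False, True, True])
        merged, n = merge_iteration(peaks, labels)
        assert n == 1
        assert (merged.iloc[1]["start"], merged.iloc[1]["end"]) == (160, 700)

    def test_merge_conserves_tags_and_span(self):
        peaks, _ = generate_fragmented_units(n_units=30, n_noise=50, seed=9)
        labels = np.random.default_rng(0).random(len(peaks)) < 0.5
        merged, n = merge_iteration(peaks, labels)
        assert merged["n_tags"].sum() == peaks["n_tags"].sum()
        assert len(merged) == len(peaks) - n
        # merged intervals sorted within chromosome
        assert (merged["start"].to_numpy()[1:] >= merged["start"].to_numpy()[:-1]).all()


class TestRunGCLS:
    def test_unimodal_input_returned_unchanged(self):
        rng = np.random.default_rng(10)
        starts = np.cumsum(rng.integers(45_000, 55_000, 300))
        peaks = make_peaks([(int(s), int(s + rng.integers(150, 400)))
                            for s in starts])
        units, log = run_gcls(peaks)
        pd.testing.assert_frame_equal(units, peaks)

    def test_unit_count_non_increasing_and_disjoint(self):
        peaks, _ = generate_fragmented_units(seed=11)
        units, log = run_gcls(peaks)
        assert len(units) <= len(peaks)
        assert (log["n_peaks"].diff().dropna() <= 0).all()
        starts = units["start"].to_numpy()
        ends = units["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()

    def test_idempotence(self):
        peaks, _ = generate_fragmented_units(n_units=80, n_noise=200, seed=12)
        once, _ = run_gcls(peaks)
        twice, _ = run_gcls(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_fragmented_units_recovered(self):
        from gcls.profiles import unit_recovery_score
        peaks, truth = generate_fragmented_units(seed=13)
        units, _ = run_gcls(peaks)
        score = unit_recovery_score(units[["chrom", "start", "end"]], truth)
        assert score["mean_jaccard"] >= 0.75
        assert score["recall"] >= 0.9


class TestKmeansCosine:
    def test_two_angular_clusters_split(self):
        rng = np.random.default_rng(14)
        n = 200
        points = pd.DataFrame({
            "peak_index": np.arange(2 * n),
            "log_d": np.r_[rng.normal(1, 0.05, n), rng.normal(4, 0.05, n)],
            "log_w": np.r_[rng.normal(4, 0.05, n), rng.normal(1, 0.05, n)]})
        labels = kmeans_cosine(points, 2, seed=0)
        assert len(np.unique(labels[:n])) == 1
        assert len(np.unique(labels[n:])) == 1
        assert labels[0] != labels[-1]

    def test_agreement_with_separator(self):
        points, _ = two_gaussian_points(2500, seed=15)
        sep_labels = classify_points(points, find_separator(points))
        km = kmeans_cosine(points, 2, seed=0) == 1
        agreement = max((km == sep_labels).mean(), (km != sep_labels).mean())
        assert agreement >= 0.9

    def test_k_one_single_label(self):
        points, _ = two_gaussian_points(50, seed=16)
        assert len(np.unique(kmeans_cosine(points, 1, seed=0))) == 1

    def test_k_exceeding_n_errors(self):
        points, _ = two_gaussian_points(2, seed=17)
        with pytest.raises(ValueError):
            kmeans_cosine(points, 10)


def test_bimodality_ratio_strong_for_separated_clusters():
    points, _ = two_gaussian_points(2000, seed=18)
    assert bimodality_ratio(points) > 2.0
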