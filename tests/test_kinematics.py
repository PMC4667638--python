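"""Motility parameters, classification, episodes, densities, statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import slithertrack as st
from slithertrack.kinematics import (
    average_path,
    binned_depth_profile,
    classify_circling,
    classify_mode,
    compare_groups,
    compute_kinematics,
    detect_slither_episodes,
    rolling_mode_labels,
    surface_density,
)
from slithertrack.simulate import intervals_to_labels, simulate_mode_switching


class TestAveragePath:
    def test_line_preserved(self):
        t = np.linspace(0, 1, 101)
        line = np.column_stack([3 * t, 1 - 2 * t])
        assert np.allclose(average_path(line, 11), line, atol=1e-12)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(40, 2))
        assert np.array_equal(average_path(p, 1), p)

    def test_full_period_window_attenuates_sinusoid(self):
        """Averaging over one full beat period nearly cancels the yaw."""
        n, period = 421, 21
        x = np.arange(n, dtype=float)
        y = 2.0 * np.sin(2 * np.pi * x / period)
        avg = average_path(np.column_stack([x, y]), period)
        core = avg[period:-period]
        assert np.abs(core[:, 1]).max() < 0.05 * 2.0

    def test_window_longer_than_track_rejected(self):
        with pytest.raises(ValueError):
            average_path(np.zeros((5, 2)), 7)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            average_path(np.zeros((10, 2)), 4)


def straight_track(v=100.0, n=100, dt=0.02):
    t = np.arange(n) * dt
    return t, np.column_stack([v * t, np.zeros(n)])


def circle_track(r=10.0, v=50.0, n=400, dt=0.005):
    t = np.arange(n) * dt
    phi = v * t / r
    return t, np.column_stack([r * np.cos(phi), r * np.sin(phi)])


class TestComputeKinematics:
    def test_straight_line_all_parameters(self):
        t, p = straight_track(v=100.0)
        rep = compute_kinematics(t, p)
        assert rep.vcl_um_s == pytest.approx(100.0)
        assert rep.vap_um_s == pytest.approx(100.0)
        assert rep.vsl_um_s == pytest.approx(100.0)
        assert rep.lin_pct == pytest.approx(100.0)
        assert rep.wob_pct == pytest.approx(100.0)
        assert rep.alh_um == pytest.approx(0.0, abs=1e-9)
        assert rep.mcr_per_um == pytest.approx(0.0, abs=1e-9)
        assert rep.bcf_hz == 0.0
        assert rep.circling == "straight"

    def test_circle_mean_curvature_is_inverse_radius(self):
        t, p = circle_track(r=10.0)
        rep = compute_kinematics(t, p, window_frames=3)
        assert rep.mcr_per_um == pytest.approx(0.1, rel=1e-6)

    def test_circle_curvature_exact_across_sampling_rates(self):
        # three points on a circle circumscribe that circle exactly
        for n in (100, 200, 400):
            t, p = circle_track(r=25.0, n=n, dt=2.0 / n)
            rep = compute_kinematics(t, p, window_frames=3)
            assert rep.mcr_per_um == pytest.approx(1 / 25.0, rel=1e-9)

    def test_bcf_is_twice_beat_frequency(self):
        """Sinusoidal yaw at f crosses the average path twice per period."""
        f, rate, dur = 5.0, 200.0, 4.0
        t = np.arange(int(rate * dur)) / rate
        p = np.column_stack([60.0 * t, 1.5 * np.sin(2 * np.pi * f * t)])
        rep = compute_kinematics(t, p, window_frames=int(rate / f) + 1)
        # independent oracle: count analytic zero crossings of the yaw
        crossings = 2 * f * (t[-1] - t[0])
        assert rep.bcf_hz == pytest.approx(crossings / (t[-1] - t[0]), rel=0.05)
        assert rep.bcf_hz == pytest.approx(2 * f, rel=0.05)

    def test_alh_of_sinusoidal_yaw(self):
        # mean |A sin| = 2A/pi for a well-resolved sinusoid
        f, rate, A = 5.0, 500.0, 2.0
        t = np.arange(int(rate * 10)) / rate
        p = np.column_stack([80.0 * t, A * np.sin(2 * np.pi * f * t)])
        rep = compute_kinematics(t, p, window_frames=101)
        assert rep.alh_um == pytest.approx(2 * A / math.pi, rel=0.05)

    def test_velocity_ordering_on_generated_tracks(self, fine_config):
        """VCL >= VAP >= VSL for helical, planar and switching swimmers."""
        rng = np.random.default_rng(5)
        for params in (
            st.bull_slither_params(),
            st.bull_bulk_params(),
            st.bull_switching_params(),
        ):
            tr = st.simulate_swimmer(params, fine_config, rng=rng,
                                     initial_position=(100, 100))
            rep = compute_kinematics(tr.times, tr.xy)
            assert rep.vcl_um_s >= rep.vap_um_s >= rep.vsl_um_s >= 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=hst.integers(min_value=0, max_value=10_000))
    def test_velocity_ordering_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(16, 120)
        p = np.cumsum(rng.normal(0, 1.0, size=(n, 2)), axis=0)
        t = np.arange(n) * 0.02
        rep = compute_kinematics(t, p)
        assert rep.vcl_um_s + 1e-9 >= rep.vap_um_s >= rep.vsl_um_s - 1e-9

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        p = np.cumsum(rng.normal(0, 1.0, size=(60, 2)), axis=0)
        t = np.arange(60) * 0.02
        a = compute_kinematics(t, p)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        b = compute_kinematics(t, p @ R.T + np.array([12.0, -7.0]))
        for name in ("vcl_um_s", "vap_um_s", "vsl_um_s", "alh_um", "mcr_per_um"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-9)
        # crossing counts are discrete: near-zero deviations may flip by
        # one crossing under rotation round-off
        total_t = t[-1] - t[0]
        assert a.bcf_hz == pytest.approx(b.bcf_hz, abs=1.5 / total_t)
        assert a.circling == b.circling

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(np.array([0.0, 0.02]), np.zeros((2, 2)))

    def test_zero_total_time_rejected(self):
        with pytest.raises(ValueError):
            compute_kinematics(np.zeros(5), np.zeros((5, 2)), min_frames=3)


class TestCircling:
    def test_generated_arc_direction(self):
        t, p = circle_track(r=20.0, v=40.0, n=300, dt=0.01)  # ~ pi/3 turn... use more
        label = classify_circling(p)
        assert label == "ccw"

    def test_reflection_antisymmetry(self):
        t, p = circle_track(r=20.0)
        mirrored = p * np.array([1.0, -1.0])
        assert classify_circling(p) == "ccw"
        assert classify_circling(mirrored) == "cw"

    def test_small_winding_is_straight(self):
        t, p = straight_track()
        assert classify_circling(p) == "straight"

    def test_stationary_track_is_straight(self):
        assert classify_circling(np.zeros((30, 2))) == "straight"

    def test_population_bias_recovered(self):
        """74% CCW-generated population recovers its bias at n = 170."""
        rng = np.random.default_rng(7)
        cfg = st.SimulationConfig(duration_s=2.0, ground_truth_rate_hz=200,
                                  fov_um=(400, 400), seed=7)
        n, gen_ccw, rec_ccw = 170, 0, 0
        for _ in range(n):
            sign = 1.0 if rng.random() < 0.74 else -1.0
            gen_ccw += sign > 0
            p = st.bull_slither_params(path_curvature_per_um=sign * 0.01)
            tr = st.simulate_swimmer(p, cfg, rng=rng, initial_position=(200, 200))
            rec_ccw += compute_kinematics(tr.times, tr.xy).circling == "ccw"
        half_width = 1.96 * math.sqrt(0.74 * 0.26 / n)
        assert abs(rec_ccw / n - 0.74) < half_width + 1e-9
        assert rec_ccw == gen_ccw  # labels track the generated handedness


class TestModeClassification:
    def test_slither_signature(self, slither_track):
        mode = classify_mode(
            slither_track.head_area, tirf_visible=True, mean_z_um=0.3
        )
        assert mode == "slither"

    def test_bulk_signature(self, bulk_track):
        mode = classify_mode(
            bulk_track.head_area, tirf_visible=False, mean_z_um=None
        )
        assert mode == "bulk"

    def test_near_wall_requires_slab(self):
        area = np.full(50, 45.0)
        assert classify_mode(area, tirf_visible=False, mean_z_um=2.0) == "near_wall"
        assert classify_mode(area, tirf_visible=False, mean_z_um=None) == "bulk"

    def test_tirf_persistence_required(self):
        area = np.full(50, 45.0)
        vis = np.zeros(50, dtype=bool)
        vis[:10] = True  # fewer than 15 consecutive frames
        assert classify_mode(area, tirf_visible=vis, mean_z_um=0.5) != "slither"

    def test_missing_area_series_rejected(self):
        with pytest.raises(ValueError):
            classify_mode(np.array([]), tirf_visible=True)


class TestEpisodes:
    def test_switching_dwell_mean_recovered(self):
        """Frame-labelled two-state process recovers the 1119-ms mean."""
        iv = simulate_mode_switching(1119.0, 1500.0, 1200.0, seed=1)
        times = np.arange(int(1200 * 50)) / 50.0
        labels = intervals_to_labels(iv, times)
        labels = np.where(labels == "slither", "slither", "other")
        ep = detect_slither_episodes(times, labels)
        assert ep.n >= 300
        assert ep.mean_duration_ms == pytest.approx(1119.0, rel=0.05)

    def test_permanent_bulk_swimmer_empty(self):
        times = np.arange(100) * 0.02
        ep = detect_slither_episodes(times, np.full(100, "other"))
        assert ep.n == 0

    def test_uninterrupted_slither_is_one_full_episode(self):
        times = np.arange(100) * 0.02
        ep = detect_slither_episodes(times, np.full(100, "slither"))
        assert ep.n == 1
        assert ep.episodes.loc[0, "duration_ms"] == pytest.approx(100 * 20.0)

    def test_episode_path_length_is_chord_sum(self):
        times = np.arange(10) * 0.02
        labels = np.full(10, "slither")
        p = np.column_stack([np.arange(10) * 2.0, np.zeros(10)])
        ep = detect_slither_episodes(times, labels, positions=p)
        assert ep.episodes.loc[0, "path_length_um"] == pytest.approx(18.0)

    def test_rolling_labels_flag_low_cv_tirf_frames(self, slither_track):
        sub = slither_track.head_area[:200]
        labels = rolling_mode_labels(sub, np.ones(len(sub), dtype=bool), window=15)
        assert (labels == "slither").mean() > 0.8


class TestSurfaceDensity:
    @staticmethod
    def _labels(rows):
        return pd.DataFrame(rows, columns=["frame", "track_id", "label"])

    def test_count_over_area(self):
        rows = [(0, i, "near_wall") for i in range(10)]
        d = surface_density(self._labels(rows), 1, 0.02, 0.01)
        assert d.near_wall_density[0] == pytest.approx(1000.0)

    def test_slither_fraction_preserved(self):
        rows = [(0, i, "slither" if i < 39 else "near_wall") for i in range(100)]
        d = surface_density(self._labels(rows), 1, 0.02, 0.01)
        assert d.slither_density[0] / d.near_wall_density[0] == pytest.approx(0.39)

    def test_empty_frame_zero_density(self):
        d = surface_density(self._labels([]), 3, 0.02, 0.01)
        assert np.all(d.near_wall_density == 0)
        assert d.switching_rate == 0.0

    def test_switching_rate_counts_transitions(self):
        rows = [(0, 0, "slither"), (1, 0, "near_wall"), (2, 0, "slither")]
        d = surface_density(self._labels(rows), 3, 0.02, 0.01)
        # 2 transitions in 3 frames (0.06 s) over 0.01 mm^2
        assert d.switching_rate == pytest.approx(2 / 0.06 / 0.01)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            surface_density(self._labels([]), 1, 0.02, 0.0)


class TestDepthProfile:
    def test_single_bin_mean(self):
        z = np.array([50.0, 120.0, 180.0])
        v = np.array([1.0, 2.0, 3.0])
        prof = binned_depth_profile(z, v)
        assert len(prof.table) == 1
        assert prof.table.loc[0, "mean"] == pytest.approx(2.0)
        assert prof.table.loc[0, "n"] == 3

    def test_half_open_bin_edges(self):
        prof = binned_depth_profile(np.array([199.0, 200.0]), np.array([1.0, 2.0]))
        assert prof.table["bin_left_nm"].tolist() == [0.0, 200.0]

    def test_null_correlation_not_significant(self):
        """z-independent quantity: |r| small, p above 0.05."""
        rng = np.random.default_rng(42)
        z = rng.uniform(0, 2000, 300)
        v = rng.normal(100.0, 5.0, 300)
        prof = binned_depth_profile(z, v)
        assert abs(prof.pearson_r) < 0.15
        assert prof.p_value > 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binned_depth_profile(np.array([]), np.array([]))


class TestCompareGroups:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = compare_groups(a, a.copy(), kind="t_test")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_null_proportion_zero_statistic(self):
        stat, _ = compare_groups((50, 100), 0.5, kind="z_test_proportion")
        assert stat == pytest.approx(0.0)

    def test_two_proportion_against_closed_form(self):
        """Pooled two-proportion z computed by hand: p=0.35, z=1.4826."""
        stat, p = compare_groups((40, 100), (30, 100), kind="z_test_proportion")
        pool = 0.35
        z_hand = (0.40 - 0.30) / math.sqrt(pool * (1 - pool) * (1 / 100 + 1 / 100))
        assert stat == pytest.approx(z_hand, rel=1e-9)
        assert 0 < p < 1

    def test_welch_separates_table_speeds(self):
        """Bulk vs slither VCL distributions are overwhelmingly separated."""
        rng = np.random.default_rng(0)
        bulk = rng.normal(176.0, 13.2, 136)
        slither = rng.normal(74.7, 16.4, 170)
        stat, p = compare_groups(bulk, slither, kind="t_test")
        assert p <= 1e-3

    def test_pearson_kind(self):
        x = np.arange(20.0)
        stat, p = compare_groups(x, 2 * x + 1, kind="pearson")
        assert stat == pytest.approx(1.0)
        assert p < 1e-10

    def test_degenerate_t_test_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0], kind="t_test")
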