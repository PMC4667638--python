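"""Ground-truth generator: switching process, trajectories, rendering."""

import math

import numpy as np
import pytest
from scipy import stats

import slithertrack as st
from slithertrack.simulate import (
    HALF_MAX_MEAN_FACTOR,
    intervals_to_labels,
    simulate_mode_switching,
)


class TestModeSwitching:
    def test_mean_slither_dwell_recovered(self):
        """Exponential slither dwells average to the configured 1119 ms.

        The exponential has sd equal to its mean, so a 5% check needs a
        few thousand episodes to sit at ~3 standard errors.
        """
        iv = simulate_mode_switching(1119.0, 1500.0, 9500.0, seed=5)
        dwells = [(b - a) * 1e3 for a, b, lab in iv[1:-1] if lab == "slither"]
        assert len(dwells) >= 3000
        assert np.mean(dwells) == pytest.approx(1119.0, rel=0.05)

    def test_infinite_off_dwell_pins_single_interval(self):
        iv = simulate_mode_switching(1119.0, math.inf, 10.0, seed=0)
        assert len(iv) == 1
        assert iv[0] == (0.0, 10.0, "off")

    def test_intervals_tile_the_recording(self):
        iv = simulate_mode_switching(500.0, 800.0, 30.0, seed=2)
        assert iv[0][0] == 0.0 and iv[-1][1] == 30.0
        for (a0, b0, l0), (a1, b1, l1) in zip(iv, iv[1:]):
            assert b0 == a1 and l0 != l1

    def test_seed_reproducibility(self):
        assert simulate_mode_switching(1119, 1500, 60, seed=7) == simulate_mode_switching(
            1119, 1500, 60, seed=7
        )

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_mode_switching(1119, 1500, 0.0, seed=0)

    def test_dwells_are_exponential_ks(self):
        """KS distance between generated dwells and the target exponential."""
        iv = simulate_mode_switching(1119.0, 300.0, 1119.0 * 1.5, seed=3)
        dwells = np.array([b - a for a, b, lab in iv[1:-1] if lab == "slither"])
        assert len(dwells) >= 1000
        d, _ = stats.kstest(dwells, "expon", args=(0, 1.119))
        assert d < 0.05


class TestSimulateSwimmer:
    @pytest.mark.parametrize(
        "params",
        [
            st.bull_slither_params(),
            st.bull_bulk_params(),
            st.bull_switching_params(),
        ],
        ids=["slither", "bulk", "switching"],
    )
    def test_polyline_speed_matches_parameter(self, params, fine_config):
        """In-plane chord-summed speed equals speed_um_s within 1%."""
        tr = st.simulate_swimmer(params, fine_config, initial_position=(100, 100))
        length = np.linalg.norm(np.diff(tr.xy, axis=0), axis=1).sum()
        speed = length / (tr.times[-1] - tr.times[0])
        assert speed == pytest.approx(params.speed_um_s, rel=0.01)

    def test_straight_line_when_no_oscillation(self, fine_config):
        p = st.bull_slither_params(
            yaw_amplitude_um=0.0, path_curvature_per_um=0.0, area_noise_cv=0.0
        )
        tr = st.simulate_swimmer(
            p, fine_config, initial_position=(50, 50), initial_heading=0.0
        )
        assert np.allclose(tr.positions[:, 1], 50.0, atol=1e-9)
        steps = np.diff(tr.positions[:, 0])
        assert np.allclose(steps, steps[0], rtol=1e-6)
        assert steps[0] * fine_config.ground_truth_rate_hz == pytest.approx(
            74.7, rel=1e-6
        )

    def test_slither_confined_below_one_micron(self, slither_track):
        assert slither_track.z_um.max() < 1.0
        assert slither_track.z_um.min() >= 0.01

    def test_bulk_z_excursion_spans_helix(self, bulk_track):
        span = bulk_track.z_um.max() - bulk_track.z_um.min()
        assert span >= bulk_track.params.helix_radius_um

    def test_bulk_area_cv_near_printed_value(self, bulk_track):
        """Roll modulation produces the ~24% apparent-area variation."""
        cv = np.std(bulk_track.head_area) / np.mean(bulk_track.head_area)
        assert 0.20 <= cv <= 0.28

    def test_slither_area_cv_near_printed_value(self, slither_track):
        cv = np.std(slither_track.head_area) / np.mean(slither_track.head_area)
        assert 0.10 <= cv <= 0.16

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_winding_sign_follows_curvature(self, sign):
        """Total turn > 2 pi winds with the sign of the path curvature."""
        cfg = st.SimulationConfig(
            duration_s=10.0, ground_truth_rate_hz=200, fov_um=(400, 400), seed=3
        )
        p = st.bull_slither_params(path_curvature_per_um=sign * 0.12)
        tr = st.simulate_swimmer(p, cfg, initial_position=(200, 200))
        avg = st.average_path(tr.xy, 41)[20:-20]
        seg = np.diff(avg, axis=0)
        head = np.arctan2(seg[:, 1], seg[:, 0])
        turns = (np.diff(head) + np.pi) % (2 * np.pi) - np.pi
        winding = turns.sum()
        assert abs(winding) > 2 * np.pi
        assert np.sign(winding) == sign

    def test_switching_track_alternates_and_respects_confinement(self):
        cfg = st.SimulationConfig(
            duration_s=20.0, ground_truth_rate_hz=100, fov_um=(400, 400), seed=8
        )
        tr = st.simulate_swimmer(
            st.bull_switching_params(), cfg, initial_position=(200, 200)
        )
        assert set(np.unique(tr.mode_label)) == {"bulk", "slither"}
        assert tr.z_um[tr.mode_label == "slither"].max() < 1.0

    def test_invalid_slither_params_rejected(self):
        with pytest.raises(ValueError):
            st.SwimmerParams(mode="slither", z_baseline_um=2.0)
        with pytest.raises(ValueError):
            st.SwimmerParams(mode="slither", helix_radius_um=1.0)
        with pytest.raises(ValueError):
            st.SwimmerParams(area_modulation=1.0)


@pytest.fixture(scope="module")
def small_cfg():
    return st.SimulationConfig(
        duration_s=0.1, frame_rate_hz=50, ground_truth_rate_hz=500,
        fov_um=(40.0, 40.0), seed=0,
    )


class TestRendering:
    @staticmethod
    def _static_track(z_um, area=45.0, pos=(20.0, 20.0)):
        return st.GroundTruthTrack(
            track_id=0,
            times=np.array([0.0, 10.0]),
            positions=np.array([[*pos, z_um], [pos[0] + 1e-3, pos[1], z_um]]),
            head_area=np.array([area, area]),
            mode_label=np.array(["slither", "slither"]),
            handedness="none",
        )

    def test_tirf_brightness_follows_evanescent_decay(self, small_cfg, optics):
        """Integrated brightness ratio across z matches exp(-(z-z_ref)/d_p)."""
        ref = st.render_frames(
            [self._static_track(0.01)], small_cfg, optics, "tirf", noise=None
        )
        probe = st.render_frames(
            [self._static_track(0.8)], small_cfg, optics, "tirf", noise=None
        )
        ratio = probe.frames[0].sum() / ref.frames[0].sum()
        d_p = st.penetration_depth(optics)
        assert ratio == pytest.approx(math.exp(-(800 - 10) / d_p), rel=0.02)

    def test_deep_head_suppressed_in_tirf(self, small_cfg, optics):
        deep = st.render_frames(
            [self._static_track(1.5)], small_cfg, optics, "tirf", noise=None
        )
        assert deep.frames.max() == 0

    def test_epi_renders_slab_only(self, small_cfg, optics):
        near = st.render_frames(
            [self._static_track(1.5)], small_cfg, optics, "epi", noise=None
        )
        far = st.render_frames(
            [self._static_track(5.0)], small_cfg, optics, "epi", noise=None
        )
        assert near.frames.max() > 0
        assert far.frames.max() == 0

    def test_noise_free_peak_at_centroid(self, small_cfg, optics):
        stack = st.render_frames(
            [self._static_track(0.05, pos=(20.0, 24.0))],
            small_cfg, optics, "tirf", noise=None,
        )
        r, c = np.unravel_index(np.argmax(stack.frames[0]), stack.frames[0].shape)
        px = small_cfg.pixel_size_um
        assert (c + 0.5) * px == pytest.approx(20.0, abs=px)
        assert (r + 0.5) * px == pytest.approx(24.0, abs=px)

    def test_mean_head_intensity_calibration_constant(self, small_cfg, optics):
        """Mean over the half-max region is (1/2)/ln2 of the peak."""
        stack = st.render_frames(
            [self._static_track(0.01)], small_cfg, optics, "tirf", noise=None
        )
        frame = stack.frames[0].astype(float)
        peak = frame.max()
        half = frame >= peak / 2
        assert frame[half].mean() / peak == pytest.approx(
            HALF_MAX_MEAN_FACTOR, rel=0.01
        )

    def test_empty_track_list_gives_valid_empty_stack(self, small_cfg, optics):
        stack = st.render_frames([], small_cfg, optics, "tirf", noise=None)
        assert stack.n_frames == 6  # 0.1 s at 50 Hz inclusive
        assert stack.frames.max() == 0

    def test_rendering_deterministic_under_seed(self, small_cfg, optics):
        tr = self._static_track(0.2)
        a = st.render_frames([tr], small_cfg, optics, "tirf",
                             noise=st.NoiseParams(), seed=4)
        b = st.render_frames([tr], small_cfg, optics, "tirf",
                             noise=st.NoiseParams(), seed=4)
        assert np.array_equal(a.frames, b.frames)


class TestPopulation:
    def test_empty_population(self):
        cfg = st.SimulationConfig(duration_s=0.2, fov_um=(30, 30), seed=0)
        tracks, epi, tirf = st.generate_population(0, cfg)
        assert tracks == []
        assert epi.frames.max() == 0 and tirf.frames.max() == 0

    def test_slither_fraction_near_request(self):
        cfg = st.SimulationConfig(duration_s=0.5, ground_truth_rate_hz=100,
                                  fov_um=(500, 500), seed=12)
        tracks, _, _ = st.generate_population(250, cfg, render=False)
        frac = np.mean([t.mode_label[0] == "slither" for t in tracks])
        # three-sigma binomial band around 0.39 at n = 250
        assert abs(frac - 0.39) < 3.0 * math.sqrt(0.39 * 0.61 / 250)

    def test_same_seed_bit_identical_stacks(self):
        cfg = st.SimulationConfig(duration_s=0.5, fov_um=(60, 60), seed=9)
        _, epi1, tirf1 = st.generate_population(3, cfg, noise=st.NoiseParams())
        _, epi2, tirf2 = st.generate_population(3, cfg, noise=st.NoiseParams())
        assert np.array_equal(epi1.frames, epi2.frames)
        assert np.array_equal(tirf1.frames, tirf2.frames)


def test_interval_labels_half_open_convention():
    iv = [(0.0, 1.0, "off"), (1.0, 2.0, "slither")]
    labels = intervals_to_labels(iv, np.array([0.0, 0.99, 1.0, 1.5]))
    assert labels.tolist() == ["off", "off", "slither", "slither"]
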