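"""Shared fixtures: small synthetic acquisitions reused across test modules.

Everything is generated at test time from seeds; rendering is kept to
short, small-field stacks so the whole suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import slithertrack as st


@pytest.fixture(scope="session")
def optics():
    """The 473-nm, 1.45-NA glass/semen configuration at 63.5 degrees."""
    return st.default_optics()


@pytest.fixture(scope="session")
def fine_config():
    """Fine-sampled short acquisition for ground-truth-level checks."""
    return st.SimulationConfig(
        duration_s=3.0,
        frame_rate_hz=50.0,
        ground_truth_rate_hz=500.0,
        fov_um=(200.0, 200.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def slither_track(fine_config):
    return st.simulate_swimmer(
        st.bull_slither_params(), fine_config, initial_position=(100.0, 100.0)
    )


@pytest.fixture(scope="session")
def bulk_track(fine_config):
    return st.simulate_swimmer(
        st.bull_bulk_params(), fine_config, initial_position=(100.0, 100.0)
    )


@pytest.fixture(scope="session")
def slither_tirf_stack(slither_track, fine_config, optics):
    """Noise-free TIRF rendering of one slither swimmer."""
    return st.render_frames(
        [slither_track], fine_config, optics, modality="tirf", noise=None
    )


@pytest.fixture(scope="session")
def recovered_slither(slither_tirf_stack):
    """The slither swimmer re-measured through the full tracking chain."""
    tracks = st.track_stack(slither_tirf_stack)
    assert tracks, "tracking lost the only swimmer"
    return tracks[0]


def interp_truth(track, times):
    """Ground-truth x, y, z (um), area at arbitrary times."""
    gx = np.interp(times, track.times, track.positions[:, 0])
    gy = np.interp(times, track.times, track.positions[:, 1])
    gz = np.interp(times, track.times, track.positions[:, 2])
    ga = np.interp(times, track.times, track.head_area)
    return gx, gy, gz, ga
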