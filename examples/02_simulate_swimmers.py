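"""Ground-truth swimmers: helical bulk motion vs surface-confined slither.

Generates one swimmer of each mode at the calibrated speed settings
(bulk 176.0 um/s, slither 74.7 um/s) and runs the CASA kinematics stage
directly on the noise-free trajectories.
"""

import numpy as np

from slithertrack import (
    SimulationConfig,
    bull_bulk_params,
    bull_slither_params,
    compute_kinematics,
    simulate_swimmer,
)

config = SimulationConfig(
    duration_s=10.0, ground_truth_rate_hz=500.0, fov_um=(2000.0, 2000.0), seed=42
)

for name, params in (("bulk", bull_bulk_params()), ("slither", bull_slither_params())):
    track = simulate_swimmer(params, config, initial_position=(1000.0, 1000.0))
    rep = compute_kinematics(track.times, track.xy)
    cv = np.std(track.head_area) / np.mean(track.head_area)
    print(f"{name:8s} VCL {rep.vcl_um_s:6.1f}  VAP {rep.vap_um_s:6.1f}  "
          f"VSL {rep.vsl_um_s:6.1f} um/s  LIN {rep.lin_pct:4.0f}%  "
          f"BCF {rep.bcf_hz:5.1f} Hz  area CV {cv:.2f}  "
          f"z range [{track.z_um.min():.2f}, {track.z_um.max():.2f}] um  "
          f"{rep.circling}")

# The bulk swimmer's rolling head modulates its apparent area (~24% CV)
# and its helix sweeps z over microns; the slither swimmer stays below
# 1 um with a steady head (~13% CV) and circles counter-clockwise.
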