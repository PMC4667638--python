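"""Render a TIRF movie of a slither swimmer and re-measure it.

The swimmer is drawn as a moving Gaussian head whose brightness decays
with height above the glass; the tracking stage then re-detects it,
links the detections and inverts the evanescent decay to recover z.
"""

import numpy as np

from slithertrack import (
    SimulationConfig,
    bull_slither_params,
    default_optics,
    render_frames,
    simulate_swimmer,
    track_stack,
)

config = SimulationConfig(
    duration_s=3.0, frame_rate_hz=50.0, ground_truth_rate_hz=500.0,
    fov_um=(200.0, 200.0), seed=11,
)
optics = default_optics()
truth = simulate_swimmer(
    bull_slither_params(), config, initial_position=(100.0, 100.0)
)
stack = render_frames([truth], config, optics, modality="tirf", noise=None)
print(f"rendered {stack.n_frames} frames of {stack.frame_shape} px "
      f"({stack.pixel_size_um} um/px)")

(track,) = track_stack(stack)
gx = np.interp(track.times, truth.times, truth.positions[:, 0])
gy = np.interp(track.times, truth.times, truth.positions[:, 1])
gz = np.interp(track.times, truth.times, truth.positions[:, 2]) * 1e3

rmse_xy = np.sqrt(np.mean((track.x_um - gx) ** 2 + (track.y_um - gy) ** 2))
rmse_z = np.sqrt(np.mean((track.z_nm - gz) ** 2))
print(f"recovered {len(track)} detections")
print(f"centroid error   : {rmse_xy * 1e3:.0f} nm RMS in the plane")
print(f"height error     : {rmse_z:.0f} nm RMS "
      f"(true heights {gz.min():.0f}-{gz.max():.0f} nm)")
print(f"mean head area   : {track.area_um2.mean():.1f} um^2 "
      f"(generator {truth.head_area.mean():.1f})")
# Sub-pixel centroiding puts the planar error far below the 270-nm
# pixel; the evanescent inversion recovers z to a few tens of nm.
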