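"""Ground-truth swimmer simulation and fluorescence rendering.

Two swimming modes are generated.  A *bulk* swimmer propagates a helical
flagellar wave: its head centroid follows an average path (a circular arc
of signed curvature) plus a rotating helical offset, and body roll
modulates the apparent head area (the projected area shrinks as the head
turns edge-on, giving the characteristic ~24% coefficient of variation).
A *slither* swimmer is confined within 1 um of the coverslip: the head
stays surface-aligned (low, ~13% area variation), the beat is planar --
a sinusoidal yaw about the average path -- and the height above the glass
only drifts slowly (a bounded random walk at a small fraction of the
in-plane speed).  A *switching* swimmer alternates between the two with
independent exponential dwell times, the memoryless two-state process
whose slither-episode mean is the observable quantity.

The ``speed_um_s`` parameter is the *in-plane curvilinear speed*: the
trajectory is calibrated so that the xy polyline arc length per unit time
equals it at the ground-truth sampling rate.  This is deliberate -- the
curvilinear velocity (VCL) reported by motility analysis is measured on
the 2D projection, so a generator whose speed parameter is the 2D path
speed makes speed-recovery exact rather than projection-biased.

Rendering draws each head as an anisotropic Gaussian spot whose
half-maximum ellipse has exactly the apparent head area and whose
integrated brightness is proportional to that area.  TIRF frames scale
brightness by ``exp(-(z - z_ref)/d_p)`` and omit heads below the
detectability cutoff; epifluorescence renders every head inside a focal
slab (default 4 um) at full brightness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .optics import OpticalConfig, penetration_depth
from .stacks import FrameStack

__all__ = [
    "SwimmerParams",
    "SimulationConfig",
    "NoiseParams",
    "GroundTruthTrack",
    "bull_bulk_params",
    "bull_slither_params",
    "bull_switching_params",
    "default_optics",
    "simulate_mode_switching",
    "simulate_swimmer",
    "render_frames",
    "generate_population",
    "HALF_MAX_MEAN_FACTOR",
]

#: Mean intensity over the half-maximum region of a 2D Gaussian spot,
#: as a fraction of its peak: (1 - 1/2) / ln 2.
HALF_MAX_MEAN_FACTOR = 0.5 / math.log(2.0)

MODES = ("bulk", "slither", "switching")


@dataclass
class SwimmerParams:
    """Generative description of one swimmer.

    ``path_curvature_per_um`` is the signed curvature of the average path;
    positive curvature turns the heading counter-clockwise as seen from
    below the coverslip (the imaging side), matching the convention used
    for circling-direction statistics.
    """

    mode: str = "slither"
    speed_um_s: float = 74.7
    beat_freq_hz: float = 8.75
    yaw_amplitude_um: float = 1.2
    helix_radius_um: float = 0.0
    roll_freq_hz: float = 5.0
    path_curvature_per_um: float = 0.01
    head_area_um2: float = 45.0
    area_modulation: float = 0.0
    area_noise_cv: float = 0.13
    z_baseline_um: float = 0.3
    z_drift_speed_fraction: float = 0.07
    slither_dwell_ms: float = 1119.0
    offmode_dwell_ms: float = 1500.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.speed_um_s <= 0 or self.beat_freq_hz <= 0:
            raise ValueError("speed and beat frequency must be positive")
        if self.slither_dwell_ms <= 0 or self.offmode_dwell_ms <= 0:
            raise ValueError("dwell-time means must be positive")
        if not (0.0 <= self.area_modulation < 1.0):
            raise ValueError("area_modulation must lie in [0, 1)")
        if self.head_area_um2 <= 0:
            raise ValueError("head area must be positive")
        if self.mode == "slither":
            if self.z_baseline_um >= 1.0:
                raise ValueError("slither swimmers are confined below z = 1 um")
            if self.helix_radius_um != 0.0:
                raise ValueError("slither mode has no helical (rolling) component")
        if self.helix_radius_um < 0 or self.yaw_amplitude_um < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class SimulationConfig:
    """Sampling and field-of-view geometry for a synthetic acquisition."""

    frame_rate_hz: float = 50.0
    duration_s: float = 5.0
    fov_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.27
    ground_truth_rate_hz: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("frame rate and duration must be positive")
        if self.ground_truth_rate_hz < self.frame_rate_hz:
            raise ValueError("ground-truth sampling must be at least the frame rate")
        if min(self.fov_um) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field of view and pixel size must be positive")


@dataclass
class NoiseParams:
    """Camera noise model: constant background, shot noise, read noise."""

    background: float = 100.0
    poisson: bool = True
    read_noise_sd: float = 2.0


@dataclass
class GroundTruthTrack:
    """Finely sampled true trajectory of one swimmer (the oracle)."""

    track_id: int
    times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # (N, 3) um; z >= 0
    head_area: np.ndarray  # um^2
    mode_label: np.ndarray  # per sample: "bulk" or "slither"
    handedness: str  # "ccw", "cw" or "none"
    params: SwimmerParams | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.positions[:, 2] < 0):
            raise ValueError("heights must be non-negative")

    @property
    def xy(self) -> np.ndarray:
        return self.positions[:, :2]

    @property
    def z_um(self) -> np.ndarray:
        return self.positions[:, 2]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": np.arange(len(self.times)),
                "t_s": self.times,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "z_um": self.positions[:, 2],
                "area_um2": self.head_area,
                "mode": self.mode_label,
            }
        )


# -- presets -------------------------------------------------------------
# Calibrated to the bull-sperm study conditions: bulk curvilinear speed
# 176.0 um/s with ~24% apparent-area variation; slither speed 74.7 um/s
# with ~13% area variation, counter-clockwise bias, mean slither dwell
# 1119 ms.  head_area_um2 is the surface-aligned (maximum) area, so the
# rolling bulk head averages ~42 um^2 under 0.51 modulation depth.


def bull_bulk_params(**overrides) -> SwimmerParams:
    p = SwimmerParams(
        mode="bulk",
        speed_um_s=176.0,
        beat_freq_hz=9.4,
        yaw_amplitude_um=3.0,
        helix_radius_um=1.2,
        roll_freq_hz=5.0,
        path_curvature_per_um=0.002,
        head_area_um2=56.0,
        area_modulation=0.51,
        area_noise_cv=0.02,
        z_baseline_um=2.5,
        z_drift_speed_fraction=0.0,
    )
    return replace(p, **overrides)


def bull_slither_params(**overrides) -> SwimmerParams:
    p = SwimmerParams(
        mode="slither",
        speed_um_s=74.7,
        beat_freq_hz=8.75,
        yaw_amplitude_um=1.2,
        helix_radius_um=0.0,
        roll_freq_hz=0.0,
        path_curvature_per_um=0.01,
        head_area_um2=45.0,
        area_modulation=0.0,
        area_noise_cv=0.13,
        z_baseline_um=0.3,
        z_drift_speed_fraction=0.07,
    )
    return replace(p, **overrides)


def bull_switching_params(**overrides) -> SwimmerParams:
    p = SwimmerParams(
        mode="switching",
        speed_um_s=74.7,
        beat_freq_hz=8.75,
        yaw_amplitude_um=1.2,
        helix_radius_um=1.2,
        roll_freq_hz=5.0,
        path_curvature_per_um=0.01,
        head_area_um2=52.0,
        area_modulation=0.51,
        area_noise_cv=0.08,
        z_baseline_um=0.3,
        z_drift_speed_fraction=0.07,
        slither_dwell_ms=1119.0,
        offmode_dwell_ms=1500.0,
    )
    return replace(p, **overrides)


def default_optics(reference_intensity: float = 1.0) -> OpticalConfig:
    """Objective-type TIRF at 473 nm through 1.45-NA glass/semen interface."""
    return OpticalConfig(
        wavelength_nm=473.0,
        n_glass=1.5255,
        n_medium=1.3635,
        numerical_aperture=1.45,
        incident_angle_deg=63.5,
        reference_intensity=reference_intensity,
        reference_depth_nm=10.0,
    )


# -- two-state switching process ----------------------------------------


def simulate_mode_switching(
    slither_dwell_ms: float,
    offmode_dwell_ms: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float, str]]:
    """Alternating slither/off intervals with exponential dwell times.

    Returns ``(start_s, end_s, label)`` tuples covering ``[0, duration_s]``;
    the final interval is truncated at the end of the recording.  The
    initial state is drawn from the stationary occupancy of the two-state
    process.  Infinite dwell means are allowed and pin the process in the
    corresponding state.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if slither_dwell_ms <= 0 or offmode_dwell_ms <= 0:
        raise ValueError("dwell-time means must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    means = {"slither": slither_dwell_ms / 1e3, "off": offmode_dwell_ms / 1e3}
    if math.isinf(means["slither"]) and math.isinf(means["off"]):
        p_slither = 0.5
    elif math.isinf(means["slither"]):
        p_slither = 1.0
    elif math.isinf(means["off"]):
        p_slither = 0.0
    else:
        p_slither = means["slither"] / (means["slither"] + means["off"])
    state = "slither" if rng.random() < p_slither else "off"

    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    while t < duration_s:
        mean = means[state]
        dwell = math.inf if math.isinf(mean) else float(rng.exponential(mean))
        end = min(t + dwell, duration_s)
        intervals.append((t, end, state))
        t = end
        state = "off" if state == "slither" else "slither"
    return intervals


def intervals_to_labels(
    intervals: Sequence[tuple[float, float, str]], times: np.ndarray
) -> np.ndarray:
    """Label each sample time with the interval that contains it."""
    starts = np.array([iv[0] for iv in intervals])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
    labels = np.array([iv[2] for iv in intervals])
    return labels[idx]


# -- trajectory construction --------------------------------------------


def _center_path(
    s: np.ndarray, kappa: float, psi0: float, origin: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Arc of constant signed curvature, analytic in arc length."""
    psi = psi0 + kappa * s
    if abs(kappa) > 1e-12:
        x = origin[0] + (np.sin(psi) - np.sin(psi0)) / kappa
        y = origin[1] - (np.cos(psi) - np.cos(psi0)) / kappa
    else:
        x = origin[0] + s * np.cos(psi0)
        y = origin[1] + s * np.sin(psi0)
    return np.stack([x, y], axis=1), psi


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary AR(1) series."""
    out = np.empty(n)
    out[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(max(1.0 - rho * rho, 0.0))
    for k in range(1, n):
        out[k] = rho * out[k - 1] + innov[k - 1]
    return out


def _reflected_height_walk(
    n: int,
    dt: float,
    z0: float,
    vmax_um_s: float,
    rng: np.random.Generator,
    lo: float = 0.01,
    hi: float = 1.0,
    tau_s: float = 0.3,
) -> np.ndarray:
    """Bounded, speed-limited height drift: AR(1) velocity, reflecting walls."""
    z = np.empty(n)
    z[0] = min(max(z0, lo), hi)
    if vmax_um_s <= 0:
        z[:] = z[0]
        return z
    rho = math.exp(-dt / tau_s)
    v = 0.0
    sig = vmax_um_s * math.sqrt(1.0 - rho * rho)
    noise = rng.standard_normal(n - 1)
    for k in range(1, n):
        v = rho * v + sig * noise[k - 1]
        v = min(max(v, -vmax_um_s), vmax_um_s)
        zk = z[k - 1] + v * dt
        if zk > hi:
            zk = 2 * hi - zk
            v = -v
        if zk < lo:
            zk = 2 * lo - zk
            v = -v
        z[k] = min(max(zk, lo), hi)
    return z


def _slither_weight(
    times: np.ndarray,
    intervals: Sequence[tuple[float, float, str]],
    ramp_s: float = 0.1,
) -> np.ndarray:
    """Blend weight: 1 inside slither intervals, cosine ramp just outside.

    The ramp lives entirely in the off-mode side so that every sample
    labelled slither has weight exactly 1 (and hence slither-mode height).
    """
    sl = [(a, b) for a, b, lab in intervals if lab == "slither"]
    if not sl:
        return np.zeros_like(times)
    dist = np.full_like(times, np.inf)
    for a, b in sl:
        d = np.where(times < a, a - times, np.where(times > b, times - b, 0.0))
        dist = np.minimum(dist, d)
    w = np.clip(1.0 - dist / ramp_s, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * w)  # smooth ends


def simulate_swimmer(
    params: SwimmerParams,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    track_id: int = 0,
    initial_position: tuple[float, float] | None = None,
    initial_heading: float | None = None,
) -> GroundTruthTrack:
    """Generate one ground-truth trajectory at the fine sampling rate.

    The centre-path progression speed is solved (scalar root find) so the
    xy polyline speed at ``ground_truth_rate_hz`` equals ``speed_um_s``
    exactly, whatever lateral oscillation rides on top.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.ground_truth_rate_hz
    n = int(round(config.duration_s * rate)) + 1
    times = np.arange(n) / rate
    dt = 1.0 / rate
    total_t = times[-1]

    psi0 = rng.uniform(0, 2 * math.pi) if initial_heading is None else initial_heading
    origin = (
        np.array([config.fov_um[0] / 2, config.fov_um[1] / 2])
        if initial_position is None
        else np.asarray(initial_position, dtype=float)
    )
    beat_phase = rng.uniform(0, 2 * math.pi)
    roll_phase = rng.uniform(0, 2 * math.pi)

    # per-sample mode labels and blend weight
    if params.mode == "switching":
        intervals = simulate_mode_switching(
            params.slither_dwell_ms, params.offmode_dwell_ms, config.duration_s, rng
        )
        raw = intervals_to_labels(intervals, times)
        mode_label = np.where(raw == "slither", "slither", "bulk")
        w = _slither_weight(times, intervals)
    elif params.mode == "slither":
        mode_label = np.full(n, "slither")
        w = np.ones(n)
    else:
        mode_label = np.full(n, "bulk")
        w = np.zeros(n)

    # lateral offsets (in the local-normal direction of the average path)
    yaw = params.yaw_amplitude_um * np.sin(2 * math.pi * params.beat_freq_hz * times + beat_phase)
    roll = 2 * math.pi * params.roll_freq_hz * times + roll_phase
    helix_lat = params.helix_radius_um * np.cos(roll)
    lateral = yaw + (1.0 - w) * helix_lat

    kappa = params.path_curvature_per_um

    def xy_for(v_c: float) -> np.ndarray:
        s = v_c * times
        center, psi = _center_path(s, kappa, psi0, origin)
        normal = np.stack([-np.sin(psi), np.cos(psi)], axis=1)
        return center + lateral[:, None] * normal

    def mean_speed_minus_target(v_c: float) -> float:
        xy = xy_for(v_c)
        length = float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))
        return length / total_t - params.speed_um_s

    lo, hi = 0.0, params.speed_um_s
    if mean_speed_minus_target(lo) > 0:
        raise ValueError(
            "lateral oscillation alone exceeds the target path speed; "
            "reduce yaw/helix amplitude or beat/roll frequency"
        )
    while mean_speed_minus_target(hi) < 0:
        hi *= 1.5
        if hi > 100 * params.speed_um_s:  # pragma: no cover - pathological
            raise RuntimeError("speed calibration failed to bracket")
    v_c = brentq(mean_speed_minus_target, lo, hi, xtol=1e-10 * params.speed_um_s)
    xy = xy_for(v_c)

    # height above the coverslip
    z_bulk = np.clip(
        params.z_baseline_um + params.helix_radius_um * np.sin(roll), 0.005, None
    )
    if params.mode == "bulk":
        z = z_bulk
    else:
        z0 = params.z_baseline_um if params.z_baseline_um < 1.0 else 0.5
        z_sl = _reflected_height_walk(
            n, dt, z0, params.z_drift_speed_fraction * params.speed_um_s, rng
        )
        z = w * z_sl + (1.0 - w) * z_bulk if params.mode == "switching" else z_sl

    # apparent head area: roll modulation in bulk phases, correlated noise
    mod = 1.0 - params.area_modulation * np.sin(roll) ** 2 * (1.0 - w)
    area = params.head_area_um2 * mod
    if params.area_noise_cv > 0:
        g = _ar1(n, math.exp(-dt / 0.2), rng)
        area = area * (1.0 + params.area_noise_cv * g)
    area = np.clip(area, 0.05 * params.head_area_um2, None)

    handed = "none"
    if abs(kappa) > 0:
        handed = "ccw" if kappa > 0 else "cw"
    positions = np.column_stack([xy, z])
    return GroundTruthTrack(
        track_id=track_id,
        times=times,
        positions=positions,
        head_area=area,
        mode_label=mode_label,
        handedness=handed,
        params=params,
    )


# -- rendering -----------------------------------------------------------


def _sample_track_at(track: GroundTruthTrack, t: float):
    """Linear interpolation of position, area and heading at time t."""
    tt = track.times
    if t < tt[0] or t > tt[-1]:
        return None
    x = np.interp(t, tt, track.positions[:, 0])
    y = np.interp(t, tt, track.positions[:, 1])
    z = np.interp(t, tt, track.positions[:, 2])
    a = np.interp(t, tt, track.head_area)
    i = min(int(np.searchsorted(tt, t)), len(tt) - 1)
    j = max(i - 1, 0)
    dx = track.positions[i, 0] - track.positions[j, 0]
    dy = track.positions[i, 1] - track.positions[j, 1]
    theta = math.atan2(dy, dx) if (dx or dy) else 0.0
    return x, y, z, a, theta


def _add_gaussian_head(
    img: np.ndarray,
    x_px: float,
    y_px: float,
    peak: float,
    sigma_a_px: float,
    sigma_b_px: float,
    theta: float,
) -> None:
    """Accumulate an oriented Gaussian spot into ``img`` (in place)."""
    h, w = img.shape
    r = 4.0 * sigma_a_px
    x0, x1 = int(math.floor(x_px - r)), int(math.ceil(x_px + r)) + 1
    y0, y1 = int(math.floor(y_px - r)), int(math.ceil(y_px + r)) + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x_px
    ys = np.arange(y0, y1) - y_px
    xx, yy = np.meshgrid(xs, ys)
    ca, sa = math.cos(theta), math.sin(theta)
    u = ca * xx + sa * yy
    v = -sa * xx + ca * yy
    img[y0:y1, x0:x1] += peak * np.exp(
        -0.5 * ((u / sigma_a_px) ** 2 + (v / sigma_b_px) ** 2)
    )


def render_frames(
    tracks: Sequence[GroundTruthTrack],
    config: SimulationConfig,
    optics: OpticalConfig | None = None,
    modality: str = "tirf",
    noise: NoiseParams | None = None,
    seed: int | np.random.Generator | None = None,
    peak_brightness: float = 3000.0,
    epi_slab_um: float = 4.0,
    aspect_ratio: float = 1.6,
) -> FrameStack:
    """Render ground-truth tracks into a synthetic fluorescence movie.

    Head spots are anisotropic Gaussians oriented along the instantaneous
    heading; ``sigma_a * sigma_b = area / (2 pi ln 2)`` so the half-maximum
    ellipse area equals the apparent head area, and the integrated
    brightness is proportional to it.  The stack metadata records the
    expected background-corrected mean head intensity at the reference
    depth (``i0_mean_intensity``), the quantity the depth-reconstruction
    stage calibrates against.
    """
    if modality not in ("epi", "tirf"):
        raise ValueError("modality must be 'epi' or 'tirf'")
    if modality == "tirf" and optics is None:
        raise ValueError("TIRF rendering needs an OpticalConfig")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    px = config.pixel_size_um
    w_px = int(round(config.fov_um[0] / px))
    h_px = int(round(config.fov_um[1] / px))
    n_frames = int(round(config.duration_s * config.frame_rate_hz)) + 1
    dt = 1.0 / config.frame_rate_hz

    if modality == "tirf":
        d_p = penetration_depth(optics)
        z_ref_um = optics.reference_depth_nm / 1e3
        cutoff = optics.detectability_ratio

    frames = np.zeros((n_frames, h_px, w_px), dtype=np.float32)
    for f in range(n_frames):
        t = f * dt
        img = frames[f]
        for track in tracks:
            sample = _sample_track_at(track, t)
            if sample is None:
                continue
            x, y, z, area, theta = sample
            if modality == "tirf":
                rel = math.exp(-(z - z_ref_um) * 1e3 / d_p)
                rel = min(rel, 1.0)
                if rel < cutoff:
                    continue
                peak = peak_brightness * rel
            else:
                if z >= epi_slab_um:
                    continue
                peak = peak_brightness
            sig_prod = area / (2 * math.pi * math.log(2.0))
            sigma_a = math.sqrt(sig_prod * aspect_ratio)
            sigma_b = sigma_a / aspect_ratio
            # pixel (r, c) samples the point ((c + 0.5) px, (r + 0.5) px)
            _add_gaussian_head(
                img, x / px - 0.5, y / px - 0.5, peak, sigma_a / px, sigma_b / px, theta
            )

    out = np.empty_like(frames, dtype=np.uint16)
    for f in range(n_frames):  # frame-wise to bound memory
        img = frames[f].astype(np.float64)
        if noise is not None:
            img += noise.background
            if noise.poisson:
                img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
            if noise.read_noise_sd > 0:
                img += rng.normal(0.0, noise.read_noise_sd, img.shape)
        out[f] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    frames = out

    meta = {
        "peak_brightness": peak_brightness,
        "i0_mean_intensity": HALF_MAX_MEAN_FACTOR * peak_brightness,
        "aspect_ratio": aspect_ratio,
        "epi_slab_um": epi_slab_um,
        "noise": None if noise is None else vars(noise),
        "n_tracks": len(tracks),
    }
    return FrameStack(
        frames=frames,
        pixel_size_um=px,
        frame_interval_s=dt,
        modality=modality,
        meta=meta,
    )


# -- population fixtures -------------------------------------------------


def generate_population(
    n_cells: int,
    config: SimulationConfig,
    optics: OpticalConfig | None = None,
    slither_fraction: float = 0.39,
    ccw_fraction: float = 0.74,
    slither_params: SwimmerParams | None = None,
    bulk_params: SwimmerParams | None = None,
    noise: NoiseParams | None = None,
    render: bool = True,
) -> tuple[list[GroundTruthTrack], FrameStack | None, FrameStack | None]:
    """Simulate a mixed near-wall population and render both channels.

    Each cell is independently assigned slither mode with probability
    ``slither_fraction`` (the observed fraction of near-wall cells in the
    slither mode); slither cells circle counter-clockwise with probability
    ``ccw_fraction``.  Entry points, headings and phases are randomized.
    Deterministic under the config seed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(config.seed)
    if optics is None:
        optics = default_optics()
    base_sl = slither_params or bull_slither_params()
    base_bk = bulk_params or bull_bulk_params()

    tracks: list[GroundTruthTrack] = []
    margin = 5.0
    for i in range(n_cells):
        is_slither = rng.random() < slither_fraction
        if is_slither:
            sign = 1.0 if rng.random() < ccw_fraction else -1.0
            p = replace(
                base_sl,
                path_curvature_per_um=sign * abs(base_sl.path_curvature_per_um),
            )
        else:
            p = base_bk
        pos = (
            rng.uniform(margin, config.fov_um[0] - margin),
            rng.uniform(margin, config.fov_um[1] - margin),
        )
        tracks.append(
            simulate_swimmer(
                p, config, rng=rng, track_id=i, initial_position=pos
            )
        )

    epi = tirf = None
    if render:
        epi = render_frames(
            tracks, config, optics, modality="epi", noise=noise,
            seed=np.random.default_rng(config.seed + 1),
        )
        tirf = render_frames(
            tracks, config, optics, modality="tirf", noise=noise,
            seed=np.random.default_rng(config.seed + 2),
        )
    return tracks, epi, tirf
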