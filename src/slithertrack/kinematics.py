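"""CASA-style motility analysis: kinematic parameters, swimming-mode and
circling classification, slither-episode statistics, surface density and
depth-binned profiles.

The eight standard head-trajectory parameters:

* **VCL** (curvilinear velocity): chord-summed path length / time.
* **VAP** (average-path velocity): arc length of the smoothed average
  path / time.
* **VSL** (straight-line velocity): first-to-last displacement / time.
* **LIN** = 100 * VSL/VCL, **WOB** = 100 * VAP/VCL (percent).
* **MCR** (mean curvature): time-averaged magnitude of the local
  three-point (circumscribed-circle) curvature of the raw path, per um.
* **ALH**: time-averaged perpendicular deviation of the head from the
  average path.  Note this is the literal mean deviation -- not the
  2 x max convention some CASA instruments use -- so absolute ALH values
  are roughly 2/pi times a sinusoidal yaw amplitude.
* **BCF** (beat-cross frequency): sign changes of the signed deviation
  from the average path per unit time; a sinusoidal yaw at beat
  frequency f crosses twice per period, giving BCF = 2f.

The average path is a centred moving average of the raw positions with
shrinking windows at the ends; the default window spans roughly one beat
period (~0.1 s of samples), e.g. 5 frames at 50 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "MotilityReport",
    "EpisodeSet",
    "DensitySeries",
    "DepthProfile",
    "average_path",
    "compute_kinematics",
    "classify_circling",
    "classify_mode",
    "rolling_mode_labels",
    "detect_slither_episodes",
    "surface_density",
    "binned_depth_profile",
    "compare_groups",
]

STRAIGHT_WINDING_THRESHOLD = math.pi / 4
AREA_CV_THRESHOLD = 0.185  # midpoint between slither (~13%) and bulk (~24%)


@dataclass
class MotilityReport:
    vcl_um_s: float
    vap_um_s: float
    vsl_um_s: float
    lin_pct: float
    wob_pct: float
    mcr_per_um: float
    alh_um: float
    bcf_hz: float
    circling: str  # "cw", "ccw" or "straight"
    area_cv: float = math.nan
    mode: str = ""  # "slither", "near_wall" or "bulk"
    mean_z_nm: float = math.nan
    track_id: int = -1
    n_frames: int = 0

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class EpisodeSet:
    """Slither episodes: onset/offset times, durations and path lengths."""

    episodes: pd.DataFrame  # start_s, end_s, duration_ms, path_length_um

    @property
    def n(self) -> int:
        return len(self.episodes)

    @property
    def mean_duration_ms(self) -> float:
        return float(self.episodes["duration_ms"].mean()) if self.n else math.nan

    @property
    def sd_duration_ms(self) -> float:
        return float(self.episodes["duration_ms"].std()) if self.n > 1 else math.nan

    @property
    def mean_path_length_um(self) -> float:
        v = self.episodes["path_length_um"]
        return float(v.mean()) if self.n and v.notna().any() else math.nan

    def summary(self) -> dict:
        return {
            "n_episodes": self.n,
            "mean_duration_ms": self.mean_duration_ms,
            "sd_duration_ms": self.sd_duration_ms,
            "mean_path_length_um": self.mean_path_length_um,
        }


@dataclass
class DensitySeries:
    times_s: np.ndarray
    near_wall_density: np.ndarray  # cells / mm^2
    slither_density: np.ndarray  # cells / mm^2
    switching_rate: float  # cells / s / mm^2

    def summary(self) -> dict:
        return {
            "near_wall_mean": float(np.mean(self.near_wall_density)),
            "near_wall_sd": float(np.std(self.near_wall_density)),
            "slither_mean": float(np.mean(self.slither_density)),
            "slither_sd": float(np.std(self.slither_density)),
            "slither_fraction": (
                float(np.sum(self.slither_density) / np.sum(self.near_wall_density))
                if np.sum(self.near_wall_density) > 0
                else math.nan
            ),
            "switching_rate": self.switching_rate,
        }


@dataclass
class DepthProfile:
    table: pd.DataFrame  # bin_left_nm, bin_right_nm, mean, n
    pearson_r: float
    r_squared: float
    p_value: float


# -- average path and kinematics ----------------------------------------


def average_path(positions: np.ndarray, window_frames: int) -> np.ndarray:
    """Centred moving average; endpoints use symmetric shrinking windows.

    Output has the same length as the input; a window of 1 is the
    identity and straight lines are preserved for any window.
    """
    p = np.asarray(positions, dtype=float)
    n = len(p)
    w = int(window_frames)
    if w < 1 or w % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if w > n:
        raise ValueError(f"window {w} exceeds track length {n}")
    if w == 1:
        return p.copy()
    half = w // 2
    csum = np.vstack([np.zeros((1, p.shape[1])), np.cumsum(p, axis=0)])
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def default_window(frame_rate_hz: float, beat_period_s: float = 0.1) -> int:
    """Smoothing window spanning about one flagellar beat period."""
    w = int(round(frame_rate_hz * beat_period_s))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def _menger_curvature(p: np.ndarray) -> np.ndarray:
    """|curvature| of the circumscribed circle through consecutive triples."""
    a, b, c = p[:-2], p[1:-1], p[2:]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(c - a, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    denom = ab * bc * ca
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(denom > 0, 2.0 * np.abs(cross) / denom, 0.0)
    return k


def _signed_deviation(raw: np.ndarray, avg: np.ndarray) -> np.ndarray:
    """Perpendicular deviation of the head from the average path, signed by
    the side (left positive) of the local average-path tangent."""
    tangent = np.gradient(avg, axis=0)
    norm = np.linalg.norm(tangent, axis=1)
    norm[norm == 0] = 1.0
    t_hat = tangent / norm[:, None]
    dev = raw - avg
    return t_hat[:, 0] * dev[:, 1] - t_hat[:, 1] * dev[:, 0]


def _count_sign_changes(signed: np.ndarray) -> int:
    """Crossings of zero; exact zeros carry the previous sign."""
    s = np.sign(signed)
    # forward-fill zeros with the previous non-zero sign
    last = 0.0
    for i in range(len(s)):
        if s[i] == 0:
            s[i] = last
        else:
            last = s[i]
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


def compute_kinematics(
    times: np.ndarray,
    positions: np.ndarray,
    window_frames: int | None = None,
    areas: np.ndarray | None = None,
    z_nm: np.ndarray | None = None,
    track_id: int = -1,
    min_frames: int = 3,
    straight_threshold_rad: float = STRAIGHT_WINDING_THRESHOLD,
) -> MotilityReport:
    """All eight motility parameters plus circling label for one track.

    ``positions`` is the (N, 2) head trajectory in um (the 2D projection);
    ``times`` in s.  Optional ``areas``/``z_nm`` series fill the apparent
    head-area CV and mean height fields used by mode classification.
    """
    times = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)[:, :2]
    n = len(p)
    if n < min_frames or n < 3:
        raise ValueError(f"need at least {max(min_frames, 3)} points, got {n}")
    total_t = times[-1] - times[0]
    if total_t <= 0:
        raise ValueError("zero total time")
    if window_frames is None:
        frame_rate = (n - 1) / total_t
        window_frames = min(default_window(frame_rate), n if n % 2 else n - 1)

    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    vcl = float(steps.sum() / total_t)

    avg = average_path(p, window_frames)
    vap = float(np.linalg.norm(np.diff(avg, axis=0), axis=1).sum() / total_t)
    vsl = float(np.linalg.norm(p[-1] - p[0]) / total_t)

    lin = 100.0 * vsl / vcl if vcl > 0 else 0.0
    wob = 100.0 * vap / vcl if vcl > 0 else 0.0

    mcr = float(np.mean(_menger_curvature(p))) if n >= 3 else 0.0

    signed = _signed_deviation(p, avg)
    alh = float(np.mean(np.abs(signed)))
    bcf = _count_sign_changes(signed) / total_t

    circ = classify_circling(
        avg,
        straight_threshold_rad=straight_threshold_rad,
        trim=window_frames // 2,
    )

    area_cv = math.nan
    if areas is not None and len(areas):
        a = np.asarray(areas, dtype=float)
        area_cv = float(np.std(a) / np.mean(a)) if np.mean(a) > 0 else math.nan
    mean_z = float(np.mean(z_nm)) if z_nm is not None and len(z_nm) else math.nan

    return MotilityReport(
        vcl_um_s=vcl,
        vap_um_s=vap,
        vsl_um_s=vsl,
        lin_pct=lin,
        wob_pct=wob,
        mcr_per_um=mcr,
        alh_um=alh,
        bcf_hz=float(bcf),
        circling=circ,
        area_cv=area_cv,
        mean_z_nm=mean_z,
        track_id=track_id,
        n_frames=n,
    )


# -- classification ------------------------------------------------------


def classify_circling(
    avg_path: np.ndarray,
    straight_threshold_rad: float = STRAIGHT_WINDING_THRESHOLD,
    trim: int = 0,
) -> str:
    """Circling direction from the net winding of the average path.

    Positive winding in image coordinates, viewed from below the
    coverslip, is counter-clockwise.  Total |winding| under the threshold
    (default pi/4), and degenerate (stationary) paths, are "straight".
    ``trim`` drops that many points at each end before measuring: the
    moving-average window shrinks at the track ends, so the endpoints
    curl back into the raw beat oscillation and add spurious winding.
    """
    p = np.asarray(avg_path, dtype=float)
    if trim > 0 and len(p) > 2 * trim + 2:
        p = p[trim:-trim]
    seg = np.diff(p, axis=0)
    ok = np.linalg.norm(seg, axis=1) > 1e-12
    seg = seg[ok]
    if len(seg) < 2:
        return "straight"
    headings = np.arctan2(seg[:, 1], seg[:, 0])
    turns = np.diff(headings)
    turns = (turns + math.pi) % (2 * math.pi) - math.pi
    winding = float(turns.sum())
    if abs(winding) < straight_threshold_rad:
        return "straight"
    return "ccw" if winding > 0 else "cw"


def classify_mode(
    area_um2: np.ndarray,
    tirf_visible: np.ndarray | bool,
    mean_z_um: float | None = None,
    area_cv_threshold: float = AREA_CV_THRESHOLD,
    min_consecutive_tirf: int = 15,
    slab_um: float = 4.0,
) -> str:
    """Swimming-mode call for one track.

    Slither: persistently visible in the TIRF channel (at least
    ``min_consecutive_tirf`` consecutive frames) with a consistently
    aligned head (area CV below the threshold separating the ~13% aligned
    from the ~24% rolling regime).  Near-wall: inside the epifluorescence
    focal slab (default 4 um) without meeting the slither criteria.
    Otherwise bulk.
    """
    a = np.asarray(area_um2, dtype=float)
    if a.size == 0:
        raise ValueError("mode classification needs a head-area series")
    cv = float(np.std(a) / np.mean(a)) if np.mean(a) > 0 else math.inf

    if isinstance(tirf_visible, (bool, np.bool_)):
        persistent = bool(tirf_visible)
    else:
        vis = np.asarray(tirf_visible, dtype=bool)
        run = best = 0
        for v in vis:
            run = run + 1 if v else 0
            best = max(best, run)
        persistent = best >= min_consecutive_tirf

    if persistent and cv < area_cv_threshold:
        return "slither"
    in_slab = mean_z_um is not None and mean_z_um < slab_um
    if in_slab or persistent:
        return "near_wall"
    return "bulk"


def rolling_mode_labels(
    area_um2: np.ndarray,
    tirf_visible: np.ndarray,
    window: int = 15,
    area_cv_threshold: float = AREA_CV_THRESHOLD,
) -> np.ndarray:
    """Per-frame slither/other labels from a sliding-window area CV.

    A frame is labelled slither when it is TIRF-visible and the area CV
    in the centred window around it is below the threshold.
    """
    a = pd.Series(np.asarray(area_um2, dtype=float))
    roll = a.rolling(window, center=True, min_periods=max(3, window // 2))
    cv = (roll.std(ddof=0) / roll.mean()).to_numpy()
    vis = np.asarray(tirf_visible, dtype=bool)
    slither = vis & (cv < area_cv_threshold)
    return np.where(slither, "slither", "other")


# -- episodes ------------------------------------------------------------


def detect_slither_episodes(
    times: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    positions: np.ndarray | None = None,
) -> EpisodeSet:
    """Maximal runs of slither-labelled frames.

    A run of k frames at interval dt has duration k*dt (each frame
    represents one sampling interval), so a track that is slither
    throughout yields a single episode covering its whole duration.
    Episode path length is the chord sum over the run when positions are
    given.
    """
    times = np.asarray(times, dtype=float)
    lab = np.asarray(labels)
    is_sl = lab == "slither"
    if len(times) != len(lab):
        raise ValueError("times and labels must have equal length")
    rows = []
    if is_sl.any():
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
        edges = np.flatnonzero(np.diff(is_sl.astype(int)))
        starts = np.concatenate([[0] if is_sl[0] else [], edges[~is_sl[edges]] + 1]).astype(int)
        ends = np.concatenate([edges[is_sl[edges]], [len(lab) - 1] if is_sl[-1] else []]).astype(int)
        for s, e in zip(starts, ends):
            k = e - s + 1
            length = math.nan
            if positions is not None and k >= 2:
                seg = np.asarray(positions, dtype=float)[s : e + 1, :2]
                length = float(
                    np.linalg.norm(np.diff(seg, axis=0), axis=1).sum()
                )
            rows.append(
                {
                    "start_s": times[s],
                    "end_s": times[e] + dt,
                    "duration_ms": k * dt * 1e3,
                    "path_length_um": length,
                }
            )
    df = pd.DataFrame(
        rows, columns=["start_s", "end_s", "duration_ms", "path_length_um"]
    )
    return EpisodeSet(episodes=df)


# -- density -------------------------------------------------------------


def surface_density(
    frame_labels: pd.DataFrame,
    n_frames: int,
    frame_interval_s: float,
    fov_area_mm2: float,
) -> DensitySeries:
    """Per-frame surface densities and the mode-switching rate.

    ``frame_labels`` has columns ``frame``, ``track_id`` and ``label``
    (``"slither"``, ``"near_wall"`` or ``"bulk"``); every row is one cell
    present in one frame.  Near-wall density counts slither and near-wall
    cells together (everything within the focal slab); the switching rate
    is the number of per-track label changes between consecutive frames
    per second per mm^2.
    """
    if fov_area_mm2 <= 0:
        raise ValueError("field-of-view area must be positive")
    near = np.zeros(n_frames)
    sli = np.zeros(n_frames)
    n_switch = 0
    if len(frame_labels):
        for f, grp in frame_labels.groupby("frame"):
            if 0 <= f < n_frames:
                near[f] = (grp["label"] != "bulk").sum()
                sli[f] = (grp["label"] == "slither").sum()
        for _, grp in frame_labels.groupby("track_id"):
            grp = grp.sort_values("frame")
            consec = np.diff(grp["frame"].to_numpy()) == 1
            lab = grp["label"].to_numpy()
            changed = lab[1:] != lab[:-1]
            n_switch += int(np.sum(consec & changed))
    total_t = n_frames * frame_interval_s
    return DensitySeries(
        times_s=np.arange(n_frames) * frame_interval_s,
        near_wall_density=near / fov_area_mm2,
        slither_density=sli / fov_area_mm2,
        switching_rate=n_switch / total_t / fov_area_mm2 if total_t > 0 else 0.0,
    )


# -- depth profile -------------------------------------------------------


def binned_depth_profile(
    z_nm: np.ndarray,
    values: np.ndarray,
    bin_nm: float = 200.0,
) -> DepthProfile:
    """Bin a quantity against height in half-open 200-nm intervals.

    Bins are [k*bin, (k+1)*bin); empty bins are omitted (missing, not
    zero).  The Pearson correlation of the unbinned quantity against z is
    reported with R^2 and two-sided p.
    """
    z = np.asarray(z_nm, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(z) != len(v) or len(z) == 0:
        raise ValueError("need matching, non-empty z and value arrays")
    k = np.floor(z / bin_nm).astype(int)
    df = pd.DataFrame({"bin": k, "value": v})
    g = df.groupby("bin")["value"]
    table = pd.DataFrame(
        {
            "bin_left_nm": g.mean().index * bin_nm,
            "bin_right_nm": (g.mean().index + 1) * bin_nm,
            "mean": g.mean().to_numpy(),
            "n": g.count().to_numpy(),
        }
    ).reset_index(drop=True)
    if len(z) >= 3 and np.std(z) > 0 and np.std(v) > 0:
        r, p = stats.pearsonr(z, v)
    else:
        r, p = math.nan, math.nan
    return DepthProfile(
        table=table, pearson_r=float(r), r_squared=float(r) ** 2, p_value=float(p)
    )


# -- group statistics ----------------------------------------------------


def compare_groups(sample_a, sample_b, kind: str = "t_test", alternative: str = "two-sided"):
    """Two-group statistics used for study summaries.

    ``t_test``: Welch two-sample t-test on numeric samples.
    ``z_test_proportion``: proportion z-test; each sample is
    ``(count, nobs)``, or ``sample_b`` may be a null proportion for a
    one-sample test.
    ``pearson``: correlation between two equal-length numeric samples.

    Returns ``(statistic, p_value)``.
    """
    if kind == "t_test":
        a = np.asarray(sample_a, dtype=float)
        b = np.asarray(sample_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs at least two observations per group")
        if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if kind == "z_test_proportion":
        count, nobs = sample_a
        if np.isscalar(sample_b):
            stat, p = proportions_ztest(
                count, nobs, value=float(sample_b), alternative=_prop_alt(alternative)
            )
        else:
            c2, n2 = sample_b
            stat, p = proportions_ztest(
                [count, c2], [nobs, n2], alternative=_prop_alt(alternative)
            )
        return float(stat), float(p)
    if kind == "pearson":
        r, p = stats.pearsonr(np.asarray(sample_a, float), np.asarray(sample_b, float))
        return float(r), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


def _prop_alt(alternative: str) -> str:
    return {"two-sided": "two-sided", "greater": "larger", "less": "smaller"}[
        alternative
    ]
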