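"""Head detection, track linking, track filtering and depth assignment.

The measurement chain mirrors standard single-particle head tracking:
background-correct the stack, segment bright head blobs per frame, take
the intensity-weighted centroid and the half-maximum area of each blob,
link detections frame-to-frame by greedy nearest neighbour under a
distance gate, drop tracks shorter than the minimum length, and -- for
TIRF stacks -- convert each detection's background-corrected mean head
intensity into a height above the coverslip via the evanescent decay.

Head area is measured as the area of the half-maximum region of the blob.
For a Gaussian spot this is independent of how bright the spot is, so the
area series of a cell fading with depth in a TIRF movie stays comparable
across frames, and the mean intensity over that region is proportional to
the peak -- the clean depth proxy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import filters, measure, restoration

from .optics import OpticalConfig, depth_from_intensity
from .stacks import FrameStack

__all__ = [
    "Detection",
    "Track",
    "correct_background",
    "detect_heads",
    "detect_stack",
    "link_tracks",
    "filter_tracks",
    "assign_depth",
    "calibrate_reference_intensity",
    "stack_threshold",
]

logger = logging.getLogger(__name__)

#: Ceiling on plausible curvilinear speed, um/s, used to derive the default
#: linking gate (comfortably above the fastest observed bulk swimmers).
VCL_MAX_UM_S = 250.0


@dataclass(frozen=True)
class Detection:
    frame_index: int
    x_um: float
    y_um: float
    area_um2: float
    mean_intensity: float
    peak_intensity: float


@dataclass
class Track:
    """Linked head detections of one cell."""

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    area_um2: np.ndarray
    mean_intensity: np.ndarray
    interpolated: np.ndarray  # True where a gap was bridged
    modality: str = "tirf"
    z_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.frames,
                "t_s": self.times,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "area_um2": self.area_um2,
                "mean_intensity": self.mean_intensity,
                "interpolated": self.interpolated.astype(int),
            }
        )
        df["z_nm"] = self.z_nm if self.z_nm is not None else np.nan
        return df


# -- background ----------------------------------------------------------


def correct_background(
    stack: FrameStack, method: str = "temporal_median", rolling_ball_radius: int = 25
) -> FrameStack:
    """Subtract the static background, clipping at zero.

    ``temporal_median`` removes the per-pixel median over time (moving
    cells contribute little to the median); stacks too short for a robust
    median fall back to per-frame rolling-ball estimation.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    frames = stack.frames.astype(np.float32)
    if method == "temporal_median" and stack.n_frames >= 3:
        bg = np.median(frames, axis=0)
        corrected = np.clip(frames - bg[None], 0, None)
    elif method in ("temporal_median", "rolling_ball"):
        corrected = np.empty_like(frames)
        for i, fr in enumerate(frames):
            bg = restoration.rolling_ball(fr, radius=rolling_ball_radius)
            corrected[i] = np.clip(fr - bg, 0, None)
    else:
        raise ValueError(f"unknown background method {method!r}")
    meta = dict(stack.meta)
    meta["background_corrected"] = method
    return FrameStack(
        frames=corrected,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        modality=stack.modality,
        meta=meta,
    )


# -- detection -----------------------------------------------------------


def stack_threshold(
    stack: FrameStack, policy: str | float = "relative", relative_fraction: float = 0.08
) -> float:
    """One segmentation threshold for the whole stack.

    ``"relative"`` (default): median + fraction of the median-to-max span,
    low enough to keep heads dimmed by evanescent decay above threshold.
    ``"otsu"``: Otsu's method on a pixel sample.  A float is used as-is.
    """
    if isinstance(policy, (int, float)) and not isinstance(policy, bool):
        return float(policy)
    pix = stack.frames
    if pix.size > 2_000_000:
        stride = pix.size // 2_000_000 + 1
        pix = pix.reshape(-1)[::stride]
    lo = float(np.median(pix))
    hi = float(pix.max())
    if hi <= lo:
        return math.inf  # featureless stack: nothing will be detected
    if policy == "relative":
        return lo + relative_fraction * (hi - lo)
    if policy == "otsu":
        return float(filters.threshold_otsu(np.asarray(pix, dtype=np.float64)))
    raise ValueError(f"unknown threshold policy {policy!r}")


def detect_heads(
    frame: np.ndarray,
    pixel_size_um: float,
    threshold: float,
    area_gate_um2: tuple[float, float] = (10.0, 120.0),
    frame_index: int = 0,
) -> list[Detection]:
    """Segment head blobs in one background-corrected frame.

    Connected components above ``threshold`` are size-gated to a plausible
    head-area window; each surviving blob contributes an intensity-weighted
    sub-pixel centroid, a half-maximum area and the mean intensity over
    the half-maximum region.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.isfinite(threshold) or frame.size == 0 or frame.max() < threshold:
        return []
    mask = frame >= threshold
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    out: list[Detection] = []
    h_img, w_img = frame.shape
    for region in measure.regionprops(labels, intensity_image=frame):
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h_img or c1 == w_img:
            continue  # clipped by the frame border: centroid/area unreliable
        peak = float(region.image_intensity.max())
        half = region.image_intensity >= 0.5 * peak
        n_half = int(half.sum())
        area = n_half * px_area
        if not (area_gate_um2[0] <= area <= area_gate_um2[1]):
            continue
        vals = region.image_intensity[half]
        mean_int = float(vals.mean())
        # intensity-weighted centroid over the half-max region (sub-pixel)
        yy, xx = np.nonzero(half)
        wsum = vals.sum()
        cy = float(((yy + r0 + 0.5) * vals).sum() / wsum)
        cx = float(((xx + c0 + 0.5) * vals).sum() / wsum)
        out.append(
            Detection(
                frame_index=frame_index,
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                area_um2=area,
                mean_intensity=mean_int,
                peak_intensity=peak,
            )
        )
    # deterministic order regardless of labelling order
    out.sort(key=lambda d: (d.x_um, d.y_um))
    return out


def detect_stack(
    stack: FrameStack,
    threshold: str | float = "relative",
    area_gate_um2: tuple[float, float] = (10.0, 120.0),
) -> list[list[Detection]]:
    """Per-frame detections for a whole (background-corrected) stack."""
    thr = stack_threshold(stack, threshold)
    return [
        detect_heads(
            stack.frames[f],
            stack.pixel_size_um,
            thr,
            area_gate_um2=area_gate_um2,
            frame_index=f,
        )
        for f in range(stack.n_frames)
    ]


# -- linking -------------------------------------------------------------


def default_max_step_um(frame_interval_s: float) -> float:
    """Linking gate: twice the per-frame displacement at the speed ceiling."""
    return 2.0 * VCL_MAX_UM_S * frame_interval_s


def link_tracks(
    detections_per_frame: list[list[Detection]],
    frame_interval_s: float,
    max_step_um: float | None = None,
    max_gap_frames: int = 2,
    modality: str = "tirf",
) -> list[Track]:
    """Greedy nearest-neighbour linking under a distance gate.

    Candidate (track, detection) pairs within ``max_step_um`` per frame of
    gap are assigned in order of increasing distance (ties broken by track
    then detection index, which the detector makes deterministic).
    Unmatched detections seed new tracks; gaps up to ``max_gap_frames``
    are bridged by linear interpolation and flagged.
    """
    if max_step_um is None:
        max_step_um = default_max_step_um(frame_interval_s)
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0
    for f, dets in enumerate(detections_per_frame):
        still = []
        for tr in active:
            if f - tr["dets"][-1].frame_index > max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        pairs = []
        for ti, tr in enumerate(active):
            last = tr["dets"][-1]
            gap = f - last.frame_index
            for di, d in enumerate(dets):
                dist = math.hypot(d.x_um - last.x_um, d.y_um - last.y_um)
                if dist <= max_step_um * gap:
                    pairs.append((dist, tr["id"], di, ti))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, _, di, ti in pairs:
            if ti in used_t or di in used_d:
                continue
            active[ti]["dets"].append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        for di, d in enumerate(dets):
            if di not in used_d:
                active.append({"id": next_id, "dets": [d]})
                next_id += 1
    finished.extend(active)
    finished.sort(key=lambda tr: tr["id"])

    tracks = []
    for tr in finished:
        tracks.append(_build_track(tr["id"], tr["dets"], frame_interval_s, modality))
    n_frag = sum(1 for t in tracks if len(t) < 3)
    if n_frag:
        logger.info("linking produced %d short fragments", n_frag)
    return tracks


def _build_track(
    track_id: int, dets: list[Detection], frame_interval_s: float, modality: str
) -> Track:
    """Assemble a Track, linearly interpolating bridged gap frames."""
    frames = np.array([d.frame_index for d in dets])
    full = np.arange(frames[0], frames[-1] + 1)
    interp = ~np.isin(full, frames)

    def fill(vals):
        return np.interp(full, frames, np.asarray(vals, dtype=float))

    return Track(
        track_id=track_id,
        frames=full,
        times=full * frame_interval_s,
        x_um=fill([d.x_um for d in dets]),
        y_um=fill([d.y_um for d in dets]),
        area_um2=fill([d.area_um2 for d in dets]),
        mean_intensity=fill([d.mean_intensity for d in dets]),
        interpolated=interp,
        modality=modality,
    )


# -- filtering -----------------------------------------------------------


def filter_tracks(
    tracks: list[Track],
    min_length_frames: int = 15,
    fov_policy: str = "none",
    fov_um: tuple[float, float] | None = None,
    n_stack_frames: int | None = None,
    edge_margin_um: float = 2.0,
) -> list[Track]:
    """Apply the minimum-track-length rule (15 frames) and, optionally,
    the field-of-view completeness rule.

    ``fov_policy="complete"`` keeps only tracks that either start and end
    near an FOV edge (cells crossing the field) or appear and disappear
    strictly inside the recording (not clipped by its first/last frame).
    Cells that leave and re-enter the field are separate tracks by
    construction of the linker.
    """
    kept = []
    for tr in tracks:
        if len(tr) < min_length_frames:
            continue
        if fov_policy == "none":
            kept.append(tr)
            continue
        if fov_policy != "complete":
            raise ValueError(f"unknown fov_policy {fov_policy!r}")
        if fov_um is None or n_stack_frames is None:
            raise ValueError("fov_policy='complete' needs fov_um and n_stack_frames")

        def near_edge(i: int) -> bool:
            x, y = tr.x_um[i], tr.y_um[i]
            return (
                x < edge_margin_um
                or y < edge_margin_um
                or x > fov_um[0] - edge_margin_um
                or y > fov_um[1] - edge_margin_um
            )

        crosses = near_edge(0) and near_edge(-1)
        inside = tr.frames[0] > 0 and tr.frames[-1] < n_stack_frames - 1
        if crosses or inside:
            kept.append(tr)
    logger.info("filter_tracks: %d of %d tracks retained", len(kept), len(tracks))
    return kept


# -- depth ---------------------------------------------------------------


def calibrate_reference_intensity(tracks: list[Track]) -> float:
    """I_0 calibration: the brightest background-corrected mean head
    intensity observed anywhere in the dataset, assigned to the closest
    possible approach.  Dataset-wide, not per-cell (dye loading varies by
    only a few percent between cells)."""
    best = 0.0
    for tr in tracks:
        if len(tr):
            best = max(best, float(np.max(tr.mean_intensity)))
    if best <= 0:
        raise ValueError("no detections to calibrate against")
    return best


def assign_depth(track: Track, optics: OpticalConfig) -> Track:
    """Attach the evanescent-decay height series (nm) to a TIRF track."""
    if track.modality != "tirf":
        raise ValueError(
            "depth reconstruction needs TIRF intensities; epifluorescence "
            "carries no height information"
        )
    z = depth_from_intensity(track.mean_intensity, optics)
    return replace(track, z_nm=np.asarray(z, dtype=float))
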