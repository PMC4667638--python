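"""End-to-end study orchestration: simulate -> render -> track -> analyze.

:func:`run_study` executes the full chain on a synthetic population and
writes every intermediate artifact (ground truth CSV, epi/TIRF TIFF
stacks, recovered track CSVs, per-track motility reports and a JSON study
summary) under one output directory.  Because the generator's trajectories
are the oracle, the summary includes a *recovery scorecard*: recovered
kinematics, mode calls and circling labels compared against the ground
truth sampled at the same frame times.  Everything is reproducible from
the configuration and seed alone.

The ``track`` and ``analyze`` stages are also usable in isolation on
externally supplied TIFF stacks / track CSVs (see :mod:`slithertrack.cli`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as stio
from .kinematics import (
    MotilityReport,
    classify_mode,
    compute_kinematics,
    detect_slither_episodes,
    rolling_mode_labels,
    surface_density,
)
from .optics import OpticalConfig
from .simulate import (
    GroundTruthTrack,
    NoiseParams,
    SimulationConfig,
    default_optics,
    generate_population,
)
from .stacks import FrameStack
from .tracking import (
    Track,
    assign_depth,
    calibrate_reference_intensity,
    correct_background,
    detect_stack,
    filter_tracks,
    link_tracks,
)

__all__ = ["StudyConfig", "StageError", "run_study", "track_stack", "analyze_tracks"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Complete, seeded description of one synthetic study."""

    optics: OpticalConfig = field(default_factory=default_optics)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_cells: int = 6
    slither_fraction: float = 0.39
    ccw_fraction: float = 0.74
    noise: NoiseParams | None = None
    threshold: str | float = "relative"
    area_gate_um2: tuple[float, float] = (10.0, 120.0)
    max_step_um: float | None = None
    max_gap_frames: int = 2
    min_track_frames: int = 15
    fov_policy: str = "none"
    smoothing_window: int | None = None
    area_cv_threshold: float = 0.185

    @property
    def seed(self) -> int:
        return self.sim.seed


def track_stack(
    stack: FrameStack,
    config: StudyConfig | None = None,
    optics: OpticalConfig | None = None,
) -> list[Track]:
    """Tracking stage: background correction, detection, linking,
    filtering and (for TIRF) depth assignment with dataset-wide I_0
    calibration."""
    cfg = config or StudyConfig()
    corrected = correct_background(stack)
    dets = detect_stack(corrected, threshold=cfg.threshold, area_gate_um2=cfg.area_gate_um2)
    tracks = link_tracks(
        dets,
        frame_interval_s=stack.frame_interval_s,
        max_step_um=cfg.max_step_um,
        max_gap_frames=cfg.max_gap_frames,
        modality=stack.modality,
    )
    tracks = filter_tracks(
        tracks,
        min_length_frames=cfg.min_track_frames,
        fov_policy=cfg.fov_policy,
        fov_um=stack.fov_um,
        n_stack_frames=stack.n_frames,
    )
    if stack.modality == "tirf" and tracks:
        opt = optics or cfg.optics
        # Prefer an instrument calibration shipped with the stack (synthetic
        # stacks record the mean head intensity at the reference depth);
        # otherwise estimate I_0 as the brightest mean head intensity seen,
        # which assumes some cell reaches the closest approach.
        i0 = stack.meta.get("i0_mean_intensity") or calibrate_reference_intensity(tracks)
        opt = opt.with_reference_intensity(float(i0))
        tracks = [assign_depth(t, opt) for t in tracks]
    return tracks


def analyze_tracks(
    tracks: list[Track],
    config: StudyConfig | None = None,
    fov_area_mm2: float | None = None,
    n_frames: int | None = None,
    frame_interval_s: float | None = None,
) -> dict:
    """Analysis stage: per-track motility reports, mode/circling calls,
    slither episodes and (when geometry is supplied) surface densities."""
    cfg = config or StudyConfig()
    reports: list[MotilityReport] = []
    label_rows = []
    episode_frames = []
    for tr in tracks:
        if len(tr) < 3:
            continue
        rep = compute_kinematics(
            tr.times,
            tr.xy,
            window_frames=cfg.smoothing_window,
            areas=tr.area_um2,
            z_nm=tr.z_nm,
            track_id=tr.track_id,
        )
        tirf_vis = tr.modality == "tirf"
        mean_z_um = (
            float(np.nanmean(tr.z_nm)) / 1e3 if tr.z_nm is not None else
            (2.0 if tr.modality == "epi" else None)
        )
        rep.mode = classify_mode(
            tr.area_um2,
            tirf_visible=np.full(len(tr), tirf_vis),
            mean_z_um=mean_z_um,
            area_cv_threshold=cfg.area_cv_threshold,
            min_consecutive_tirf=cfg.min_track_frames,
        )
        reports.append(rep)
        labels = rolling_mode_labels(
            tr.area_um2,
            np.full(len(tr), tirf_vis),
            window=cfg.min_track_frames,
            area_cv_threshold=cfg.area_cv_threshold,
        )
        episode_frames.append((tr, labels))
        for f, lab in zip(tr.frames, labels):
            label_rows.append(
                {
                    "frame": int(f),
                    "track_id": tr.track_id,
                    "label": "slither" if lab == "slither" else rep.mode,
                }
            )

    episodes = []
    for tr, labels in episode_frames:
        ep = detect_slither_episodes(tr.times, labels, positions=tr.xy)
        if ep.n:
            episodes.append(ep.episodes)
    episode_table = (
        pd.concat(episodes, ignore_index=True)
        if episodes
        else pd.DataFrame(columns=["start_s", "end_s", "duration_ms", "path_length_um"])
    )

    density = None
    if fov_area_mm2 and n_frames and frame_interval_s and label_rows:
        density = surface_density(
            pd.DataFrame(label_rows), n_frames, frame_interval_s, fov_area_mm2
        )

    return {
        "reports": reports,
        "episode_table": episode_table,
        "density": density,
    }


def _match_tracks(
    recovered: list[Track], truth: list[GroundTruthTrack], max_mean_dist_um: float = 3.0
) -> dict[int, int]:
    """Match recovered tracks to ground truth by mean xy distance at the
    recovered frame times."""
    matches: dict[int, int] = {}
    for tr in recovered:
        best, best_d = None, max_mean_dist_um
        for gt in truth:
            gx = np.interp(tr.times, gt.times, gt.positions[:, 0])
            gy = np.interp(tr.times, gt.times, gt.positions[:, 1])
            d = float(np.mean(np.hypot(tr.x_um - gx, tr.y_um - gy)))
            if d < best_d:
                best, best_d = gt.track_id, d
        if best is not None:
            matches[tr.track_id] = best
    return matches


def _scorecard(
    recovered: list[Track],
    reports: list[MotilityReport],
    truth: list[GroundTruthTrack],
    window: int | None,
) -> dict:
    """Recovered-vs-truth errors, with the truth resampled to the same
    frame times so the comparison isolates the measurement chain."""
    rep_by_id = {r.track_id: r for r in reports}
    matches = _match_tracks(recovered, truth)
    gt_by_id = {g.track_id: g for g in truth}
    rows = []
    for tr in recovered:
        if tr.track_id not in matches or tr.track_id not in rep_by_id:
            continue
        gt = gt_by_id[matches[tr.track_id]]
        gx = np.interp(tr.times, gt.times, gt.positions[:, 0])
        gy = np.interp(tr.times, gt.times, gt.positions[:, 1])
        gt_rep = compute_kinematics(
            tr.times, np.column_stack([gx, gy]), window_frames=window
        )
        rep = rep_by_id[tr.track_id]
        centroid_rmse = float(
            np.sqrt(np.mean((tr.x_um - gx) ** 2 + (tr.y_um - gy) ** 2))
        )
        row = {
            "track_id": tr.track_id,
            "gt_track_id": gt.track_id,
            "centroid_rmse_um": centroid_rmse,
            "circling_match": rep.circling == gt_rep.circling,
            "mode_truth": _dominant_mode(gt),
            "mode_recovered": rep.mode,
        }
        for name in ("vcl_um_s", "vap_um_s", "vsl_um_s", "alh_um", "bcf_hz"):
            t = getattr(gt_rep, name)
            r = getattr(rep, name)
            row[f"{name}_rel_err"] = abs(r - t) / abs(t) if t else np.nan
        if tr.z_nm is not None:
            gz = np.interp(tr.times, gt.times, gt.positions[:, 2]) * 1e3
            row["z_rmse_nm"] = float(np.sqrt(np.mean((tr.z_nm - gz) ** 2)))
            row["z_rms_rel_err"] = row["z_rmse_nm"] / float(
                np.sqrt(np.mean(gz**2))
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {"n_matched": len(df), "n_recovered": len(recovered), "n_truth": len(truth)}
    if len(df):
        summary["mean_centroid_rmse_um"] = float(df["centroid_rmse_um"].mean())
        for name in ("vcl_um_s", "vap_um_s", "vsl_um_s", "alh_um", "bcf_hz"):
            summary[f"{name}_mean_rel_err"] = float(df[f"{name}_rel_err"].mean())
        summary["circling_agreement"] = float(df["circling_match"].mean())
        # slither calls are only defined for TIRF-channel tracks
        tirf_rows = df[df["z_rmse_nm"].notna()] if "z_rmse_nm" in df else df.iloc[:0]
        if len(tirf_rows):
            summary["mode_agreement"] = float(
                (
                    (tirf_rows["mode_recovered"] == "slither")
                    == (tirf_rows["mode_truth"] == "slither")
                ).mean()
            )
        if "z_rms_rel_err" in df:
            sub = df["z_rms_rel_err"].dropna()
            if len(sub):
                summary["z_mean_rms_rel_err"] = float(sub.mean())
    return {"per_track": rows, "summary": summary}


def _dominant_mode(gt: GroundTruthTrack) -> str:
    return "slither" if np.mean(gt.mode_label == "slither") >= 0.5 else "bulk"


def _group_summary(reports: list[MotilityReport]) -> dict:
    """Mean +/- s.d. of every motility parameter per recovered mode."""
    df = stio.reports_to_dataframe(reports)
    out = {}
    params = [
        "vcl_um_s", "vap_um_s", "vsl_um_s", "lin_pct", "wob_pct",
        "mcr_per_um", "alh_um", "bcf_hz",
    ]
    for mode, grp in df.groupby("mode"):
        out[str(mode)] = {
            "n": int(len(grp)),
            **{
                p: {"mean": float(grp[p].mean()), "sd": float(grp[p].std(ddof=1))}
                for p in params
            },
        }
    return out


def run_study(config: StudyConfig, outdir: str | Path) -> dict:
    """Execute the full synthetic study and write all artifacts.

    Returns the study summary (also written as ``summary.json``).  Any
    stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config": _config_dict(config)}
    stage = "simulate"
    t0 = time.perf_counter()
    try:
        truth, epi, tirf = generate_population(
            config.n_cells,
            config.sim,
            config.optics,
            slither_fraction=config.slither_fraction,
            ccw_fraction=config.ccw_fraction,
            noise=config.noise,
        )
        stio.write_ground_truth_csv(truth, outdir / "ground_truth.csv")
        _stage_done(stage, t0)

        stage = "render"
        t0 = time.perf_counter()
        epi.save(outdir / "stack_epi.tiff")
        tirf.save(outdir / "stack_tirf.tiff")
        _stage_done(stage, t0)

        stage = "track"
        t0 = time.perf_counter()
        all_tracks: list[Track] = []
        for offset, (stack, name) in enumerate(((epi, "epi"), (tirf, "tirf"))):
            tracks = track_stack(stack, config, optics=config.optics)
            for t in tracks:
                t.track_id += offset * 10000  # keep per-channel ids disjoint
            stio.write_tracks_csv(tracks, outdir / f"tracks_{name}.csv")
            all_tracks.extend(tracks)
        _stage_done(stage, t0)

        stage = "analyze"
        t0 = time.perf_counter()
        result = analyze_tracks(
            all_tracks,
            config,
            fov_area_mm2=tirf.fov_area_mm2,
            n_frames=tirf.n_frames,
            frame_interval_s=tirf.frame_interval_s,
        )
        reports = result["reports"]
        stio.write_reports_csv(reports, outdir / "reports.csv")
        summary["groups"] = _group_summary(reports) if reports else {}
        ep = result["episode_table"]
        summary["episodes"] = {
            "n_episodes": int(len(ep)),
            "mean_duration_ms": float(ep["duration_ms"].mean()) if len(ep) else None,
            "mean_path_length_um": (
                float(ep["path_length_um"].dropna().mean())
                if len(ep) and ep["path_length_um"].notna().any()
                else None
            ),
        }
        if result["density"] is not None:
            summary["density"] = result["density"].summary()
        _stage_done(stage, t0)

        stage = "scorecard"
        t0 = time.perf_counter()
        card = _scorecard(all_tracks, reports, truth, config.smoothing_window)
        summary["scorecard"] = card["summary"]
        pd.DataFrame(card["per_track"]).to_csv(outdir / "scorecard.csv", index=False)
        _stage_done(stage, t0)
    except Exception as exc:  # noqa: BLE001 - stage-named re-raise
        raise StageError(stage, exc) from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True)
    )
    return summary


def _stage_done(stage: str, t0: float) -> None:
    logger.info("stage %-9s done in %.2f s", stage, time.perf_counter() - t0)


def _config_dict(config: StudyConfig) -> dict:
    return _clean(dataclasses.asdict(config))


def _clean(v):
    if isinstance(v, dict):
        return {k: _clean(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_clean(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
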