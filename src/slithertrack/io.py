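"""CSV/JSON serialization of tracks, reports and configurations.

Schemas (all headers carry units):

* ground truth: ``track_id, frame, t_s, x_um, y_um, z_um, area_um2, mode``
* recovered tracks: ``track_id, frame, t_s, x_um, y_um, area_um2,
  mean_intensity, interpolated, z_nm``
* per-track reports: one row per :class:`~slithertrack.kinematics.MotilityReport`

Configs are plain JSON; a missing field raises a validation error naming
the field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import MotilityReport
from .optics import OpticalConfig
from .simulate import GroundTruthTrack, NoiseParams, SimulationConfig
from .tracking import Track

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "reports_to_dataframe",
    "write_reports_csv",
    "read_reports_csv",
    "config_to_dict",
    "optical_config_from_dict",
    "simulation_config_from_dict",
    "noise_params_from_dict",
]


def write_tracks_csv(tracks: list[Track], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if tracks:
        df = pd.concat([t.to_dataframe() for t in tracks], ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=[
                "track_id", "frame", "t_s", "x_um", "y_um", "area_um2",
                "mean_intensity", "interpolated", "z_nm",
            ]
        )
    df.to_csv(path, index=False)
    return path


def read_tracks_csv(path: str | Path, modality: str = "tirf") -> list[Track]:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "t_s", "x_um", "y_um", "area_um2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing column(s): {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        z = None
        if "z_nm" in grp and grp["z_nm"].notna().any():
            z = grp["z_nm"].to_numpy(dtype=float)
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                times=grp["t_s"].to_numpy(dtype=float),
                x_um=grp["x_um"].to_numpy(dtype=float),
                y_um=grp["y_um"].to_numpy(dtype=float),
                area_um2=grp["area_um2"].to_numpy(dtype=float),
                mean_intensity=(
                    grp["mean_intensity"].to_numpy(dtype=float)
                    if "mean_intensity" in grp
                    else np.full(len(grp), np.nan)
                ),
                interpolated=(
                    grp["interpolated"].to_numpy().astype(bool)
                    if "interpolated" in grp
                    else np.zeros(len(grp), dtype=bool)
                ),
                modality=modality,
                z_nm=z,
            )
        )
    return tracks


def write_ground_truth_csv(tracks: list[GroundTruthTrack], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if tracks:
        df = pd.concat([t.to_dataframe() for t in tracks], ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["track_id", "frame", "t_s", "x_um", "y_um", "z_um", "area_um2", "mode"]
        )
    df.to_csv(path, index=False)
    return path


def read_ground_truth_csv(path: str | Path) -> list[GroundTruthTrack]:
    df = pd.read_csv(path)
    out = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        out.append(
            GroundTruthTrack(
                track_id=int(tid),
                times=grp["t_s"].to_numpy(dtype=float),
                positions=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                head_area=grp["area_um2"].to_numpy(dtype=float),
                mode_label=grp["mode"].to_numpy(),
                handedness="none",
            )
        )
    return out


def reports_to_dataframe(reports: list[MotilityReport]) -> pd.DataFrame:
    cols = [f.name for f in dataclasses.fields(MotilityReport)]
    return pd.DataFrame([r.to_dict() for r in reports], columns=cols)


def write_reports_csv(reports: list[MotilityReport], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    reports_to_dataframe(reports).to_csv(path, index=False)
    return path


def read_reports_csv(path: str | Path) -> list[MotilityReport]:
    df = pd.read_csv(path)
    return [MotilityReport(**row) for row in df.to_dict(orient="records")]


# -- configuration -------------------------------------------------------


def config_to_dict(cfg) -> dict:
    """Dataclass config -> plain-JSON dict (tuples become lists)."""
    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return clean(d)


def _from_dict(cls, data: dict, name: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(data)
    if missing:
        raise ValueError(f"missing field(s) {sorted(missing)} in {name}")
    unknown = set(data) - field_names
    if unknown:
        raise ValueError(f"unknown field(s) {sorted(unknown)} in {name}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def optical_config_from_dict(data: dict) -> OpticalConfig:
    return _from_dict(OpticalConfig, data, "OpticalConfig")


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    return _from_dict(SimulationConfig, data, "SimulationConfig")


def noise_params_from_dict(data: dict | None) -> NoiseParams | None:
    if data is None:
        return None
    return _from_dict(NoiseParams, data, "NoiseParams")
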