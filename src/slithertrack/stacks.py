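"""Time-lapse image stacks with acquisition metadata.

A :class:`FrameStack` is the package's in-memory form of a single-channel
fluorescence movie: a ``(T, H, W)`` array plus the pixel size, frame
interval and imaging modality (``"epi"`` or ``"tirf"``).  On disk it is a
multi-page TIFF with a JSON sidecar carrying the metadata, so stacks
written by the simulator and stacks from a microscope are interchangeable
inputs to the tracking stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FrameStack"]

MODALITIES = ("epi", "tirf")


@dataclass
class FrameStack:
    frames: np.ndarray  # (T, H, W)
    pixel_size_um: float
    frame_interval_s: float
    modality: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def fov_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in micrometres."""
        h, w = self.frame_shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    @property
    def fov_area_mm2(self) -> float:
        w, h = self.fov_um
        return w * h * 1e-6

    def save(self, path: str | Path) -> Path:
        """Write a multi-page 16-bit TIFF plus a ``.json`` sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = self.frames
        if data.dtype != np.uint16:
            data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "modality": self.modality,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"missing metadata sidecar {sidecar_path.name}; a FrameStack "
                "TIFF needs its JSON sidecar (pixel size, frame interval, modality)"
            )
        sidecar = json.loads(sidecar_path.read_text())
        return cls(
            frames=frames,
            pixel_size_um=sidecar["pixel_size_um"],
            frame_interval_s=sidecar["frame_interval_s"],
            modality=sidecar["modality"],
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
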