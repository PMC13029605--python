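"""Frame-stack container and on-disk formats (multi-page TIFF + JSON sidecar)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

__all__ = ["FrameSequence", "write_stack", "read_stack"]


@dataclass
class FrameSequence:
    """Timestamped grayscale image stack with physical calibration.

    Attributes
    ----------
    frames
        ``(n_frames, height, width)`` uint8 array.
    frame_rate
        Acquisition rate in frames per second.
    pixel_pitch_um
        Object-plane pixel pitch in micrometres (sensor pixel / magnification).
    meta
        Free-form provenance (seed, protocol, condition, ROI...).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) stack")
        if self.frame_rate <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("frame_rate and pixel_pitch_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) / self.frame_rate


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_stack(seq: FrameSequence, path: Union[str, Path]) -> Path:
    """Write a multi-page TIFF (one page per frame) plus a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        path = path / "stack.tif"
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames.astype(np.uint8), photometric="minisblack")
    sidecar = {
        "frame_rate_fps": seq.frame_rate,
        "pixel_pitch_um": seq.pixel_pitch_um,
        "n_frames": int(seq.n_frames),
        "frame_shape": [int(s) for s in seq.shape],
        **seq.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_stack(
    path: Union[str, Path],
    frame_rate: Optional[float] = None,
    pixel_pitch_um: Optional[float] = None,
) -> FrameSequence:
    """Read a stack written by :func:`write_stack`, or any TIFF stack /
    directory of single-frame TIFFs with calibration supplied explicitly."""
    path = Path(path)
    if path.is_dir():
        tiffs = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if len(tiffs) == 1:
            path = tiffs[0]
        elif tiffs:
            frames = np.stack([tifffile.imread(p) for p in tiffs])
            return FrameSequence(
                frames,
                frame_rate or 57.0,
                pixel_pitch_um or 0.74,
                {"source": str(path)},
            )
        else:
            raise FileNotFoundError(f"no TIFF frames under {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fr = frame_rate or meta.get("frame_rate_fps")
    pitch = pixel_pitch_um or meta.get("pixel_pitch_um")
    if fr is None or pitch is None:
        raise ValueError(
            "frame_rate and pixel_pitch_um must come from the sidecar or arguments"
        )
    return FrameSequence(frames, float(fr), float(pitch), meta)
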