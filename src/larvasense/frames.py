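"""Grayscale frame stacks (video) and their on-disk representation.

Stacks travel as multi-page TIFF (or a directory of numbered PNGs) with a
JSON sidecar carrying acquisition metadata and, for synthetic renders, the
ground-truth trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import InvalidParameterError

__all__ = ["FrameStack", "write_frames", "read_frames"]


@dataclass
class FrameStack:
    """(n_frames, rows, cols) grayscale array plus frame rate and pixel pitch."""

    frames: np.ndarray
    fps: float
    pixel_pitch: float  # um / pixel
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (n, rows, cols) array")
        if not self.fps > 0:
            raise InvalidParameterError("fps must be positive")
        if not self.pixel_pitch > 0:
            raise InvalidParameterError("pixel_pitch must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _sidecar(stack: FrameStack) -> dict[str, Any]:
    meta = {}
    for key, value in stack.metadata.items():
        if isinstance(value, np.ndarray):
            meta[key] = value.tolist()
        elif hasattr(value, "__dataclass_fields__"):
            meta[key] = {f: getattr(value, f) for f in value.__dataclass_fields__}
        else:
            meta[key] = value
    return {"fps": stack.fps, "pixel_pitch": stack.pixel_pitch, "metadata": meta}


def write_frames(stack: FrameStack, path: str | Path) -> None:
    """Write a multi-page TIFF (``.tif``) or numbered PNGs (directory path)."""
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, stack.frames)
        sidecar = path.with_suffix(path.suffix + ".json")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for k in range(stack.n_frames):
            iio.imwrite(path / f"frame_{k:05d}.png", stack.frames[k])
        sidecar = path / "stack.json"
    sidecar.write_text(json.dumps(_sidecar(stack), indent=1, default=str))


def read_frames(path: str | Path) -> FrameStack:
    """Read a stack written by :func:`write_frames` (TIFF file or PNG directory)."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise InvalidParameterError(f"{path}: no frame_*.png files found")
        frames = np.stack([iio.imread(f) for f in files])
        sidecar = path / "stack.json"
    else:
        import tifffile

        frames = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
    fps, pitch, meta = 30.0, 1.0, {}
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        fps = info.get("fps", fps)
        pitch = info.get("pixel_pitch", pitch)
        meta = info.get("metadata", {})
    return FrameStack(frames=frames, fps=fps, pixel_pitch=pitch, metadata=meta)
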