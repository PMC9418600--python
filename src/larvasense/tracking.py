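"""Video quantification of larval motion.

Frames are binarized (Otsu threshold, polarity configurable), the y position
of the outer (topmost) body boundary in a chosen pixel column is traced
relative to the first frame, and the dominant motion frequency of the
displacement trace is estimated with the same windowed-FFT machinery used
for the electrical channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import pipeline
from .errors import InsufficientDataError, InvalidParameterError
from .frames import FrameStack
from .waveform import Waveform

__all__ = ["Track", "binarize", "trace_displacement", "track_frequency", "write_track_csv"]


@dataclass
class Track:
    """Boundary-point displacement d(t) in micrometres, d(0) = 0."""

    times: np.ndarray  # s
    displacement: np.ndarray  # um, positive toward the top of the frame
    fps: float
    interpolated: np.ndarray = field(default=None)  # per-frame gap flags
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise InvalidParameterError("times and displacement must align")
        if self.interpolated is None:
            self.interpolated = np.zeros(self.times.shape, dtype=bool)


def binarize(stack: FrameStack, method: str = "otsu", polarity: str = "dark") -> FrameStack:
    """Foreground (larva) mask per frame.

    ``polarity="dark"`` treats darker-than-threshold pixels as the body
    (dark animal on a bright background); ``"bright"`` inverts that.  A
    blank frame (single intensity) yields an empty mask with a warning.
    """
    if method != "otsu":
        raise InvalidParameterError(f"unknown binarization method {method!r}")
    if polarity not in {"dark", "bright"}:
        raise InvalidParameterError("polarity must be 'dark' or 'bright'")
    if stack.n_frames == 0:
        raise InvalidParameterError("empty frame stack")
    masks = np.zeros(stack.frames.shape, dtype=bool)
    for k in range(stack.n_frames):
        frame = stack.frames[k]
        if frame.min() == frame.max():
            warnings.warn(f"frame {k}: single intensity, degenerate threshold", stacklevel=2)
            continue
        thr = threshold_otsu(frame)
        # Otsu returns the lower class level on clean two-level frames, so the
        # dark comparison is inclusive and the bright one exclusive
        masks[k] = frame <= thr if polarity == "dark" else frame > thr
    return FrameStack(
        frames=masks,
        fps=stack.fps,
        pixel_pitch=stack.pixel_pitch,
        metadata={**stack.metadata, "binarized": True, "polarity": polarity},
    )


def trace_displacement(stack: FrameStack, column: int) -> Track:
    """y displacement (um) of the topmost foreground pixel in ``column``.

    Displacement is referenced to frame 0 and positive when the boundary
    moves toward the top of the frame.  Frames with no foreground in the
    column are linearly interpolated and flagged.
    """
    if stack.frames.dtype != bool:
        raise InvalidParameterError("trace_displacement expects a binarized stack")
    n, rows, cols = stack.frames.shape
    if not 0 <= column < cols:
        raise InvalidParameterError(f"column {column} outside frame width {cols}")
    top = np.full(n, np.nan)
    for k in range(n):
        fg = np.nonzero(stack.frames[k, :, column])[0]
        if fg.size:
            top[k] = fg[0]
    if np.isnan(top[0]):
        raise InvalidParameterError(f"no foreground in column {column} of frame 0")
    gaps = np.isnan(top)
    if gaps.any():
        idx = np.arange(n)
        top[gaps] = np.interp(idx[gaps], idx[~gaps], top[~gaps])
    displacement = (top[0] - top) * stack.pixel_pitch
    return Track(
        times=np.arange(n) / stack.fps,
        displacement=displacement,
        fps=stack.fps,
        interpolated=gaps,
        metadata={**stack.metadata, "column": column},
    )


def track_frequency(
    track: Track, band: tuple[float, float] = (0.2, 4.0), min_cycles: float = 2.0
) -> float:
    """Dominant frequency (Hz) of d(t) via the windowed amplitude spectrum.

    Uses the largest power-of-two FFT length that fits the track.  Returns
    NaN (with a ``no_peak`` flag in the track metadata) when the trace
    carries no measurable oscillation, e.g. a static larva.
    """
    n = track.times.size
    low = max(band[0], 1e-6)
    if n / track.fps < min_cycles / low:
        raise InsufficientDataError(
            f"track too short: need >= {min_cycles} cycles at {low} Hz"
        )
    n_fft = 2 ** int(np.floor(np.log2(n)))
    w = Waveform(track.displacement - track.displacement.mean(), track.fps)
    spec = pipeline.amplitude_spectrum(w, n_fft=n_fft)
    high = min(band[1], track.fps / 2 * 0.99)
    banded = pipeline.band_filter(spec, low, high)
    if banded.amplitudes.max() <= 1e-12:
        track.metadata["no_peak"] = True
        return float("nan")
    return pipeline.dominant_peak(banded)


def write_track_csv(track: Track, path: str | Path) -> None:
    """``time_s,displacement_um`` CSV."""
    pd.DataFrame(
        {"time_s": track.times, "displacement_um": track.displacement}
    ).to_csv(path, index=False, float_format="%.9g")
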