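"""Measurement analysis chain for the larval voltage recordings.

The chain mirrors the bench protocol: the logged waveform is cut into 10 s
segments; each segment is smoothed with a 200-point centred moving average
(at 1 kHz this passes the 0.2--4 Hz larval band while suppressing
high-frequency readout noise); consecutive 4096-sample frames of each
segment are Hamming-windowed and Fourier transformed; single-sided amplitude
spectra are averaged; the spectrum is restricted to 0.2--4 Hz; and the
*activity index* -- the integral of the band-limited FFT amplitude over
frequency -- summarises larval vitality.  The dominant in-band peak
identifies the motion frequency.

Amplitude normalisation is single-sided 2/N scaling divided by the window's
coherent gain (mean Hamming value ~0.54), so a unit-amplitude in-band
sinusoid reads ~1 V at its bin.  All reference readouts (peak locations,
ratios, condition contrasts) are invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
import scipy.signal

from .errors import InsufficientDataError, InvalidParameterError
from .waveform import Waveform

__all__ = [
    "Spectrum",
    "ActivityScore",
    "segment",
    "moving_average",
    "amplitude_spectrum",
    "band_filter",
    "activity",
    "dominant_peak",
    "analyze_recording",
]


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum, possibly averaged over frames."""

    frequencies: np.ndarray  # Hz, ascending
    amplitudes: np.ndarray  # V, >= 0
    n_fft: int = 4096
    window_name: str = "hamming"
    n_segments_averaged: int = 1
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.frequencies.shape != self.amplitudes.shape:
            raise InvalidParameterError("frequencies and amplitudes must align")

    @property
    def df(self) -> float:
        """Frequency resolution (Hz per bin)."""
        if len(self.frequencies) < 2:
            return np.nan
        return float(self.frequencies[1] - self.frequencies[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency_hz": self.frequencies, "amplitude": self.amplitudes}
        )


@dataclass(frozen=True)
class ActivityScore:
    """Integrated band-limited FFT amplitude (V*Hz), the vitality statistic."""

    value: float
    band: tuple[float, float] = (0.2, 4.0)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidParameterError("activity must be >= 0")
        if not self.band[0] < self.band[1]:
            raise InvalidParameterError("band must satisfy low < high")


def segment(w: Waveform, segment_length: float = 10.0) -> list[Waveform]:
    """Cut into consecutive non-overlapping segments; drop the partial tail."""
    if segment_length <= 0:
        raise InvalidParameterError("segment_length must be positive")
    n_seg = int(round(segment_length * w.sampling_rate))
    if w.n_samples < n_seg:
        raise InsufficientDataError(
            f"recording ({w.duration:.3g} s) shorter than one segment ({segment_length} s)"
        )
    k = w.n_samples // n_seg
    return [w.copy_with(w.samples[i * n_seg : (i + 1) * n_seg], segment_index=i) for i in range(k)]


def moving_average(w: Waveform, window: int = 200) -> Waveform:
    """Centred moving mean; edges use shrunken windows so length is preserved."""
    if window < 1:
        raise InvalidParameterError("window must be >= 1")
    if window > w.n_samples:
        raise InsufficientDataError("window longer than the recording")
    smoothed = (
        pd.Series(w.samples).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return w.copy_with(smoothed, moving_average_window=window)


def amplitude_spectrum(
    w: Waveform, n_fft: int = 4096, window_name: str = "hamming"
) -> Spectrum:
    """Frame-averaged single-sided amplitude spectrum.

    The input is split into consecutive ``n_fft``-sample frames (a 10 s
    segment at 1 kHz yields two frames; the trailing 1808 samples are
    unused).  Each frame is tapered and transformed; amplitudes are averaged
    across frames.
    """
    if n_fft < 2:
        raise InvalidParameterError("n_fft must be >= 2")
    if w.n_samples < n_fft:
        raise InsufficientDataError(
            f"{w.n_samples} samples < n_fft = {n_fft}; cannot form one frame"
        )
    taper = scipy.signal.get_window(window_name, n_fft, fftbins=True)
    coherent_gain = float(taper.mean())
    n_frames = w.n_samples // n_fft
    frames = w.samples[: n_frames * n_fft].reshape(n_frames, n_fft)
    spectra = np.abs(np.fft.rfft(frames * taper, axis=1))
    # single-sided scaling: double all bins except DC (and Nyquist for even n)
    scale = np.full(spectra.shape[1], 2.0)
    scale[0] = 1.0
    if n_fft % 2 == 0:
        scale[-1] = 1.0
    amplitudes = spectra.mean(axis=0) * scale / (n_fft * coherent_gain)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / w.sampling_rate)
    return Spectrum(
        frequencies=freqs,
        amplitudes=amplitudes,
        n_fft=n_fft,
        window_name=window_name,
        n_segments_averaged=n_frames,
        metadata=dict(w.metadata),
    )


def band_filter(s: Spectrum, low: float = 0.2, high: float = 4.0) -> Spectrum:
    """Retain bins with ``low <= f <= high`` (the 0.2--4 Hz larval band)."""
    nyquist = s.frequencies[-1]
    if not low < high:
        raise InvalidParameterError("band must satisfy low < high")
    if high > nyquist + 1e-12:
        raise InvalidParameterError(f"band edge {high} Hz above Nyquist {nyquist} Hz")
    mask = (s.frequencies >= low) & (s.frequencies <= high)
    if not mask.any():
        raise InvalidParameterError("band contains no spectral bins")
    return replace(
        s,
        frequencies=s.frequencies[mask],
        amplitudes=s.amplitudes[mask],
        metadata={**s.metadata, "band": (low, high)},
    )


def activity(s: Spectrum) -> ActivityScore:
    """Trapezoidal integral of amplitude over the (band-limited) frequencies."""
    if len(s.frequencies) == 0:
        raise InvalidParameterError("empty spectrum")
    value = float(np.trapezoid(s.amplitudes, s.frequencies))
    band = s.metadata.get("band", (float(s.frequencies[0]), float(s.frequencies[-1])))
    return ActivityScore(value=max(value, 0.0), band=tuple(band))


def dominant_peak(s: Spectrum) -> float:
    """Frequency of the maximum-amplitude bin; ties break toward lower f."""
    if len(s.frequencies) == 0:
        raise InvalidParameterError("empty spectrum")
    return float(s.frequencies[int(np.argmax(s.amplitudes))])


def analyze_recording(
    w: Waveform,
    segment_length: float = 10.0,
    ma_window: int = 200,
    n_fft: int = 4096,
    window_name: str = "hamming",
    band: tuple[float, float] = (0.2, 4.0),
    smoothing: str = "smooth",
) -> dict[str, Any]:
    """Full chain: segment -> smooth -> spectrum -> band limit -> summarise.

    ``smoothing`` selects whether the FFT sees the moving-averaged signal
    (``"smooth"``, the default) or the residual after smoothing
    (``"residual"``).  Returns the frame-averaged band-limited spectrum, the
    per-segment activity scores, their mean (the per-recording activity) and
    the dominant in-band peak frequency.
    """
    if smoothing not in {"smooth", "residual"}:
        raise InvalidParameterError("smoothing must be 'smooth' or 'residual'")
    segments = segment(w, segment_length)
    seg_spectra: list[Spectrum] = []
    seg_activity: list[float] = []
    for s in segments:
        sm = moving_average(s, ma_window)
        if smoothing == "residual":
            sm = s.copy_with(s.samples - sm.samples)
        spec = amplitude_spectrum(sm, n_fft=n_fft, window_name=window_name)
        banded = band_filter(spec, *band)
        seg_spectra.append(banded)
        seg_activity.append(activity(banded).value)
    mean_amp = np.mean([s.amplitudes for s in seg_spectra], axis=0)
    mean_spectrum = replace(
        seg_spectra[0], amplitudes=mean_amp, n_segments_averaged=len(segments)
    )
    return {
        "spectrum": mean_spectrum,
        "segment_activity": seg_activity,
        "activity": ActivityScore(float(np.mean(seg_activity)), band),
        "peak_frequency": dominant_peak(mean_spectrum),
        "n_segments": len(segments),
    }
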