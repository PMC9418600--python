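"""Uniformly sampled voltage time series: the currency between every stage.

A :class:`Waveform` is what the data logger produces (1 kHz sampling in the
reference set-up), what the synthetic generator emulates and what the
electrostatic forward model outputs.  On disk it is a two-column CSV
(``time_s,voltage_V``) with a header row, one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, InvalidParameterError

__all__ = ["Waveform", "read_waveform_csv", "write_waveform_csv"]


@dataclass
class Waveform:
    """Voltage samples (V) at a fixed sampling rate (Hz) plus free-form metadata."""

    samples: np.ndarray
    sampling_rate: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")
        if not self.sampling_rate > 0:
            raise InvalidParameterError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, samples: np.ndarray, **extra_meta: Any) -> "Waveform":
        meta = {**self.metadata, **extra_meta}
        return Waveform(np.asarray(samples, dtype=float), self.sampling_rate, meta)


def write_waveform_csv(w: Waveform, path: str | Path) -> None:
    """Write ``time_s,voltage_V`` CSV (the data-logger export dialect)."""
    df = pd.DataFrame({"time_s": w.times, "voltage_V": w.samples})
    df.to_csv(path, index=False, float_format="%.12g")


def read_waveform_csv(path: str | Path) -> Waveform:
    """Read a two-column ``time_s,voltage_V`` CSV.

    The sampling rate is inferred from the time column, which must be
    uniform to within 1 ppm of the mean step; non-uniform spacing or
    non-numeric rows raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ["time_s", "voltage_V"]
    if list(df.columns[:2]) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(df.columns)}")
    if len(df) == 0:
        raise InsufficientDataError(f"{path}: no data rows")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2  # header is line 1
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = coerced
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 samples to infer a rate")
    dt = np.diff(df["time_s"].to_numpy())
    mean_dt = float(dt.mean())
    # 1 ppm relative tolerance plus a 10 ns absolute allowance for the
    # decimal rounding of the printed time column
    if mean_dt <= 0 or np.max(np.abs(dt - mean_dt)) > 1e-6 * mean_dt + 1e-8:
        raise FormatError(f"{path}: time column is not uniformly sampled (1 ppm tolerance)")
    return Waveform(df["voltage_V"].to_numpy(), 1.0 / mean_dt, {"source": str(path)})
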