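"""Single flat configuration for the whole pipeline.

Every constant of the measurement protocol and of the forward model is
visible and overridable in one YAML file with per-stage sections; unknown
keys are rejected so typos cannot silently fall back to defaults.  A config
hash (sha256 of the canonical dump) plus the seed is stamped into every
output for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import InvalidParameterError

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class RecordingSection:
    sampling_rate: float = 1000.0
    duration: float = 60.0


@dataclass(frozen=True)
class MotionSection:
    n_larvae: int = 10
    active_fraction: float = 0.8
    motion_frequency: float = 2.0
    burst_duty: float = 0.5
    per_larva_amplitude: float = 0.11e-3 / 8
    phase_jitter: float = 1.0


@dataclass(frozen=True)
class NoiseSection:
    white_sd: float = 2e-6
    drift_amplitude: float = 0.0
    drift_frequency: float = 0.05


@dataclass(frozen=True)
class AnalysisSection:
    segment_length: float = 10.0
    ma_window: int = 200
    n_fft: int = 4096
    window_name: str = "hamming"
    band_low: float = 0.2
    band_high: float = 4.0
    smoothing: str = "smooth"


@dataclass(frozen=True)
class ElectrostaticsSection:
    tooth_width: float = 80.0
    gap_width: float = 20.0
    n_teeth: int = 60
    out_of_plane_depth: float = 200.0
    domain_width: float = 680.0
    domain_height: float = 130.0
    grid_spacing: float = 2.5
    permittivity_water: float = 80.0
    symmetry: bool = True
    length_min: float = 80.0
    length_max: float = 600.0
    larva_height: float = 100.0
    surface_potential: float = -21e-3
    clearance: float = 10.0
    cycle_frequency: float = 2.0
    load_resistance: float = 150.0
    n_steps: int = 64
    n_cycles: int = 1
    mode: str = "open"


@dataclass(frozen=True)
class StatsSection:
    p_star: float = 0.05
    p_double_star: float = 0.01
    equal_var: bool = True
    replicates: int = 3


@dataclass(frozen=True)
class TrackingSection:
    polarity: str = "dark"
    column: int = -1  # -1: centre column


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results"
    recording: RecordingSection = field(default_factory=RecordingSection)
    motion: MotionSection = field(default_factory=MotionSection)
    noise: NoiseSection = field(default_factory=NoiseSection)
    analysis: AnalysisSection = field(default_factory=AnalysisSection)
    electrostatics: ElectrostaticsSection = field(default_factory=ElectrostaticsSection)
    stats: StatsSection = field(default_factory=StatsSection)
    tracking: TrackingSection = field(default_factory=TrackingSection)


_SECTIONS = {
    "recording": RecordingSection,
    "motion": MotionSection,
    "noise": NoiseSection,
    "analysis": AnalysisSection,
    "electrostatics": ElectrostaticsSection,
    "stats": StatsSection,
    "tracking": TrackingSection,
}


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load a YAML config (all keys optional), rejecting unknown keys."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise InvalidParameterError(f"{path}: config must be a mapping")
        data = loaded
    if overrides:
        data = _merge(data, overrides)
    top_known = {"seed", "output_dir", *_SECTIONS}
    unknown = set(data) - top_known
    if unknown:
        raise InvalidParameterError(f"unknown config key(s) {sorted(unknown)} in section 'root'")
    kwargs: dict[str, Any] = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise InvalidParameterError(f"config section '{name}' must be a mapping")
            known = {f.name for f in fields(cls)}
            bad = set(section) - known
            if bad:
                raise InvalidParameterError(
                    f"unknown config key(s) {sorted(bad)} in section '{name}'"
                )
            kwargs[name] = cls(**section)
    return PipelineConfig(**kwargs)


def _merge(base: dict[str, Any], extra: dict[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """sha256 of the canonical YAML dump (first 12 hex digits)."""
    dump = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(dump.encode()).hexdigest()[:12]
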