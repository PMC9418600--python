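"""Synthetic bench data: larval voltage recordings, driven-vibration
recordings, no-larvae controls, condition series and rendered frame stacks.

The generator emulates the study conditions of the reference experiment: a
pool of up to ~10 rehydrated chironomid larvae over a 1 x 1 cm comb-electrode
device, logged at 1 kHz.  Each active larva contributes intermittent
bend--stretch bursts: raised-cosine-gated sinusoid packets at the larval
motion frequency (nominally 1--2 Hz), with an independent uniformly random
phase per burst, geometric-distributed burst lengths of a few cycles, and a
duty cycle controlling the fraction of time spent moving.  Instrument noise
is white Gaussian plus a slow sub-0.2 Hz drift, standing in for the
low-frequency artifact background of the real logger.

Determinism: the top-level seed spawns independent per-larva and per-noise
substreams (``numpy.random.SeedSequence`` spawn keys), so identical
(seed, parameters) give bit-identical output and a k-larva recording equals
the sample-wise sum of its k per-larva components plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .frames import FrameStack
from .waveform import Waveform

__all__ = [
    "RecordingConfig",
    "LarvaMotionSpec",
    "NoiseModel",
    "ConditionResponse",
    "FrameStackSpec",
    "generate_recording",
    "generate_driven_recording",
    "generate_condition_series",
    "larva_component",
    "noise_component",
    "render_larva_frames",
]

# burst length in carrier cycles: 5 + geometric (mean ~8); long enough that
# >=99% of the burst-train power stays within +/-0.5 Hz of the carrier
# (see docs/methods.md)
_BURST_MIN_CYCLES = 5
_BURST_GEOM_P = 0.35


@dataclass(frozen=True)
class RecordingConfig:
    """Acquisition parameters of one synthetic recording."""

    duration: float
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if not self.duration > 0:
            raise InvalidParameterError("duration must be positive")


@dataclass(frozen=True)
class LarvaMotionSpec:
    """Population motion model: how many larvae, how active, how fast.

    ``per_larva_amplitude`` defaults to 0.11 mV / 8 so that the reference
    condition (8 of 10 larvae active) sums to the ~0.11 mV group amplitude
    observed on the device.
    """

    n_larvae: int = 10
    active_fraction: float = 0.8
    motion_frequency: float = 2.0
    burst_duty: float = 0.5
    per_larva_amplitude: float = 0.11e-3 / 8
    phase_jitter: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.active_fraction <= 1:
            raise InvalidParameterError("active_fraction must be in [0, 1]")
        if not self.motion_frequency > 0:
            raise InvalidParameterError("motion_frequency must be positive")
        if self.per_larva_amplitude < 0:
            raise InvalidParameterError("per_larva_amplitude must be >= 0")
        if not 0 < self.burst_duty <= 1:
            raise InvalidParameterError("burst_duty must be in (0, 1]")
        if self.n_larvae < 0:
            raise InvalidParameterError("n_larvae must be >= 0")

    @property
    def n_active(self) -> int:
        return int(round(self.active_fraction * self.n_larvae))


@dataclass(frozen=True)
class NoiseModel:
    """White logger noise plus a slow drift below the 0.2 Hz analysis edge."""

    white_sd: float = 2e-6
    drift_amplitude: float = 0.0
    drift_frequency: float = 0.05

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise InvalidParameterError("white_sd must be >= 0")
        if not 0 <= self.drift_frequency < 0.2:
            raise InvalidParameterError("drift_frequency must lie below 0.2 Hz")
        if self.drift_amplitude < 0:
            raise InvalidParameterError("drift_amplitude must be >= 0")


QUIET = NoiseModel(white_sd=0.0, drift_amplitude=0.0)


def _larva_seed_sequences(seed: int, n_larvae: int) -> list[np.random.SeedSequence]:
    return [np.random.SeedSequence(seed, spawn_key=(i,)) for i in range(n_larvae)]


def _burst_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    frequency: float,
    duty: float,
    amplitude: float,
    phase_jitter: float,
) -> np.ndarray:
    """One larva's gated-oscillator signal: Hann-enveloped sine packets."""
    out = np.zeros(n)
    t_total = n / fs
    mean_cycles = _BURST_MIN_CYCLES + 1.0 / _BURST_GEOM_P
    mean_burst = mean_cycles / frequency
    mean_gap = mean_burst * (1.0 / duty - 1.0)
    # random initial offset so larvae are unsynchronised from t = 0
    pos = rng.uniform(0.0, mean_burst + mean_gap)
    while pos < t_total:
        n_cycles = _BURST_MIN_CYCLES + rng.geometric(_BURST_GEOM_P)
        burst_dur = n_cycles / frequency
        phase = phase_jitter * rng.uniform(0.0, 2 * np.pi)
        i0 = int(np.ceil(pos * fs))
        i1 = min(int((pos + burst_dur) * fs), n)
        if i1 > i0:
            tt = np.arange(i0, i1) / fs - pos
            envelope = 0.5 * (1.0 - np.cos(2 * np.pi * tt / burst_dur))
            out[i0:i1] += amplitude * envelope * np.sin(2 * np.pi * frequency * tt + phase)
        gap = rng.exponential(mean_gap) if mean_gap > 0 else 0.0
        pos += burst_dur + gap
    return out


def larva_component(config: RecordingConfig, motion: LarvaMotionSpec, index: int) -> np.ndarray:
    """Signal contributed by larva ``index`` (zero array if it is inactive).

    Components are generated from independent substreams of the recording
    seed, so the full recording's signal part is exactly the sum of its
    components (superposition).
    """
    if not 0 <= index < motion.n_larvae:
        raise InvalidParameterError(f"larva index {index} out of range")
    n = int(round(config.duration * config.sampling_rate))
    if index >= motion.n_active:
        return np.zeros(n)
    rng = np.random.default_rng(_larva_seed_sequences(config.seed, motion.n_larvae)[index])
    return _burst_train(
        rng,
        n,
        config.sampling_rate,
        motion.motion_frequency,
        motion.burst_duty,
        motion.per_larva_amplitude,
        motion.phase_jitter,
    )


def noise_component(config: RecordingConfig, noise: NoiseModel) -> np.ndarray:
    """Instrument noise drawn from its own substream (independent of larvae)."""
    n = int(round(config.duration * config.sampling_rate))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2**16,)))
    out = rng.normal(0.0, noise.white_sd, n) if noise.white_sd > 0 else np.zeros(n)
    if noise.drift_amplitude > 0:
        t = np.arange(n) / config.sampling_rate
        phase = rng.uniform(0.0, 2 * np.pi)
        out += noise.drift_amplitude * np.sin(2 * np.pi * noise.drift_frequency * t + phase)
    return out


def generate_recording(
    config: RecordingConfig,
    motion: LarvaMotionSpec | None = None,
    noise: NoiseModel | None = None,
) -> Waveform:
    """Synthesize one larval voltage recording.

    The signal is the superposition of the active larvae's burst trains plus
    instrument noise; the generating parameters are recorded in the waveform
    metadata for parameter-recovery tests.
    """
    motion = motion if motion is not None else LarvaMotionSpec()
    noise = noise if noise is not None else NoiseModel()
    n = int(round(config.duration * config.sampling_rate))
    signal = np.zeros(n)
    for i in range(motion.n_active):
        signal += larva_component(config, motion, i)
    samples = signal + noise_component(config, noise)
    meta = {
        "kind": "larvae" if motion.n_active else "control",
        "seed": config.seed,
        "n_larvae": motion.n_larvae,
        "n_active": motion.n_active,
        "motion_frequency": motion.motion_frequency,
        "per_larva_amplitude": motion.per_larva_amplitude,
        "burst_duty": motion.burst_duty,
        "white_sd": noise.white_sd,
    }
    return Waveform(samples, config.sampling_rate, meta)


def generate_driven_recording(
    config: RecordingConfig,
    drive_frequency: float,
    amplitude: float,
    noise: NoiseModel | None = None,
) -> Waveform:
    """Constant-vibration-machine recording: one fixed-frequency tone plus noise."""
    noise = noise if noise is not None else NoiseModel()
    if not 0 < drive_frequency < config.sampling_rate / 2:
        raise InvalidParameterError(
            f"drive_frequency must lie in (0, Nyquist={config.sampling_rate / 2} Hz)"
        )
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    samples = amplitude * np.sin(2 * np.pi * drive_frequency * t)
    samples = samples + noise_component(config, noise)
    meta = {
        "kind": "driven",
        "seed": config.seed,
        "drive_frequency": drive_frequency,
        "amplitude": amplitude,
        "white_sd": noise.white_sd,
    }
    return Waveform(samples, config.sampling_rate, meta)


@dataclass(frozen=True)
class ConditionResponse:
    """Phenomenological response curves: activity drivers vs. condition value.

    The defaults interpolate the qualitative anchors of the reference study:
    the temperature response vanishes at 10 and 50 degC and peaks at 30 degC
    with intermediate activity at 40 degC; the pH response vanishes at pH 2
    and 13 and peaks over pH 5--7, with a stronger acid than base shoulder.
    Curves are piecewise-linear through the grid anchors and fully
    overridable.
    """

    condition_name: str = "temperature"
    grid: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
    active_fraction_curve: tuple[float, ...] = (0.0, 0.5, 0.8, 0.3, 0.0)
    frequency_curve: tuple[float, ...] = (0.5, 1.5, 2.0, 1.2, 0.5)

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise InvalidParameterError("condition grid must be non-empty")
        if len(self.active_fraction_curve) != len(self.grid) or len(
            self.frequency_curve
        ) != len(self.grid):
            raise InvalidParameterError("response curves must match the grid length")
        if any(not 0 <= a <= 1 for a in self.active_fraction_curve):
            raise InvalidParameterError("active fractions must lie in [0, 1]")
        if any(f <= 0 for f in self.frequency_curve):
            raise InvalidParameterError("frequency curve must be positive")

    @classmethod
    def temperature_default(cls) -> "ConditionResponse":
        return cls()

    @classmethod
    def ph_default(cls) -> "ConditionResponse":
        return cls(
            condition_name="pH",
            grid=(2.0, 3.0, 5.0, 7.0, 9.0, 12.0, 13.0),
            active_fraction_curve=(0.0, 0.3, 0.8, 0.8, 0.4, 0.1, 0.0),
            frequency_curve=(0.5, 1.5, 2.0, 2.0, 1.5, 1.0, 0.5),
        )

    def motion_at(self, value: float, base: LarvaMotionSpec | None = None) -> LarvaMotionSpec:
        """Motion spec at an arbitrary condition value (linear interpolation)."""
        base = base if base is not None else LarvaMotionSpec()
        af = float(np.interp(value, self.grid, self.active_fraction_curve))
        freq = float(np.interp(value, self.grid, self.frequency_curve))
        return replace(base, active_fraction=af, motion_frequency=freq)


def generate_condition_series(
    config: RecordingConfig,
    response: ConditionResponse,
    replicates: int = 3,
    noise: NoiseModel | None = None,
    base_motion: LarvaMotionSpec | None = None,
) -> list[Waveform]:
    """One recording per (grid point, replicate), seeded deterministically.

    Replicate ``r`` of grid point ``g`` uses the substream with spawn key
    ``(g, r)`` of the top-level seed, so the full n = 3 experiment is
    reproducible and each recording is independent.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    out: list[Waveform] = []
    for gi, value in enumerate(response.grid):
        motion = response.motion_at(value, base_motion)
        for ri in range(replicates):
            sub_seed = int(
                np.random.SeedSequence(config.seed, spawn_key=(gi, ri)).generate_state(1)[0]
                & 0x7FFFFFFF
            )
            w = generate_recording(replace(config, seed=sub_seed), motion, noise)
            w.metadata.update(
                {
                    "condition_name": response.condition_name,
                    "condition_value": value,
                    "replicate": ri,
                }
            )
            out.append(w)
    return out


# ---------------------------------------------------------------------------
# frame-stack renderer (fixture source for the tracking stage)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameStackSpec:
    """Synthetic video of a single bending larva.

    The body is a horizontal capsule (rounded rectangle) whose vertical
    position oscillates sinusoidally; the outer (top) boundary therefore
    moves with known frequency and amplitude, which is stored as ground
    truth.  Dimensions mirror the real animal: ~2 mm long, ~0.2 mm wide,
    imaged at 30 fps.
    """

    frame_size: tuple[int, int] = (120, 320)  # rows, cols
    pixel_pitch: float = 10.0  # um / pixel
    fps: float = 30.0
    duration: float = 10.0
    bend_frequency: float = 2.0
    bend_amplitude: float = 150.0  # um
    larva_length: float = 2000.0  # um
    larva_width: float = 200.0  # um
    background_gray: int = 220
    larva_gray: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fps > 2 * self.bend_frequency:
            raise InvalidParameterError("fps must exceed twice the bend frequency (Nyquist)")
        rows, cols = self.frame_size
        if self.larva_length / self.pixel_pitch >= cols:
            raise InvalidParameterError("larva longer than the frame")
        extent = (self.larva_width / 2 + self.bend_amplitude) / self.pixel_pitch
        if extent >= rows / 2:
            raise InvalidParameterError("larva leaves the frame at maximal bend")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


def render_larva_frames(spec: FrameStackSpec) -> FrameStack:
    """Render the frame stack described by ``spec`` with ground truth attached.

    Ground truth metadata records, per frame, the y position (um, image row
    direction) of the top boundary of the body, which is what the tracker is
    expected to recover up to pixel quantisation.
    """
    rows, cols = spec.frame_size
    n = spec.n_frames
    t = np.arange(n) / spec.fps
    # capsule axis endpoints in pixel coordinates
    half_len_px = spec.larva_length / 2 / spec.pixel_pitch
    radius_px = spec.larva_width / 2 / spec.pixel_pitch
    cx = cols / 2
    y_mid = rows / 2
    y_c = y_mid + (spec.bend_amplitude / spec.pixel_pitch) * np.sin(
        2 * np.pi * spec.bend_frequency * t
    )
    yy, xx = np.mgrid[0:rows, 0:cols]
    frames = np.full((n, rows, cols), spec.background_gray, dtype=np.uint8)
    x0, x1 = cx - half_len_px + radius_px, cx + half_len_px - radius_px
    for k in range(n):
        # distance from pixel centre to capsule axis segment
        px = np.clip(xx + 0.5, x0, x1)
        dist2 = (xx + 0.5 - px) ** 2 + (yy + 0.5 - y_c[k]) ** 2
        frames[k][dist2 <= radius_px**2] = spec.larva_gray
    top_boundary_um = (y_c - radius_px) * spec.pixel_pitch
    meta = {
        "spec": spec,
        "truth_top_boundary_um": top_boundary_um,
        "truth_bend_frequency": spec.bend_frequency,
        "truth_bend_amplitude": spec.bend_amplitude,
        "truth_center_column": int(cx),
    }
    return FrameStack(frames=frames, fps=spec.fps, pixel_pitch=spec.pixel_pitch, metadata=meta)
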