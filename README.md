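# larvasense

Modeling and signal analysis for a biohybrid "living sensor": detecting the
vitality of anhydrobiotic chironomid larvae (*Polypedilum vanderplanki*)
from the voltage they induce on interdigital comb electrodes while moving in
water.

Dried larvae of this species survive extreme environments and revive on
rehydration. Because a revived larva carries a natural negative surface
charge (zeta potential ~ −21 mV), its 1–2 Hz bend–stretch motion over a
comb-electrode array modulates the electrostatically induced charge and
produces a measurable voltage — a power-free readout of whether the local
environment (temperature, pH, water) supports life. This package implements
the computational chain of that experiment for anyone who wants to study,
extend or re-analyze it:

- **`larvasense.synthetic`** — a seeded generator for every input the bench
  produces: larval recordings (superposed burst oscillators plus logger
  noise), machine-driven constant-frequency recordings, no-larvae controls,
  temperature/pH condition series, and rendered video frame stacks of a
  bending larva with ground truth.
- **`larvasense.electrostatics`** — a quasi-static 2D finite-difference
  model of the device: a charged rectangular body (length oscillating
  80–600 µm at 2 Hz, surface potential −21 mV) moving 10 µm above
  80 µm-wide grounded comb teeth with 20 µm gaps in water, yielding the
  induced open-circuit voltage waveform, the Ohmic current through the
  150 Ω device resistance and the generated power.
- **`larvasense.pipeline`** — the measurement analysis: 10 s segmentation,
  200-point centred moving average, Hamming-window 4096-point amplitude
  spectra, 0.2–4 Hz band limiting, and the **activity index**

  *A* = ∫₀.₂⁴ |V̂(f)| df  (V·Hz),

  the integral of the band-limited FFT amplitude, plus dominant-peak
  detection of the motion frequency.
- **`larvasense.stats`** — per-condition mean ± SEM (n = 3) and two-sided
  pooled Student's *t*-tests against the inactive control
  (\* p < 0.05, \*\* p < 0.01).
- **`larvasense.tracking`** — Otsu binarization of frame stacks and
  displacement tracing of the larva's outer body line, with frequency
  recovery through the same spectral machinery.
- **`larvasense.config` / `larvasense.cli`** — one YAML config holding every
  protocol constant, and a `larvasense` command with `generate`, `simulate`,
  `analyze`, `stats`, `track` and `demo` subcommands.

## Worked example

```python
from larvasense import synthetic as syn, pipeline as pl

cfg = syn.RecordingConfig(duration=60.0, seed=1)   # 60 s at 1 kHz
rec = syn.generate_recording(cfg)                  # 8 of 10 larvae active at 2 Hz
res = pl.analyze_recording(rec)
print(res["peak_frequency"], res["activity"].value)
```

prints `1.953125 5.26e-06`: the dominant in-band peak sits at 1.953 Hz (the
spectral bin closest to the 2 Hz motion, resolution 1000/4096 ≈ 0.244 Hz)
and the activity is ≈ 5.3×10⁻⁶ V·Hz — about 31× the no-larvae control under
the same noise model, which is how the device separates "alive" from
"nothing there".

The analysis is organised as numbered drivers over the library:

```sh
python analysis/01_simulate_power.py      # forward model + convergence table
python analysis/02_generate_recordings.py # synthetic bench recordings
python analysis/03_spectral_readout.py    # spectra, peaks, activity
python analysis/04_condition_response.py  # temperature & pH profiles, t-tests
python analysis/05_track_motion.py        # video tracking vs ground truth
```

`04_condition_response.py` reproduces the qualitative sensing result:
activity peaks at 30 °C (20–40 °C significant vs the 10 °C control) and
within pH 5–7. `01_simulate_power.py` reports the simulated open-circuit
amplitude (≈ 3.5 mV at the default grid) and the current/power the device
resistance implies; see `docs/methods.md` for the readout model and its
relation to the measured 0.11 mV / 730 nA / 80 pW scale.

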