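# Methods

This note documents the models, the numerical choices and the limits of
what the package's synthetic experiments can show.

## 1. The physical system

A revived chironomid larva in water carries a negative surface (zeta)
potential, estimated at −21 mV from electrophoretic measurements on ground
dried larvae. When the larva performs its characteristic bend–stretch
motion (1–2 Hz) over an interdigital comb-electrode array (80 µm Ni teeth,
20 µm gaps, 60 teeth, SiO₂-passivated, in a water pool), the overlap
between the charged body and the electrodes changes, modulating the
electrostatically induced charge and hence the voltage read by a data
logger at 1 kHz. Vitality is quantified by the **activity index**: the
integral of the band-limited (0.2–4 Hz) FFT amplitude of that voltage.

## 2. Electrostatic forward model

**Geometry and discretisation.** The device cross-section is modelled in
2D: a 680 × 130 µm water window (relative permittivity 80) above the
electrode plane, mirror-symmetric about its left edge, containing 6.5
teeth (pitch 100 µm; the half tooth sits on the mirror plane). The larva
is a rectangle of height 100 µm whose extent oscillates triangularly
between 80 and 600 µm at 2 Hz (mean edge speed 2.08 mm/s), riding 10 µm
above the plane. The Laplace equation is solved with 5-point finite
differences on a uniform grid (default 2.5 µm; the 20 µm gap must be
resolved by ≥ 4 cells) and a direct sparse LU factorisation; the residual
is checked against a 10⁻⁸ relative tolerance. Boundary conditions:
Dirichlet on conductors (earthed teeth at 0 V, larva at its surface
potential, treating the body as an equipotential and excluding its
interior from the dielectric), zero-flux (Neumann) on the mirror plane,
the glass between teeth, the far side and the top. The 100 nm SiO₂ film
is ignored: in series with the 10 µm water gap it changes the coupling by
< 20 % and is far below the grid scale. Charges are obtained by summing
the discrete normal displacement flux over conductor faces, which makes
Gauss's law hold to solver precision (the induced charges on all earthed
conductors balance the larva's boundary charge exactly), and are scaled
by an out-of-plane depth (default 0.2 mm, the larval diameter).

**Readout model.** Two electrode conditions are implemented:

- `open` (default): the base comb is earthed and the counter comb floats,
  as seen by a high-impedance logger. By linearity the floating potential
  is V_c = −Q_lv / C_cc, where Q_lv is the counter-comb charge induced by
  the larva with the counter earthed and C_cc the counter-comb
  self-capacitance with the larva present. Device teeth outside the
  simulated window load the node with a stray capacitance
  (30 − n_window) · C_tooth, with C_tooth the per-tooth self-capacitance
  computed on the same grid without a larva. The reported waveform is the
  AC component of V_c(t); it fluctuates around 0 V as teeth are covered
  and uncovered, is linear in the surface potential, and is independent of
  the out-of-plane depth (depth cancels in the charge/capacitance ratio).
- `shorted`: both combs earthed; the counter-comb charge Q(t) is
  differentiated (central differences) and converted to a voltage across
  the 150 Ω load. This mode is used for charge bookkeeping and oracle
  tests. Its output is of order 10⁻¹⁰ V at the study parameters: ε₀-scale
  induced currents through 150 Ω cannot produce millivolts, which is why
  the open-circuit potential is the package's default observable for the
  millivolt-scale signals the device reports. The measured current is
  derived from the voltage amplitude via Ohm's law (0.11 mV / 150 Ω
  ≈ 730 nA; power = V·I ≈ 80 pW), exactly as done for the bench data.

**Convergence and accuracy.** Halving the grid from 5 to 2.5 µm changes
the cycle amplitude by ~4.5 %, and from 2.5 to 1.25 µm by ~2.2 %
(`analysis/01_simulate_power.py` prints the table). The solver reproduces
the parallel-plate capacitor field and the image-charge induced-charge
distribution to < 2 % on degenerate geometries.

**Known limitations.** The model is quasi-static and purely electrostatic:
no electrochemistry, double layers, ionic screening or 3D effects. At the
default parameters it yields an open-circuit amplitude of ≈ 3.5 mV — the
same order as, but about 4× above, the ~0.8 mV reported for the original
finite-element simulation (which itself sits ~7× above the bench measurement of 0.11 mV).
The gap is expected: the published description of the simulation readout
(current through 150 Ω) is not self-consistent at these scales, and real
measurements add stray loading (bus bars, wiring, logger input) that the
2D window cannot see. The claimed benefit of finer comb pitch does not
reproduce here either: at fixed tooth count the open-circuit amplitude
*grows* with pitch (3.3 / 3.5 / 4.9 mV for 40/10, 80/20, 160/40 µm), and
the short-circuit current is pitch-independent to first order at fixed
width/pitch ratio, so only same-order behaviour across geometries is
asserted.

## 3. Synthetic recordings

Each of the `n_larvae` (default 10) larvae is an intermittent gated
oscillator. Active larvae (default 8 of 10, the fraction observed at
30 °C) emit bursts: Hann-enveloped sine packets at the motion frequency
(default 2 Hz) whose length in cycles is 5 + Geometric(0.35) (mean ≈ 8),
separated by exponential gaps sized so that moving time matches
`burst_duty` (default 0.5), each with an independent uniform phase. Burst
lengths were chosen so that, noise-free, ≥ 99 % of signal power falls
within ±0.5 Hz of the carrier — the property that makes the group peak
identifiable — while keeping motion visibly intermittent. Per-larva
amplitude defaults to 0.11 mV / 8 so the coherent sum of the reference
condition matches the device-scale group amplitude.

Noise is white Gaussian (default SD 2 µV) plus an optional sinusoidal
drift below 0.2 Hz. The drift default is 0: at the pipeline's 0.244 Hz
resolution, any visible drift leaks through the Hamming main lobe into
the first in-band bin and would put a spurious peak in every control —
the band's high-pass edge cannot remove main-lobe leakage. The drift
field exists to emulate the low-frequency artifact background of real
loggers and is exercised in tests.

Determinism: the recording seed spawns independent substreams per larva
and for the noise (`SeedSequence` spawn keys), so a k-larva recording is
exactly the sample-wise sum of its per-larva components plus noise, and
condition series derive replicate seeds from (seed, grid index,
replicate index).

**Condition response curves** are phenomenological, piecewise-linear
through qualitative anchors: temperature active fraction
(0, 0.5, 0.8, 0.3, 0) and frequency (0.5, 1.5, 2.0, 1.2, 0.5) Hz over
(10, 20, 30, 40, 50) °C — zero at the extremes, maximal at 30 °C,
intermediate at 40 °C; pH active fraction (0, 0.3, 0.8, 0.8, 0.4, 0.1, 0)
over pH (2, 3, 5, 7, 9, 12, 13) — an optimum at pH 5–7 with a stronger
acid than base shoulder. They encode the observed pattern, not larval
physiology; no mechanistic water-uptake or vitrification model is
attempted, and the curves are config-overridable.

**Frame renderer.** The video fixture is a dark capsule (2 mm × 0.2 mm at
10 µm/pixel) on a bright background whose vertical position oscillates
sinusoidally at the bend frequency; the ground-truth top-boundary
trajectory is stored in the stack metadata. It emulates the binarizable
high-contrast geometry of the real video, not its texture, lighting or
non-rigid bending — so tracking tests certify pixel-level recovery of a
known trajectory, not robustness to real imaging conditions.

## 4. Measurement pipeline

Segments of 10 s (10 000 samples) are smoothed with a 200-point centred
moving average (shrunken windows at the edges avoid phase shift; the
choice of alignment is not dictated by the protocol). The moving average
has the Dirichlet-kernel response |sin(πfN/fs) / (N sin(πf/fs))|: gain
0.757 at 2 Hz, a null at 5 Hz — it passes the analysis band and
suppresses readout noise. By default the FFT is applied to the smoothed
signal; a `residual` mode (signal minus smoothing) is config-selectable
since the original protocol does not state which was transformed.

Each segment yields two consecutive 4096-sample frames (the trailing
1808 samples are unused; zero-padding is deliberately not applied since
the protocol states a plain 4096-point transform). Frames are Hamming
windowed; single-sided amplitudes are scaled by 2/N and divided by the
window's coherent gain (mean value ≈ 0.54) so a unit in-band sinusoid
reads ≈ 1, then averaged across frames and segments. Absolute units are
therefore defined, but every reference readout (peak locations, activity
ratios, significance patterns) is invariant to this normalisation.

The band filter keeps bins with 0.2 ≤ f ≤ 4 Hz (bins 1–16 at the default
resolution). Activity is the trapezoidal integral of amplitude over the
band, averaged over segments; the dominant peak is the global in-band
argmax with ties broken toward lower frequency (no peak-shape test —
small sub-peaks near 1 Hz are an accepted FFT artifact).

## 5. Statistics

Conditions are summarised as mean ± SEM (SD/√n, ddof = 1; a single
replicate reports SEM 0 with a warning) and compared against the inactive
control condition with a two-sided pooled equal-variance Student's t-test
(Welch's form available by flag; the protocol names Student's test but
states neither sidedness nor variance assumption). Stars: \* p < 0.05,
\*\* p < 0.01. No multiple-testing correction is applied, matching the
original per-condition-vs-control design — a caveat, since with several
conditions a ~5 % false-positive rate per comparison applies; in the
synthetic pH series the near-zero-variance inactive conditions can flag
"significant" micro-differences against the control for exactly this
reason.

## 6. Tracking

Frames are binarized with Otsu's threshold (polarity configurable; on
clean two-level renders the dark comparison is inclusive because Otsu
returns the foreground level). The "outer body line" is operationalised
as the topmost foreground pixel in a caller-chosen column — the protocol
traces a single boundary point without defining its selection, so the
column is an explicit input. Gap frames are linearly interpolated and
flagged. Track frequency reuses the amplitude-spectrum/dominant-peak
machinery at the frame rate with the largest power-of-two FFT length that
fits; a flat trace returns NaN with a `no_peak` flag.

## 7. Problem sizes and defaults

Synthetic experiments default to 60 s recordings at 1 kHz (6 segments,
12 averaged frames), n = 3 replicates per condition, and the forward
model to a 2.5 µm grid (273 × 53 nodes) with 64 quasi-static solves per
cycle — sizes chosen so every analysis and the full test suite run in
seconds to minutes on a single CPU while keeping the spectral resolution
and replicate structure of the original protocol.
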