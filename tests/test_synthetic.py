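"""Generator correctness: determinism, superposition, spectral placement."""

import numpy as np
import pytest

from larvasense import pipeline as pl
from larvasense import synthetic as syn
from larvasense.errors import InvalidParameterError


class TestGenerateRecording:
    def test_no_sources_no_noise_is_exactly_zero(self, quiet):
        cfg = syn.RecordingConfig(duration=5.0, seed=0)
        w = syn.generate_recording(cfg, syn.LarvaMotionSpec(active_fraction=0.0), quiet)
        assert w.n_samples == 5000
        assert np.all(w.samples == 0.0)

    def test_identical_seed_gives_bit_identical_output(self):
        cfg = syn.RecordingConfig(duration=10.0, seed=42)
        a = syn.generate_recording(cfg)
        b = syn.generate_recording(cfg)
        assert np.array_equal(a.samples, b.samples)
        c = syn.generate_recording(syn.RecordingConfig(duration=10.0, seed=43))
        assert not np.array_equal(a.samples, c.samples)

    def test_signal_scales_linearly_with_amplitude_noise_unchanged(self):
        cfg = syn.RecordingConfig(duration=10.0, seed=3)
        m1 = syn.LarvaMotionSpec()
        m2 = syn.LarvaMotionSpec(per_larva_amplitude=2 * m1.per_larva_amplitude)
        noise = syn.NoiseModel()
        w1 = syn.generate_recording(cfg, m1, noise)
        w2 = syn.generate_recording(cfg, m2, noise)
        n = syn.noise_component(cfg, noise)
        np.testing.assert_allclose(w2.samples - n, 2 * (w1.samples - n), atol=1e-18)

    def test_superposition_over_larvae(self, quiet):
        cfg = syn.RecordingConfig(duration=8.0, seed=7)
        motion = syn.LarvaMotionSpec(n_larvae=5, active_fraction=1.0)
        total = syn.generate_recording(cfg, motion, quiet)
        parts = sum(syn.larva_component(cfg, motion, i) for i in range(5))
        np.testing.assert_array_equal(total.samples, parts)

    def test_group_amplitude_matches_device_scale_and_band(self):
        # 8 of 10 larvae at ~0.11 mV summed amplitude: pipeline peak in 1-2 Hz
        cfg = syn.RecordingConfig(duration=60.0, seed=1)
        w = syn.generate_recording(cfg)
        assert w.metadata["n_active"] == 8
        peak = pl.analyze_recording(w)["peak_frequency"]
        assert 1.0 <= peak <= 2.0 + 1000 / 4096

    @pytest.mark.parametrize("bad", [dict(duration=0.0), dict(duration=-1.0)])
    def test_invalid_duration_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            syn.RecordingConfig(seed=0, **bad)

    def test_invalid_motion_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.LarvaMotionSpec(active_fraction=1.5)
        with pytest.raises(InvalidParameterError):
            syn.LarvaMotionSpec(motion_frequency=0.0)
        with pytest.raises(InvalidParameterError):
            syn.NoiseModel(drift_frequency=0.3)


class TestSpectralPlacement:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_99pct_power_within_half_hz_of_carrier(self, seed, quiet):
        cfg = syn.RecordingConfig(duration=120.0, seed=seed)
        motion = syn.LarvaMotionSpec(n_larvae=1, active_fraction=1.0)
        sig = syn.generate_recording(cfg, motion, quiet).samples
        freqs = np.fft.rfftfreq(sig.size, 1e-3)
        power = np.abs(np.fft.rfft(sig)) ** 2
        inband = (freqs >= 1.5) & (freqs <= 2.5)
        assert power[inband].sum() / power.sum() >= 0.99

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_control_has_no_spurious_in_band_peak(self, seed):
        cfg = syn.RecordingConfig(duration=60.0, seed=seed)
        ctrl = syn.generate_recording(cfg, syn.LarvaMotionSpec(active_fraction=0.0))
        spec = pl.analyze_recording(ctrl)["spectrum"]
        assert spec.amplitudes.max() <= 3 * np.median(spec.amplitudes)


class TestDrivenRecording:
    def test_pure_tone_autocorrelation_period(self, quiet):
        cfg = syn.RecordingConfig(duration=12.0, seed=0)
        w = syn.generate_driven_recording(cfg, 3.0, 1e-4, quiet)
        x = w.samples
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        # first local maximum after the zero-lag peak sits one period away
        trough = int(np.argmin(ac[: int(0.5 * 1000)]))
        period = trough + int(np.argmax(ac[trough : int(0.6 * 1000)]))
        assert abs(period - 1000 / 3) <= 1.0

    def test_band_rms_of_sinusoid(self, quiet):
        amp = 2.5e-4
        cfg = syn.RecordingConfig(duration=10.0, seed=0)  # integer cycle count
        w = syn.generate_driven_recording(cfg, 2.0, amp, quiet)
        np.testing.assert_allclose(np.sqrt(np.mean(w.samples**2)), amp / np.sqrt(2), rtol=1e-6)

    def test_drive_at_or_above_nyquist_rejected(self, quiet):
        cfg = syn.RecordingConfig(duration=1.0, seed=0)
        with pytest.raises(InvalidParameterError):
            syn.generate_driven_recording(cfg, 500.0, 1e-4, quiet)
        with pytest.raises(InvalidParameterError):
            syn.generate_driven_recording(cfg, 0.0, 1e-4, quiet)


class TestConditionSeries:
    def test_grid_replicate_layout_and_inactive_control(self):
        cfg = syn.RecordingConfig(duration=1.0, seed=5)
        resp = syn.ConditionResponse.temperature_default()
        waves = syn.generate_condition_series(cfg, resp, replicates=3)
        assert len(waves) == 15
        cold = [w for w in waves if w.metadata["condition_value"] == 10.0]
        assert all(w.metadata["n_active"] == 0 for w in cold)

    def test_ph_grid_has_seven_conditions(self):
        cfg = syn.RecordingConfig(duration=1.0, seed=5)
        waves = syn.generate_condition_series(cfg, syn.ConditionResponse.ph_default(), 1)
        assert sorted({w.metadata["condition_value"] for w in waves}) == [
            2.0, 3.0, 5.0, 7.0, 9.0, 12.0, 13.0,
        ]
        assert len(waves) == 7

    def test_single_point_single_replicate(self):
        cfg = syn.RecordingConfig(duration=1.0, seed=5)
        resp = syn.ConditionResponse(
            grid=(30.0,), active_fraction_curve=(0.8,), frequency_curve=(2.0,)
        )
        assert len(syn.generate_condition_series(cfg, resp, replicates=1)) == 1

    def test_replicates_are_independent_but_reproducible(self):
        cfg = syn.RecordingConfig(duration=2.0, seed=5)
        resp = syn.ConditionResponse.temperature_default()
        a = syn.generate_condition_series(cfg, resp, replicates=2)
        b = syn.generate_condition_series(cfg, resp, replicates=2)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.samples, wb.samples)
        active = [w for w in a if w.metadata["n_active"] > 0]
        assert not np.array_equal(active[0].samples, active[1].samples)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.ConditionResponse(grid=(), active_fraction_curve=(), frequency_curve=())
        cfg = syn.RecordingConfig(duration=1.0, seed=0)
        with pytest.raises(InvalidParameterError):
            syn.generate_condition_series(
                cfg, syn.ConditionResponse.temperature_default(), replicates=0
            )


class TestFrameRenderer:
    def test_zero_bend_gives_identical_frames(self):
        stack = syn.render_larva_frames(syn.FrameStackSpec(bend_amplitude=0.0, duration=2.0))
        assert np.all(stack.frames == stack.frames[0])

    def test_frame_count_and_truth_excursion(self):
        spec = syn.FrameStackSpec()  # 2 Hz at 30 fps for 10 s
        stack = syn.render_larva_frames(spec)
        assert stack.n_frames == 300
        truth = np.asarray(stack.metadata["truth_top_boundary_um"])
        # 30 fps sampling of a 2 Hz sine misses the exact crest by < 2.5%
        excursion = (truth.max() - truth.min()) / 2
        np.testing.assert_allclose(excursion, spec.bend_amplitude, rtol=0.025)

    def test_larva_exceeding_frame_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.FrameStackSpec(bend_amplitude=600.0)
        with pytest.raises(InvalidParameterError):
            syn.FrameStackSpec(larva_length=4000.0)
        with pytest.raises(InvalidParameterError):
            syn.FrameStackSpec(bend_frequency=20.0)  # Nyquist at 30 fps
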