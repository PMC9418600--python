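"""FD solver vs. closed-form oracles, charge bookkeeping, cycle invariants."""

from dataclasses import replace

import numpy as np
import pytest

from larvasense import electrostatics as es
from larvasense.errors import InvalidParameterError


def _full_bottom_comb(width: float) -> es.CombGeometry:
    """Single electrode covering the whole bottom boundary (plate oracle)."""
    return es.CombGeometry(tooth_width=2 * width, gap_width=40.0, n_teeth=2)


class TestKinematics:
    def test_triangular_edge_speed_identity(self):
        kin = es.MotionKinematics(cycle_frequency=2.0)
        larva = es.LarvaBody(length_min=80.0, length_max=600.0)
        assert kin.edge_speed_mm_s(larva) == pytest.approx(2.08, abs=1e-12)

    def test_extent_spans_the_length_range(self):
        kin = es.MotionKinematics()
        larva = es.LarvaBody()
        t = np.linspace(0.0, 1.0, 2001)
        ext = kin.extent_at(t, larva)
        assert ext.min() == pytest.approx(80.0)
        assert ext.max() == pytest.approx(600.0)


class TestSolverOracles:
    def test_no_larva_potential_identically_zero(self):
        f = es.solve_potential(es.SimDomain(), es.CombGeometry(), None, 0.0)
        assert np.all(f.phi == 0.0)

    def test_parallel_plate_interior_is_linear(self):
        # slab spanning the full width over a full-bottom electrode: 1D capacitor
        domain = es.SimDomain(width=400.0, height=130.0, grid_spacing=2.5, symmetry=False)
        larva = es.LarvaBody(length_min=80.0, length_max=2000.0, clearance=30.0)
        f = es.solve_potential(domain, _full_bottom_comb(400.0), larva, 400.0, larva_x0=200.0)
        rows = np.arange(13)  # y = 0 .. 30 um
        expected = -21e-3 * rows * 2.5 / 30.0
        err = np.abs(f.phi[rows, 80] - expected).max() / 21e-3
        assert err < 0.02

    def test_image_charge_total_and_profile(self):
        # small square far above a wide grounded plane ~ 2D line charge image
        width, a = 6000.0, 200.0
        domain = es.SimDomain(width=width, height=1600.0, grid_spacing=10.0, symmetry=False)
        comb = _full_bottom_comb(width)
        body = es.LarvaBody(length_min=10.0, length_max=30.0, height=20.0, clearance=190.0)
        f = es.solve_potential(domain, comb, body, 20.0, larva_x0=width / 2)
        q_plane = es.induced_charge(f, comb, 0)
        q_body = es.conductor_charge(f, f.larva_mask)
        assert -q_plane / q_body == pytest.approx(1.0, rel=0.02)
        sigma = -f.phi[1, :] / 10.0  # proportional to induced surface density
        xs = np.arange(f.phi.shape[1]) * 10.0
        for x_lim in (2 * a, 3 * a):
            numeric = sigma[np.abs(xs - width / 2) <= x_lim].sum() / sigma.sum()
            analytic = (2 / np.pi) * np.arctan(x_lim / a)
            assert numeric == pytest.approx(analytic, rel=0.02)

    def test_potential_linear_in_surface_potential(self):
        domain = es.SimDomain(grid_spacing=5.0)
        comb = es.CombGeometry()
        f1 = es.solve_potential(domain, comb, es.LarvaBody(), 400.0)
        f2 = es.solve_potential(
            domain, comb, es.LarvaBody(surface_potential=-42e-3), 400.0
        )
        np.testing.assert_allclose(f2.phi, 2 * f1.phi, atol=1e-15)

    def test_translation_by_one_pitch_preserves_tooth_charge(self):
        domain = es.SimDomain(width=1500.0, height=130.0, grid_spacing=2.5, symmetry=False)
        comb = es.CombGeometry()
        larva = es.LarvaBody()
        fa = es.solve_potential(domain, comb, larva, 300.0, larva_x0=700.0)
        fb = es.solve_potential(domain, comb, larva, 300.0, larva_x0=900.0)
        qa = es.induced_charge(fa, comb, 7)
        qb = es.induced_charge(fb, comb, 9)
        assert qb == pytest.approx(qa, rel=1e-9)

    def test_gauss_bookkeeping_teeth_balance_larva(self):
        f = es.solve_potential(es.SimDomain(), es.CombGeometry(), es.LarvaBody(), 400.0)
        q_teeth = sum(es.induced_charge(f, es.CombGeometry(), i) for i in range(len(f.tooth_masks)))
        q_larva = es.conductor_charge(f, f.larva_mask)
        assert abs(q_teeth + q_larva) <= 0.05 * abs(q_larva)

    def test_electrode_id_out_of_range(self):
        f = es.solve_potential(es.SimDomain(), es.CombGeometry(), None, 0.0)
        with pytest.raises(InvalidParameterError):
            es.induced_charge(f, es.CombGeometry(), 99)


class TestSimulateCycle:
    def test_zero_surface_potential_gives_zero_output(self, coarse_sim):
        parts = dict(coarse_sim)
        parts["larva"] = replace(parts["larva"], surface_potential=0.0)
        w = es.simulate_cycle(n_steps=24, **parts)
        assert np.allclose(w.samples, 0.0, atol=1e-18)

    def test_stationary_larva_gives_no_signal(self, coarse_sim):
        parts = dict(coarse_sim)
        parts["larva"] = replace(parts["larva"], length_min=300.0, length_max=300.0)
        w_open = es.simulate_cycle(n_steps=24, **parts)
        assert np.allclose(w_open.samples, 0.0, atol=1e-15)
        w_short = es.simulate_cycle(n_steps=24, mode="shorted", **parts)
        assert np.allclose(w_short.samples[1:], 0.0, atol=1e-20)

    def test_amplitude_linear_in_surface_potential(self, coarse_sim):
        base = es.waveform_amplitude(es.simulate_cycle(n_steps=24, **coarse_sim))
        for factor in (2.0, 0.5):
            parts = dict(coarse_sim)
            parts["larva"] = replace(
                parts["larva"], surface_potential=factor * parts["larva"].surface_potential
            )
            amp = es.waveform_amplitude(es.simulate_cycle(n_steps=24, **parts))
            assert amp == pytest.approx(factor * base, rel=1e-9)

    def test_output_fluctuates_around_zero(self, coarse_sim):
        w = es.simulate_cycle(n_steps=24, **coarse_sim)
        assert abs(w.samples.mean()) <= 1e-9 * es.waveform_amplitude(w)

    def test_grid_convergence_within_10pct(self, coarse_sim):
        amps = {}
        for h in (5.0, 2.5):
            parts = dict(coarse_sim)
            parts["domain"] = replace(parts["domain"], grid_spacing=h)
            amps[h] = es.waveform_amplitude(es.simulate_cycle(n_steps=24, **parts))
        assert abs(amps[2.5] - amps[5.0]) / amps[2.5] < 0.10

    def test_unresolved_gap_rejected(self, coarse_sim):
        parts = dict(coarse_sim)
        parts["domain"] = replace(parts["domain"], grid_spacing=10.0)
        with pytest.raises(InvalidParameterError):
            es.simulate_cycle(n_steps=24, **parts)

    def test_alternate_comb_pitches_stay_same_order(self, coarse_sim):
        ref = es.waveform_amplitude(es.simulate_cycle(n_steps=24, **coarse_sim))
        for tw, gw in ((40.0, 10.0), (160.0, 40.0)):
            parts = dict(coarse_sim)
            parts["comb"] = es.CombGeometry(tooth_width=tw, gap_width=gw)
            parts["domain"] = replace(parts["domain"], grid_spacing=2.5 if gw == 10.0 else 5.0)
            amp = es.waveform_amplitude(es.simulate_cycle(n_steps=24, **parts))
            assert ref / 10 < amp < ref * 10

    def test_too_few_steps_rejected(self, coarse_sim):
        with pytest.raises(InvalidParameterError):
            es.simulate_cycle(n_steps=10, **coarse_sim)


class TestCircuitArithmetic:
    def test_measured_amplitude_gives_reported_current(self):
        current = es.ohmic_current(0.11e-3, es.Circuit(load_resistance=150.0))
        assert current == pytest.approx(733e-9, rel=1e-3)
        assert current == pytest.approx(730e-9, rel=0.01)  # printed, rounded

    def test_simulated_amplitude_current(self):
        assert es.ohmic_current(0.8e-3, es.Circuit()) == pytest.approx(5.33e-6, rel=1e-3)
        assert es.ohmic_current(0.0, es.Circuit()) == 0.0

    def test_power_worked_example(self):
        power = es.electrical_power(0.11e-3, 730e-9)
        assert power == pytest.approx(8.03e-11, rel=1e-3)  # ~80 pW
        assert es.electrical_power(0.0, 1.0) == 0.0

    def test_power_bilinearity(self):
        base = es.electrical_power(1e-4, 1e-7)
        assert es.electrical_power(3e-4, 3e-7) == pytest.approx(9 * base)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            es.ohmic_current(-1.0, es.Circuit())
        with pytest.raises(InvalidParameterError):
            es.electrical_power(-1.0, 1.0)
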