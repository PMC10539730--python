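"""Tests of the spatially encoded ultra-fast Z experiment simulator."""

import dataclasses
import json
import math

import numpy as np
import pytest

import xecest as x
from conftest import make_mixture_ufz


class TestDensityProfile:
    def test_edges_vanish_and_center_peaks(self, tube):
        rho = x.density_profile(tube, 257)
        assert rho.intensity[0] == pytest.approx(0.0, abs=1e-12)
        assert rho.intensity[-1] == pytest.approx(0.0, abs=1e-12)
        assert np.argmax(rho.intensity) == 128

    def test_chord_shape_ratio(self, tube):
        # rho(0)/rho(d/4) = 1/sqrt(1 - 1/4) = 2/sqrt(3)
        rho = x.density_profile(tube, 1025)
        quarter = np.argmin(np.abs(rho.axis - tube.inner_diameter_m / 4))
        ratio = rho.intensity[512] / rho.intensity[quarter]
        assert ratio == pytest.approx(2 / math.sqrt(3), rel=1e-3)

    def test_integral_matches_quadrature(self, tube):
        # closed form: integral of sqrt(h^2-x^2)/h over [-h, h] is pi h / 2
        rho = x.density_profile(tube, 4097)
        h = tube.inner_diameter_m / 2
        assert np.trapezoid(rho.intensity, rho.axis) == pytest.approx(
            math.pi * h / 2, rel=1e-4
        )


class TestLocalOffset:
    def test_center_unchanged(self, field_1t, benchtop_gradients):
        assert x.local_offset(0.0, 47.0, benchtop_gradients, field_1t) == 47.0

    def test_gradient_sign_mirrors_mapping(self, field_1t, benchtop_gradients):
        flipped = x.GradientScheme(-benchtop_gradients.g_sat, benchtop_gradients.g_acq)
        a = x.local_offset(1e-3, 47.0, benchtop_gradients, field_1t)
        b = x.local_offset(-1e-3, 47.0, flipped, field_1t)
        assert a == pytest.approx(b)

    def test_pool_on_resonance_at_dip_position(self, field_1t, benchtop_gradients):
        x_b = x.dip_position(47.0, 52.0, benchtop_gradients, field_1t)
        eff = x.local_offset(x_b, 47.0, benchtop_gradients, field_1t)
        assert eff == pytest.approx(52.0, rel=1e-12)


class TestSimulateProfiles:
    def test_no_rf_no_relaxation_gives_identical_profiles(self, field_1t):
        system = x.ExchangeSystem(
            field_1t, x.FreePool(196, 0.0, 20),
            (x.BoundPool(f=0.04, k_out=50, delta_ppm=52),),
        )
        exp = make_mixture_ufz(system, omega1=0.0, t_sat=3.0, off_scale=2.0)
        on, off = x.simulate_profiles(exp)
        assert np.allclose(on.intensity, off.intensity / 2.0)

    def test_two_dips_inside_envelope(self, mixture_system):
        exp = make_mixture_ufz(mixture_system)
        on, off = x.simulate_profiles(exp)
        centers = x.ufz_dip_centers(on, off, exp.gradients, mixture_system.field, 2)
        assert len(centers) == 2

    def test_negated_gradient_mirrors_dips(self, mixture_system):
        exp = make_mixture_ufz(mixture_system)
        neg = dataclasses.replace(
            exp, gradients=x.GradientScheme(-exp.gradients.g_sat, exp.gradients.g_acq)
        )
        on_p, off_p = x.simulate_profiles(exp)
        on_n, off_n = x.simulate_profiles(neg)
        # saturation pattern mirrored about the tube center
        assert np.allclose(on_n.intensity, on_p.intensity[::-1], atol=1e-12)

    def test_fixed_seed_is_bit_reproducible(self, mixture_system):
        exp = make_mixture_ufz(mixture_system, noise_sigma=0.02, seed=7)
        on1, off1 = x.simulate_profiles(exp)
        on2, off2 = x.simulate_profiles(exp)
        assert np.array_equal(on1.intensity, on2.intensity)
        assert np.array_equal(off1.intensity, off2.intensity)

    def test_off_integral_dominates_on_integral(self, mixture_system):
        exp = make_mixture_ufz(mixture_system)
        on, off = x.simulate_profiles(exp)
        assert np.trapezoid(off.intensity, off.axis) > np.trapezoid(
            on.intensity, on.axis
        )


class TestAcquireUfz:
    def test_equal_traces_give_zero_spectrum(self, tube, field_1t, benchtop_gradients):
        rho = x.density_profile(tube, 128)
        ufz = x.acquire_ufz(rho, rho, benchtop_gradients, field_1t)
        assert np.allclose(ufz.intensity, 0.0)
        assert ufz.kind == x.AxisKind.APPARENT_PPM

    def test_apparent_width_is_gamma_gacq_r(self, tube, field_1t, benchtop_gradients):
        rho = x.density_profile(tube, 128)
        ufz = x.acquire_ufz(rho, rho, benchtop_gradients, field_1t)
        width_hz = field_1t.gamma_bar_hz_t * abs(benchtop_gradients.g_acq) * tube.r_m
        expected_ppm = width_hz / field_1t.larmor_mhz
        assert abs(ufz.axis[-1] - ufz.axis[0]) == pytest.approx(expected_ppm)

    def test_axis_mismatch_raises(self, tube, field_1t, benchtop_gradients):
        a = x.density_profile(tube, 128)
        b = x.density_profile(tube, 64)
        with pytest.raises(ValueError):
            x.acquire_ufz(a, b, benchtop_gradients, field_1t)

    def test_ten_ppm_splitting_magnified_fourfold(self, mixture_system):
        exp = make_mixture_ufz(mixture_system)
        on, off = x.simulate_profiles(exp)
        centers = x.ufz_dip_centers(on, off, exp.gradients, mixture_system.field, 2)
        assert abs(centers[1] - centers[0]) == pytest.approx(40.0, abs=0.7)

    def test_gradient_sign_symmetries_of_spectrum(self, mixture_system):
        exp = make_mixture_ufz(mixture_system)
        on, off = x.simulate_profiles(exp)
        base = x.acquire_ufz(on, off, exp.gradients, mixture_system.field)

        both = x.GradientScheme(-exp.gradients.g_sat, -exp.gradients.g_acq)
        exp_b = dataclasses.replace(exp, gradients=both)
        on_b, off_b = x.simulate_profiles(exp_b)
        ufz_b = x.acquire_ufz(on_b, off_b, both, mixture_system.field)
        # negating both gradients leaves the spectrum invariant (the stored
        # arrays come out reversed because the position grid is symmetric)
        assert np.allclose(ufz_b.axis[::-1], base.axis, atol=1e-15)
        assert np.allclose(ufz_b.intensity[::-1], base.intensity, atol=1e-12)

        one = x.GradientScheme(exp.gradients.g_sat, -exp.gradients.g_acq)
        on_o, off_o = x.simulate_profiles(exp)
        ufz_o = x.acquire_ufz(on_o, off_o, one, mixture_system.field)
        # negating exactly one gradient mirrors the spectrum about zero
        assert np.allclose(ufz_o.axis, -base.axis)
        assert np.allclose(ufz_o.intensity, base.intensity)


class TestApparentSplitting:
    def test_benchtop_gradient_pair(self, benchtop_gradients):
        assert x.apparent_splitting(52, 42, benchtop_gradients) == pytest.approx(40.0)

    def test_highfield_gradient_pair(self):
        grads = x.GradientScheme(g_sat=0.035, g_acq=0.090)
        predicted = x.apparent_splitting(52, 42, grads)
        assert predicted == pytest.approx(25.714, rel=1e-3)
        assert abs(predicted - 25.4) / 25.4 < 0.05  # matches the measured value

    def test_unit_ratio_is_identity(self):
        grads = x.GradientScheme(g_sat=0.05, g_acq=0.05)
        assert x.apparent_splitting(52, 42, grads) == pytest.approx(10.0)

    def test_zero_gsat_raises(self):
        grads = x.GradientScheme(g_sat=0.0, g_acq=0.084)
        with pytest.raises(ZeroDivisionError):
            x.apparent_splitting(52, 42, grads)


class TestEnvelopeExit:
    def test_on_resonance_dip_is_central(self, tube, field_1t):
        assert not x.envelope_exit_check(52.0, 52.0, 0.021, tube, field_1t)

    def test_boundary_condition(self, tube, field_1t):
        # rf-to-pool distance exactly gamma |Gsat| r / 2: inside (strict)
        g_sat = 0.021
        dnu = field_1t.gamma_bar_hz_t * g_sat * tube.r_m / 2
        delta = dnu / field_1t.larmor_mhz
        assert not x.envelope_exit_check(52.0, 52.0 - 0.999 * delta, g_sat, tube, field_1t)
        assert x.envelope_exit_check(52.0, 52.0 - 1.001 * delta, g_sat, tube, field_1t)

    def test_benchtop_mixture_both_dips_visible(self, tube, field_1t):
        # rf on one cage, second cage 10 ppm away, Gsat = 21 mT/m
        assert not x.envelope_exit_check(52.0, 52.0, 0.021, tube, field_1t)
        assert not x.envelope_exit_check(52.0, 42.0, 0.021, tube, field_1t)


class TestMakeFixtures:
    def test_writes_replicates_and_truth(self, tmp_path, mixture_system):
        exp = make_mixture_ufz(mixture_system, noise_sigma=0.02)
        x.make_fixtures(tmp_path / "fx", exp, n_replicates=3, seed=11)
        files = sorted(p.name for p in (tmp_path / "fx").iterdir())
        assert "truth.json" in files
        assert sum(f.endswith("_on.csv") for f in files) == 3
        truth = json.loads((tmp_path / "fx" / "truth.json").read_text())
        assert truth["seeds"] == [11, 12, 13]
        assert truth["pools"][0]["k_out_s"] == 50
        trace = x.read_trace(tmp_path / "fx" / "rep000_on.csv")
        assert len(trace) == exp.n_positions
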