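"""Closed-form beam-on-foundation mechanics against a numeric oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microbeam import (
    BeamGeometry,
    DomainError,
    buckling_threshold_modulus,
    buckling_wavelength,
    critical_buckling_force,
    critical_buckling_stress,
    critical_force_curve,
    minimize_force_curve,
    modulus_from_buckling,
    second_moment,
)

I_100UM = second_moment(100e-6)


class TestSecondMoment:
    @pytest.mark.parametrize("R, expected", [
        (1.0, math.pi / 4.0),
        (0.0, 0.0),
        (100e-6, math.pi * 1e-16 / 4.0),
    ])
    def test_values(self, R, expected):
        assert second_moment(R) == pytest.approx(expected, rel=1e-12)

    def test_quartic_scaling(self, rng):
        for R in rng.uniform(1e-6, 1e-3, 10):
            assert second_moment(2 * R) / second_moment(R) == pytest.approx(16.0)

    def test_negative_radius_rejected(self):
        with pytest.raises(DomainError):
            second_moment(-1.0)


class TestBucklingWavelength:
    def test_unit_arguments(self):
        assert buckling_wavelength(1, 1, 1) == pytest.approx(2 * math.pi)

    def test_doubling_modulus_is_19_percent(self):
        lam1 = buckling_wavelength(1.0, 1e-16, 1.0)
        lam2 = buckling_wavelength(2.0, 1e-16, 1.0)
        assert lam2 / lam1 == pytest.approx(2 ** 0.25)
        assert lam2 / lam1 - 1 == pytest.approx(0.1892, abs=5e-4)

    def test_soft_beam_in_microgel(self):
        # E = 0.035 Pa, R = 100 um, G' = 1.92 Pa: lambda ~ 217 um
        lam = buckling_wavelength(0.035, I_100UM, 1.92)
        assert lam == pytest.approx(2.17e-4, rel=2e-3)
        # the numeric minimiser of the force curve selects the same wavelength
        lam_num, _ = minimize_force_curve(0.035, I_100UM, 1.92)
        assert lam_num == pytest.approx(lam, rel=1e-6)

    def test_scaling_in_each_argument(self):
        lam = buckling_wavelength(1.0, I_100UM, 1.0)
        assert buckling_wavelength(16.0, I_100UM, 1.0) == pytest.approx(2 * lam)
        assert buckling_wavelength(1.0, I_100UM, 16.0) == pytest.approx(lam / 2)
        # lambda is linear in R through I ~ R^4
        assert (buckling_wavelength(1.0, second_moment(200e-6), 1.0)
                == pytest.approx(2 * lam))

    @pytest.mark.parametrize("E, I, G", [(0, 1, 1), (1, 0, 1), (1, 1, 0),
                                         (-1, 1, 1)])
    def test_nonpositive_inputs_rejected(self, E, I, G):
        with pytest.raises(DomainError):
            buckling_wavelength(E, I, G)


class TestCriticalForce:
    def test_curve_at_optimum_equals_2_sqrt_EIG(self):
        E, I, G = 0.5, 3e-17, 2.0
        lam = buckling_wavelength(E, I, G)
        assert critical_force_curve(lam, E, I, G) == pytest.approx(
            2 * math.sqrt(E * I * G), rel=1e-12)

    def test_euler_term_only_without_foundation(self):
        assert critical_force_curve(1.0, 1.0, 1.0, 0.0) == pytest.approx(
            4 * math.pi ** 2)

    def test_closed_form_force(self):
        # (R, E, G') = (1e-4 m, 1 Pa, 1 Pa): F_b = 1e-8 sqrt(pi)
        F = critical_buckling_force(1e-4, 1.0, 1.0)
        assert F == pytest.approx(1e-8 * math.sqrt(math.pi), rel=1e-12)
        lam_num, F_num = minimize_force_curve(1.0, second_moment(1e-4), 1.0)
        assert F_num == pytest.approx(F, rel=1e-9)

    def test_force_scales_with_radius_squared(self):
        assert (critical_buckling_force(2e-4, 1.0, 1.0)
                == pytest.approx(4 * critical_buckling_force(1e-4, 1.0, 1.0)))

    def test_zero_modulus_gives_zero_force(self):
        assert critical_buckling_force(1e-4, 0.0, 1.0) == 0.0

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(DomainError):
            critical_force_curve(0.0, 1.0, 1.0, 1.0)


class TestOracleEquivalence:
    def test_analytic_forms_minimise_the_force_curve(self, rng):
        """Eq.-free check: brute-force minimisation over wavelength must
        land on the analytic wavelength and critical force for randomized
        (E, G', R) spanning the experimental decades."""
        for _ in range(100):
            E = 10 ** rng.uniform(-2, 2)
            G = 10 ** rng.uniform(-1, 2)
            R = 10 ** rng.uniform(-5, -3)
            I = second_moment(R)
            lam_num, F_num = minimize_force_curve(E, I, G)
            assert lam_num == pytest.approx(buckling_wavelength(E, I, G),
                                            rel=1e-6)
            assert F_num == pytest.approx(critical_buckling_force(R, E, G),
                                          rel=1e-6)


class TestCriticalStress:
    def test_unit_value(self):
        assert critical_buckling_stress(math.pi, 1.0) == pytest.approx(1.0)

    def test_at_buckling_threshold_modulus(self):
        assert critical_buckling_stress(1.0, 3.4) == pytest.approx(1.040, abs=1e-3)

    def test_equals_force_over_area(self, rng):
        for _ in range(50):
            E = 10 ** rng.uniform(-2, 2)
            G = 10 ** rng.uniform(-1, 2)
            R = 10 ** rng.uniform(-5, -3)
            assert critical_buckling_stress(E, G) == pytest.approx(
                critical_buckling_force(R, E, G) / (math.pi * R ** 2), rel=1e-12)

    def test_strictly_increasing_in_both_moduli(self):
        base = critical_buckling_stress(1.0, 1.0)
        assert critical_buckling_stress(1.5, 1.0) > base
        assert critical_buckling_stress(1.0, 1.5) > base


class TestThresholdModulus:
    def test_round_trip_with_critical_stress(self, rng):
        for E in 10 ** rng.uniform(-2, 2, 10):
            sigma = math.sqrt(E / math.pi)
            assert buckling_threshold_modulus(sigma, E) == pytest.approx(1.0)

    def test_quadratic_in_stress(self):
        assert (buckling_threshold_modulus(2.0, 1.0)
                == pytest.approx(4 * buckling_threshold_modulus(1.0, 1.0)))

    def test_inverts_the_critical_stress(self):
        assert buckling_threshold_modulus(1.040, 1.0) == pytest.approx(3.4, abs=2e-2)

    def test_zero_modulus_rejected(self):
        with pytest.raises(DomainError):
            buckling_threshold_modulus(1.0, 0.0)


class TestModulusFromBuckling:
    def test_round_trip_identity(self, rng):
        for E in 10 ** rng.uniform(-2, 2, 20):
            lam = buckling_wavelength(E, I_100UM, 1.92)
            assert modulus_from_buckling(lam, 100e-6, 1.92) == pytest.approx(
                E, rel=1e-12)

    def test_unit_inversion(self):
        # lam = 2 pi with I = 1 and G' = 1 corresponds to E = 1
        R = (4.0 / math.pi) ** 0.25
        assert modulus_from_buckling(2 * math.pi, R, 1.0) == pytest.approx(1.0)

    def test_measured_wavelength_yields_soft_modulus(self):
        assert modulus_from_buckling(2.17e-4, 100e-6, 1.92) == pytest.approx(
            0.035, rel=0.01)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DomainError):
            modulus_from_buckling(0.0, 1e-4, 1.0)


class TestAlgebraicProperties:
    @settings(deadline=None, derandomize=True)
    @given(E=st.floats(1e-2, 1e2), G=st.floats(1e-1, 1e2),
           R=st.floats(1e-5, 1e-3))
    def test_wavelength_inversion_is_exact(self, E, G, R):
        lam = buckling_wavelength(E, second_moment(R), G)
        assert modulus_from_buckling(lam, R, G) == pytest.approx(E, rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(E=st.floats(1e-2, 1e2), G=st.floats(1e-1, 1e2))
    def test_threshold_modulus_inverts_critical_stress(self, E, G):
        sigma = critical_buckling_stress(E, G)
        assert buckling_threshold_modulus(sigma, E) == pytest.approx(G, rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(E=st.floats(1e-2, 1e2), I=st.floats(1e-20, 1e-14),
           G=st.floats(1e-1, 1e2),
           frac=st.floats(-0.5, 0.5))
    def test_force_curve_minimum_is_at_the_analytic_wavelength(self, E, I, G,
                                                               frac):
        lam = buckling_wavelength(E, I, G)
        off = lam * (1.0 + frac)
        assert critical_force_curve(off, E, I, G) >= critical_force_curve(
            lam, E, I, G) * (1 - 1e-12)


class TestBeamGeometry:
    def test_derived_section_properties(self):
        g = BeamGeometry(R=100e-6, L0=5e-3)
        assert g.D == pytest.approx(200e-6)
        assert g.I == pytest.approx(second_moment(100e-6))
        assert g.aspect == pytest.approx(25.0)

    @pytest.mark.parametrize("R, L0", [(-1e-6, 5e-3), (0, 5e-3), (1e-6, 0)])
    def test_invalid_dimensions_rejected(self, R, L0):
        with pytest.raises(DomainError):
            BeamGeometry(R=R, L0=L0)
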