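"""Energy-balance failure model and the axial-contraction force balance."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from microbeam import (
    ContractionState,
    DomainError,
    FailureAssessment,
    contraction_strain,
    critical_buckling_stress,
    equilibrium_cell_stress,
    failure_stress,
    failure_threshold_yield,
    griffith_failure_stress,
    predicted_contraction_strain,
    strain_energy,
    triple_point_check,
    yield_energy,
)


class TestEnergies:
    def test_strain_energy_value(self):
        # sigma_int = 1 Pa, E = 1 Pa, R = 100 um, L0 = 5 mm
        assert strain_energy(1.0, 1.0, 1e-4, 5e-3) == pytest.approx(
            math.pi * 1e-8 * 5e-3, rel=1e-12)

    def test_strain_energy_quadratic_in_stress(self):
        assert strain_energy(2.0, 1.0, 1e-4, 5e-3) == pytest.approx(
            4 * strain_energy(1.0, 1.0, 1e-4, 5e-3))

    def test_zero_stress_stores_nothing(self):
        assert strain_energy(0.0, 1.0, 1e-4, 5e-3) == 0.0

    def test_yield_energy_with_conserved_length(self):
        # N segments of length L0/N cost the same as one full beam length
        L0, N = 5e-3, 7
        assert yield_energy(0.8, N, 1e-4, L0 / N) == pytest.approx(
            0.8 * math.pi * 1e-8 * L0, rel=1e-12)

    def test_zero_yield_stress_costs_nothing(self):
        assert yield_energy(0.0, 3, 1e-4, 1e-3) == 0.0

    def test_invalid_segment_count_rejected(self):
        with pytest.raises(DomainError):
            yield_energy(1.0, 0, 1e-4, 1e-3)

    def test_energy_balance_reproduces_failure_stress(self, rng):
        """Solving U_s(sigma) = U_y numerically for sigma must land on
        sqrt(E sigma_y) whenever N L1 = L0 — the algebraic identity behind
        the failure threshold."""
        for _ in range(20):
            E = 10 ** rng.uniform(-2, 1)
            sy = 10 ** rng.uniform(-2, 1)
            R = 10 ** rng.uniform(-5, -3.5)
            L0 = 10 ** rng.uniform(-3, -1.5)
            N = int(rng.integers(1, 20))
            root = brentq(
                lambda s: strain_energy(s, E, R, L0)
                - yield_energy(sy, N, R, L0 / N),
                1e-12, 1e6)
            assert root == pytest.approx(failure_stress(E, sy), rel=1e-9)


class TestFailureStress:
    def test_simple_value(self):
        assert failure_stress(4.0, 1.0) == pytest.approx(2.0)

    def test_at_observed_threshold(self):
        assert failure_stress(1.0, 1.95) == pytest.approx(1.396, abs=1e-3)

    def test_square_root_scaling_in_modulus(self, rng):
        sy = 0.7
        for E in 10 ** rng.uniform(-2, 1, 10):
            assert failure_stress(4 * E, sy) == pytest.approx(
                2 * failure_stress(E, sy), rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            failure_stress(-1.0, 1.0)


class TestGriffithVariant:
    def test_uniform_ratio_to_energy_balance(self, rng):
        for _ in range(10):
            E = 10 ** rng.uniform(-2, 1)
            sy = 10 ** rng.uniform(-2, 1)
            assert griffith_failure_stress(E, sy) / failure_stress(E, sy) \
                == pytest.approx(1 / math.sqrt(math.pi), rel=1e-12)

    def test_unit_value(self):
        assert griffith_failure_stress(math.pi, 1.0) == pytest.approx(1.0)

    def test_effective_surface_energy(self):
        stress, gamma = griffith_failure_stress(1.0, 1.95, R=1e-4)
        assert gamma == pytest.approx(9.75e-5, rel=1e-9)


class TestThresholdYield:
    def test_round_trip_with_failure_stress(self, rng):
        for _ in range(10):
            E = 10 ** rng.uniform(-2, 1)
            sy = 10 ** rng.uniform(-2, 1)
            assert failure_threshold_yield(failure_stress(E, sy), E) \
                == pytest.approx(sy, rel=1e-12)

    def test_inverts_the_printed_threshold(self):
        assert failure_threshold_yield(1.396, 1.0) == pytest.approx(1.95, abs=5e-3)

    def test_quadratic_in_stress(self):
        assert failure_threshold_yield(2.0, 1.0) == pytest.approx(
            4 * failure_threshold_yield(1.0, 1.0))

    def test_buckling_and_failure_thresholds_related_by_pi(self, rng):
        """Equating the critical buckling stress and the failure stress at
        equal E forces G' = pi sigma_y exactly."""
        for _ in range(10):
            E = 10 ** rng.uniform(-2, 1)
            sy = 10 ** rng.uniform(-2, 1)
            assert critical_buckling_stress(E, math.pi * sy) == pytest.approx(
                failure_stress(E, sy), rel=1e-12)


class TestContraction:
    @pytest.mark.parametrize("dL, L0, expected", [
        (0.0, 5e-3, 0.0),
        (50e-6, 5e-3, 0.01),
        (0.05 * 5e-3, 5e-3, 0.05),
    ])
    def test_strain_values(self, dL, L0, expected):
        assert contraction_strain(dL, L0) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(DomainError):
            contraction_strain(1e-6, 0.0)

    def test_equilibrium_stress_values(self):
        assert equilibrium_cell_stress(0.0, 1.0, 1.0, 0.1) == pytest.approx(10.0)
        assert equilibrium_cell_stress(0.05, 2.0, 0.9, 0.05) == pytest.approx(20.0)

    def test_elastic_contribution_window(self):
        # strains of 1-5% at beam moduli of 1-10 Pa span 0.01-0.5 Pa
        lo = 0.01 * 1.0
        hi = 0.05 * 10.0
        assert lo == pytest.approx(0.01)
        assert hi == pytest.approx(0.5)
        state = ContractionState(delta_L=0.05 * 5e-3, L0=5e-3, E=10.0, sigma_y=1.95)
        assert state.elastic_stress == pytest.approx(0.5)
        assert state.negligible_elastic

    def test_invalid_volume_fraction_rejected(self):
        with pytest.raises(DomainError):
            equilibrium_cell_stress(0.01, 1.0, 1.0, 0.0)


class TestPredictedStrain:
    def test_yield_stress_blocks_contraction(self):
        assert predicted_contraction_strain(0.01, 10.0, 1.0, 1.0) == 0.0

    def test_forward_value(self):
        assert predicted_contraction_strain(0.05, 20.0, 2.0, 0.9) \
            == pytest.approx(0.05)

    def test_round_trip_with_equilibrium(self, rng):
        for _ in range(10):
            eps = rng.uniform(0.005, 0.05)
            E = 10 ** rng.uniform(-1, 1)
            sy = 10 ** rng.uniform(-2, 0)
            phi = rng.uniform(0.03, 0.2)
            sigma = equilibrium_cell_stress(eps, E, sy, phi)
            assert predicted_contraction_strain(phi, sigma, E, sy) \
                == pytest.approx(eps, rel=1e-9)

    def test_monotonicity(self):
        base = predicted_contraction_strain(0.1, 20.0, 1.0, 0.5)
        assert predicted_contraction_strain(0.2, 20.0, 1.0, 0.5) > base
        assert predicted_contraction_strain(0.1, 30.0, 1.0, 0.5) > base
        assert predicted_contraction_strain(0.1, 20.0, 1.0, 1.0) < base


class TestTriplePoint:
    def test_exact_prediction_gives_unity(self):
        assert triple_point_check(1.0, 1.0) == pytest.approx(1.0)

    def test_observed_location_within_factor_two(self):
        ratio = triple_point_check(1.95, 1.0)
        assert ratio == pytest.approx(1.95)
        assert 0.5 <= ratio <= 2.0

    def test_bound_violation_detected(self):
        assert triple_point_check(5.0, 1.0) > 2.0

    def test_zero_modulus_rejected(self):
        with pytest.raises(DomainError):
            triple_point_check(1.0, 0.0)


class TestFailureAssessment:
    def test_consistent_segments_accepted(self):
        fa = FailureAssessment.assess(sigma_int=1.0, E=1.0, sigma_y=0.5,
                                      R=1e-4, L0=5e-3, N=5)
        assert fa.N * fa.L1 == pytest.approx(5e-3)
        assert fa.sigma_f == pytest.approx(failure_stress(1.0, 0.5))
        assert fa.gamma_eff == pytest.approx(1e-4 * 0.5 / 2)

    def test_inconsistent_segments_rejected(self):
        with pytest.raises(DomainError):
            FailureAssessment.assess(sigma_int=1.0, E=1.0, sigma_y=0.5,
                                     R=1e-4, L0=5e-3, N=5, L1=2e-3)
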