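"""Energy-balance failure model and axial-contraction force balance.

At low collagen concentration a contracting cell--ECM beam does not buckle
when the medium is stiff; instead it fragments into short contracting
segments.  The failure threshold comes from balancing the elastic strain
energy stored in the beam,

    U_s = (sigma_int^2 / E) pi R^2 L0,

against the cost of yielding the microgel that must flow in between the
separating segments,

    U_y = sigma_y N pi R^2 L1,        with N L1 ~ L0,

which gives an internal failure stress sigma_f = sqrt(E sigma_y).  A
Griffith-style variant treating the yielded microgel as an effective
surface energy gamma ~ R sigma_y / 2 gives the same scaling with a 1/sqrt(pi)
prefactor.

At high collagen concentration the beam stays intact and contracts axially
by a strain eps = dL/L0; equilibrium of cell contraction against beam
elasticity and medium yield stress reads

    sigma_cell phi = eps E + sigma_y.

All stresses Pa, lengths m, energies J.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "FailureAssessment",
    "ContractionState",
    "strain_energy",
    "yield_energy",
    "failure_stress",
    "griffith_failure_stress",
    "failure_threshold_yield",
    "contraction_strain",
    "equilibrium_cell_stress",
    "predicted_contraction_strain",
    "triple_point_check",
]

#: relative tolerance accepted between N*L1 and L0 when both are supplied
SEGMENT_LENGTH_RTOL = 0.05


@dataclass(frozen=True)
class FailureAssessment:
    """Energy bookkeeping for one beam at its failure threshold."""

    sigma_int: float      # internal beam stress, Pa
    U_s: float            # stored strain energy, J
    U_y: float            # break-up (yield) energy, J
    N: int                # number of segments
    L1: float             # segment length, m
    sigma_f: float        # failure stress sqrt(E sigma_y), Pa
    gamma_eff: float      # effective surface energy density R sigma_y / 2, J/m^2

    def __post_init__(self) -> None:
        if self.U_s < 0 or self.U_y < 0:
            raise DomainError("energies must be non-negative")
        if self.N < 1:
            raise DomainError(f"segment count must be >= 1, got {self.N}")

    @classmethod
    def assess(cls, sigma_int: float, E: float, sigma_y: float,
               R: float, L0: float, N: int = 1,
               L1: float | None = None) -> "FailureAssessment":
        """Build an assessment for a beam broken into N equal segments.

        If ``L1`` is omitted it is set to L0/N; if supplied, N*L1 must
        agree with L0 within ``SEGMENT_LENGTH_RTOL``.
        """
        if L1 is None:
            L1 = L0 / N
        elif abs(N * L1 - L0) > SEGMENT_LENGTH_RTOL * L0:
            raise DomainError(
                f"N*L1 = {N * L1:.4g} m inconsistent with L0 = {L0:.4g} m"
            )
        return cls(
            sigma_int=sigma_int,
            U_s=strain_energy(sigma_int, E, R, L0),
            U_y=yield_energy(sigma_y, N, R, L1),
            N=N,
            L1=L1,
            sigma_f=failure_stress(E, sigma_y),
            gamma_eff=R * sigma_y / 2.0,
        )


@dataclass(frozen=True)
class ContractionState:
    """Axial contraction of an intact beam."""

    delta_L: float        # length change, m
    L0: float             # as-printed length, m
    E: float              # beam modulus, Pa
    sigma_y: float        # medium yield stress, Pa

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise DomainError(f"L0 must be positive, got {self.L0}")

    @property
    def strain(self) -> float:
        return contraction_strain(self.delta_L, self.L0)

    @property
    def elastic_stress(self) -> float:
        """eps * E, the elastic contribution to the force balance, Pa."""
        return self.strain * self.E

    @property
    def negligible_elastic(self) -> bool:
        """True when the elastic term is dominated by the yield stress."""
        return self.elastic_stress <= self.sigma_y


# ---------------------------------------------------------------------------
# Energies and failure thresholds
# ---------------------------------------------------------------------------

def strain_energy(sigma_int: float, E: float, R: float, L0: float) -> float:
    """Elastic strain energy stored in the beam: (sigma_int^2/E) pi R^2 L0, J."""
    if E <= 0:
        raise DomainError(f"E must be positive, got {E}")
    if R < 0 or L0 < 0:
        raise DomainError("R and L0 must be >= 0")
    return sigma_int ** 2 / E * math.pi * R ** 2 * L0


def yield_energy(sigma_y: float, N: int, R: float, L1: float) -> float:
    """Energy to yield the microgel around N segments of length L1.

    sigma_y N pi R^2 L1, assuming the yielded hydrodynamic volume equals
    the segment volume.
    """
    if N < 1:
        raise DomainError(f"segment count must be >= 1, got {N}")
    if sigma_y < 0:
        raise DomainError(f"yield stress must be >= 0, got {sigma_y}")
    if R <= 0 or L1 <= 0:
        raise DomainError("R and L1 must be positive")
    return sigma_y * N * math.pi * R ** 2 * L1


def failure_stress(E: float, sigma_y: float) -> float:
    """Internal stress at beam break-up: sigma_f = sqrt(E sigma_y), Pa.

    Solves U_s = U_y with N L1 = L0; scales as E^(1/2) at fixed sigma_y.
    """
    if E < 0 or sigma_y < 0:
        raise DomainError(f"E, sigma_y must be >= 0, got E={E}, sigma_y={sigma_y}")
    return math.sqrt(E * sigma_y)


def griffith_failure_stress(E: float, sigma_y: float,
                            R: float | None = None) -> float | tuple[float, float]:
    """Griffith-style failure stress sqrt(E sigma_y / pi), Pa.

    Treats the yielded microgel as an effective fracture surface energy
    gamma_eff = R sigma_y / 2; uniformly 1/sqrt(pi) times
    :func:`failure_stress`.  With ``R`` given, returns
    ``(stress, gamma_eff)``.
    """
    if E < 0 or sigma_y < 0:
        raise DomainError(f"E, sigma_y must be >= 0, got E={E}, sigma_y={sigma_y}")
    stress = math.sqrt(E * sigma_y / math.pi)
    if R is None:
        return stress
    if R < 0:
        raise DomainError(f"R must be >= 0, got {R}")
    return stress, R * sigma_y / 2.0


def failure_threshold_yield(sigma_f: float, E: float) -> float:
    """Medium yield stress above which a stress sigma_f cannot break the beam.

    sigma_y^f = sigma_f^2 / E — the inverse of :func:`failure_stress`.
    """
    if E <= 0:
        raise DomainError(f"E must be positive, got {E}")
    if sigma_f < 0:
        raise DomainError(f"sigma_f must be >= 0, got {sigma_f}")
    return sigma_f ** 2 / E


# ---------------------------------------------------------------------------
# Axial contraction
# ---------------------------------------------------------------------------

def contraction_strain(delta_L: float, L0: float) -> float:
    """Axial strain eps = dL / L0 (dimensionless)."""
    if L0 <= 0:
        raise DomainError(f"L0 must be positive, got {L0}")
    return delta_L / L0


def equilibrium_cell_stress(strain: float, E: float, sigma_y: float,
                            phi: float) -> float:
    """Per-cell stress from the contraction balance: (eps E + sigma_y) / phi.

    ``phi`` is the cell volume fraction; the average internal stress is
    phi * sigma_cell.  The elastic term eps*E is typically negligible
    against sigma_y at the strains (1-5%) and moduli (~1-10 Pa) seen in
    contracting beams.
    """
    if phi <= 0 or phi > 1:
        raise DomainError(f"phi must be in (0, 1], got {phi}")
    return (strain * E + sigma_y) / phi


def predicted_contraction_strain(phi: float, sigma_cell: float, E: float,
                                 sigma_y: float) -> float:
    """Forward prediction of axial strain from a per-cell stress.

    eps = max(0, (phi sigma_cell - sigma_y) / E); zero means the cells
    cannot overcome the medium yield stress, so the beam does not contract.
    """
    if E <= 0:
        raise DomainError(f"E must be positive, got {E}")
    if phi < 0:
        raise DomainError(f"phi must be >= 0, got {phi}")
    return max(0.0, (phi * sigma_cell - sigma_y) / E)


def triple_point_check(sigma_y_f: float, E_star: float) -> float:
    """Ratio sigma_y^f / E* at the breakup-contraction-stability triple point.

    Equating the buckling- and failure-model internal stresses, with the
    elastic contraction term neglected, predicts E = sigma_y at the triple
    point, i.e. a ratio of 1; the model is considered consistent when the
    ratio lies within a factor of two of unity.
    """
    if E_star <= 0:
        raise DomainError(f"E* must be positive, got {E_star}")
    if sigma_y_f < 0:
        raise DomainError(f"sigma_y^f must be >= 0, got {sigma_y_f}")
    return sigma_y_f / E_star
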