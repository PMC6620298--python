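"""Euler-Bernoulli mechanics of a slender elastic beam in an elastic medium.

A cylindrical cell--ECM beam of radius ``R`` and modulus ``E`` embedded in a
packed-microgel medium of shear modulus ``G'`` buckles, under sufficient
axial load, into a sinusoidal undulation.  Treating the medium as an elastic
foundation, the equilibrium of a laterally deflected beam selects the
wavelength that minimises the combined cost of bending the beam and
deforming the medium:

    lambda = 2 pi (E I / G')^(1/4),        I = pi R^4 / 4

The axial force required to hold an undulation of wavelength ``lam`` is

    F(lam) = (4 pi^2 / lam^2) E I + (lam^2 / 4 pi^2) G'

which is strictly convex in ``lam**2``; its minimum over wavelength is the
critical buckling force F_b = R^2 sqrt(pi E G'), equivalently a critical
axial stress sigma_b = sqrt(E G' / pi) independent of radius.

All quantities are SI (m, N, Pa).  Unit conversion belongs at the I/O
boundary, not here.  Functions are pure; the dataclasses bundle validated
parameter sets for the rest of the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError

__all__ = [
    "BeamGeometry",
    "BeamMaterial",
    "MediumProperties",
    "BucklingSolution",
    "second_moment",
    "buckling_wavelength",
    "critical_force_curve",
    "critical_buckling_force",
    "critical_buckling_stress",
    "buckling_threshold_modulus",
    "modulus_from_buckling",
    "minimize_force_curve",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamGeometry:
    """As-printed beam dimensions with derived section properties.

    Parameters
    ----------
    R : float
        Beam radius in meters.
    L0 : float
        As-printed beam length in meters.
    """

    R: float
    L0: float

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise DomainError(f"beam radius must be positive, got {self.R}")
        if self.L0 <= 0:
            raise DomainError(f"beam length must be positive, got {self.L0}")

    @property
    def D(self) -> float:
        """Diameter, m."""
        return 2.0 * self.R

    @property
    def I(self) -> float:  # noqa: E743 - standard mechanics symbol
        """Second moment of area of the circular section, m^4."""
        return second_moment(self.R)

    @property
    def aspect(self) -> float:
        """Aspect ratio L0/D (dimensionless)."""
        return self.L0 / self.D


@dataclass(frozen=True)
class BeamMaterial:
    """Beam constitutive parameters.

    Either the collagen-1 concentration (mg/mL) or the elastic modulus
    ``E`` (Pa) may be left ``None``; the missing one is filled in through
    the concentration-modulus calibration map (see ``classify``).
    """

    collagen_conc: float | None = None
    E: float | None = None

    def __post_init__(self) -> None:
        if self.collagen_conc is None and self.E is None:
            raise DomainError("BeamMaterial needs collagen_conc or E (or both)")
        if self.E is not None and self.E < 0:
            raise DomainError(f"elastic modulus must be >= 0, got {self.E}")
        if self.collagen_conc is not None and self.collagen_conc < 0:
            raise DomainError(
                f"collagen concentration must be >= 0, got {self.collagen_conc}"
            )


@dataclass(frozen=True)
class MediumProperties:
    """Packed-microgel medium: shear modulus G' and yield stress sigma_y, Pa."""

    G_prime: float
    sigma_y: float = 0.0

    def __post_init__(self) -> None:
        if self.G_prime <= 0:
            raise DomainError(f"G' must be positive, got {self.G_prime}")
        if self.sigma_y < 0:
            raise DomainError(f"yield stress must be >= 0, got {self.sigma_y}")


@dataclass(frozen=True)
class BucklingSolution:
    """Buckling threshold of one (beam, medium) pair.

    Attributes
    ----------
    wavelength : float
        Selected undulation wavelength, m.
    F_b : float
        Critical axial buckling force, N.
    sigma_b : float
        Critical axial buckling stress F_b / (pi R^2), Pa.
    F : float
        The force curve evaluated at ``wavelength`` (equals ``F_b``), N.
    """

    wavelength: float
    F_b: float
    sigma_b: float
    F: float = field(default=float("nan"))

    @classmethod
    def solve(cls, geom: BeamGeometry, E: float, medium: MediumProperties
              ) -> "BucklingSolution":
        lam = buckling_wavelength(E, geom.I, medium.G_prime)
        F_b = critical_buckling_force(geom.R, E, medium.G_prime)
        sigma_b = critical_buckling_stress(E, medium.G_prime)
        return cls(wavelength=lam, F_b=F_b, sigma_b=sigma_b, F=F_b)


# ---------------------------------------------------------------------------
# Closed-form operations
# ---------------------------------------------------------------------------

def second_moment(R: float) -> float:
    """Second moment of area of a circular cross-section, pi R^4 / 4.

    Parameters
    ----------
    R : float
        Radius, m.  Must be non-negative.
    """
    if R < 0:
        raise DomainError(f"radius must be >= 0, got {R}")
    return math.pi * R ** 4 / 4.0


def buckling_wavelength(E: float, I: float, G_prime: float) -> float:
    """Wavelength selected by a beam buckling in an elastic medium.

    lambda = 2 pi (E I / G')^(1/4).  The quarter power makes the wavelength
    weakly sensitive to the moduli: doubling E or G' moves lambda by only
    2^(1/4) - 1, about 19%.
    """
    if E <= 0 or I <= 0 or G_prime <= 0:
        raise DomainError(
            f"E, I, G' must all be positive, got E={E}, I={I}, G'={G_prime}"
        )
    return 2.0 * math.pi * (E * I / G_prime) ** 0.25


def critical_force_curve(lam: float, E: float, I: float, G_prime: float) -> float:
    """Axial force sustaining an undulation of wavelength ``lam``.

    F(lam) = (4 pi^2 / lam^2) E I  +  (lam^2 / 4 pi^2) G'

    The first term is the Euler bending cost, the second the cost of
    deforming the foundation.  Strictly convex in lam^2 with a unique
    minimum at the buckling wavelength.
    """
    if lam <= 0:
        raise DomainError(f"wavelength must be positive, got {lam}")
    four_pi2 = 4.0 * math.pi ** 2
    return four_pi2 / lam ** 2 * E * I + lam ** 2 / four_pi2 * G_prime


def critical_buckling_force(R: float, E: float, G_prime: float) -> float:
    """Minimum axial force that buckles the beam: F_b = R^2 sqrt(pi E G').

    Exactly the minimum over wavelength of :func:`critical_force_curve`
    with I = pi R^4 / 4 (substituting the optimal wavelength makes the two
    terms equal, each sqrt(E I G')).
    """
    if R < 0 or E < 0 or G_prime < 0:
        raise DomainError(
            f"R, E, G' must be >= 0, got R={R}, E={E}, G'={G_prime}"
        )
    return R ** 2 * math.sqrt(math.pi * E * G_prime)


def critical_buckling_stress(E: float, G_prime: float) -> float:
    """Critical axial stress for buckling: sigma_b = sqrt(E G' / pi).

    Radius-independent: F_b / (pi R^2) for any R.
    """
    if E < 0 or G_prime < 0:
        raise DomainError(f"E, G' must be >= 0, got E={E}, G'={G_prime}")
    return math.sqrt(E * G_prime / math.pi)


def buckling_threshold_modulus(sigma_int: float, E: float) -> float:
    """Medium shear modulus above which a stress sigma_int cannot buckle.

    G'^b = pi sigma_int^2 / E — the inverse of
    :func:`critical_buckling_stress` in G'.
    """
    if E <= 0:
        raise DomainError(f"E must be positive, got {E}")
    if sigma_int < 0:
        raise DomainError(f"sigma_int must be >= 0, got {sigma_int}")
    return math.pi * sigma_int ** 2 / E


def modulus_from_buckling(lam: float, R: float, G_prime: float) -> float:
    """Beam modulus inferred from a measured buckling wavelength.

    Exact inverse of :func:`buckling_wavelength`:
    E = G' (lam / 2 pi)^4 / (pi R^4 / 4).  Because lambda enters to the
    fourth power, relative errors in the measured wavelength are amplified
    fourfold in E.
    """
    if lam <= 0 or R <= 0 or G_prime <= 0:
        raise DomainError(
            f"lam, R, G' must be positive, got lam={lam}, R={R}, G'={G_prime}"
        )
    return G_prime * (lam / (2.0 * math.pi)) ** 4 / second_moment(R)


# ---------------------------------------------------------------------------
# Brute-force numeric oracle
# ---------------------------------------------------------------------------

def minimize_force_curve(E: float, I: float, G_prime: float,
                         n_grid: int = 1000) -> tuple[float, float]:
    """Numerically minimise the force curve over wavelength.

    Independent of the closed forms above: a log-spaced grid bracketing
    the minimum followed by bounded golden-section/Brent refinement.
    Returns ``(lam_min, F_min)``.  Used to verify that the analytic
    wavelength and critical force are the true minimisers.
    """
    if E <= 0 or I <= 0 or G_prime <= 0:
        raise DomainError("E, I, G' must all be positive")
    # Bracket around the dimensional scale (E I / G')^(1/4); the curve is
    # convex in lam^2 so one order of magnitude each way is ample.
    scale = (E * I / G_prime) ** 0.25
    grid = np.logspace(math.log10(scale) - 1.0, math.log10(scale) + 2.0, n_grid)
    vals = np.array([critical_force_curve(g, E, I, G_prime) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda u: critical_force_curve(math.exp(u), E, I, G_prime),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-9},
    )
    lam_min = math.exp(res.x)
    return lam_min, critical_force_curve(lam_min, E, I, G_prime)
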