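"""Single-cell stress estimators and the stress--stiffness power-law fit.

A beam loaded with cells at volume fraction ``phi`` carries an average
internal stress phi * sigma_cell.  Observing the instability thresholds of
many beams therefore turns the mechanical models into estimators of the
contractile stress a single cell generates:

* at the buckling threshold G'^b:    sigma_cell = sqrt(E G'^b / pi) / phi
* at the break-up threshold s_y^f:   sigma_cell = sqrt(E s_y^f) / phi
* from axial contraction:            sigma_cell = (eps E + sigma_y) / phi

Both threshold estimators are homogeneous of degree 1/2 in E, so cohorts
whose thresholds are E-independent produce sigma_cell ~ E^(1/2)/phi.
Pooled estimates are summarised by an unweighted ordinary-least-squares
power-law fit in log-log space, sigma_cell = a E^b.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .failure import equilibrium_cell_stress

__all__ = [
    "CellLoading",
    "CellStressEstimate",
    "ScalingFit",
    "sigma_cell_from_buckling",
    "sigma_cell_from_failure",
    "sigma_cell_from_contraction",
    "fit_stress_scaling",
]

#: hard-sphere random close packing — an absolute ceiling on phi
PHI_RCP = 0.64
#: above this volume fraction the collagen network differs enough that the
#: modulus calibration becomes unreliable; estimates are flagged, not dropped
PHI_DETAILED = 0.2


@dataclass(frozen=True)
class CellLoading:
    """Cell volume fraction in the printed beam."""

    phi: float

    def __post_init__(self) -> None:
        if not 0 <= self.phi < PHI_RCP:
            raise DomainError(
                f"phi must be in [0, {PHI_RCP}) (random close packing), got {self.phi}"
            )

    @property
    def above_detailed_analysis_limit(self) -> bool:
        return self.phi > PHI_DETAILED


@dataclass(frozen=True)
class CellStressEstimate:
    """One per-cell stress estimate, tagged with the estimator used."""

    sigma_cell: float   # Pa
    method: str         # "buckling" | "failure" | "contraction"
    E: float            # beam modulus at which estimated, Pa
    phi: float          # cell volume fraction used

    def __post_init__(self) -> None:
        if self.sigma_cell < 0:
            raise DomainError("sigma_cell must be >= 0")
        if self.method not in ("buckling", "failure", "contraction"):
            raise DomainError(f"unknown estimator method {self.method!r}")

    @property
    def flagged_dense(self) -> bool:
        """True for phi above the detailed-analysis limit (kept, but flagged)."""
        return self.phi > PHI_DETAILED


@dataclass(frozen=True)
class ScalingFit:
    """Fitted power law sigma_cell = a * E^b with log-log goodness of fit."""

    a: float            # prefactor, Pa
    b: float            # exponent, dimensionless
    r_squared: float    # R^2 of the OLS fit on ln-ln axes
    n: int              # number of points

    def predict(self, E: float) -> float:
        return self.a * E ** self.b

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps({"a_Pa": d["a"], "b": d["b"],
                           "r_squared": d["r_squared"], "n": d["n"]})


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def sigma_cell_from_buckling(phi: float, E: float,
                             G_prime_b: float) -> CellStressEstimate:
    """Per-cell stress inferred from the buckling threshold.

    At onset the average internal stress equals the critical buckling
    stress, phi sigma_cell = sqrt(E G'^b / pi).
    """
    if phi <= 0:
        raise DomainError(f"phi must be positive, got {phi}")
    if E < 0 or G_prime_b < 0:
        raise DomainError("E and G'^b must be >= 0")
    sigma = math.sqrt(E * G_prime_b / math.pi) / phi
    return CellStressEstimate(sigma_cell=sigma, method="buckling", E=E, phi=phi)


def sigma_cell_from_failure(phi: float, E: float,
                            sigma_y_f: float) -> CellStressEstimate:
    """Per-cell stress inferred from the break-up threshold.

    phi sigma_cell = sqrt(E sigma_y^f) at the failure boundary.
    """
    if phi <= 0:
        raise DomainError(f"phi must be positive, got {phi}")
    if E < 0 or sigma_y_f < 0:
        raise DomainError("E and sigma_y^f must be >= 0")
    sigma = math.sqrt(E * sigma_y_f) / phi
    return CellStressEstimate(sigma_cell=sigma, method="failure", E=E, phi=phi)


def sigma_cell_from_contraction(phi: float, strain: float, E: float,
                                sigma_y: float) -> CellStressEstimate:
    """Per-cell stress from the axial-contraction force balance."""
    sigma = equilibrium_cell_stress(strain, E, sigma_y, phi)
    return CellStressEstimate(sigma_cell=sigma, method="contraction", E=E, phi=phi)


# ---------------------------------------------------------------------------
# Power-law fit
# ---------------------------------------------------------------------------

def fit_stress_scaling(estimates: Sequence[CellStressEstimate] |
                       Iterable[CellStressEstimate]) -> ScalingFit:
    """Unweighted OLS of ln(sigma_cell) on ln(E) over pooled estimates.

    Returns a :class:`ScalingFit` with ``a = exp(intercept)``, ``b = slope``
    and R^2 computed in the fit's native log-log space.  Estimates from the
    three methods are pooled with equal weight.  Deterministic and
    invariant to point order.
    """
    ests = list(estimates)
    if len(ests) < 2:
        raise InsufficientDataError(
            f"power-law fit needs >= 2 points, got {len(ests)}"
        )
    E = np.array([e.E for e in ests], dtype=float)
    s = np.array([e.sigma_cell for e in ests], dtype=float)
    if np.any(E <= 0) or np.any(s <= 0):
        raise DomainError("all E and sigma_cell must be positive for a log-log fit")
    res = stats.linregress(np.log(E), np.log(s))
    r2 = float(res.rvalue ** 2)
    if math.isnan(r2):  # zero variance in x or y
        r2 = 1.0 if np.allclose(np.log(s), np.log(s).mean()) else 0.0
    return ScalingFit(
        a=float(math.exp(res.intercept)),
        b=float(res.slope),
        r_squared=min(max(r2, 0.0), 1.0),
        n=len(ests),
    )
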