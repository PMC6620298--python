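"""Stability-diagram classification and threshold estimation.

The fate of a printed cell--ECM beam — buckle, break up, contract axially,
or remain stable — is organised by a small set of empirical thresholds on
the beam and medium properties:

* ``G_prime_b``  — medium shear modulus above which buckling is suppressed
  (default 3.4 Pa),
* ``sigma_y_f``  — medium yield stress above which break-up and contraction
  are suppressed (default 1.95 Pa),
* ``E_star``     — beam modulus separating break-up (softer) from axial
  contraction (stiffer) (default 1 Pa),
* ``phi_min``    — minimum cell volume fraction for buckling (default 0.03),
* ``aspect_min`` — minimum L/D for buckling (default 10),
* ``L_max_contract`` — beam length above which axial contraction is
  friction-suppressed (default 30 mm).

Classification applies these rules in a fixed order (see
:func:`classify_outcome`) rather than by comparing critical-stress
magnitudes: at the parameter values of interest the failure stress is
below the buckling stress almost everywhere, yet soft media produce
buckling — the ordered empirical rules reproduce the observed diagram.

Material calibrations (collagen concentration -> E; medium G' -> sigma_y)
are log-log piecewise-linear maps through printed anchor points.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError, ValidationError
from .mechanics import BeamGeometry, BeamMaterial, MediumProperties

__all__ = [
    "Thresholds",
    "Outcome",
    "OUTCOME_LABELS",
    "CalibrationMap",
    "DEFAULT_E_OF_CONC",
    "DEFAULT_SIGMA_Y_OF_G",
    "collagen_to_modulus",
    "yield_stress_from_modulus",
    "classify_outcome",
    "estimate_thresholds",
]

OUTCOME_LABELS = ("buckled", "breakup", "contracted", "stable", "undetermined")

#: multiplicative margin used when selecting the beams that constrain one
#: boundary: beams within this factor of *another* boundary are excluded,
#: since per-beam threshold variability makes their fate ambiguous there.
BOUNDARY_MARGIN = 1.5


@dataclass(frozen=True)
class Outcome:
    """Fate label of one beam."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in OUTCOME_LABELS:
            raise ValidationError(
                f"outcome must be one of {OUTCOME_LABELS}, got {self.label!r}"
            )


@dataclass
class Thresholds:
    """Stability-diagram boundary parameters (all user-overridable)."""

    G_prime_b: float = 3.4        # Pa
    sigma_y_f: float = 1.95       # Pa
    E_star: float = 1.0           # Pa
    phi_min: float = 0.03         # dimensionless
    aspect_min: float = 10.0      # dimensionless
    L_max_contract: float = 0.03  # m
    #: names of boundaries left at their defaults by estimate_thresholds
    #: because the cohort had no data on one side
    flagged: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        for name in ("G_prime_b", "sigma_y_f", "E_star", "phi_min",
                     "aspect_min", "L_max_contract"):
            if getattr(self, name) <= 0:
                raise DomainError(f"threshold {name} must be positive")

    @property
    def threshold_ratio(self) -> float:
        """G'^b / sigma_y^f; the buckling/failure models predict pi."""
        return self.G_prime_b / self.sigma_y_f

    @property
    def triple_point_ratio(self) -> float:
        """sigma_y^f / E*; predicted to be 1 within a factor of two."""
        return self.sigma_y_f / self.E_star

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps({
            "G_prime_b_Pa": d["G_prime_b"],
            "sigma_y_f_Pa": d["sigma_y_f"],
            "E_star_Pa": d["E_star"],
            "phi_min": d["phi_min"],
            "aspect_min": d["aspect_min"],
            "L_max_contract_m": d["L_max_contract"],
            "flagged": list(d["flagged"]),
        })


# ---------------------------------------------------------------------------
# Calibration maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationMap:
    """Log-log piecewise-linear map through positive anchor points.

    Interpolates between anchors; extrapolates with the nearest segment's
    slope, emitting a warning (extrapolated calibrations carry no data).
    """

    anchors: tuple[tuple[float, float], ...]
    name: str = "calibration"

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValidationError(f"{self.name}: need >= 2 anchor points")
        xs = [a[0] for a in self.anchors]
        if any(x <= 0 or y <= 0 for x, y in self.anchors):
            raise ValidationError(f"{self.name}: anchors must be positive")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValidationError(
                f"{self.name}: anchor inputs must be strictly increasing"
            )

    def __call__(self, x: float) -> float:
        if x <= 0:
            raise DomainError(f"{self.name}: input must be positive, got {x}")
        xs = np.log([a[0] for a in self.anchors])
        ys = np.log([a[1] for a in self.anchors])
        lx = math.log(x)
        if lx < xs[0] or lx > xs[-1]:
            warnings.warn(
                f"{self.name}: {x:.4g} outside anchor range "
                f"[{self.anchors[0][0]:.4g}, {self.anchors[-1][0]:.4g}]; "
                "extrapolating with the nearest segment slope",
                stacklevel=2,
            )
        # np.interp clamps, so handle extrapolation with the end segments
        if lx <= xs[0]:
            slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            return math.exp(ys[0] + slope * (lx - xs[0]))
        if lx >= xs[-1]:
            slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            return math.exp(ys[-1] + slope * (lx - xs[-1]))
        return math.exp(float(np.interp(lx, xs, ys)))

    def inverse(self, y: float) -> float:
        """Invert the map (monotone anchors assumed), same log-log rules."""
        inv = CalibrationMap(
            anchors=tuple((b, a) for a, b in self.anchors),
            name=f"{self.name}^-1",
        )
        return inv(y)


#: collagen concentration (mg/mL) -> beam elastic modulus (Pa)
DEFAULT_E_OF_CONC = CalibrationMap(
    anchors=((0.5, 0.04), (1.0, 1.0), (1.5, 10.0)),
    name="E(collagen)",
)

#: medium shear modulus (Pa) -> medium yield stress (Pa); a two-anchor
#: power law, approximately sigma_y = 0.130 * G'^0.999
DEFAULT_SIGMA_Y_OF_G = CalibrationMap(
    anchors=((0.46, 0.06), (1.92, 0.25)),
    name="sigma_y(G')",
)


def collagen_to_modulus(conc: float,
                        cmap: CalibrationMap = DEFAULT_E_OF_CONC) -> float:
    """Beam elastic modulus (Pa) from collagen-1 concentration (mg/mL)."""
    return cmap(conc)


def yield_stress_from_modulus(G_prime: float,
                              cmap: CalibrationMap = DEFAULT_SIGMA_Y_OF_G
                              ) -> float:
    """Medium yield stress (Pa) from its shear modulus (Pa).

    Media in this family co-vary G' and sigma_y nearly proportionally;
    measured sigma_y values should be used directly when available.
    """
    return cmap(G_prime)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_outcome(geom: BeamGeometry, mat: BeamMaterial,
                     medium: MediumProperties, phi: float,
                     thr: Thresholds | None = None) -> Outcome:
    """Assign a fate label from the ordered stability-diagram rules.

    Rules, in order (boundaries inclusive as noted):

    1. phi < phi_min: buckling cannot be ruled out in buckling-permissive
       media (G' < G'^b) -> ``undetermined``; otherwise ``stable``.
    2. aspect L/D < aspect_min -> ``stable``.
    3. G' < G'^b -> ``buckled``  (G' = G'^b does not buckle).
    4. sigma_y >= sigma_y^f -> ``stable``.
    5. E < E* -> ``breakup``  (E = E* contracts).
    6. otherwise ``contracted`` — unless L0 >= L_max_contract, where
       friction pins the beam -> ``stable``.

    ``sigma_y`` is taken from ``medium``; if it is zero/unset it is derived
    through the default G' -> sigma_y calibration.
    """
    thr = thr or Thresholds()
    if mat.E is None:
        E = collagen_to_modulus(mat.collagen_conc)
    else:
        E = mat.E
    if E < 0 or phi < 0:
        raise ValidationError("E and phi must be non-negative")
    sigma_y = medium.sigma_y
    if sigma_y == 0.0:
        sigma_y = yield_stress_from_modulus(medium.G_prime)

    if phi < thr.phi_min:
        if medium.G_prime < thr.G_prime_b:
            return Outcome("undetermined")
        return Outcome("stable")
    if geom.aspect < thr.aspect_min:
        return Outcome("stable")
    if medium.G_prime < thr.G_prime_b:
        return Outcome("buckled")
    if sigma_y >= thr.sigma_y_f:
        return Outcome("stable")
    if E < thr.E_star:
        return Outcome("breakup")
    if geom.L0 >= thr.L_max_contract:
        return Outcome("stable")
    return Outcome("contracted")


# ---------------------------------------------------------------------------
# Threshold estimation from outcome cohorts
# ---------------------------------------------------------------------------

def _log_midpoint(lower_side: np.ndarray, upper_side: np.ndarray
                  ) -> float | None:
    """Geometric mean of (max of the values below, min of the values above)."""
    if lower_side.size == 0 or upper_side.size == 0:
        return None
    return float(math.sqrt(lower_side.max() * upper_side.min()))


def estimate_thresholds(records: Sequence, defaults: Thresholds | None = None
                        ) -> Thresholds:
    """Estimate stability boundaries from a classified cohort.

    ``records`` is a sequence of objects exposing ``phi``, ``aspect``,
    ``G_prime``, ``sigma_y``, ``E``, ``L0`` and ``outcome`` (a label
    string or :class:`Outcome`) — :class:`microbeam.cohort.OutcomeRecord`
    qualifies, as does any namespace built from the cohort CSV.

    Each boundary is the log-midpoint (geometric mean) between the extreme
    observations on its two sides, restricted to beams for which that
    boundary is the active one; beams within ``BOUNDARY_MARGIN`` of a
    *different* boundary are excluded as ambiguous.  Boundaries lacking
    data on either side keep their default value and are listed in
    ``flagged``.
    """
    if len(records) == 0:
        raise InsufficientDataError("cannot estimate thresholds from an empty cohort")
    defaults = defaults or Thresholds()

    def col(name: str) -> np.ndarray:
        return np.array([float(getattr(r, name)) for r in records])

    labels = np.array([
        r.outcome.label if isinstance(r.outcome, Outcome) else str(r.outcome)
        for r in records
    ])
    phi = col("phi")
    aspect = col("aspect")
    G = col("G_prime")
    sy = col("sigma_y")
    E = col("E")
    L0 = col("L0")

    m = BOUNDARY_MARGIN
    flagged: list[str] = []

    # --- G'^b: buckled vs non-buckled along G' -----------------------------
    # active only for beams clearly above the phi and aspect floors
    elig = (phi >= m * defaults.phi_min) & (aspect >= m * defaults.aspect_min)
    buck = elig & (labels == "buckled")
    nonb = elig & ~np.isin(labels, ("buckled", "undetermined"))
    G_b = _log_midpoint(G[buck], G[nonb])
    if G_b is None:
        G_b = defaults.G_prime_b
        flagged.append("G_prime_b")

    # --- sigma_y^f: failing (breakup|contracted) vs stable along sigma_y ---
    # active in the non-buckling regime, away from the phi floor and the
    # friction length limit
    elig_f = (elig & (G >= m * G_b) & (L0 < defaults.L_max_contract / m))
    failing = elig_f & np.isin(labels, ("breakup", "contracted"))
    stab = elig_f & (labels == "stable")
    sy_f = _log_midpoint(sy[failing], sy[stab])
    if sy_f is None:
        sy_f = defaults.sigma_y_f
        flagged.append("sigma_y_f")

    # --- E*: breakup vs contracted along E, below the yield boundary -------
    elig_e = elig_f & (sy <= sy_f / m)
    br = elig_e & (labels == "breakup")
    co = elig_e & (labels == "contracted")
    E_star = _log_midpoint(E[br], E[co])
    if E_star is None:
        E_star = defaults.E_star
        flagged.append("E_star")

    # --- phi_min: non-buckled vs buckled along phi in permissive media -----
    elig_p = (aspect >= m * defaults.aspect_min) & (G <= G_b / m)
    low = elig_p & np.isin(labels, ("undetermined", "stable"))
    high = elig_p & (labels == "buckled")
    phi_min = _log_midpoint(phi[low], phi[high])
    if phi_min is None:
        phi_min = defaults.phi_min
        flagged.append("phi_min")

    return Thresholds(
        G_prime_b=G_b,
        sigma_y_f=sy_f,
        E_star=E_star,
        phi_min=phi_min,
        aspect_min=defaults.aspect_min,
        L_max_contract=defaults.L_max_contract,
        flagged=tuple(flagged + ["aspect_min", "L_max_contract"]),
    )
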