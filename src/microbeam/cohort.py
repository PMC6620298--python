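"""Virtual-experiment generator for cell--ECM microbeam cohorts.

The study's raw imaging data is not deposited, so analysis code is
exercised on synthetic cohorts that carry the same statistical structure
the experiments report: beams with radii 25-100 um and length 5 mm,
collagen 0.5-2.5 mg/mL (hence moduli ~0.04 Pa and up through the
concentration-modulus calibration), cell volume fractions up to 0.2,
packed-microgel media with G' spanning 0.4-55 Pa whose yield stress
co-varies with G', fates assigned by the stability-diagram rules with
per-beam lognormal jitter on the thresholds, buckled centerlines shaped by
the beam-theory wavelength plus measurement noise, and contraction strains
of 1-5%.

Reproducibility: a single root seed spawns an independent random stream
per beam (keyed by beam index), so cohorts are byte-identical across runs
and adding beams does not perturb earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (
    Thresholds,
    classify_outcome,
    collagen_to_modulus,
    yield_stress_from_modulus,
)
from .errors import ConfigError, ValidationError
from .failure import failure_threshold_yield, predicted_contraction_strain
from .mechanics import (
    BeamGeometry,
    BeamMaterial,
    MediumProperties,
    buckling_threshold_modulus,
    buckling_wavelength,
)
from .wavelength import Centerline

__all__ = [
    "CohortConfig",
    "OutcomeRecord",
    "ThresholdObservation",
    "generate_cohort",
    "generate_centerline",
    "generate_threshold_observations",
    "write_cohort_csv",
    "read_cohort_csv",
    "cohort_to_frame",
    "write_centerline_csv",
    "read_centerline_csv",
    "COHORT_COLUMNS",
]

#: bit-exact cohort CSV column order
COHORT_COLUMNS = [
    "beam_id", "R_um", "L0_mm", "collagen_mg_ml", "E_Pa", "G_prime_Pa",
    "sigma_y_Pa", "phi", "outcome", "lambda_true_um", "lambda_measured_um",
    "strain", "delta_L_um",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a virtual cohort.

    Ranges are ``(min, max)``; a degenerate range (min == max) pins the
    parameter.  ``phi`` and ``G'`` are sampled log-uniformly (both span
    more than a decade in the experiments), ``R`` and collagen
    concentration uniformly.  ``E_range``, when set, samples the beam
    modulus log-uniformly and bypasses the concentration calibration.
    """

    n_beams: int = 500
    seed: int = 0
    R_range: tuple[float, float] = (25e-6, 100e-6)        # m
    conc_range: tuple[float, float] = (0.5, 2.5)          # mg/mL
    phi_range: tuple[float, float] = (0.005, 0.2)         # log-uniform
    G_prime_range: tuple[float, float] = (0.4, 55.0)      # Pa, log-uniform
    E_range: tuple[float, float] | None = None            # Pa, log-uniform
    L0: float = 5e-3                                      # m
    stress_law: tuple[float, float] = (15.0, 0.46)        # sigma_cell = a E^b
    jitter_sd_log: float = 0.1       # lognormal sd on each per-beam threshold
    noise_sd_frac: float = 0.1       # centerline noise as fraction of amplitude
    amplitude_frac: float = 0.2      # undulation amplitude as fraction of lambda
    samples_per_centerline: int = 512
    strain_range: tuple[float, float] = (0.01, 0.05)      # contracted beams
    strain_from_equilibrium: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        for name in ("R_range", "conc_range", "phi_range", "G_prime_range",
                     "strain_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be positive and ordered, got {lo}, {hi}")
        if self.E_range is not None:
            lo, hi = self.E_range
            if lo <= 0 or hi < lo:
                raise ConfigError(f"E_range must be positive and ordered, got {lo}, {hi}")
        if self.n_beams < 1:
            raise ConfigError("n_beams must be >= 1")
        if self.jitter_sd_log < 0 or self.noise_sd_frac < 0:
            raise ConfigError("jitter and noise must be non-negative")
        if self.samples_per_centerline < 16:
            raise ConfigError("samples_per_centerline must be >= 16")
        if self.L0 <= 0:
            raise ConfigError("L0 must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        thr = d.pop("thresholds", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        for key in ("R_range", "conc_range", "phi_range", "G_prime_range",
                    "E_range", "strain_range", "stress_law"):
            if key in d and d[key] is not None:
                d[key] = tuple(float(v) for v in d[key])
        if thr is not None:
            d["thresholds"] = Thresholds(**thr)
        return cls(**d)


@dataclass
class OutcomeRecord:
    """One beam of a (virtual or real) cohort: parameters, fate, measurements.

    SI units internally; the CSV boundary converts to um/mm.
    ``lambda_true`` is set only for buckled beams, ``strain``/``delta_L``
    only for contracted ones; ``lambda_measured`` is filled later by the
    measurement stage.
    """

    beam_id: str
    index: int
    R: float                 # m
    L0: float                # m
    collagen_conc: float     # mg/mL (NaN if E was sampled directly)
    E: float                 # Pa
    G_prime: float           # Pa
    sigma_y: float           # Pa
    phi: float
    outcome: str
    lambda_true: float | None = None       # m
    lambda_measured: float | None = None   # m
    strain: float | None = None
    delta_L: float | None = None           # m

    @property
    def aspect(self) -> float:
        return self.L0 / (2.0 * self.R)

    @property
    def geometry(self) -> BeamGeometry:
        return BeamGeometry(R=self.R, L0=self.L0)

    @property
    def medium(self) -> MediumProperties:
        return MediumProperties(G_prime=self.G_prime, sigma_y=self.sigma_y)


@dataclass(frozen=True)
class ThresholdObservation:
    """A per-beam instability threshold as an experiment would record it.

    The cell population in a beam of modulus ``E`` generates a per-cell
    stress drawn from the configured law sigma_cell = a E^b with
    multiplicative lognormal noise; the internal stress phi*sigma_cell
    then fixes the medium property at which that beam sits exactly on its
    instability boundary — the shear modulus G'^b for buckling, the yield
    stress sigma_y^f for break-up.
    """

    method: str          # "buckling" | "failure"
    phi: float
    E: float             # Pa
    threshold: float     # G'^b (Pa) or sigma_y^f (Pa)


def _rng(seed: int, beam: int, stream: int) -> np.random.Generator:
    """Independent per-beam generator keyed by (root seed, beam, stream)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(beam, stream)))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: CohortConfig) -> list[OutcomeRecord]:
    """Sample a cohort of beams and assign each its fate.

    Beam parameters are drawn from the configured ranges; the beam modulus
    comes from the collagen-concentration calibration (or directly from
    ``E_range``), the medium yield stress from the G' calibration.  Each
    beam's fate is classified with its own lognormally jittered copy of
    the true thresholds.  Buckled beams receive the beam-theory wavelength
    as ground truth; contracted beams receive a strain drawn from the
    configured window (or from the contraction force balance when
    ``strain_from_equilibrium`` is set).
    """
    records: list[OutcomeRecord] = []
    thr = cfg.thresholds
    a_law, b_law = cfg.stress_law
    for i in range(cfg.n_beams):
        rng = _rng(cfg.seed, i, 0)
        R = _uniform(rng, *cfg.R_range)
        phi = _log_uniform(rng, *cfg.phi_range)
        G_prime = _log_uniform(rng, *cfg.G_prime_range)
        if cfg.E_range is not None:
            conc = float("nan")
            E = _log_uniform(rng, *cfg.E_range)
        else:
            conc = _uniform(rng, *cfg.conc_range)
            E = collagen_to_modulus(conc)
        sigma_y = yield_stress_from_modulus(G_prime)

        def jit() -> float:
            if cfg.jitter_sd_log == 0:
                return 1.0
            return float(rng.lognormal(0.0, cfg.jitter_sd_log))
        beam_thr = replace(
            thr,
            G_prime_b=thr.G_prime_b * jit(),
            sigma_y_f=thr.sigma_y_f * jit(),
            E_star=thr.E_star * jit(),
            phi_min=thr.phi_min * jit(),
        )
        geom = BeamGeometry(R=R, L0=cfg.L0)
        outcome = classify_outcome(
            geom, BeamMaterial(E=E, collagen_conc=None if math.isnan(conc) else conc),
            MediumProperties(G_prime=G_prime, sigma_y=sigma_y), phi, beam_thr,
        ).label

        rec = OutcomeRecord(
            beam_id=f"beam_{i:04d}", index=i, R=R, L0=cfg.L0,
            collagen_conc=conc, E=E, G_prime=G_prime, sigma_y=sigma_y,
            phi=phi, outcome=outcome,
        )
        if outcome == "buckled":
            rec.lambda_true = buckling_wavelength(E, geom.I, G_prime)
        elif outcome == "contracted":
            if cfg.strain_from_equilibrium:
                sigma_cell = a_law * E ** b_law
                rec.strain = predicted_contraction_strain(phi, sigma_cell, E, sigma_y)
            else:
                rec.strain = _uniform(rng, *cfg.strain_range)
            rec.delta_L = rec.strain * cfg.L0
        records.append(rec)
    return records


def generate_centerline(rec: OutcomeRecord, cfg: CohortConfig) -> Centerline:
    """Synthesize the observed 2D centerline of one beam.

    Buckled beams are sinusoids at the beam's true wavelength with
    amplitude ``amplitude_frac * lambda``, a random phase, and additive
    Gaussian noise of sd ``noise_sd_frac * amplitude`` (centerline
    digitisation error).  Non-buckled beams yield a flat line with noise
    scaled to ``noise_sd_frac * R`` — the localisation error is a fraction
    of the beam radius.
    """
    rng = _rng(cfg.seed, rec.index, 1)
    z = np.linspace(0.0, rec.L0, cfg.samples_per_centerline)
    if rec.outcome == "buckled" and rec.lambda_true is not None:
        A = cfg.amplitude_frac * rec.lambda_true
        psi = rng.uniform(0.0, 2.0 * math.pi)
        x = A * np.sin(2.0 * math.pi * z / rec.lambda_true + psi)
        noise_sd = cfg.noise_sd_frac * A
    else:
        x = np.zeros_like(z)
        noise_sd = cfg.noise_sd_frac * rec.R
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=z.size)
    return Centerline(z=z, x=x)


# ---------------------------------------------------------------------------
# Threshold observations for the stress-scaling recovery loop
# ---------------------------------------------------------------------------

def generate_threshold_observations(
    n: int,
    seed: int,
    E_range: tuple[float, float] = (0.04, 10.0),
    phi_range: tuple[float, float] = (0.03, 0.2),
    stress_law: tuple[float, float] = (15.0, 0.46),
    noise_sd_log: float = 0.2,
) -> list[ThresholdObservation]:
    """Simulate per-beam instability thresholds under a cell-stress law.

    ``E`` and ``phi`` are sampled log-uniformly; per-cell stress is
    ``a E^b`` with lognormal noise (sd ``noise_sd_log`` in log); methods
    alternate between buckling and break-up.  The recorded threshold is
    the medium property at which the internal stress phi*sigma_cell sits
    exactly on the corresponding instability boundary, so applying the
    threshold estimators to these observations recovers the noisy per-cell
    stresses, and the power-law fit recovers (a, b).
    """
    if n < 2:
        raise ConfigError("need at least 2 observations")
    a_law, b_law = stress_law
    obs: list[ThresholdObservation] = []
    for i in range(n):
        rng = _rng(seed, i, 2)
        E = _log_uniform(rng, *E_range)
        phi = _log_uniform(rng, *phi_range)
        sigma_cell = a_law * E ** b_law * float(rng.lognormal(0.0, noise_sd_log))
        sigma_int = phi * sigma_cell
        if i % 2 == 0:
            obs.append(ThresholdObservation(
                method="buckling", phi=phi, E=E,
                threshold=buckling_threshold_modulus(sigma_int, E)))
        else:
            obs.append(ThresholdObservation(
                method="failure", phi=phi, E=E,
                threshold=failure_threshold_yield(sigma_int, E)))
    return obs


# ---------------------------------------------------------------------------
# CSV boundary (um / mm on disk, SI in memory)
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Sequence[OutcomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "beam_id": r.beam_id,
            "R_um": r.R * 1e6,
            "L0_mm": r.L0 * 1e3,
            "collagen_mg_ml": r.collagen_conc,
            "E_Pa": r.E,
            "G_prime_Pa": r.G_prime,
            "sigma_y_Pa": r.sigma_y,
            "phi": r.phi,
            "outcome": r.outcome,
            "lambda_true_um": None if r.lambda_true is None else r.lambda_true * 1e6,
            "lambda_measured_um": (None if r.lambda_measured is None
                                   else r.lambda_measured * 1e6),
            "strain": r.strain,
            "delta_L_um": None if r.delta_L is None else r.delta_L * 1e6,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Sequence[OutcomeRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown cohort column: {sorted(unknown)[0]}")
    missing = {"beam_id", "R_um", "L0_mm", "E_Pa", "G_prime_Pa",
               "sigma_y_Pa", "phi", "outcome"} - set(df.columns)
    if missing:
        raise ValidationError(f"missing cohort column: {sorted(missing)[0]}")

    def opt(row, col, scale=1.0):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return float(row[col]) * scale

    records = []
    for i, row in df.iterrows():
        records.append(OutcomeRecord(
            beam_id=str(row["beam_id"]), index=int(i),
            R=float(row["R_um"]) * 1e-6,
            L0=float(row["L0_mm"]) * 1e-3,
            collagen_conc=(float(row["collagen_mg_ml"])
                           if "collagen_mg_ml" in df.columns
                           and not pd.isna(row["collagen_mg_ml"]) else float("nan")),
            E=float(row["E_Pa"]),
            G_prime=float(row["G_prime_Pa"]),
            sigma_y=float(row["sigma_y_Pa"]),
            phi=float(row["phi"]),
            outcome=str(row["outcome"]),
            lambda_true=opt(row, "lambda_true_um", 1e-6),
            lambda_measured=opt(row, "lambda_measured_um", 1e-6),
            strain=opt(row, "strain"),
            delta_L=opt(row, "delta_L_um", 1e-6),
        ))
    return records


def write_centerline_csv(cl: Centerline, path: str | Path) -> None:
    pd.DataFrame({"z_um": cl.z * 1e6, "x_um": cl.x * 1e6}).to_csv(path, index=False)


def read_centerline_csv(path: str | Path) -> Centerline:
    df = pd.read_csv(path)
    if list(df.columns) != ["z_um", "x_um"]:
        raise ValidationError(
            f"centerline file must have columns z_um,x_um, got {list(df.columns)}"
        )
    return Centerline(z=df["z_um"].to_numpy() * 1e-6,
                      x=df["x_um"].to_numpy() * 1e-6)
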