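"""End-to-end orchestration: generate/ingest -> measure -> classify ->
estimate thresholds -> estimate cell stresses -> fit scaling law -> report.

The pipeline ties the other modules together into one reproducible run
driven by a YAML/JSON configuration and a seed.  Outputs are a cohort CSV,
per-beam centerline CSVs, and a single JSON analysis report collecting

* the measured-vs-predicted wavelength regression,
* the estimated stability thresholds,
* the per-cell stress power-law fit,
* outcome counts, and
* the cross-model consistency checks: G'^b / sigma_y^f against the
  predicted pi, sigma_y^f / E* against the predicted 1 (both judged at a
  factor of two), and the largest elastic contraction stress eps*E.
"""

from __future__ import annotations

import json
import logging
import math
import shutil
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import yaml

from .classify import Thresholds, estimate_thresholds
from .cohort import (
    CohortConfig,
    OutcomeRecord,
    ThresholdObservation,
    generate_centerline,
    generate_cohort,
    generate_threshold_observations,
    read_centerline_csv,
    read_cohort_csv,
    write_centerline_csv,
    write_cohort_csv,
)
from .errors import ConfigError, MicrobeamError, NoUndulationError
from .mechanics import buckling_wavelength, second_moment
from .scaling import (
    CellStressEstimate,
    ScalingFit,
    fit_stress_scaling,
    sigma_cell_from_buckling,
    sigma_cell_from_contraction,
    sigma_cell_from_failure,
)
from .wavelength import RegressionReport, measure_wavelength_fft, regress_lambda

__all__ = [
    "AnalysisReport",
    "run_pipeline",
    "measure_cohort",
    "cell_stress_estimates",
    "estimates_from_observations",
    "load_config",
]

log = logging.getLogger("microbeam")

REPORT_SCHEMA_VERSION = 1
FACTOR_OF_TWO = 2.0


@dataclass
class AnalysisReport:
    """Aggregated results of one pipeline run; serializes to one JSON doc."""

    regression: RegressionReport | None
    thresholds: Thresholds
    scaling: ScalingFit | None
    outcome_counts: dict[str, int]
    consistency: dict[str, float | bool]
    warnings: list[str] = field(default_factory=list)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "regression": None if self.regression is None else asdict(self.regression),
            "thresholds": json.loads(self.thresholds.to_json()),
            "scaling": None if self.scaling is None else asdict(self.scaling),
            "outcome_counts": self.outcome_counts,
            "consistency": self.consistency,
            "warnings": self.warnings,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Read a YAML/JSON run configuration; missing file -> defaults.

    Top-level keys: ``cohort`` (CohortConfig fields), ``thresholds``
    (Thresholds overrides for classification), ``scaling_observations``
    (generate_threshold_observations arguments), ``seed``.
    """
    cfg: dict = {}
    if path is not None:
        text = Path(path).read_text()
        cfg = yaml.safe_load(text) or {}
        if not isinstance(cfg, dict):
            raise ConfigError(f"config root must be a mapping, got {type(cfg)}")
    known = {"cohort", "thresholds", "scaling_observations", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if overrides:
        cfg.update(overrides)
    return cfg


def cohort_config_from(cfg: dict, seed: int | None = None) -> CohortConfig:
    body = dict(cfg.get("cohort", {}))
    if "thresholds" in cfg and "thresholds" not in body:
        body["thresholds"] = cfg["thresholds"]
    if seed is not None:
        body["seed"] = seed
    elif "seed" in cfg and "seed" not in body:
        body["seed"] = cfg["seed"]
    return CohortConfig.from_dict(body)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def measure_cohort(records: Sequence[OutcomeRecord],
                   centerlines: dict[str, "object"] | None = None,
                   cfg: CohortConfig | None = None) -> int:
    """Fill ``lambda_measured`` for buckled beams, in place.

    Centerlines are taken from ``centerlines`` (beam_id -> Centerline) or
    synthesized on the fly from ``cfg``.  Returns the number of beams
    measured; beams whose centerline carries no undulation are left
    unmeasured with a log warning.
    """
    n = 0
    for rec in records:
        if rec.outcome != "buckled":
            continue
        if centerlines is not None and rec.beam_id in centerlines:
            cl = centerlines[rec.beam_id]
        elif cfg is not None:
            cl = generate_centerline(rec, cfg)
        else:
            continue
        try:
            rec.lambda_measured = measure_wavelength_fft(cl)
            n += 1
        except NoUndulationError:
            log.warning("beam %s: no undulation found in centerline", rec.beam_id)
    return n


def wavelength_regression(records: Sequence[OutcomeRecord]
                          ) -> RegressionReport | None:
    """Regress measured wavelengths on the beam-theory prediction."""
    measured, predicted = [], []
    for rec in records:
        if rec.lambda_measured is None:
            continue
        measured.append(rec.lambda_measured)
        predicted.append(
            buckling_wavelength(rec.E, second_moment(rec.R), rec.G_prime))
    if len(measured) < 2:
        return None
    return regress_lambda(measured, predicted)


def cell_stress_estimates(records: Sequence[OutcomeRecord],
                          thresholds: Thresholds) -> list[CellStressEstimate]:
    """Per-cell stress estimates from each beam's observed instability.

    Buckled beams use the buckling-threshold estimator at the cohort's
    estimated G'^b, broken beams the failure estimator at sigma_y^f, and
    contracted beams the contraction force balance with their own strain
    and medium yield stress.  Stable/undetermined beams carry no estimate.
    """
    out: list[CellStressEstimate] = []
    for rec in records:
        if rec.phi <= 0:
            continue
        if rec.outcome == "buckled":
            out.append(sigma_cell_from_buckling(rec.phi, rec.E, thresholds.G_prime_b))
        elif rec.outcome == "breakup":
            out.append(sigma_cell_from_failure(rec.phi, rec.E, thresholds.sigma_y_f))
        elif rec.outcome == "contracted" and rec.strain is not None:
            out.append(sigma_cell_from_contraction(
                rec.phi, rec.strain, rec.E, rec.sigma_y))
    return out


def estimates_from_observations(obs: Sequence[ThresholdObservation]
                                ) -> list[CellStressEstimate]:
    """Apply the threshold estimators to per-beam threshold observations."""
    out = []
    for o in obs:
        if o.method == "buckling":
            out.append(sigma_cell_from_buckling(o.phi, o.E, o.threshold))
        elif o.method == "failure":
            out.append(sigma_cell_from_failure(o.phi, o.E, o.threshold))
        else:
            raise ConfigError(f"unknown observation method {o.method!r}")
    return out


def consistency_block(thresholds: Thresholds,
                      records: Sequence[OutcomeRecord]) -> dict:
    """Cross-model checks evaluated on the estimated thresholds."""
    ratio = thresholds.threshold_ratio
    triple = thresholds.triple_point_ratio
    elastic = [rec.strain * rec.E for rec in records
               if rec.outcome == "contracted" and rec.strain is not None]
    return {
        "threshold_ratio": ratio,
        "threshold_ratio_predicted": math.pi,
        "threshold_ratio_within_factor_two": (
            math.pi / FACTOR_OF_TWO <= ratio <= math.pi * FACTOR_OF_TWO),
        "triple_point_ratio": triple,
        "triple_point_predicted": 1.0,
        "triple_point_within_factor_two": (
            1.0 / FACTOR_OF_TWO <= triple <= FACTOR_OF_TWO),
        "max_elastic_stress_Pa": max(elastic) if elastic else 0.0,
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: str | Path | dict | None = None,
                 outdir: str | Path | None = None,
                 seed: int | None = None,
                 write_centerlines: bool = True) -> AnalysisReport:
    """Execute every stage on a (generated or ingested) cohort.

    ``config`` may be a path to a YAML/JSON file or an already-parsed
    mapping.  With ``outdir`` set, the cohort CSV, centerline CSVs and the
    report JSON are written there; partial outputs are removed if a stage
    fails.  Deterministic for a fixed (config, seed).
    """
    t0 = time.perf_counter()
    if isinstance(config, (str, Path)):
        cfg_dict = load_config(config)
    else:
        cfg_dict = dict(config or {})
    ccfg = cohort_config_from(cfg_dict, seed=seed)

    out = Path(outdir) if outdir is not None else None
    created_out = False
    if out is not None and not out.exists():
        out.mkdir(parents=True)
        created_out = True

    try:
        log.info("generating cohort: n=%d seed=%d", ccfg.n_beams, ccfg.seed)
        records = generate_cohort(ccfg)

        if out is not None:
            if write_centerlines:
                cl_dir = out / "centerlines"
                cl_dir.mkdir(exist_ok=True)
                for rec in records:
                    if rec.outcome == "buckled":
                        write_centerline_csv(generate_centerline(rec, ccfg),
                                             cl_dir / f"{rec.beam_id}.csv")

        n_meas = measure_cohort(records, cfg=ccfg)
        log.info("measured wavelength on %d buckled beams", n_meas)
        regression = wavelength_regression(records)

        thresholds = estimate_thresholds(records, defaults=ccfg.thresholds)
        log.info("estimated thresholds: G'^b=%.3g Pa, sigma_y^f=%.3g Pa, "
                 "E*=%.3g Pa, phi_min=%.3g",
                 thresholds.G_prime_b, thresholds.sigma_y_f,
                 thresholds.E_star, thresholds.phi_min)

        sc = cfg_dict.get("scaling_observations", {})
        if sc:
            obs = generate_threshold_observations(
                n=int(sc.get("n", 50)),
                seed=int(sc.get("seed", ccfg.seed)),
                E_range=tuple(sc.get("E_range", (0.04, 10.0))),
                phi_range=tuple(sc.get("phi_range", (0.03, 0.2))),
                stress_law=tuple(sc.get("stress_law", ccfg.stress_law)),
                noise_sd_log=float(sc.get("noise_sd_log", 0.2)),
            )
            estimates = estimates_from_observations(obs)
        else:
            estimates = cell_stress_estimates(records, thresholds)
        scaling = fit_stress_scaling(estimates) if len(estimates) >= 2 else None

        counts: dict[str, int] = {}
        for rec in records:
            counts[rec.outcome] = counts.get(rec.outcome, 0) + 1

        warn = []
        if thresholds.flagged:
            warn.append("thresholds left at defaults: "
                        + ", ".join(thresholds.flagged))
        n_dense = sum(1 for rec in records if rec.phi > 0.2)
        if n_dense:
            warn.append(f"{n_dense} beams above the phi=0.2 detailed-analysis limit")

        report = AnalysisReport(
            regression=regression,
            thresholds=thresholds,
            scaling=scaling,
            outcome_counts=counts,
            consistency=consistency_block(thresholds, records),
            warnings=warn,
        )
        if out is not None:
            write_cohort_csv(records, out / "cohort.csv")
            (out / "report.json").write_text(report.to_json() + "\n")
        log.info("pipeline finished in %.2f s", time.perf_counter() - t0)
        return report
    except MicrobeamError:
        if out is not None and created_out:
            shutil.rmtree(out, ignore_errors=True)
        raise


def run_on_csv(cohort_csv: str | Path,
               centerline_dir: str | Path | None = None,
               thresholds: Thresholds | None = None) -> AnalysisReport:
    """Analyse an existing cohort CSV (optionally with centerline files)."""
    records = read_cohort_csv(cohort_csv)
    centerlines = {}
    if centerline_dir is not None:
        for p in sorted(Path(centerline_dir).glob("*.csv")):
            centerlines[p.stem] = read_centerline_csv(p)
        measure_cohort(records, centerlines=centerlines)
    regression = wavelength_regression(records)
    est_thr = estimate_thresholds(records, defaults=thresholds or Thresholds())
    estimates = cell_stress_estimates(records, est_thr)
    scaling = fit_stress_scaling(estimates) if len(estimates) >= 2 else None
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.outcome] = counts.get(rec.outcome, 0) + 1
    return AnalysisReport(
        regression=regression,
        thresholds=est_thr,
        scaling=scaling,
        outcome_counts=counts,
        consistency=consistency_block(est_thr, records),
    )
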