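"""End-to-end identifiability experiments.

Two workflows mirror the study design:

* **parameter identifiability** - every synthetic tumour is re-calibrated
  with the model that generated it, at each noise level, and the
  absolute percentage error of each recovered parameter is summarized
  per model and noise level (median / IQR);
* **model identifiability** - every synthetic tumour is calibrated with
  all eleven variants, the minimum-AICc model is selected, and the
  selected model's agreement with the ground truth is scored at the last
  calibration time point (week 3 of RT) and at the held-out prediction
  time point (four weeks post-RT).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CalibrationConfig, Observations, levenberg_marquardt
from .cohort import DEFAULT_NOISE_LEVELS, generate_cohort
from .constants import DEFAULT_CONSTANTS
from .forward import SimulationWorkspace, SolverConfig, simulate
from .metrics import DEFAULT_MASK_THRESHOLD, score_states, summarize
from .params import ParameterBounds
from .selection import select, tally
from .variants import VARIANTS, get_variant

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    n_patients: int = 3
    dims: tuple = (16, 16, 3)
    noise_levels: tuple = DEFAULT_NOISE_LEVELS
    variants: tuple = None          # None -> all eleven
    master_seed: int = 0
    bounds: ParameterBounds = None
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    mask_threshold: float = DEFAULT_MASK_THRESHOLD
    output_dir: str = None

    def __post_init__(self):
        for lv in self.noise_levels:
            if not 0.0 <= lv < 1.0:
                raise ValueError(f"noise level {lv} outside [0, 1)")
        if self.bounds is None:
            self.bounds = ParameterBounds()

    @classmethod
    def from_yaml(cls, path):
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "bounds" in raw:
            raw["bounds"] = ParameterBounds(bounds={
                k: tuple(v) for k, v in raw["bounds"].items()
            })
        if "dims" in raw:
            raw["dims"] = tuple(raw["dims"])
        if "noise_levels" in raw:
            raw["noise_levels"] = tuple(raw["noise_levels"])
        return cls(**raw)


@dataclass
class ExperimentReport:
    kind: str
    tables: dict                    # name -> DataFrame
    provenance: dict
    selections: list = field(default_factory=list)
    confusion: object = None
    failures: list = field(default_factory=list)

    def content_hash(self) -> str:
        parts = [self.tables[k].to_csv() for k in sorted(self.tables)]
        return hashlib.sha256("".join(parts).encode()).hexdigest()


def _provenance(config: ExperimentConfig, kind: str) -> dict:
    import gliosel

    return {
        "kind": kind,
        "master_seed": config.master_seed,
        "n_patients": config.n_patients,
        "dims": list(config.dims),
        "noise_levels": list(config.noise_levels),
        "package_version": getattr(gliosel, "__version__", "unknown"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _cohort(config: ExperimentConfig):
    return generate_cohort(
        n_patients=config.n_patients,
        variants=config.variants,
        bounds=config.bounds,
        noise_levels=config.noise_levels,
        master_seed=config.master_seed,
        dims=config.dims,
        solver=config.solver,
    )


def run_parameter_identifiability(config: ExperimentConfig) -> ExperimentReport:
    """Calibrate each tumour with its generating model at every noise level."""
    patients, manifest = _cohort(config)
    rows = []
    failures = []
    for patient in patients:
        variant = patient.generating_variant
        workspace = SimulationWorkspace(patient.anatomy, DEFAULT_CONSTANTS)
        for level in config.noise_levels:
            obs = Observations.from_states(patient.observations[level], noise_level=level)
            try:
                result = levenberg_marquardt(
                    variant, patient.anatomy, patient.schedule, obs,
                    bounds=config.bounds, config=config.calibration,
                    solver=config.solver, workspace=workspace,
                )
            except Exception as exc:  # keep the run alive, record the failure
                logger.exception(
                    "calibration failed: patient %s %s noise %s",
                    patient.patient_id, variant.id, level,
                )
                failures.append(
                    {"patient_id": patient.patient_id, "variant": variant.id,
                     "noise_level": level, "error": str(exc)}
                )
                continue
            truth = patient.true_params.to_dict()
            est = result.params_hat.to_dict()
            for name in variant.free_params:
                if truth[name] == 0:
                    continue  # percentage error undefined at zero truth
                rows.append({
                    "patient_id": patient.patient_id,
                    "variant": variant.id,
                    "noise_level": level,
                    "parameter": name,
                    "truth": truth[name],
                    "estimate": est[name],
                    "abs_pct_error": abs(100.0 * (est[name] - truth[name]) / truth[name]),
                    "converged": result.converged,
                    "iterations": result.iterations,
                })
    errors = pd.DataFrame(rows)
    summary_rows = []
    if not errors.empty:
        for (vid, level, name), grp in errors.groupby(["variant", "noise_level", "parameter"]):
            med, iqr = summarize(grp["abs_pct_error"])
            summary_rows.append({
                "variant": vid, "noise_level": level, "parameter": name,
                "median_abs_pct_error": med, "iqr_abs_pct_error": iqr,
                "n": len(grp),
            })
    return ExperimentReport(
        kind="parameter_identifiability",
        tables={
            "manifest": manifest,
            "parameter_errors": errors,
            "parameter_error_summary": pd.DataFrame(summary_rows),
        },
        provenance=_provenance(config, "parameter_identifiability"),
        failures=failures,
    )


def calibrate_all_variants(patient, obs, config: ExperimentConfig, workspace=None):
    """All-eleven (or configured subset) calibrations of one tumour."""
    workspace = workspace or SimulationWorkspace(patient.anatomy, DEFAULT_CONSTANTS)
    candidates = (
        [get_variant(v) for v in config.variants]
        if config.variants is not None
        else sorted(VARIANTS.values(), key=lambda v: v.index)
    )
    return {
        v.id: levenberg_marquardt(
            v, patient.anatomy, patient.schedule, obs,
            bounds=config.bounds, config=config.calibration,
            solver=config.solver, workspace=workspace,
        )
        for v in candidates
    }


def run_model_identifiability(config: ExperimentConfig) -> ExperimentReport:
    """Calibrate all variants per tumour, select by AICc, score predictions."""
    patients, manifest = _cohort(config)
    metric_rows = []
    selections = []
    failures = []
    for patient in patients:
        workspace = SimulationWorkspace(patient.anatomy, DEFAULT_CONSTANTS)
        obs_days = tuple(int(s.day) for s in patient.truth.states)
        for level in config.noise_levels:
            obs = Observations.from_states(patient.observations[level], noise_level=level)
            try:
                calibrations = calibrate_all_variants(patient, obs, config, workspace)
                sel = select(
                    calibrations,
                    generating=patient.generating_variant,
                    allow_subset=config.variants is not None,
                    patient_id=patient.patient_id,
                    noise_level=level,
                )
                chosen = calibrations[sel.selected]
                predicted = simulate(
                    get_variant(sel.selected), chosen.params_hat,
                    patient.anatomy, patient.schedule, obs_days,
                    config=config.solver, initial_state=obs.baseline,
                    workspace=workspace,
                )
            except Exception as exc:
                logger.exception(
                    "selection failed: patient %s %s noise %s",
                    patient.patient_id, patient.generating_variant.id, level,
                )
                failures.append(
                    {"patient_id": patient.patient_id,
                     "variant": patient.generating_variant.id,
                     "noise_level": level, "error": str(exc)}
                )
                continue
            selections.append(sel)
            by_day_pred = {int(s.day): s for s in predicted.states}
            by_day_true = {int(s.day): s for s in patient.truth.states}
            for label, day in (
                ("calibration", obs.calibration_days[-1]),
                ("prediction", obs.prediction_day),
            ):
                rep = score_states(
                    by_day_pred[day], obs.fields[day], by_day_true[day],
                    patient.anatomy.grid,
                    threshold=config.mask_threshold, time_label=label,
                )
                metric_rows.append({
                    "patient_id": patient.patient_id,
                    "generating": patient.generating_variant.id,
                    "selected": sel.selected,
                    "correct": sel.correct,
                    "noise_level": level,
                    "time_label": label,
                    "dsc": rep.dsc,
                    "ccc": rep.ccc,
                    "pe_ttc": rep.pe_ttc,
                })
    metrics = pd.DataFrame(metric_rows)
    summary_rows = []
    if not metrics.empty:
        for (vid, level, label), grp in metrics.groupby(
            ["generating", "noise_level", "time_label"]
        ):
            row = {"variant": vid, "noise_level": level, "time_label": label, "n": len(grp)}
            for m in ("ccc", "dsc", "pe_ttc"):
                med, iqr = summarize(grp[m])
                row[f"median_{m}"] = med
                row[f"iqr_{m}"] = iqr
            summary_rows.append(row)
    confusion = tally(selections) if selections else None
    tables = {
        "manifest": manifest,
        "metrics": metrics,
        "metrics_summary": pd.DataFrame(summary_rows),
    }
    if confusion is not None:
        tables["confusion"] = confusion.counts
    return ExperimentReport(
        kind="model_identifiability",
        tables=tables,
        provenance=_provenance(config, "model_identifiability"),
        selections=selections,
        confusion=confusion,
        failures=failures,
    )


def write_report(report: ExperimentReport, output_dir) -> Path:
    """Persist every table as CSV plus provenance/selections as JSON."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables.items():
        table.to_csv(out / f"{name}.csv", index=name == "confusion")
    prov = dict(report.provenance)
    prov["content_hash"] = report.content_hash()
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=float))
    if report.selections:
        with open(out / "selections.jsonl", "w") as fh:
            for sel in report.selections:
                fh.write(json.dumps(sel.to_dict(), default=float) + "\n")
    if report.failures:
        (out / "failures.json").write_text(json.dumps(report.failures, indent=2, default=str))
    if report.confusion is not None:
        (out / "confusion.txt").write_text(str(report.confusion))
    return out
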