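"""File formats, run configuration, logging and the pipeline orchestrator.

Tabular interchange formats are plain TSV/CSV with fixed column orders so
runs diff cleanly; reports are versioned JSON. The orchestrator
:func:`run_pipeline` ties the stages together: input-function
construction -> model-menu fits and AIC selection -> two-stage fixed-k4
run -> reliability filtering -> group statistics -> scan-duration
truncation analysis. Any stage failure raises :class:`PipelineError`
carrying the stage name and a machine-readable code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    apply_reliability_filter,
    build_cohort_table,
    group_compare,
    lesion_contrast,
    truncation_analysis,
)
from .core import FrameSchedule, TissueTAC
from .fitting import (
    DualStageResult,
    FitResult,
    ModelSpec,
    WeightScheme,
    fit_tac,
    run_dual_stage,
    select_model,
)
from .input_function import (
    ContinuousBloodSeries,
    InputFunctionSet,
    ManualSample,
    build_input_set,
    fit_delay,
    fit_parent_fraction,
    fit_plasma_ratio,
    merge_blood,
)
from .synthetic import PopulationSpec, SubjectDataset, generate_cohort

__all__ = [
    "SCHEMA_VERSION",
    "PipelineError",
    "RunConfig",
    "setup_logging",
    "read_tac_table",
    "write_tac_table",
    "read_continuous_blood",
    "write_continuous_blood",
    "read_manual_samples",
    "write_manual_samples",
    "write_subject_dataset",
    "fit_report_dict",
    "run_pipeline",
]

SCHEMA_VERSION = "1.0"

logger = logging.getLogger("petkin")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger with a plain console handler."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_tac_table(path: str | Path) -> tuple[FrameSchedule, dict[str, TissueTAC]]:
    """Read a TAC TSV (columns ``frame_start_s``, ``frame_end_s``, then one
    column of frame-averaged kBq/mL per ROI)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("frame_start_s", "frame_end_s"):
        if col not in df.columns:
            raise ValueError(f"TAC table missing required column {col!r}")
    if df.shape[1] < 3:
        raise ValueError("TAC table contains no ROI columns")
    try:
        values = df.to_numpy(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"TAC table contains non-numeric cells: {exc}") from exc
    if not np.isfinite(values).all():
        raise ValueError("TAC table contains non-numeric or missing cells")
    start = df["frame_start_s"].to_numpy(float)
    dur = df["frame_end_s"].to_numpy(float) - start
    schedule = FrameSchedule(start, dur)  # raises on overlap, naming rows
    tacs = {
        roi: TissueTAC(roi, schedule, df[roi].to_numpy(float))
        for roi in df.columns[2:]
    }
    return schedule, tacs


def write_tac_table(path: str | Path, tacs: Mapping[str, TissueTAC]) -> None:
    """Write TACs sharing one schedule to the TAC TSV format (full
    precision, so write-then-read round-trips bit-exactly)."""
    first = next(iter(tacs.values()))
    data = {
        "frame_start_s": first.schedule.frame_start_s,
        "frame_end_s": first.schedule.frame_end_s,
    }
    for roi, tac in tacs.items():
        if tac.schedule.n_frames != first.schedule.n_frames:
            raise ValueError("all TACs in one table must share the schedule")
        data[roi] = tac.activity
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_continuous_blood(path: str | Path) -> ContinuousBloodSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return ContinuousBloodSeries(df["time_s"].to_numpy(float),
                                 df["wb_kBq_ml"].to_numpy(float))


def write_continuous_blood(path: str | Path, series: ContinuousBloodSeries) -> None:
    pd.DataFrame({"time_s": series.time_s,
                  "wb_kBq_ml": series.whole_blood_activity}
                 ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_manual_samples(path: str | Path) -> tuple[ManualSample, ...]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return tuple(
        ManualSample(row.time_min, row.wb_kBq_ml, row.plasma_kBq_ml,
                     row.parent_fraction)
        for row in df.itertuples()
    )


def write_manual_samples(path: str | Path, samples: Sequence[ManualSample]) -> None:
    pd.DataFrame({
        "time_min": [s.draw_time_min for s in samples],
        "wb_kBq_ml": [s.whole_blood_activity for s in samples],
        "plasma_kBq_ml": [s.plasma_activity for s in samples],
        "parent_fraction": [s.parent_fraction for s in samples],
    }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_subject_dataset(out_dir: str | Path, subject: SubjectDataset) -> None:
    """Emit one synthetic subject as the TSV formats plus a ground-truth
    JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    write_tac_table(out / f"{sid}_tac.tsv", subject.tacs)
    write_continuous_blood(out / f"{sid}_blood_continuous.tsv",
                           subject.continuous_blood)
    write_manual_samples(out / f"{sid}_blood_manual.tsv", subject.manual_samples)
    truth = {
        "schema_version": SCHEMA_VERSION,
        "subject": sid, "group": subject.group, "seed": subject.seed,
        "true_params": {roi: p.as_dict() for roi, p in subject.true_params.items()},
        "tissue_class": dict(subject.tissue_class),
    }
    (out / f"{sid}_truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run.

    With ``tac_path`` (plus blood paths) set, the pipeline analyses that
    single subject's files; otherwise it generates and analyses a
    synthetic cohort (``n_rrms``/``n_hc`` per group at noise ``sigma0``).
    """

    out_dir: str = "petkin_out"
    seed: int = 0
    # file mode
    tac_path: str | None = None
    continuous_blood_path: str | None = None
    manual_blood_path: str | None = None
    # synthetic-cohort mode
    n_rrms: int = 5
    n_hc: int = 5
    sigma0: float = 0.05
    # analysis options
    model_menu: tuple[str, ...] = ("1T2k_VB", "2T3k_VB", "2T4k_VB")
    weight_mode: str = "frame"
    filter_mode: str = "full"
    ttest_variant: str = "student"
    truncation_cut_min: float = 60.0
    fit_delay_correction: bool = True
    n_starts: int = 10

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "model_menu" in d:
            d["model_menu"] = tuple(d["model_menu"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["model_menu"] = list(d["model_menu"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _menu_spec(label: str) -> ModelSpec:
    base = label.removesuffix("_VB")
    include_vb = label.endswith("_VB")
    return ModelSpec(base, include_vb=include_vb)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _fit_result_dict(fit: FitResult) -> dict[str, Any]:
    macro = fit.macro
    return {
        "model": fit.model_label,
        "estimates": fit.estimates.as_dict(),
        "percent_se": {k: float(v) for k, v in fit.percent_se.items()},
        "rss": fit.rss, "aic": fit.aic,
        "n_frames": fit.n_frames, "n_free": fit.n_free,
        "converged": fit.converged,
        "macro": {"VT": macro.VT, "VND": macro.VND, "BPND": macro.BPND,
                  "K1k2": macro.K1k2, "Ki": macro.Ki},
    }


def fit_report_dict(dual: DualStageResult,
                    menu_fits: Mapping[str, Mapping[str, FitResult]] | None = None,
                    selected: Mapping[str, str] | None = None) -> dict[str, Any]:
    """Assemble the versioned per-subject fit report."""
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "stage1_k4": {cls: float(v) for cls, v in dual.k4_by_class.items()},
        "rois": {},
    }
    for roi, fit in dual.stage2.items():
        entry = _fit_result_dict(fit)
        entry["stage1_k4_used"] = float(fit.estimates.k4)
        if menu_fits and roi in menu_fits:
            entry["model_menu_aic"] = {lab: f.aic for lab, f in menu_fits[roi].items()}
        if selected and roi in selected:
            entry["selected_model"] = selected[roi]
        report["rois"][roi] = entry
    return report


def _process_blood(continuous: ContinuousBloodSeries,
                   manual: Sequence[ManualSample],
                   early_tac: TissueTAC,
                   fit_delay_correction: bool) -> InputFunctionSet:
    wb = merge_blood(continuous, manual)
    parent = fit_parent_fraction(manual)
    ratio = fit_plasma_ratio(manual)
    delay = fit_delay(wb, early_tac) if fit_delay_correction else 0.0
    return build_input_set(wb, ratio, parent, delay_s=delay)


def _analyse_subject(tacs: Mapping[str, TissueTAC],
                     tissue_class: Mapping[str, str],
                     inputs: InputFunctionSet,
                     config: RunConfig) -> tuple[DualStageResult,
                                                 dict[str, dict[str, FitResult]],
                                                 dict[str, str]]:
    weights = WeightScheme(config.weight_mode)
    menu_fits: dict[str, dict[str, FitResult]] = {}
    for roi, tac in tacs.items():
        menu_fits[roi] = {
            lab: fit_tac(tac, inputs, _menu_spec(lab), weights=weights,
                         n_starts=config.n_starts, seed=config.seed)
            for lab in config.model_menu
        }
    dual = run_dual_stage(tacs, tissue_class, inputs, weights=weights,
                          n_starts=config.n_starts, seed=config.seed)
    selected = {}
    for roi in tacs:
        candidates = list(menu_fits[roi].values()) + [dual.stage2[roi]]
        selected[roi] = select_model(candidates).model_label
    return dual, menu_fits, selected


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle.

    Returns a summary dictionary (also written to ``out_dir``); in
    synthetic-cohort mode it contains group statistics, lesion contrasts
    and the truncation agreement, in single-subject file mode the fit
    report only.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"schema_version": SCHEMA_VERSION, "petkin_version": __version__,
            "seed": config.seed, "config_hash": config.config_hash,
            "config": config.to_dict()}

    file_mode = config.tac_path is not None
    if file_mode:
        return _run_file_mode(config, out, meta)
    return _run_cohort_mode(config, out, meta)


def _run_file_mode(config: RunConfig, out: Path, meta: dict) -> dict[str, Any]:
    stage = "load"
    try:
        if not config.continuous_blood_path or not config.manual_blood_path:
            raise FileNotFoundError("blood file paths are required")
        schedule, tacs = read_tac_table(config.tac_path)
    except FileNotFoundError as exc:
        raise PipelineError(stage, "missing_input", str(exc)) from exc
    except ValueError as exc:
        raise PipelineError(stage, "bad_format", str(exc)) from exc

    stage = "input_function"
    try:
        continuous = read_continuous_blood(config.continuous_blood_path)
        manual = read_manual_samples(config.manual_blood_path)
        early = next(iter(tacs.values()))
        inputs = _process_blood(continuous, manual, early,
                                config.fit_delay_correction)
    except FileNotFoundError as exc:
        raise PipelineError(stage, "missing_input", str(exc)) from exc
    except ValueError as exc:
        raise PipelineError(stage, "blood_processing_failed", str(exc)) from exc

    stage = "fit"
    try:
        classes = {roi: ("WM" if "WM" in roi or "lesion" in roi.lower() else "GM")
                   for roi in tacs}
        dual, menu_fits, selected = _analyse_subject(tacs, classes, inputs, config)
    except Exception as exc:
        raise PipelineError(stage, "fit_failed", str(exc)) from exc

    report = fit_report_dict(dual, menu_fits, selected)
    report["meta"] = meta
    (out / "fit_report.json").write_text(json.dumps(report, indent=1))
    logger.info("wrote %s", out / "fit_report.json")
    return report


def _run_cohort_mode(config: RunConfig, out: Path, meta: dict) -> dict[str, Any]:
    stage = "synthesize"
    try:
        pop = PopulationSpec(n_rrms=config.n_rrms, n_hc=config.n_hc,
                             sigma0=config.sigma0)
        subjects = generate_cohort(pop, seed=config.seed)
    except ValueError as exc:
        raise PipelineError(stage, "bad_population", str(exc)) from exc

    stage = "input_function"
    inputs: list[InputFunctionSet] = []
    try:
        for s in subjects:
            early = s.tacs["whole_brain_GM"]
            inputs.append(_process_blood(s.continuous_blood, s.manual_samples,
                                         early, config.fit_delay_correction))
            logger.info("input function built for %s", s.subject_id)
    except ValueError as exc:
        raise PipelineError(stage, "blood_processing_failed", str(exc)) from exc

    stage = "fit"
    per_subject = {}
    fit_reports = {}
    duals = []
    try:
        for s, inp in zip(subjects, inputs):
            dual, menu_fits, selected = _analyse_subject(
                s.tacs, s.tissue_class, inp, config)
            duals.append(dual)
            per_subject[s.subject_id] = (s.group, s.tissue_class, dual.stage2)
            fit_reports[s.subject_id] = fit_report_dict(dual, menu_fits, selected)
            logger.info("fitted %s", s.subject_id)
    except Exception as exc:
        raise PipelineError(stage, "fit_failed", str(exc)) from exc

    stage = "filter"
    table = build_cohort_table(per_subject)
    table, exclusions = apply_reliability_filter(table, mode=config.filter_mode)

    stage = "group_stats"
    group_stats = {}
    test_rois = [r for r in table["roi"].unique()
                 if not r.startswith("whole_brain") and "lesion" not in r.lower()]
    n_tests = 0
    for ep in ("VT", "BPND"):
        group_stats[ep] = {}
        for roi in test_rois:
            try:
                cmp_res = group_compare(table, ep, roi,
                                        variant=config.ttest_variant)
            except ValueError as exc:
                group_stats[ep][roi] = {"error": str(exc)}
                continue
            group_stats[ep][roi] = {
                "t": cmp_res.t, "df": cmp_res.df, "p": cmp_res.p,
                "mean_RRMS": cmp_res.mean_a, "mean_HC": cmp_res.mean_b,
                "n_RRMS": cmp_res.n_a, "n_HC": cmp_res.n_b,
            }
            n_tests += 1
    # uncorrected p-values are reported; the Bonferroni-adjusted threshold
    # is printed alongside for reference
    group_stats["bonferroni_threshold"] = 0.05 / max(n_tests, 1)

    stage = "lesions"
    lesions = {}
    for s in subjects:
        if s.group != "RRMS":
            continue
        sub_tab = table[table["subject"] == s.subject_id]
        lesions[s.subject_id] = lesion_contrast(sub_tab)

    stage = "truncation"
    try:
        trunc = truncation_analysis(subjects, inputs, full_results=duals,
                                    cut_minutes=config.truncation_cut_min,
                                    weights=WeightScheme(config.weight_mode),
                                    n_starts=config.n_starts, seed=config.seed,
                                    filter_mode=config.filter_mode)
    except ValueError as exc:
        raise PipelineError(stage, "truncation_failed", str(exc)) from exc
    agreement = {ep: dataclasses.asdict(st) for ep, st in trunc.agreement.items()}

    stage = "report"
    table.to_csv(out / "cohort.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    trunc.table.to_csv(out / "truncation.csv", index=False)
    summary = {
        "meta": meta,
        "selected_models": {sid: {roi: rep["rois"][roi].get("selected_model")
                                  for roi in rep["rois"]}
                            for sid, rep in fit_reports.items()},
        "group_stats": group_stats,
        "lesion_contrasts": lesions,
        "truncation_agreement": agreement,
        "n_excluded": int((~table["included"]).sum()),
    }
    (out / "fit_report.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "meta": meta,
                    "subjects": fit_reports}, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("report bundle written to %s", out)
    return summary
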