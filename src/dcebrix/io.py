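"""Tabular I/O, run configuration, logging, and the end-to-end pipeline.

The pipeline's interchange format is CSV throughout (lesion-mean time series,
not images): curves.csv and patients.csv in, then normalized.csv, params.csv,
features.csv, table2_style.csv, model_result.csv, metrics.txt and a
run-manifest out.  Each stage logs counts and exclusions to a plain-text log
with a JSON-lines mirror.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brix, features as feat, model as mdl, preprocess, stats, synthetic_data
from .errors import (
    BaselineContaminationError,
    DataError,
    DcebrixError,
    InsufficientDataError,
    NoArrivalError,
    SchemaError,
)

__all__ = ["RunConfig", "PipelineLog", "read_curves", "read_patients",
           "run_pipeline", "load_config"]

CURVE_COLUMNS = ("patient_id", "time_s", "intensity")


@dataclass
class RunConfig:
    """Knobs for one pipeline run; defaults mirror the emulated study."""

    outdir: str = "dcebrix_out"
    curves_path: str | None = None  # None -> simulate a cohort
    patients_path: str | None = None
    seed: int = 0
    # simulation
    n_pcr: int = 15
    n_retu: int = 7
    noise_sd_fraction: float = 0.01
    # preprocessing
    baseline_frames: int = 5
    arrival_threshold: float = 1.05
    # features
    auc_window: float = 60.0
    # model
    n_folds: int = 10
    n_repeats: int = 10
    n_trees: int = 500
    mtry: object = "tune"
    cutoff: float = 0.5
    run_selection: bool = False
    selection_features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arrival_threshold <= 1:
            raise DcebrixError("arrival_threshold must exceed 1")
        for name in ("baseline_frames", "auc_window", "n_folds", "n_repeats",
                     "n_trees", "cutoff"):
            if getattr(self, name) <= 0:
                raise DcebrixError(f"{name} must be positive")


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


class PipelineLog:
    """Plain-text log with a machine-readable JSON-lines mirror."""

    def __init__(self, outdir: Path):
        outdir.mkdir(parents=True, exist_ok=True)
        self.text_path = outdir / "pipeline.log"
        self.jsonl_path = outdir / "pipeline.jsonl"
        self._text = self.text_path.open("w")
        self._jsonl = self.jsonl_path.open("w")

    def event(self, stage: str, message: str, **fields) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._text.write(f"{stamp} [{stage}] {message}\n")
        self._text.flush()
        self._jsonl.write(json.dumps({"stage": stage, "message": message,
                                      **fields}) + "\n")
        self._jsonl.flush()

    def close(self) -> None:
        self._text.close()
        self._jsonl.close()


def read_curves(path) -> list[preprocess.RawCurve]:
    """Read curves.csv (long format) into per-patient RawCurve objects.

    Rows are grouped by patient and sorted by time; duplicate timestamps
    within a patient are rejected.
    """
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"curves file missing columns: {sorted(missing)}")
    bad = df[df[["time_s", "intensity"]].isna().any(axis=1)]
    if len(bad):
        raise DataError(
            f"malformed rows (NaN) at lines {[i + 2 for i in bad.index[:10]]}"
        )
    curves = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"duplicate timestamps for patient {pid!r}")
        curves.append(
            preprocess.RawCurve(
                patient_id=str(pid),
                times=t,
                intensities=grp["intensity"].to_numpy(dtype=float),
            )
        )
    return curves


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns or "label" not in df.columns:
        raise SchemaError("patients file needs patient_id and label columns")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def _write_manifest(outdir: Path, config: RunConfig) -> None:
    blob = yaml.safe_dump(asdict(config), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": asdict(config),
    }
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                             sort_keys=False))


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> preprocess -> fit -> features -> stats
    -> model, writing every stage's artifact under ``config.outdir``.

    Returns a dict of artifact paths plus headline metrics.  Patients whose
    curve cannot be preprocessed or fitted are excluded and logged; every
    input patient ends up either in features.csv or in the exclusion log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = PipelineLog(outdir)
    try:
        return _run_pipeline(config, outdir, log)
    finally:
        log.close()


def _run_pipeline(config: RunConfig, outdir: Path, log: PipelineLog) -> dict:
    if config.curves_path is None:
        sim = synthetic_data.SimulationConfig(
            n_pcr=config.n_pcr,
            n_retu=config.n_retu,
            noise_sd_fraction=config.noise_sd_fraction,
            seed=config.seed,
        )
        records, curves = synthetic_data.generate_cohort(sim)
        curves_path, patients_path = synthetic_data.write_cohort(
            records, curves, outdir
        )
        log.event("simulate", f"generated {len(records)} patients",
                  n_pcr=config.n_pcr, n_retu=config.n_retu, seed=config.seed)
    else:
        curves_path, patients_path = Path(config.curves_path), Path(
            config.patients_path
        )

    curves = read_curves(curves_path)
    patients = read_patients(patients_path)
    log.event("read", f"{len(curves)} curves, {len(patients)} patients")

    # preprocess + fit + features, with exclusions
    norm_rows, param_rows, feat_rows, excluded = [], [], [], []
    for curve in curves:
        try:
            nc = preprocess.preprocess_curve(curve)
        except (NoArrivalError, BaselineContaminationError,
                InsufficientDataError) as exc:
            excluded.append((curve.patient_id, type(exc).__name__, str(exc)))
            log.event("preprocess", f"excluded {curve.patient_id}: {exc}",
                      patient_id=curve.patient_id, reason=type(exc).__name__)
            continue
        norm_rows.append(
            pd.DataFrame(
                {"patient_id": nc.patient_id, "t_since_arrival_s": nc.times,
                 "enhancement": nc.enhancement}
            )
        )
        try:
            params = brix.fit_brix(nc.times, nc.enhancement)
        except DcebrixError as exc:
            excluded.append((curve.patient_id, type(exc).__name__, str(exc)))
            log.event("fit", f"excluded {curve.patient_id}: {exc}",
                      patient_id=curve.patient_id, reason=type(exc).__name__)
            continue
        param_rows.append(
            {"patient_id": nc.patient_id, "A": params.A, "kep": params.kep,
             "kel": params.kel, "rss": params.rss,
             "converged": params.converged, "n_points": params.n_points}
        )
        cf = feat.compute_features(
            params, window_end=float(nc.times[-1]), auc_window=config.auc_window
        )
        feat_rows.append(
            {"patient_id": nc.patient_id, "A": params.A, "kep": params.kep,
             "kel": params.kel, "TTP": cf.TTP, "PE": cf.PE, "AUC": cf.AUC,
             "wash_in": cf.wash_in, "wash_out": cf.wash_out}
        )

    pd.concat(norm_rows, ignore_index=True).to_csv(outdir / "normalized.csv",
                                                   index=False)
    pd.DataFrame(param_rows).to_csv(outdir / "params.csv", index=False)
    features_df = pd.DataFrame(feat_rows).merge(patients, on="patient_id")
    features_df.to_csv(outdir / "features.csv", index=False)
    log.event("features", f"{len(features_df)} patients with features, "
              f"{len(excluded)} excluded", n_excluded=len(excluded))

    # cohort statistics
    param_names = [c for c in mdl.PREDICTOR_COLUMNS
                   if c in features_df.columns and c != "hpv_p16"]
    table2 = stats.group_comparison_table(
        features_df, features_df["label"], parameters=param_names
    )
    table2.to_csv(outdir / "table2_style.csv", index=False)
    log.event("stats", f"group comparison over {len(table2)} parameters")

    # response model
    feature_set = None
    trace = None
    if config.run_selection:
        feature_set, trace = mdl.backward_select(
            features_df, features_df["label"],
            features=config.selection_features or None,
            seed=config.seed, n_folds=config.n_folds,
            n_repeats=max(1, config.n_repeats // 5),
            n_trees=config.n_trees, mtry=config.mtry, cutoff=config.cutoff,
        )
        log.event("select", f"selected {feature_set}")
    result = mdl.crossvalidate_parrf(
        features_df, features_df["label"], features=feature_set,
        n_folds=config.n_folds, n_repeats=config.n_repeats,
        seed=config.seed, n_trees=config.n_trees, mtry=config.mtry,
        cutoff=config.cutoff,
    )
    pid_order = features_df["patient_id"].reset_index(drop=True)
    model_df = pd.DataFrame(
        {
            "patient_id": pid_order.iloc[result.patient_probabilities.index].values,
            "probability": result.patient_probabilities.values,
        }
    )
    model_df["prediction"] = np.where(
        model_df["probability"] >= config.cutoff, "pCR", "ReTu"
    )
    model_df.to_csv(outdir / "model_result.csv", index=False)

    metrics_lines = [
        f"AUC_ROC: {result.auc_roc:.4f} "
        f"(95% CI {result.auc_ci[0]:.4f}-{result.auc_ci[1]:.4f})",
        f"sensitivity_pct: {result.sensitivity:.1f} "
        f"(95% CI {result.sensitivity_ci[0]:.2f}-{result.sensitivity_ci[1]:.2f})",
        f"specificity_pct: {result.specificity:.1f} "
        f"(95% CI {result.specificity_ci[0]:.2f}-{result.specificity_ci[1]:.2f})",
        f"cutoff: {config.cutoff}",
        f"features: {result.selected_features}",
    ]
    if trace is not None:
        metrics_lines.append(f"elimination_trace: {trace}")
    (outdir / "metrics.txt").write_text("\n".join(metrics_lines) + "\n")
    pd.DataFrame(excluded, columns=["patient_id", "reason", "detail"]).to_csv(
        outdir / "exclusions.csv", index=False
    )
    _write_manifest(outdir, config)
    log.event("model", "done", auc=result.auc_roc,
              sensitivity=result.sensitivity, specificity=result.specificity)

    return {
        "outdir": str(outdir),
        "n_patients": len(features_df),
        "n_excluded": len(excluded),
        "auc_roc": result.auc_roc,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "artifacts": sorted(p.name for p in outdir.iterdir()),
    }
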