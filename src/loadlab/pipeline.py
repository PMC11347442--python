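"""Experiment orchestration: the 7-metric x 3-lag x 2-model grid.

One run takes a training log (read from disk or synthesized), computes the
metric panel once, and then for every grid cell builds the lag-aligned
dataset, standardizes, splits 70/30, fits, and evaluates. Failing cells
(separation, empty data, degenerate feature) are recorded in the manifest
and skipped. Per-cell seeds are derived deterministically from the master
seed and the cell identity, so cells are independent yet the whole bundle
reruns byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import lagged, models
from .metrics import MetricConfig, MetricPanel, METRIC_NAMES, compute_all_metrics
from .models import MLPConfig, LogisticReport, ModelReport
from .synthetic import SyntheticConfig, generate_cohort
from .training_log import TrainingLog, read_training_log

__all__ = ["ExperimentConfig", "CellResult", "ReportBundle", "run_experiment", "write_bundle"]

DEFAULT_LAGS = (0, 5, 10)
MODEL_KINDS = ("logistic", "mlp")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from the master seed and a cell identity (< 2^31)."""
    text = ":".join([str(int(master_seed)), *map(str, parts)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """The full experiment grid and its seeding.

    Exactly one of ``input_path`` (a training-log file) or ``synthetic``
    must be given. ``shared_split`` reuses one split seed across cells for
    controlled comparisons; by default each (metric, lag) cell draws its own
    split, since validity masks change the row set per metric.
    """

    input_path: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    metrics: Sequence[str] = METRIC_NAMES
    lags: Sequence[int] = DEFAULT_LAGS
    models: Sequence[str] = MODEL_KINDS
    train_fraction: float = 0.7
    master_seed: int = 0
    shared_split: bool = False
    metric_config: MetricConfig = field(default_factory=MetricConfig)
    mlp_config: MLPConfig = field(default_factory=MLPConfig)

    def __post_init__(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of input_path or synthetic")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        unknown = set(self.models) - set(MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown model kinds {sorted(unknown)}")

    @property
    def grid_size(self) -> int:
        return len(self.metrics) * len(self.lags) * len(self.models)


@dataclass
class CellResult:
    metric: str
    lag_days: int
    model_kind: str
    seed: int
    report: Optional[ModelReport] = None
    logistic: Optional[LogisticReport] = None
    error: Optional[str] = None
    rows: dict = field(default_factory=dict)


@dataclass
class ReportBundle:
    """Everything one run produces: per-cell results, tables, manifest."""

    config: ExperimentConfig
    cells: list
    logistic_tables: dict   # lag -> DataFrame in the Wald-table shape
    mlp_tables: dict        # lag -> DataFrame with CE train/test, AUC, accuracy
    summary: pd.DataFrame   # mean accuracy / AUC per (model, lag)
    manifest: dict


def _load_log(config: ExperimentConfig) -> TrainingLog:
    if config.input_path is not None:
        return read_training_log(config.input_path)
    return generate_cohort(config.synthetic)


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    log = _load_log(config)
    panel = compute_all_metrics(log, config.metric_config)

    cells = []
    for metric in config.metrics:
        for lag in config.lags:
            split_seed = (derive_seed(config.master_seed, "split")
                          if config.shared_split
                          else derive_seed(config.master_seed, "split", metric, lag))
            try:
                ds = lagged.align_labels(panel, log, metric, lag)
                dropped = dict(ds.dropped)
                ds = lagged.standardize(ds)
                ds = lagged.split(ds, config.train_fraction, seed=split_seed)
                prep_error = None
            except (lagged.EmptyDatasetError, lagged.DegenerateFeatureError,
                    lagged.SplitError) as exc:
                prep_error, ds, dropped = f"{type(exc).__name__}: {exc}", None, {}
            for model_kind in config.models:
                cell = CellResult(
                    metric=metric, lag_days=lag, model_kind=model_kind,
                    seed=derive_seed(config.master_seed, model_kind, metric, lag),
                )
                if prep_error is not None:
                    cell.error = prep_error
                    cells.append(cell)
                    continue
                train = ds.part("train")
                cell.rows = {
                    **dropped,
                    "used": len(ds),
                    "train": len(train),
                    "test": len(ds) - len(train),
                }
                try:
                    if model_kind == "logistic":
                        report, scorer = models.fit_logistic(
                            train["x"].to_numpy(), train["y"].to_numpy()
                        )
                        cell.logistic = report
                    else:
                        mlp_cfg = MLPConfig(
                            hidden_units=config.mlp_config.hidden_units,
                            max_epochs=config.mlp_config.max_epochs,
                            tolerance=config.mlp_config.tolerance,
                            seed=cell.seed,
                        )
                        scorer, info = models.fit_mlp(
                            train["x"].to_numpy(), train["y"].to_numpy(), mlp_cfg
                        )
                        cell.rows["hidden_units"] = info["hidden_units"]
                    cell.report = models.evaluate(scorer, ds, model_kind=model_kind)
                except (models.SeparationError, ValueError) as exc:
                    cell.error = f"{type(exc).__name__}: {exc}"
                cells.append(cell)

    logistic_tables = {lag: _logistic_table(cells, lag) for lag in config.lags}
    mlp_tables = {lag: _mlp_table(cells, lag) for lag in config.lags}
    summary = _summary_table(cells, config.lags)
    manifest = _manifest(config, cells)
    return ReportBundle(config=config, cells=cells,
                        logistic_tables=logistic_tables, mlp_tables=mlp_tables,
                        summary=summary, manifest=manifest)


def _logistic_table(cells, lag) -> pd.DataFrame:
    rows = []
    for c in cells:
        if c.model_kind != "logistic" or c.lag_days != lag:
            continue
        if c.logistic is None:
            rows.append({"metric": c.metric, "error": c.error})
            continue
        r, rep = c.logistic, c.report
        rows.append({
            "metric": c.metric,
            "B": r.B, "SE": r.SE, "Wald": r.wald, "p": r.p, "Exp(B)": r.expB,
            "CI95_low": r.ci_low, "CI95_high": r.ci_high,
            "accuracy_pct": rep.accuracy_overall * 100.0,
            "accuracy_injury_pct": None if rep.accuracy_injury is None
            else rep.accuracy_injury * 100.0,
            "accuracy_noninjury_pct": None if rep.accuracy_noninjury is None
            else rep.accuracy_noninjury * 100.0,
            "error": None,
        })
    return pd.DataFrame(rows)


def _mlp_table(cells, lag) -> pd.DataFrame:
    rows = []
    for c in cells:
        if c.model_kind != "mlp" or c.lag_days != lag:
            continue
        if c.report is None:
            rows.append({"metric": c.metric, "error": c.error})
            continue
        rep = c.report
        rows.append({
            "metric": c.metric,
            "cross_entropy_train": rep.cross_entropy_train,
            "cross_entropy_test": rep.cross_entropy_test,
            "auc": rep.auc,
            "accuracy_pct": rep.accuracy_overall * 100.0,
            "accuracy_injury_pct": None if rep.accuracy_injury is None
            else rep.accuracy_injury * 100.0,
            "accuracy_noninjury_pct": None if rep.accuracy_noninjury is None
            else rep.accuracy_noninjury * 100.0,
            "hidden_units": c.rows.get("hidden_units"),
            "error": None,
        })
    return pd.DataFrame(rows)


def _summary_table(cells, lags) -> pd.DataFrame:
    rows = []
    for kind in MODEL_KINDS:
        for lag in lags:
            sub = [c for c in cells
                   if c.model_kind == kind and c.lag_days == lag and c.report]
            if not sub:
                continue
            accs = [c.report.accuracy_overall for c in sub]
            aucs = [c.report.auc for c in sub if c.report.auc is not None]
            rows.append({
                "model": kind,
                "lag_days": lag,
                "n_cells": len(sub),
                "mean_accuracy_pct": 100.0 * float(np.mean(accs)),
                "mean_auc": float(np.mean(aucs)) if aucs else None,
            })
    return pd.DataFrame(rows)


def _manifest(config: ExperimentConfig, cells) -> dict:
    cfg = {
        "input_path": config.input_path,
        "synthetic": None if config.synthetic is None else {
            k: (v if not isinstance(v, MetricConfig) else asdict(v))
            for k, v in asdict(config.synthetic).items()
        },
        "metrics": list(config.metrics),
        "lags": [int(v) for v in config.lags],
        "models": list(config.models),
        "train_fraction": config.train_fraction,
        "master_seed": int(config.master_seed),
        "shared_split": config.shared_split,
        "metric_config": asdict(config.metric_config),
        "mlp_config": asdict(config.mlp_config),
    }
    cell_entries = []
    for c in cells:
        cell_entries.append({
            "metric": c.metric,
            "lag_days": int(c.lag_days),
            "model": c.model_kind,
            "seed": int(c.seed),
            "rows": {k: int(v) for k, v in c.rows.items()},
            "error": c.error,
        })
    return {"config": cfg, "grid_size": config.grid_size, "cells": cell_entries}


def _curves_frame(cells) -> pd.DataFrame:
    rows = []
    for c in cells:
        if c.report is None or not c.report.roc_points:
            continue
        rep = c.report
        base = {"metric": c.metric, "lag_days": c.lag_days, "model": c.model_kind}
        for fx, fy in zip(rep.roc_points["fpr"], rep.roc_points["tpr"]):
            rows.append({**base, "curve": "roc", "x": fx, "y": fy})
        g = rep.gain_points
        for qx, gy in zip(g["q"], g["gain"]):
            rows.append({**base, "curve": "gain", "x": qx, "y": gy})
        for qx, ly in zip(g["lift_q"], g["lift"]):
            rows.append({**base, "curve": "lift", "x": qx, "y": ly})
    return pd.DataFrame(rows)


def write_bundle(bundle: ReportBundle, output_dir) -> None:
    """Write tables, curves and the manifest as deterministic text files."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for lag, table in bundle.logistic_tables.items():
        table.to_csv(out / f"logistic_lag{lag}.csv", index=False)
    for lag, table in bundle.mlp_tables.items():
        table.to_csv(out / f"mlp_lag{lag}.csv", index=False)
    bundle.summary.to_csv(out / "summary.csv", index=False)
    _curves_frame(bundle.cells).to_csv(out / "curves.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
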