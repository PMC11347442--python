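"""Lag-aligned single-metric datasets for injury classification.

The injury process may trail the workload exposure, so the metric measured
at day t is paired with the injury flag at day t + lag (lag in {0, 5, 10}
by default): the load precedes the label. Rows whose metric cell is invalid
(burn-in / degenerate) are dropped with counts kept, as are the final `lag`
days of each athlete, which have no future label. Predictors are
standardized over the full dataset before the uniform random 70/30 split;
labels are never transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import MetricPanel, METRIC_NAMES
from .training_log import TrainingLog

__all__ = [
    "LaggedDataset",
    "EmptyDatasetError",
    "DegenerateFeatureError",
    "SplitError",
    "align_labels",
    "standardize",
    "split",
]


class EmptyDatasetError(ValueError):
    """Alignment produced no rows (lag at or beyond the series length)."""


class DegenerateFeatureError(ValueError):
    """The predictor is constant and cannot be standardized."""


class SplitError(RuntimeError):
    """No usable train/test split found within the retry budget."""


@dataclass(frozen=True)
class LaggedDataset:
    """Single-metric feature vector with lag-aligned binary labels.

    ``frame`` columns: athlete_id, day_index (the metric's day), x, y, and —
    after :func:`split` — a 'split' column in {'train','test'}.
    ``standardization`` is the (mean, sd) applied to x, None before
    :func:`standardize`. ``dropped`` counts rows removed during alignment.
    """

    metric_name: str
    lag_days: int
    frame: pd.DataFrame
    standardization: Optional[tuple] = None
    dropped: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def x(self) -> np.ndarray:
        return self.frame["x"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=int)

    def part(self, which: str) -> pd.DataFrame:
        if "split" not in self.frame.columns:
            raise KeyError("dataset has no split assignment yet")
        return self.frame[self.frame["split"] == which]

    def write(self, path, *, delimiter: str = ",") -> None:
        out = self.frame.copy()
        out.insert(2, "metric", self.metric_name)
        out.insert(3, "lag", self.lag_days)
        out.to_csv(path, sep=delimiter, index=False)


def align_labels(panel: MetricPanel, log: TrainingLog, metric: str,
                 lag_days: int) -> LaggedDataset:
    """Pair metric(athlete, t) with injured(athlete, t + lag_days).

    Returns an unstandardized dataset; drops the per-athlete trailing
    ``lag_days`` rows (no future label) and all invalid metric cells,
    recording both counts in ``dropped``.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    if lag_days < 0:
        raise ValueError("lag_days must be >= 0")

    rows = []
    dropped = {"lag_trimmed": 0, "invalid_metric": 0, "raw": 0}
    mvals = panel.values.set_index(["athlete_id", "day_index"])[metric]
    for athlete in log.athlete_ids:
        sub = log.athlete_frame(athlete)
        injured = sub["injured"].to_numpy()
        n = len(sub)
        dropped["raw"] += n
        if lag_days >= n:
            dropped["lag_trimmed"] += n
            continue
        x = mvals.loc[athlete].to_numpy(dtype=float)[: n - lag_days]
        y = injured[lag_days:]
        valid = ~np.isnan(x)
        dropped["lag_trimmed"] += lag_days
        dropped["invalid_metric"] += int((~valid).sum())
        t = np.nonzero(valid)[0]
        rows.append(pd.DataFrame({
            "athlete_id": athlete,
            "day_index": t,
            "x": x[valid],
            "y": y[valid].astype(int),
        }))
    frame = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["athlete_id", "day_index", "x", "y"]))
    if frame.empty:
        raise EmptyDatasetError(
            f"lag {lag_days} leaves no labelled rows for metric {metric!r}"
        )
    return LaggedDataset(metric_name=metric, lag_days=lag_days, frame=frame,
                         dropped=dropped)


def standardize(dataset: LaggedDataset, *, mean: Optional[float] = None,
                sd: Optional[float] = None) -> LaggedDataset:
    """Center and scale x to zero mean / unit SD over all rows; y untouched.

    Statistics are computed on the full dataset (both future split halves),
    or taken from ``mean``/``sd`` when provided (e.g. to re-apply stored
    training statistics in a leakage-free workflow).
    """
    if len(dataset) < 2:
        raise DegenerateFeatureError("need at least 2 rows to standardize")
    x = dataset.x
    m = float(np.mean(x)) if mean is None else float(mean)
    s = float(np.std(x, ddof=1)) if sd is None else float(sd)
    if s == 0.0 or not np.isfinite(s):
        raise DegenerateFeatureError(
            f"constant predictor {dataset.metric_name!r} cannot be standardized"
        )
    frame = dataset.frame.assign(x=(x - m) / s)
    return replace(dataset, frame=frame, standardization=(m, s))


def split(dataset: LaggedDataset, train_fraction: float = 0.7, *,
          seed: int, max_retries: int = 20) -> LaggedDataset:
    """Uniform random row-level train/test assignment.

    round(n * train_fraction) rows go to train; the same seed reproduces the
    same assignment. If train ends up single-class the draw is retried (with
    a warning) up to ``max_retries`` times before raising :class:`SplitError`.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    n_train = int(round(n * train_fraction))
    y = dataset.y
    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        perm = rng.permutation(n)
        assignment = np.full(n, "test", dtype=object)
        assignment[perm[:n_train]] = "train"
        if len(np.unique(y[assignment == "train"])) > 1:
            if attempt:
                warnings.warn(
                    f"single-class train draw; resampled {attempt} time(s)",
                    RuntimeWarning, stacklevel=2,
                )
            return replace(dataset, frame=dataset.frame.assign(split=assignment))
    raise SplitError(
        f"could not draw a two-class training set in {max_retries} retries"
    )
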