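"""The seven session-RPE-derived workload metrics as daily rolling series.

All metrics are evaluated every day on trailing windows of one athlete's
daily workload series (athletes never share windows):

* ``acwr_coupled`` — trailing 7-day load sum over the mean of the 4 trailing
  non-overlapping 7-day block sums, the acute week included ("coupled").
* ``acwr_uncoupled`` — the same acute sum over the mean of the 3 blocks
  strictly preceding the acute week.
* ``diff`` — weekly ratio of workload change: trailing 7-day sum over the
  preceding 7-day sum.
* ``monotony`` — within-week load uniformity: mean of the trailing 7 daily
  loads over their standard deviation (Foster's convention).
* ``sd_delta`` — z-score-style deviation of the acute weekly sum from the
  mean of the trailing weekly block sums, divided by their SD (or, as a
  literal variant, their variance).
* ``ewma_acwr`` — trailing 7-day mean of the exponentially weighted moving
  average of daily load over its trailing 28-day mean, with smoothing
  lambda = 2/(N+1), decay time N = 5.
* ``redi_acwr`` — the same 7-day/28-day ratio built on the robust
  exponential decreasing index, a weighted mean of the last
  ``redi_window_days`` loads with weights e^(-i) zeroed on missing
  (rest/stoppage) days.

A cell is *invalid* — NaN value plus a reason string — exactly when its full
look-back window is unavailable (burn-in) or a denominator is degenerate.
Degenerate cells never become +/-inf; downstream model matrices stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .training_log import TrainingLog

__all__ = [
    "MetricConfig",
    "MetricPanel",
    "METRIC_NAMES",
    "acute_load",
    "coupled_acwr",
    "uncoupled_acwr",
    "weekly_change_ratio",
    "monotony",
    "sd_delta",
    "ewma_series",
    "ewma_acwr",
    "redi_series",
    "redi_acwr",
    "metric_series",
    "compute_all_metrics",
]

METRIC_NAMES = (
    "acwr_coupled",
    "acwr_uncoupled",
    "diff",
    "monotony",
    "sd_delta",
    "ewma_acwr",
    "redi_acwr",
)

# invalid-cell reason codes
BURN_IN = "burn_in"
ZERO_CHRONIC = "zero_chronic_load"
ZERO_PREVIOUS_WEEK = "zero_previous_week"
ZERO_VARIABILITY = "zero_variability"
ALL_MISSING = "all_missing"


@dataclass(frozen=True)
class MetricConfig:
    """Window and convention choices for the seven metrics.

    Defaults follow the common field conventions: 7-day acute window, 4-week
    coupled chronic window, 3 prior weeks uncoupled, EWMA decay time N=5
    (lambda = 2/(N+1) = 1/3), REDI look-back of one 5-day microcycle, and
    sample (n-1) standard deviations.
    """

    acute_window_days: int = 7
    chronic_weeks_coupled: int = 4
    chronic_weeks_uncoupled: int = 3
    ewma_N: int = 5
    ewma_form: str = "standard"  # or "literal"
    redi_window_days: int = 5
    sd_convention: str = "sample"  # or "population"
    sddelta_denominator: str = "sd"  # or "variance"

    def __post_init__(self):
        if self.ewma_form not in ("standard", "literal"):
            raise ValueError(f"ewma_form must be 'standard' or 'literal', got {self.ewma_form!r}")
        if self.sd_convention not in ("sample", "population"):
            raise ValueError(f"unknown sd_convention {self.sd_convention!r}")
        if self.sddelta_denominator not in ("sd", "variance"):
            raise ValueError(f"unknown sddelta_denominator {self.sddelta_denominator!r}")
        if not 0.0 < self.ewma_lambda < 1.0:
            raise ValueError(f"ewma_lambda = 2/(N+1) must lie in (0,1); ewma_N={self.ewma_N}")

    @property
    def ewma_lambda(self) -> float:
        return 2.0 / (self.ewma_N + 1.0)

    @property
    def _ddof(self) -> int:
        return 1 if self.sd_convention == "sample" else 0

    @property
    def chronic_window_days(self) -> int:
        """Total trailing days the widest metrics need (28 by default)."""
        return self.acute_window_days * self.chronic_weeks_coupled


DEFAULT_CONFIG = MetricConfig()


def _cfg(config: Optional[MetricConfig]) -> MetricConfig:
    return DEFAULT_CONFIG if config is None else config


def _series(series) -> np.ndarray:
    w = np.asarray(series, dtype=float)
    if w.ndim != 1:
        raise ValueError("workload series must be one-dimensional")
    return w


# ---------------------------------------------------------------------------
# per-day metric cells: each returns (value, reason); reason is None iff valid
# ---------------------------------------------------------------------------

def _acute_cell(w, day, window):
    if day < window - 1:
        return np.nan, BURN_IN
    return float(w[day - window + 1 : day + 1].sum()), None


def _block_sums(w, day, window, n_blocks):
    """Trailing non-overlapping `window`-day block sums, most recent first."""
    return [float(w[day - (k + 1) * window + 1 : day - k * window + 1].sum())
            for k in range(n_blocks)]


def _coupled_cell(w, day, cfg):
    win = cfg.acute_window_days
    nb = cfg.chronic_weeks_coupled
    if day < win * nb - 1:
        return np.nan, BURN_IN
    blocks = _block_sums(w, day, win, nb)
    chronic = float(np.mean(blocks))
    if chronic == 0.0:
        return np.nan, ZERO_CHRONIC
    return blocks[0] / chronic, None


def _uncoupled_cell(w, day, cfg):
    win = cfg.acute_window_days
    nb = cfg.chronic_weeks_uncoupled
    if day < win * (nb + 1) - 1:
        return np.nan, BURN_IN
    blocks = _block_sums(w, day, win, nb + 1)
    chronic = float(np.mean(blocks[1:]))
    if chronic == 0.0:
        return np.nan, ZERO_CHRONIC
    return blocks[0] / chronic, None


def _diff_cell(w, day, cfg):
    win = cfg.acute_window_days
    if day < 2 * win - 1:
        return np.nan, BURN_IN
    last, prev = _block_sums(w, day, win, 2)
    if prev == 0.0:
        return np.nan, ZERO_PREVIOUS_WEEK
    return last / prev, None


def _monotony_cell(w, day, cfg):
    win = cfg.acute_window_days
    if day < win - 1:
        return np.nan, BURN_IN
    daily = w[day - win + 1 : day + 1]
    sd = float(np.std(daily, ddof=cfg._ddof))
    if sd == 0.0:
        return np.nan, ZERO_VARIABILITY
    return float(np.mean(daily)) / sd, None


def _sd_delta_cell(w, day, cfg):
    win = cfg.acute_window_days
    nb = cfg.chronic_weeks_coupled
    if day < win * nb - 1:
        return np.nan, BURN_IN
    blocks = np.array(_block_sums(w, day, win, nb))
    num = float(blocks[0] - blocks.mean())
    if num == 0.0:
        # exact fixed point: acute week at the historical mean scores 0 even
        # when the block SD is degenerate (constant load)
        return 0.0, None
    sd = float(np.std(blocks, ddof=cfg._ddof))
    if sd == 0.0:
        return np.nan, ZERO_VARIABILITY
    denom = sd if cfg.sddelta_denominator == "sd" else sd * sd
    return num / denom, None


def ewma_series(series, config: Optional[MetricConfig] = None) -> np.ndarray:
    """Daily exponentially weighted moving average of the workload series.

    Standard form (default): E_t = lambda*W_t + (1-lambda)*E_{t-1}, E_0 = W_0.
    Literal form: P_t = W_t + (1-lambda)*P_{t-1}, initialized P_0 = W_0/lambda
    so that P_t = E_t/lambda for every t; the scale cancels in the
    acute:chronic ratio, so both forms yield identical ``ewma_acwr``.
    """
    cfg = _cfg(config)
    w = _series(series)
    if w.size == 0:
        raise ValueError("series must be non-empty")
    lam = cfg.ewma_lambda
    out = np.empty_like(w)
    if cfg.ewma_form == "standard":
        out[0] = w[0]
        for t in range(1, w.size):
            out[t] = lam * w[t] + (1.0 - lam) * out[t - 1]
    else:
        out[0] = w[0] / lam
        for t in range(1, w.size):
            out[t] = w[t] + (1.0 - lam) * out[t - 1]
    return out


def _ewma_acwr_cell(e, day, cfg):
    chronic_days = cfg.chronic_window_days
    if day < chronic_days - 1:
        return np.nan, BURN_IN
    acute = float(np.mean(e[day - cfg.acute_window_days + 1 : day + 1]))
    chronic = float(np.mean(e[day - chronic_days + 1 : day + 1]))
    if chronic == 0.0:
        return np.nan, ZERO_CHRONIC
    return acute / chronic, None


def redi_series(series, rest_mask=None, config: Optional[MetricConfig] = None) -> np.ndarray:
    """Daily robust exponential decreasing index of the workload series.

    REDI_t is the weighted mean of the last ``redi_window_days`` daily loads
    with weights alpha_i = e^(-i) (i = 0 for today), where alpha_i is zeroed
    for *missing* days so that gaps do not drag the index down; the remaining
    weights renormalize. ``rest_mask`` marks missing days (scheduled rest or
    injury stoppage); by default every 0 A.U. day is treated as missing,
    since a true zero-load training day is indistinguishable in the log.
    Days whose whole window is missing are NaN.
    """
    cfg = _cfg(config)
    w = _series(series)
    if w.size == 0:
        raise ValueError("series must be non-empty")
    if rest_mask is None:
        rest_mask = w == 0.0
    else:
        rest_mask = np.asarray(rest_mask, dtype=bool)
        if rest_mask.shape != w.shape:
            raise ValueError("rest_mask must match the series shape")
    K = cfg.redi_window_days
    alpha = np.exp(-np.arange(K, dtype=float))
    out = np.full_like(w, np.nan)
    for t in range(w.size):
        lo = max(0, t - K + 1)
        idx = np.arange(t, lo - 1, -1)  # i = 0 .. window-1 back in time
        a = alpha[: idx.size].copy()
        a[rest_mask[idx]] = 0.0
        denom = a.sum()
        if denom > 0.0:
            out[t] = float(a @ w[idx]) / denom
    return out


def _redi_acwr_cell(r, day, cfg):
    chronic_days = cfg.chronic_window_days
    if day < chronic_days - 1:
        return np.nan, BURN_IN
    acute = r[day - cfg.acute_window_days + 1 : day + 1]
    chronic = r[day - chronic_days + 1 : day + 1]
    if np.all(np.isnan(acute)) or np.all(np.isnan(chronic)):
        return np.nan, ALL_MISSING
    a = float(np.nanmean(acute))
    c = float(np.nanmean(chronic))
    if c == 0.0:
        return np.nan, ZERO_CHRONIC
    return a / c, None


# ---------------------------------------------------------------------------
# public per-day operations (NaN marks an invalid cell; no exceptions for
# insufficient history or degenerate denominators)
# ---------------------------------------------------------------------------

def acute_load(series, day: int, window: int = 7) -> float:
    """Trailing ``window``-day workload sum ending at ``day`` (inclusive)."""
    return _acute_cell(_series(series), day, window)[0]


def coupled_acwr(series, day: int, config: Optional[MetricConfig] = None) -> float:
    return _coupled_cell(_series(series), day, _cfg(config))[0]


def uncoupled_acwr(series, day: int, config: Optional[MetricConfig] = None) -> float:
    return _uncoupled_cell(_series(series), day, _cfg(config))[0]


def weekly_change_ratio(series, day: int, config: Optional[MetricConfig] = None) -> float:
    return _diff_cell(_series(series), day, _cfg(config))[0]


def monotony(series, day: int, config: Optional[MetricConfig] = None) -> float:
    return _monotony_cell(_series(series), day, _cfg(config))[0]


def sd_delta(series, day: int, config: Optional[MetricConfig] = None) -> float:
    return _sd_delta_cell(_series(series), day, _cfg(config))[0]


def ewma_acwr(series, day: int, config: Optional[MetricConfig] = None) -> float:
    cfg = _cfg(config)
    return _ewma_acwr_cell(ewma_series(series, cfg), day, cfg)[0]


def redi_acwr(series, day: int, config: Optional[MetricConfig] = None,
              rest_mask=None) -> float:
    cfg = _cfg(config)
    return _redi_acwr_cell(redi_series(series, rest_mask, cfg), day, cfg)[0]


def metric_series(series, name: str, config: Optional[MetricConfig] = None,
                  rest_mask=None):
    """One metric's full daily series for one athlete.

    Returns ``(values, reasons)``: a float array with NaN at invalid days and
    an object array with the reason string there (None where valid).
    """
    cfg = _cfg(config)
    w = _series(series)
    if name not in METRIC_NAMES:
        raise KeyError(f"unknown metric {name!r}; expected one of {METRIC_NAMES}")
    if name == "ewma_acwr":
        e = ewma_series(w, cfg)
        cells = [_ewma_acwr_cell(e, t, cfg) for t in range(w.size)]
    elif name == "redi_acwr":
        r = redi_series(w, rest_mask, cfg)
        cells = [_redi_acwr_cell(r, t, cfg) for t in range(w.size)]
    else:
        fn = {
            "acwr_coupled": _coupled_cell,
            "acwr_uncoupled": _uncoupled_cell,
            "diff": _diff_cell,
            "monotony": _monotony_cell,
            "sd_delta": _sd_delta_cell,
        }[name]
        cells = [fn(w, t, cfg) for t in range(w.size)]
    values = np.array([c[0] for c in cells], dtype=float)
    reasons = np.array([c[1] for c in cells], dtype=object)
    return values, reasons


@dataclass(frozen=True)
class MetricPanel:
    """Per athlete-day values of the seven metrics with validity bookkeeping.

    ``values`` has columns athlete_id, day_index, the seven metric names,
    and the raw intermediates ewma_value / redi_value; invalid metric cells
    are NaN. ``reasons`` mirrors the metric columns with the reason string
    for each invalid cell (None where valid).
    """

    values: pd.DataFrame
    reasons: pd.DataFrame
    config: MetricConfig = field(default_factory=MetricConfig)

    def metric(self, name: str) -> pd.DataFrame:
        """athlete_id, day_index, value, valid, invalid_reason for one metric."""
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        out = self.values[["athlete_id", "day_index", name]].rename(columns={name: "value"})
        out["valid"] = self.reasons[name].isna()
        out["invalid_reason"] = self.reasons[name].where(~out["valid"], None)
        return out

    def to_long_frame(self) -> pd.DataFrame:
        parts = []
        for name in METRIC_NAMES:
            sub = self.metric(name)
            sub.insert(2, "metric", name)
            parts.append(sub)
        return pd.concat(parts, ignore_index=True)

    def write(self, path, *, delimiter: str = ",") -> None:
        self.to_long_frame().to_csv(path, sep=delimiter, index=False)


def compute_all_metrics(log: TrainingLog, config: Optional[MetricConfig] = None) -> MetricPanel:
    """Evaluate all seven metrics for every athlete-day of a validated log."""
    cfg = _cfg(config)
    val_parts, reason_parts = [], []
    for athlete in log.athlete_ids:
        w = log.workload_series(athlete)
        vals = {"athlete_id": athlete, "day_index": np.arange(w.size)}
        reas = {"athlete_id": athlete, "day_index": np.arange(w.size)}
        vals["ewma_value"] = ewma_series(w, cfg)
        vals["redi_value"] = redi_series(w, config=cfg)
        for name in METRIC_NAMES:
            v, r = metric_series(w, name, cfg)
            vals[name] = v
            reas[name] = r
        val_parts.append(pd.DataFrame(vals))
        reason_parts.append(pd.DataFrame(reas))
    values = pd.concat(val_parts, ignore_index=True)
    reasons = pd.concat(reason_parts, ignore_index=True)
    return MetricPanel(values=values, reasons=reasons, config=cfg)
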