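"""Synthetic training-log cohorts with a metric-driven injury process.

The generator emulates the structure the analysis assumes: a squad of
athletes logged daily over consecutive days, training organised in short
microcycles whose last day is rest (0 A.U.), slowly ramping load blocks so
chronic windows have real dynamic range, and a Bernoulli injury process
whose log-odds are linear in one chosen (standardized) workload metric at a
chosen lag:

    P(injured at t + lag) = expit(beta0 + beta1 * z_t)

Generation is sequential in time: z_t is the driving metric evaluated on
the athlete's *realized* workload history up to day t — including the 0
A.U. days a previous injury stoppage has already forced — standardized
with moments taken from a pilot (injury-free) cohort drawn from the same
seed. Recomputing the driving metric from the emitted log therefore
reproduces the very values the hazard saw; there is no hidden counterfactual
load series. Days without a defined source value (metric burn-in, or
t < lag) use the baseline rate expit(beta0). Everything is reproducible
from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .metrics import (
    MetricConfig,
    METRIC_NAMES,
    metric_series,
    _coupled_cell,
    _uncoupled_cell,
    _diff_cell,
    _monotony_cell,
    _sd_delta_cell,
    _ewma_acwr_cell,
    _redi_acwr_cell,
)
from .training_log import TrainingLog

__all__ = ["SyntheticConfig", "CalibrationError", "generate_cohort", "calibrate_beta0"]

#: Default injury prevalence target: the 38:174 injury:non-injury ratio.
DEFAULT_PREVALENCE = 38.0 / 212.0

_WORKLOAD_STREAM = 0x10AD
_INJURY_STREAM = 0xF00D

_PER_DAY_CELLS = {
    "acwr_coupled": _coupled_cell,
    "acwr_uncoupled": _uncoupled_cell,
    "diff": _diff_cell,
    "monotony": _monotony_cell,
    "sd_delta": _sd_delta_cell,
}


class CalibrationError(RuntimeError):
    """Baseline-hazard calibration failed to bracket the target prevalence."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort shape, load distributions and injury-hazard parameters.

    Defaults mirror the study conditions the pipeline is exercised under:
    8 athletes over 211 consecutive days, 5-day microcycles with the fifth
    day rest, and a baseline hazard at the 38:212 injury:sample ratio.
    Load magnitudes (CR-10 mean 5 +/- 1.5, sessions 90 +/- 20 min) are a
    realistic team-sport scale; the field attaches no canonical A.U. range.
    ``block_amplitude`` is the relative amplitude of a slow sinusoidal ramp
    of mean session duration across mesocycles (period ``block_period_days``)
    so ACWR-family metrics move through a realistic range. After each injury
    the next 0..``stoppage_days_max`` days (uniform draw) are forced to
    0 A.U., emulating short injury stoppages.
    """

    n_athletes: int = 8
    n_days: int = 211
    microcycle_days: int = 5
    rpe_mean: float = 5.0
    rpe_sd: float = 1.5
    duration_mean: float = 90.0
    duration_sd: float = 20.0
    block_amplitude: float = 0.3
    block_period_days: int = 42
    driving_metric: str = "ewma_acwr"
    hazard_beta0: float = logit(DEFAULT_PREVALENCE)
    hazard_beta1: float = 1.0
    hazard_lag_days: int = 0
    stoppage_days_max: int = 3
    seed: int = 0
    metric_config: MetricConfig = field(default_factory=MetricConfig)

    def __post_init__(self):
        if self.driving_metric not in METRIC_NAMES:
            raise ValueError(f"unknown driving_metric {self.driving_metric!r}")
        if not 0.0 < expit(self.hazard_beta0) < 1.0:
            raise ValueError("hazard_beta0 must give a baseline probability in (0,1)")
        if self.n_days < self.metric_config.chronic_window_days + self.hazard_lag_days:
            raise ValueError(
                "n_days must cover the chronic burn-in plus the hazard lag "
                f"({self.metric_config.chronic_window_days + self.hazard_lag_days} days)"
            )
        if self.microcycle_days < 2:
            raise ValueError("microcycle_days must be >= 2 (training + rest)")
        if self.stoppage_days_max < 0:
            raise ValueError("stoppage_days_max must be >= 0")


def _simulate_workloads(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """RPE/duration/workload rows for the whole cohort, before injuries."""
    parts = []
    for a in range(config.n_athletes):
        t = np.arange(config.n_days)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ramp = 1.0 + config.block_amplitude * np.sin(
            2.0 * np.pi * t / config.block_period_days + phase
        )
        rpe = np.clip(np.round(rng.normal(config.rpe_mean, config.rpe_sd, config.n_days)),
                      0.0, 10.0)
        dur = np.clip(rng.normal(config.duration_mean * ramp, config.duration_sd),
                      0.0, None)
        rest = (t % config.microcycle_days) == (config.microcycle_days - 1)
        rpe[rest] = 0.0
        dur[rest] = 0.0
        parts.append(pd.DataFrame({
            "athlete_id": f"ath{a:02d}",
            "day_index": t,
            "rpe": rpe,
            "duration_min": dur,
        }))
    frame = pd.concat(parts, ignore_index=True)
    frame["workload"] = frame["rpe"] * frame["duration_min"]
    return frame


def _driving_values(frame: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Raw driving-metric value per row (NaN where undefined)."""
    vals = np.full(len(frame), np.nan)
    for _, sub in frame.groupby("athlete_id", sort=False):
        w = sub["workload"].to_numpy(dtype=float)
        v, _ = metric_series(w, config.driving_metric, config.metric_config)
        vals[sub.index.to_numpy()] = v
    return vals


def _metric_moments(frame: pd.DataFrame, config: SyntheticConfig) -> tuple:
    """(mean, sd) of the driving metric over its valid pilot-cohort cells."""
    vals = _driving_values(frame, config)
    valid = vals[~np.isnan(vals)]
    if valid.size < 2:
        raise CalibrationError("pilot cohort has no valid driving-metric cells")
    return float(valid.mean()), float(valid.std(ddof=1))


def _sequential_injuries(rpe, dur, mu, sd, config: SyntheticConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Day-by-day injury draw with stoppage feedback, for one athlete.

    Mutates ``rpe``/``dur`` in place when a stoppage zeroes a day; returns
    the injury labels. The driving metric at day t is evaluated on the
    realized workload history w[0..t]; its standardized value drives the
    label at day t + lag.
    """
    cfg = config.metric_config
    T = rpe.size
    lag = config.hazard_lag_days
    lam = cfg.ewma_lambda
    name = config.driving_metric
    alpha = np.exp(-np.arange(cfg.redi_window_days, dtype=float))
    p_base = expit(config.hazard_beta0)

    w = rpe * dur
    injured = np.zeros(T, dtype=np.int64)
    if lag > 0:
        injured[:min(lag, T)] = rng.binomial(1, p_base, size=min(lag, T))

    e = np.empty(T)  # running EWMA (standard form) of realized load
    r = np.empty(T)  # running REDI of realized load
    stop_until = -1
    for t in range(T):
        if t <= stop_until:
            rpe[t] = dur[t] = w[t] = 0.0
        e[t] = w[t] if t == 0 else lam * w[t] + (1.0 - lam) * e[t - 1]
        lo = max(0, t - cfg.redi_window_days + 1)
        ww = w[lo:t + 1][::-1]  # i = 0 (today) .. back in time
        a = alpha[:ww.size].copy()
        a[ww == 0.0] = 0.0
        r[t] = (a @ ww) / a.sum() if a.sum() > 0.0 else np.nan

        if name == "ewma_acwr":
            v = _ewma_acwr_cell(e, t, cfg)[0]
        elif name == "redi_acwr":
            v = _redi_acwr_cell(r, t, cfg)[0]
        else:
            v = _PER_DAY_CELLS[name](w, t, cfg)[0]
        z = (v - mu) / sd if np.isfinite(v) and sd > 0.0 else 0.0

        if t + lag < T:
            p = expit(config.hazard_beta0 + config.hazard_beta1 * z)
            injured[t + lag] = rng.binomial(1, p)
        if injured[t] and config.stoppage_days_max > 0:
            k = int(rng.integers(0, config.stoppage_days_max + 1))
            stop_until = max(stop_until, t + k)
    return injured


def generate_cohort(config: SyntheticConfig) -> TrainingLog:
    """Draw one cohort: workloads, metric-driven lagged injuries, stoppages.

    The injury label at (athlete, t) is Bernoulli(expit(beta0 + beta1 *
    z_{t-lag})) with z the athlete's standardized driving metric on the
    realized load history; standardization moments come from an injury-free
    pilot cohort drawn from the same seed. After each injury, 0 to
    ``stoppage_days_max`` following days are zeroed (RPE, duration,
    workload) to emulate injury stoppages scored as 0 A.U.; the labels
    themselves are left as drawn.
    """
    rng_w = np.random.default_rng(np.random.SeedSequence([int(config.seed), _WORKLOAD_STREAM]))
    frame = _simulate_workloads(config, rng_w)
    mu, sd = _metric_moments(frame, config)

    rng_i = np.random.default_rng(np.random.SeedSequence([int(config.seed), _INJURY_STREAM]))
    injured_all = np.zeros(len(frame), dtype=np.int64)
    rpe_all = frame["rpe"].to_numpy(dtype=float).copy()
    dur_all = frame["duration_min"].to_numpy(dtype=float).copy()
    for _, sub in frame.groupby("athlete_id", sort=False):
        idx = sub.index.to_numpy()
        rpe, dur = rpe_all[idx], dur_all[idx]
        injured_all[idx] = _sequential_injuries(rpe, dur, mu, sd, config, rng_i)
        rpe_all[idx], dur_all[idx] = rpe, dur

    prevalence = injured_all.mean()
    if prevalence == 0.0 or prevalence == 1.0:
        warnings.warn(
            f"hazard parameters produced degenerate prevalence {prevalence:g}",
            RuntimeWarning, stacklevel=2,
        )

    frame["rpe"] = rpe_all
    frame["duration_min"] = dur_all
    frame["workload"] = rpe_all * dur_all
    frame["injured"] = injured_all
    return TrainingLog.from_frame(frame)


def calibrate_beta0(target_prevalence: float, config: SyntheticConfig,
                    *, bracket: tuple = (-20.0, 20.0)) -> float:
    """Baseline log-odds beta0 whose pilot-cohort mean hazard hits the target.

    Draws one injury-free pilot cohort's standardized driving-metric values
    z (workloads do not depend on beta0) and solves

        mean(expit(beta0 + beta1 * z)) = target_prevalence

    by root bracketing; the mean hazard is continuous and strictly
    increasing in beta0, so the root is unique. Rows whose lag-source value
    is undefined enter at the baseline rate (z = 0), as in generation.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _WORKLOAD_STREAM]))
    frame = _simulate_workloads(config, rng)
    mu, sd = _metric_moments(frame, config)
    vals = _driving_values(frame, config)
    z = np.where(np.isnan(vals) | (sd <= 0.0), 0.0, (vals - mu) / (sd if sd > 0 else 1.0))

    lag = config.hazard_lag_days
    z_src = np.zeros(len(z))
    for _, sub in frame.groupby("athlete_id", sort=False):
        idx = sub.index.to_numpy()
        if lag < idx.size:
            z_src[idx[lag:]] = z[idx[: idx.size - lag]]

    def gap(b0):
        return float(np.mean(expit(b0 + config.hazard_beta1 * z_src))) - target_prevalence

    lo, hi = bracket
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target prevalence {target_prevalence:g} not bracketed by beta0 in {bracket}"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))
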