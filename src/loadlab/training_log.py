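"""Daily session-RPE training logs: ingestion, validation, derived workload.

A training log holds exactly one row per athlete-day. Each row carries the
post-session rating of perceived exertion on Borg's CR-10 scale (0-10), the
session duration in minutes, and a binary injury indicator. The daily
workload, in arbitrary units (A.U.), is the session-RPE product

    workload = RPE x duration (min)

Rest days and injury stoppages are encoded as explicit rows with 0 A.U.
(RPE 0, duration 0); a physically absent athlete-day is a data error, so
per-athlete day indices must form a gap-free ascending sequence and every
athlete must cover the same number of days. Multiple sessions on one day
must be pre-summed upstream into the single daily row.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "IntegrityError",
    "TrainingLog",
    "compute_daily_workload",
    "read_training_log",
    "write_training_log",
]

#: Columns a log file must provide (plus either ``day_index`` or ``date``).
REQUIRED_COLUMNS = ("athlete_id", "rpe", "duration_min", "injured")

#: Canonical column order of the in-memory frame and the written file.
CANONICAL_COLUMNS = (
    "athlete_id",
    "day_index",
    "rpe",
    "duration_min",
    "injured",
    "workload",
)

RPE_MAX = 10.0


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """A field value is outside its physiological/encoding range."""


class IntegrityError(ValueError):
    """Duplicate or gapped athlete-day structure."""


def compute_daily_workload(rpe: float, duration_min: float) -> float:
    """Session-RPE workload in A.U.: ``rpe * duration_min``.

    Parameters
    ----------
    rpe : float
        CR-10 rating, must lie in [0, 10].
    duration_min : float
        Session duration in minutes, must be >= 0.
    """
    if not isinstance(rpe, Real) or not isinstance(duration_min, Real):
        raise TypeError("rpe and duration_min must be real numbers")
    if not 0.0 <= float(rpe) <= RPE_MAX:
        raise ValidationError(f"rpe={rpe!r} outside the CR-10 range [0, {RPE_MAX:g}]")
    if float(duration_min) < 0.0:
        raise ValidationError(f"duration_min={duration_min!r} must be >= 0")
    return float(rpe) * float(duration_min)


@dataclass(frozen=True)
class TrainingLog:
    """Validated per-athlete daily records with derived workload.

    ``frame`` is sorted by (athlete_id, day_index) and has the columns of
    :data:`CANONICAL_COLUMNS`. Construct via :meth:`from_frame` or
    :func:`read_training_log`; the bare constructor performs no checks.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrainingLog":
        return cls(_validate(frame))

    @property
    def athlete_ids(self) -> list:
        return list(pd.unique(self.frame["athlete_id"]))

    @property
    def n_athletes(self) -> int:
        return self.frame["athlete_id"].nunique()

    @property
    def n_days(self) -> int:
        return 0 if self.frame.empty else int(self.frame["day_index"].max()) + 1

    def __len__(self) -> int:
        return len(self.frame)

    def athlete_frame(self, athlete_id) -> pd.DataFrame:
        sub = self.frame[self.frame["athlete_id"] == athlete_id]
        if sub.empty:
            raise KeyError(f"unknown athlete_id {athlete_id!r}")
        return sub.reset_index(drop=True)

    def workload_series(self, athlete_id) -> np.ndarray:
        """Daily workload of one athlete as a dense float array indexed by day."""
        return self.athlete_frame(athlete_id)["workload"].to_numpy(dtype=float)


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()

    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
    if "day_index" not in frame.columns:
        if "date" not in frame.columns:
            raise SchemaError("missing required column 'day_index' (or 'date')")
        frame = _dates_to_day_index(frame)

    for col in ("day_index", "rpe", "duration_min", "injured"):
        frame[col] = pd.to_numeric(frame[col], errors="raise")

    bad = frame.index[(frame["rpe"] < 0) | (frame["rpe"] > RPE_MAX) | frame["rpe"].isna()]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: rpe={frame.loc[bad[0], 'rpe']!r} outside the CR-10 range [0, 10]"
        )
    bad = frame.index[(frame["duration_min"] < 0) | frame["duration_min"].isna()]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: duration_min={frame.loc[bad[0], 'duration_min']!r} must be >= 0"
        )
    bad = frame.index[~frame["injured"].isin((0, 1))]
    if len(bad):
        raise ValidationError(
            f"row {bad[0]}: injured={frame.loc[bad[0], 'injured']!r} must be 0 or 1"
        )
    if (frame["day_index"] < 0).any() or (frame["day_index"] % 1 != 0).any():
        raise ValidationError("day_index must be a non-negative integer")

    frame["day_index"] = frame["day_index"].astype(np.int64)
    frame["injured"] = frame["injured"].astype(np.int64)
    frame["rpe"] = frame["rpe"].astype(float)
    frame["duration_min"] = frame["duration_min"].astype(float)

    dup = frame.duplicated(subset=["athlete_id", "day_index"])
    if dup.any():
        a, d = frame.loc[dup.idxmax(), ["athlete_id", "day_index"]]
        raise IntegrityError(f"duplicate athlete-day ({a!r}, day {d})")

    frame = frame.sort_values(["athlete_id", "day_index"], kind="stable").reset_index(drop=True)

    n_days = None
    for athlete, sub in frame.groupby("athlete_id", sort=False):
        days = sub["day_index"].to_numpy()
        if days[0] != 0 or not np.array_equal(days, np.arange(len(days))):
            raise IntegrityError(
                f"athlete {athlete!r}: day_index must run 0..n-1 without gaps "
                "(encode rest/stoppage days as explicit 0 A.U. rows)"
            )
        if n_days is None:
            n_days = len(days)
        elif len(days) != n_days:
            raise IntegrityError(
                f"athlete {athlete!r} has {len(days)} days, expected {n_days}"
            )

    derived = frame["rpe"].to_numpy() * frame["duration_min"].to_numpy()
    if "workload" in frame.columns:
        given = pd.to_numeric(frame["workload"], errors="raise").to_numpy(dtype=float)
        if not np.allclose(given, derived, rtol=0, atol=1e-9):
            i = int(np.argmax(np.abs(given - derived)))
            raise ValidationError(
                f"row {i}: workload={given[i]!r} != rpe*duration_min={derived[i]!r}"
            )
    frame["workload"] = derived
    return frame[list(CANONICAL_COLUMNS)]


def _dates_to_day_index(frame: pd.DataFrame) -> pd.DataFrame:
    """Convert an ISO-8601 ``date`` column into per-athlete 0-based day indices."""
    dates = pd.to_datetime(frame["date"], format="ISO8601")
    frame = frame.assign(_date=dates).sort_values(["athlete_id", "_date"], kind="stable")
    out = []
    for athlete, sub in frame.groupby("athlete_id", sort=False):
        delta = (sub["_date"] - sub["_date"].iloc[0]).dt.days
        out.append(sub.assign(day_index=delta.to_numpy()))
    frame = pd.concat(out, ignore_index=True)
    return frame.drop(columns=["date", "_date"])


def read_training_log(path, *, delimiter: str = ",") -> TrainingLog:
    """Read a delimited-text training log and return a validated :class:`TrainingLog`.

    The file must have a header with athlete_id, rpe, duration_min, injured and
    either day_index or date (ISO-8601). A workload column, if present, is
    checked against rpe*duration_min; otherwise it is derived.
    """
    frame = pd.read_csv(path, delimiter=delimiter)
    return TrainingLog.from_frame(frame)


def write_training_log(log: TrainingLog, path, *, delimiter: str = ",") -> None:
    """Write the canonical schema (including derived workload) as delimited text."""
    log.frame.to_csv(path, sep=delimiter, index=False)
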