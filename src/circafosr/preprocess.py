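"""Epoch-level actigraphy I/O, aggregation to the 5-minute grid, and day QC.

The modelling grid is 288 five-minute epochs per day: epoch ``t`` covers clock
time ``[5t, 5t+5)`` minutes after midnight, ``t = 0..287`` (0-based,
half-open).  Raw device exports at 60-second epochs are aggregated by summing
the five constituent minutes, which conserves the daily total count.  The
model operates on ``log(1 + count)``, the standard variance-stabilising
transform for skewed activity counts.

Day-level quality control: recordings occasionally contain implausible zero
runs scattered through waking hours (device removed or malfunctioning).  A
day is flagged invalid when the fraction of zero-count epochs inside a
daytime window (default 08:00-22:00) exceeds a threshold (default 0.5).  A
subject is excluded only when every one of their days is invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_EPOCHS",
    "MINUTES_PER_DAY",
    "EpochDay",
    "CovariateRow",
    "aggregate_minutes",
    "log_transform",
    "detect_invalid_day",
    "screen_days",
    "read_epoch_csv",
    "write_epoch_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "split_to_minutes",
    "epoch_to_clock",
]

logger = logging.getLogger(__name__)

N_EPOCHS = 288
MINUTES_PER_DAY = 1440
_MINUTES_PER_EPOCH = 5

DAYTIME_WINDOW = (96, 264)  # epochs covering 08:00-22:00, half-open
MAX_ZERO_FRACTION = 0.5


def epoch_to_clock(epoch: int) -> str:
    """Clock label HH:MM of the start of 5-minute epoch ``epoch`` (0..287)."""
    minutes = (int(epoch) % N_EPOCHS) * _MINUTES_PER_EPOCH
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


@dataclass
class EpochDay:
    """One subject-day of activity counts on the 288-slot 5-minute grid."""

    subject_id: str
    day_index: int
    counts: np.ndarray
    date: str | None = None
    valid: bool = True
    log_counts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (N_EPOCHS,):
            raise ValueError(
                f"counts must have length {N_EPOCHS}, got shape {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        self.counts = counts
        self.log_counts = np.log1p(counts)


@dataclass(frozen=True)
class CovariateRow:
    """Scalar covariates of one subject (group indicator, age, sex)."""

    subject_id: str
    group: int
    age: float
    sex: int

    def __post_init__(self) -> None:
        if self.group not in (0, 1):
            raise ValueError(f"group must be 0 or 1, got {self.group}")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex}")
        if not 18 <= self.age <= 120:
            raise ValueError(f"age {self.age} outside plausible range [18, 120]")


def aggregate_minutes(minute_counts: np.ndarray, how: str = "sum") -> np.ndarray:
    """Aggregate 1440 one-minute counts to 288 five-minute epochs.

    ``how="sum"`` (default) accumulates the five constituent minutes and thus
    conserves the daily total; ``how="mean"`` divides by 5.
    """
    x = np.asarray(minute_counts, dtype=float)
    if x.shape != (MINUTES_PER_DAY,):
        raise ValueError(
            f"expected {MINUTES_PER_DAY} minute counts, got shape {x.shape}"
        )
    if np.any(x < 0):
        raise ValueError("minute counts must be non-negative")
    agg = x.reshape(N_EPOCHS, _MINUTES_PER_EPOCH).sum(axis=1)
    if how == "mean":
        agg = agg / _MINUTES_PER_EPOCH
    elif how != "sum":
        raise ValueError(f"how must be 'sum' or 'mean', got {how!r}")
    return agg


def log_transform(counts: np.ndarray) -> np.ndarray:
    """Elementwise ``ln(1 + count)``; strictly monotone, invertible by expm1."""
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    return np.log1p(x)


def detect_invalid_day(
    day: EpochDay,
    daytime_window: tuple[int, int] = DAYTIME_WINDOW,
    max_zero_fraction: float = MAX_ZERO_FRACTION,
) -> bool:
    """True (invalid) iff the zero-epoch fraction in the daytime window exceeds the threshold.

    Operationalises the exclusion of days with incoherent zero values spread
    through the 24-hour cycle: zeros at night are expected, zeros covering
    most of the daytime window are not.
    """
    lo, hi = daytime_window
    if not (0 <= lo < hi <= N_EPOCHS):
        raise ValueError(f"daytime window {daytime_window} outside [0, {N_EPOCHS})")
    if not 0 <= max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    window = day.counts[lo:hi]
    zero_fraction = float(np.mean(window == 0))
    return zero_fraction > max_zero_fraction


def screen_days(
    days: list[EpochDay],
    daytime_window: tuple[int, int] = DAYTIME_WINDOW,
    max_zero_fraction: float = MAX_ZERO_FRACTION,
) -> tuple[list[EpochDay], list[dict]]:
    """Apply day QC; return (valid days, exclusion log).

    Days, not subjects, are the QC unit; a subject disappears from the valid
    set only when all their days fail (logged per excluded day).
    """
    valid, exclusions = [], []
    for day in days:
        invalid = detect_invalid_day(day, daytime_window, max_zero_fraction)
        day.valid = not invalid
        if invalid:
            exclusions.append(
                {
                    "subject_id": day.subject_id,
                    "day_index": day.day_index,
                    "rule": f"daytime zero fraction > {max_zero_fraction}",
                }
            )
            logger.warning(
                "excluding %s day %d: daytime zero fraction exceeds %.2f",
                day.subject_id,
                day.day_index,
                max_zero_fraction,
            )
        else:
            valid.append(day)
    return valid, exclusions


_EPOCH_COLUMNS = ["subject_id", "date", "epoch_index", "count"]


def read_epoch_csv(
    path,
    epoch_seconds: int = 300,
    aggregate: str = "sum",
) -> list[EpochDay]:
    """Read an epoch CSV (``subject_id,date,epoch_index,count``) into EpochDays.

    ``epoch_seconds=60`` inputs (1440 rows per day) are aggregated to the
    288-slot grid; ``epoch_seconds=300`` inputs are used as-is.  Only days
    with complete 24-hour coverage are kept; partial days are dropped with a
    logged warning.  Day indices are assigned per subject in date order,
    starting at 1.
    """
    if epoch_seconds not in (60, 300):
        raise ValueError(f"epoch_seconds must be 60 or 300, got {epoch_seconds}")
    per_day = MINUTES_PER_DAY if epoch_seconds == 60 else N_EPOCHS
    try:
        frame = pd.read_csv(path, dtype={"subject_id": str, "date": str})
    except pd.errors.EmptyDataError:
        logger.warning("epoch file %s is empty", path)
        return []
    missing = [c for c in _EPOCH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"epoch file {path} lacks columns {missing}")
    if frame.empty:
        logger.warning("epoch file %s has no rows", path)
        return []
    for col in ("epoch_index", "count"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(
                f"malformed value {frame[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line} of {path}"
            )
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ValueError(f"missing value in column {col!r} at line {line} of {path}")
        frame[col] = coerced
    if (frame["count"] < 0).any():
        line = int(np.flatnonzero((frame["count"] < 0).to_numpy())[0]) + 2
        raise ValueError(f"negative count at line {line} of {path}")

    days: list[EpochDay] = []
    for subject_id, sub in frame.groupby("subject_id", sort=True):
        day_index = 0
        for date, grp in sub.groupby("date", sort=True):
            idx = grp["epoch_index"].to_numpy(dtype=int)
            if len(grp) != per_day or not np.array_equal(
                np.sort(idx), np.arange(per_day)
            ):
                logger.warning(
                    "dropping %s %s: incomplete day (%d of %d epochs)",
                    subject_id,
                    date,
                    len(np.unique(idx)),
                    per_day,
                )
                continue
            counts = np.empty(per_day)
            counts[idx] = grp["count"].to_numpy(dtype=float)
            if epoch_seconds == 60:
                counts = aggregate_minutes(counts, how=aggregate)
            day_index += 1
            days.append(
                EpochDay(
                    subject_id=str(subject_id),
                    day_index=day_index,
                    counts=counts,
                    date=str(date),
                )
            )
    return days


def write_epoch_csv(days: list[EpochDay], path) -> None:
    """Write EpochDays in the epoch CSV dialect (5-minute rows, UTF-8, \\n)."""
    records = []
    for day in days:
        date = day.date if day.date is not None else f"day{day.day_index:03d}"
        for t in range(N_EPOCHS):
            records.append((day.subject_id, date, t, day.counts[t]))
    frame = pd.DataFrame(records, columns=_EPOCH_COLUMNS)
    # integers written without a decimal point so round trips are bit-exact
    if np.allclose(frame["count"], np.rint(frame["count"])):
        frame["count"] = frame["count"].astype(np.int64)
    frame.to_csv(path, index=False, lineterminator="\n")


def read_covariates_csv(path) -> list[CovariateRow]:
    frame = pd.read_csv(path, dtype={"subject_id": str})
    required = ["subject_id", "group", "age", "sex"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"covariates file {path} lacks columns {missing}")
    if frame["subject_id"].duplicated().any():
        dupes = frame.loc[frame["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in {path}: {dupes}")
    return [
        CovariateRow(
            subject_id=str(r.subject_id),
            group=int(r.group),
            age=float(r.age),
            sex=int(r.sex),
        )
        for r in frame.itertuples()
    ]


def write_covariates_csv(rows: list[CovariateRow], path) -> None:
    frame = pd.DataFrame(
        [(r.subject_id, r.group, r.age, r.sex) for r in rows],
        columns=["subject_id", "group", "age", "sex"],
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def split_to_minutes(epoch_counts: np.ndarray) -> np.ndarray:
    """Spread 288 five-minute integer counts over 1440 minutes, conserving sums.

    Each epoch's count is divided as evenly as integers allow (remainder to
    the earliest minutes); ``aggregate_minutes`` inverts this exactly.
    """
    x = np.asarray(epoch_counts)
    if x.shape != (N_EPOCHS,):
        raise ValueError(f"expected {N_EPOCHS} epoch counts, got shape {x.shape}")
    base = np.asarray(x, dtype=np.int64)
    if not np.array_equal(base, x):
        raise ValueError("minute splitting requires integer epoch counts")
    rem = base % _MINUTES_PER_EPOCH
    # minute m within an epoch gets an extra count iff m < remainder
    out = np.repeat(base // _MINUTES_PER_EPOCH, _MINUTES_PER_EPOCH)
    minute_in_epoch = np.tile(np.arange(_MINUTES_PER_EPOCH), N_EPOCHS)
    out += (minute_in_epoch < np.repeat(rem, _MINUTES_PER_EPOCH)).astype(np.int64)
    return out
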