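"""Conventional sum-score descriptives: intensity cut-points and group OLS.

The comparator to the functional analysis: minute-level counts are classified
into sedentary (0-99 counts/min), light (100-2019), moderate (2020-5998) and
vigorous (>= 5999) intensity — the Troiano NHANES cut-points — and summarised
per day as percent time per level and the mean count per minute.  Groups are
compared on per-subject average counts with an ordinary least-squares
regression adjusted for age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import MINUTES_PER_DAY, CovariateRow

__all__ = [
    "IntensityCutpoints",
    "LEVELS",
    "classify_intensity",
    "classify_minutes",
    "summarize_day",
    "summarize_days",
    "group_regression",
    "GroupComparison",
    "DailySummary",
]

LEVELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class IntensityCutpoints:
    """Counts-per-minute thresholds; the vigorous floor closes the 5999 gap."""

    sedentary_max: int = 99
    light_max: int = 2019
    moderate_max: int = 5998

    def __post_init__(self) -> None:
        if not 0 <= self.sedentary_max < self.light_max < self.moderate_max:
            raise ValueError("cut-points must be strictly increasing")

    @property
    def vigorous_min(self) -> int:
        return self.moderate_max + 1


DEFAULT_CUTPOINTS = IntensityCutpoints()


def classify_intensity(
    count_per_min: float, cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS
) -> str:
    """Intensity label of one minute's count."""
    if count_per_min < 0:
        raise ValueError("counts must be non-negative")
    if count_per_min <= cutpoints.sedentary_max:
        return "sedentary"
    if count_per_min <= cutpoints.light_max:
        return "light"
    if count_per_min <= cutpoints.moderate_max:
        return "moderate"
    return "vigorous"


def classify_minutes(
    minute_counts: np.ndarray, cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS
) -> np.ndarray:
    """Vectorised minute classification: integer level codes 0..3."""
    x = np.asarray(minute_counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    bins = [cutpoints.sedentary_max, cutpoints.light_max, cutpoints.moderate_max]
    return np.digitize(x, bins, right=True)


@dataclass(frozen=True)
class DailySummary:
    subject_id: str
    day_index: int
    pct_sedentary: float
    pct_light: float
    pct_moderate: float
    pct_vigorous: float
    pct_mvpa: float
    avg_count: float


def summarize_day(
    minute_counts: np.ndarray,
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
    subject_id: str = "",
    day_index: int = 1,
) -> DailySummary:
    """Percent time per intensity level and mean counts/min over 1440 minutes."""
    x = np.asarray(minute_counts, dtype=float)
    if x.shape != (MINUTES_PER_DAY,):
        raise ValueError(
            f"expected {MINUTES_PER_DAY} minute counts, got shape {x.shape}"
        )
    codes = classify_minutes(x, cutpoints)
    pct = 100.0 * np.bincount(codes, minlength=4) / MINUTES_PER_DAY
    return DailySummary(
        subject_id=subject_id,
        day_index=day_index,
        pct_sedentary=float(pct[0]),
        pct_light=float(pct[1]),
        pct_moderate=float(pct[2]),
        pct_vigorous=float(pct[3]),
        pct_mvpa=float(pct[2] + pct[3]),
        avg_count=float(x.mean()),
    )


def summarize_days(
    minute_days: dict[tuple[str, int], np.ndarray],
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
) -> pd.DataFrame:
    """Summaries for a mapping ``(subject_id, day_index) -> 1440 minute counts``."""
    rows = [
        summarize_day(counts, cutpoints, subject_id=sid, day_index=di)
        for (sid, di), counts in sorted(minute_days.items())
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class GroupComparison:
    """Adjusted OLS group contrast on per-subject average counts per minute."""

    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def group_regression(
    summaries: pd.DataFrame,
    covariates: list[CovariateRow],
    adjust: tuple[str, ...] = ("age", "sex"),
) -> GroupComparison:
    """OLS of per-subject mean ``avg_count`` on group, adjusted for age and sex.

    ``summaries`` must carry ``subject_id`` and ``avg_count`` (one row per
    day); days are averaged within subject before regression.
    """
    import statsmodels.formula.api as smf

    per_subject = (
        summaries.groupby("subject_id", sort=True)["avg_count"].mean().reset_index()
    )
    cov_frame = pd.DataFrame(
        [(c.subject_id, c.group, c.age, c.sex) for c in covariates],
        columns=["subject_id", "group", "age", "sex"],
    )
    data = per_subject.merge(cov_frame, on="subject_id", how="inner")
    if len(data) < 3:
        raise ValueError(f"need at least 3 subjects with data, got {len(data)}")
    rhs = " + ".join(("group",) + tuple(adjust))
    design_cols = ["group", *adjust]
    rank = np.linalg.matrix_rank(
        np.column_stack([np.ones(len(data)), data[design_cols].to_numpy(float)])
    )
    if rank < len(design_cols) + 1:
        raise ValueError(f"singular regression design over columns {design_cols}")
    fit = smf.ols(f"avg_count ~ {rhs}", data=data).fit()
    ci = fit.conf_int().loc["group"]
    return GroupComparison(
        coefficient=float(fit.params["group"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["group"]),
        n_subjects=int(len(data)),
    )
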