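"""Synthetic actigraphy cohorts from the function-on-scalar generative model.

Each subject-day is simulated forward from the mixed model the package fits:
on the log(1+count) scale,

    y_ij(t) = b_i + beta0(t) + group_i * beta1(t) + sum_k beta_k(t) xi_ik + eps_ij(t)

with a subject random intercept ``b_i ~ N(0, tau^2)``, iid Gaussian residuals
``eps_ij(t) ~ N(0, sigma^2)`` per 5-minute epoch, and counts obtained by
``max(round(exp(y) - 1), 0)``.  The back-transform makes the fitted model
correctly specified up to integer rounding, so parameter-recovery and
coverage checks have an exact known truth.

Defaults emulate an older-adult cohort: a smooth circadian baseline with a
low nocturnal plateau (~23:20-07:40) and a daytime plateau with a gentle
midday crest; a group effect of two localized negative dips (morning ~06:05,
evening ~21:40, depth log(1-0.4) ~ -40% relative activity); age ~ N(67, 7)
truncated to [50, 90]; sex ~ Bernoulli(1/2); tau = 0.3, sigma = 0.5; five
recording days per subject (devices were worn between one and eight days).

By default the baseline and effect curves are projected onto the wavelet
basis (``snap_to_basis=True``) so the true coefficient vectors gamma_k exist
exactly; the projection changes the smooth default shapes imperceptibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .basis import DEFAULT_FILTER, DEFAULT_LEVEL, WaveletBasis, build_basis
from .preprocess import (
    N_EPOCHS,
    CovariateRow,
    EpochDay,
    split_to_minutes,
    write_covariates_csv,
    write_epoch_csv,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "CohortTruth",
    "default_circadian_profile",
    "default_group_effect",
    "simulate_cohort",
    "write_cohort",
]

# clock anchors, in 5-minute epochs
_WAKE_EPOCH = 92  # 07:40
_SLEEP_EPOCH = 280  # 23:20
_TRANSITION_HALFWIDTH = 6  # 30 min raised-cosine ramp on each side

_NIGHT_LEVEL = 2.0  # log(1+count): ~6 counts / 5 min of nocturnal movement
_DAY_LEVEL = 7.3  # ~1480 counts / 5 min (~300 counts/min) of waking activity
_MIDDAY_BUMP = 0.25

_DIP_EPOCHS = (73, 260)  # 06:05 and 21:40
_DIP_DEPTH = np.log(1.0 - 0.4)  # -40% relative activity at the dip centre
_DIP_SD = 2.5  # epochs (~12 min): localized, a few epochs wide


def default_circadian_profile() -> np.ndarray:
    """Smooth periodic baseline beta0(t) on the log(1+count) scale.

    Low nocturnal plateau between ~23:20 and ~07:40, daytime plateau with a
    gentle midday crest, raised-cosine transitions.  Periodic by
    construction (the night plateau spans midnight unchanged).
    """
    t = np.arange(N_EPOCHS)
    wake = np.zeros(N_EPOCHS)
    ramp = np.linspace(-1, 1, 2 * _TRANSITION_HALFWIDTH + 1)
    rise = 0.5 * (1 + np.sin(0.5 * np.pi * ramp))
    lo, hi = _WAKE_EPOCH - _TRANSITION_HALFWIDTH, _WAKE_EPOCH + _TRANSITION_HALFWIDTH
    wake[lo : hi + 1] = rise
    wake[hi + 1 : _SLEEP_EPOCH - _TRANSITION_HALFWIDTH] = 1.0
    lo, hi = _SLEEP_EPOCH - _TRANSITION_HALFWIDTH, _SLEEP_EPOCH + _TRANSITION_HALFWIDTH
    wake[lo : hi + 1] = rise[::-1]
    midday = np.cos(2 * np.pi * (t - 162) / N_EPOCHS)  # crest at 13:30
    return _NIGHT_LEVEL + (_DAY_LEVEL - _NIGHT_LEVEL) * wake + _MIDDAY_BUMP * wake * midday


def _circular_gaussian(center: int, sd: float) -> np.ndarray:
    t = np.arange(N_EPOCHS)
    d = np.abs(t - center)
    d = np.minimum(d, N_EPOCHS - d)
    return np.exp(-0.5 * (d / sd) ** 2)


def default_group_effect() -> np.ndarray:
    """Default beta1(t): two localized negative log-scale dips (morning, evening)."""
    effect = np.zeros(N_EPOCHS)
    for center in _DIP_EPOCHS:
        effect += _DIP_DEPTH * _circular_gaussian(center, _DIP_SD)
    return effect


def _as_profile(value, name: str) -> np.ndarray:
    if callable(value):
        value = value()
    profile = np.asarray(value, dtype=float)
    if profile.shape == ():
        profile = np.full(N_EPOCHS, float(profile))
    if profile.shape != (N_EPOCHS,):
        raise ValueError(f"{name} must have length {N_EPOCHS}, got {profile.shape}")
    if not np.all(np.isfinite(profile)):
        raise ValueError(f"{name} contains non-finite values")
    return profile


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic cohort (two groups)."""

    n_subjects_per_group: int = 50
    days_per_subject: int = 5
    baseline_profile: np.ndarray | Callable | float = field(
        default_factory=default_circadian_profile
    )
    group_effect_profile: np.ndarray | Callable | float = field(
        default_factory=default_group_effect
    )
    covariate_effects: dict = field(
        default_factory=lambda: {"age": -0.01, "sex": 0.15}
    )
    tau: float = 0.3
    sigma: float = 0.5
    seed: int = 0
    snap_to_basis: bool = True
    filter_name: str = DEFAULT_FILTER
    level: int = DEFAULT_LEVEL

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        if not 1 <= self.days_per_subject <= 8:
            raise ValueError(
                f"days_per_subject must be in [1, 8], got {self.days_per_subject}"
            )
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("tau and sigma must be non-negative")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth carried alongside a synthetic cohort for recovery tests."""

    covariate_names: tuple[str, ...]
    beta: np.ndarray  # (p+1, 288) true coefficient curves, rows match names
    gamma: np.ndarray | None  # (p+1, K) exact basis coordinates when snapped
    tau: float
    sigma: float


@dataclass
class SyntheticCohort:
    days: list[EpochDay]
    covariates: list[CovariateRow]
    truth: CohortTruth


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def simulate_cohort(
    config: SimulationConfig, basis: WaveletBasis | None = None
) -> SyntheticCohort:
    """Simulate the generative model forward; deterministic given the seed."""
    beta0 = _as_profile(config.baseline_profile, "baseline_profile")
    beta1 = _as_profile(config.group_effect_profile, "group_effect_profile")
    cov_names = tuple(config.covariate_effects)
    cov_profiles = [
        _as_profile(config.covariate_effects[name], f"covariate effect {name!r}")
        for name in cov_names
    ]
    beta = np.vstack([beta0, beta1, *cov_profiles]) if cov_profiles else np.vstack(
        [beta0, beta1]
    )
    gamma = None
    if config.snap_to_basis:
        if basis is None:
            basis = build_basis(N_EPOCHS, config.filter_name, config.level)
        gamma = beta @ basis.matrix
        beta = gamma @ basis.matrix.T

    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_subjects_per_group
    group = np.repeat([0, 1], config.n_subjects_per_group)
    age = _truncated_normal(rng, 67.0, 7.0, 50.0, 90.0, n)
    sex = rng.integers(0, 2, n)
    intercepts = rng.normal(0.0, config.tau, n) if config.tau > 0 else np.zeros(n)

    cov_values = {"age": age, "sex": sex.astype(float)}
    extra = [c for c in cov_names if c not in cov_values]
    if extra:
        raise ValueError(f"unsupported covariate effects {extra}; use 'age'/'sex'")

    covariates = []
    days: list[EpochDay] = []
    names = ("intercept", "group") + cov_names
    for i in range(n):
        subject_id = f"S{i + 1:04d}"
        covariates.append(
            CovariateRow(
                subject_id=subject_id,
                group=int(group[i]),
                age=float(age[i]),
                sex=int(sex[i]),
            )
        )
        mean = beta[0] + group[i] * beta[1] + intercepts[i]
        for j, name in enumerate(cov_names):
            mean = mean + cov_values[name][i] * beta[2 + j]
        noise = (
            rng.normal(0.0, config.sigma, (config.days_per_subject, N_EPOCHS))
            if config.sigma > 0
            else np.zeros((config.days_per_subject, N_EPOCHS))
        )
        y = mean[None, :] + noise
        counts = np.maximum(np.rint(np.expm1(y)), 0.0)
        for j in range(config.days_per_subject):
            days.append(
                EpochDay(subject_id=subject_id, day_index=j + 1, counts=counts[j])
            )

    truth = CohortTruth(
        covariate_names=names,
        beta=beta,
        gamma=gamma,
        tau=config.tau,
        sigma=config.sigma,
    )
    return SyntheticCohort(days=days, covariates=covariates, truth=truth)


def write_cohort(
    cohort: SyntheticCohort, outdir, epoch_seconds: int = 300
) -> dict[str, Path]:
    """Write a cohort as delimited text: epochs, covariates, and truth curves.

    With ``epoch_seconds=60`` the 5-minute counts are spread over their five
    minutes (integer-conserving) so the preprocessing aggregation can be
    exercised end to end.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epochs_path = outdir / "epochs.csv"
    if epoch_seconds == 300:
        write_epoch_csv(cohort.days, epochs_path)
    elif epoch_seconds == 60:
        records = []
        for day in cohort.days:
            date = day.date if day.date is not None else f"day{day.day_index:03d}"
            minutes = split_to_minutes(day.counts.astype(np.int64))
            records.extend(
                (day.subject_id, date, m, int(minutes[m])) for m in range(len(minutes))
            )
        pd.DataFrame(
            records, columns=["subject_id", "date", "epoch_index", "count"]
        ).to_csv(epochs_path, index=False, lineterminator="\n")
    else:
        raise ValueError("epoch_seconds must be 60 or 300")

    cov_path = outdir / "covariates.csv"
    write_covariates_csv(cohort.covariates, cov_path)

    truth = cohort.truth
    truth_path = outdir / "truth.csv"
    frame = pd.DataFrame(truth.beta.T, columns=list(truth.covariate_names))
    frame.insert(0, "epoch", np.arange(N_EPOCHS))
    frame.to_csv(truth_path, index=False, lineterminator="\n")
    meta_path = outdir / "truth_meta.json"
    import json

    meta_path.write_text(
        json.dumps({"tau": truth.tau, "sigma": truth.sigma}, indent=2) + "\n"
    )
    return {
        "epochs": epochs_path,
        "covariates": cov_path,
        "truth": truth_path,
        "truth_meta": meta_path,
    }
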