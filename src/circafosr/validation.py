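"""Monte-Carlo validation harness: family-wise error, power, band coverage.

Repeatedly simulates cohorts from a :class:`SimulationConfig`, fits the FoSR
mixed model, and summarises the group-effect inference across replicates:

* family-wise error — under a null group effect, the fraction of replicates
  with any Bonferroni-significant epoch (should not exceed alpha for a
  conservative procedure);
* power — under a non-null effect, the fraction of replicates in which some
  detected period overlaps the true effect's support (epochs where the true
  curve exceeds half its maximum absolute deviation);
* coverage — the empirical pointwise coverage of the 1 - alpha/K bands over
  the true group curve, averaged over epochs and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .basis import build_basis
from .model import FoSRModel
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["SimulationStudySummary", "simulation_study"]


@dataclass(frozen=True)
class SimulationStudySummary:
    n_reps: int
    alpha: float
    any_significant_rate: float
    familywise_error: float | None  # set when the true group effect is null
    power: float | None  # set when the true group effect is non-null
    mean_coverage: float
    min_pointwise_coverage: float
    mean_abs_gamma_error: float | None  # vs truth, when the truth is in span

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def simulation_study(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    formula: tuple[str, ...] = ("group", "age", "sex"),
) -> SimulationStudySummary:
    """Run ``n_reps`` simulate-fit-infer replicates and summarise them."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    basis = build_basis(288, config.filter_name, config.level)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)

    any_sig = np.zeros(n_reps, dtype=bool)
    detected = np.zeros(n_reps, dtype=bool)
    coverage = np.zeros((n_reps, 288))
    gamma_errors = []

    truth_probe = simulate_cohort(replace(config, seed=0), basis=basis).truth
    beta1_true = truth_probe.beta[1]
    null_truth = bool(np.allclose(beta1_true, 0.0))
    if not null_truth:
        support = np.abs(beta1_true) > 0.5 * np.abs(beta1_true).max()

    for r in range(n_reps):
        cohort = simulate_cohort(replace(config, seed=int(rep_seeds[r])), basis=basis)
        fit = FoSRModel(
            cohort.days, cohort.covariates, basis=basis, formula=formula
        ).fit()
        curve = fit.effect_curve("group", alpha=alpha)
        sig = curve.p_adj < alpha
        any_sig[r] = bool(sig.any())
        beta1 = cohort.truth.beta[1]
        coverage[r] = (curve.ci_lo <= beta1) & (beta1 <= curve.ci_hi)
        if not null_truth:
            detected[r] = bool(np.any(sig & support))
        if cohort.truth.gamma is not None:
            k = fit.covariate_names.index("group")
            gamma_errors.append(
                float(np.mean(np.abs(fit.gamma[k] - cohort.truth.gamma[1])))
            )

    pointwise = coverage.mean(axis=0)
    return SimulationStudySummary(
        n_reps=n_reps,
        alpha=alpha,
        any_significant_rate=float(any_sig.mean()),
        familywise_error=float(any_sig.mean()) if null_truth else None,
        power=None if null_truth else float(detected.mean()),
        mean_coverage=float(pointwise.mean()),
        min_pointwise_coverage=float(pointwise.min()),
        mean_abs_gamma_error=(
            float(np.mean(gamma_errors)) if gamma_errors else None
        ),
    )
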