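"""FoSR mixed-model estimation, inference arithmetic and period reporting."""

import numpy as np
import pytest

from circafosr.basis import build_basis
from circafosr.model import (
    EffectCurve,
    FoSRModel,
    extract_significant_periods,
    fit_fosr,
    pointwise_inference,
    relative_activity,
)
from circafosr.preprocess import N_EPOCHS, EpochDay
from circafosr.simulate import SimulationConfig, simulate_cohort
from conftest import make_covariates, make_day


def _cohort_days_from_log_curves(log_curves):
    """EpochDay records with exact (non-integer) counts expm1(log curve)."""
    days = []
    for subject_id, curves in log_curves.items():
        for j, y in enumerate(curves, start=1):
            days.append(EpochDay(subject_id, j, np.expm1(np.maximum(y, 0.0))))
    return days


class TestFitting:
    def test_gls_oracle_at_fixed_variance_components(self, basis288, rng):
        """gamma-hat equals brute-force GLS on the dense stacked system."""
        cohort = simulate_cohort(
            SimulationConfig(
                n_subjects_per_group=2, days_per_subject=3, seed=5, tau=0.2, sigma=0.3
            )
        )
        model = FoSRModel(cohort.days, cohort.covariates, basis=basis288)
        tau2, sigma2 = 0.05, 0.1
        res = model.fit(tau2=tau2, sigma2=sigma2)

        idx = {s: i for i, s in enumerate(model.subject_ids)}
        C = model.exog_subjects
        X, y, Z = [], [], []
        for day in cohort.days:
            i = idx[day.subject_id]
            X.append(np.kron(C[i], basis288.matrix))
            y.append(day.log_counts)
            z = np.zeros(len(idx))
            z[i] = 1.0
            Z.append(np.tile(z, (N_EPOCHS, 1)))
        X, y, Z = np.vstack(X), np.concatenate(y), np.vstack(Z)
        V = sigma2 * np.eye(len(y)) + tau2 * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        theta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.abs(theta - res.gamma.ravel()).max() < 1e-8

    def test_reml_matches_mixedlm_oracle(self, basis288):
        """REML estimates agree with statsmodels MixedLM on the stacked data."""
        import statsmodels.api as sm

        cohort = simulate_cohort(
            SimulationConfig(
                n_subjects_per_group=5,
                days_per_subject=3,
                seed=11,
                covariate_effects={},
                tau=0.25,
                sigma=0.4,
            )
        )
        model = FoSRModel(
            cohort.days, cohort.covariates, basis=basis288, formula=("group",)
        )
        res = model.fit()

        idx = {s: i for i, s in enumerate(model.subject_ids)}
        C = model.exog_subjects
        X, y, groups = [], [], []
        for day in cohort.days:
            i = idx[day.subject_id]
            X.append(np.kron(C[i], basis288.matrix))
            y.append(day.log_counts)
            groups.extend([i] * N_EPOCHS)
        mm = sm.MixedLM(
            np.concatenate(y), np.vstack(X), groups=np.array(groups)
        ).fit(reml=True)
        assert np.abs(mm.fe_params - res.gamma.ravel()).max() < 1e-6
        assert res.sigma2 == pytest.approx(float(mm.scale), abs=1e-4)
        assert res.tau2 == pytest.approx(
            float(np.asarray(mm.cov_re).ravel()[0]), abs=1e-3
        )
        se = np.sqrt(np.diag(res.gamma_cov))
        assert np.abs(se - mm.bse_fe).max() / se.mean() < 0.01

    def test_noise_free_recovery_is_exact(self, basis288, rng):
        """With effects in the basis span and vanishing noise, gamma is
        recovered to numerical precision."""
        gamma0 = basis288.matrix.T @ np.full(N_EPOCHS, 7.0)
        gamma1 = basis288.matrix.T @ (
            -0.3 * np.cos(2 * np.pi * np.arange(N_EPOCHS) / N_EPOCHS)
        )
        beta0 = basis288.matrix @ gamma0
        beta1 = basis288.matrix @ gamma1
        jitter = 1e-6
        log_curves = {}
        groups = []
        for i in range(6):
            g = i % 2
            groups.append(g)
            y = beta0 + g * beta1
            log_curves[f"S{i + 1:04d}"] = [
                y + jitter * rng.standard_normal(N_EPOCHS) for _ in range(2)
            ]
        days = _cohort_days_from_log_curves(log_curves)
        covs = make_covariates(groups)
        res = fit_fosr(days, covs, basis=basis288, formula=("group",))
        assert np.abs(res.gamma[0] - gamma0).max() < 1e-3
        assert np.abs(res.gamma[1] - gamma1).max() < 1e-3
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_constant_days(self, basis288):
        days = [
            make_day(f"S{i + 1:04d}", j, 50.0) for i in range(3) for j in (1, 2)
        ]
        covs = make_covariates([0, 1, 0])
        res = fit_fosr(days, covs, basis=basis288, formula=("group",))
        assert np.allclose(res.beta_curves[0], np.log1p(50.0), atol=1e-8)
        assert res.tau2 == pytest.approx(0.0, abs=1e-10)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-10)

    def test_reconstruction_identity(self, basis288):
        cohort = simulate_cohort(
            SimulationConfig(n_subjects_per_group=3, days_per_subject=2, seed=8)
        )
        res = fit_fosr(cohort.days, cohort.covariates, basis=basis288)
        assert np.abs(
            res.beta_curves - res.gamma @ basis288.matrix.T
        ).max() < 1e-10
        assert np.abs(res.gamma_cov - res.gamma_cov.T).max() < 1e-10
        assert np.linalg.eigvalsh(res.gamma_cov).min() > -1e-10

    def test_presmoothing_leaves_gamma_unchanged(self, basis288):
        """Pre-projecting the response onto the basis span only affects the
        residual variance (projection orthogonality)."""
        cohort = simulate_cohort(
            SimulationConfig(n_subjects_per_group=4, days_per_subject=2, seed=15)
        )
        raw = FoSRModel(cohort.days, cohort.covariates, basis=basis288)
        pre = FoSRModel(
            cohort.days, cohort.covariates, basis=basis288, presmooth=True
        )
        res_raw = raw.fit(tau2=0.09, sigma2=0.25)
        res_pre = pre.fit(tau2=0.09, sigma2=0.25)
        assert np.abs(res_raw.gamma - res_pre.gamma).max() < 1e-10

    def test_error_messages(self, basis288):
        days = [make_day("S0001", 1, 10.0), make_day("S0002", 1, 12.0)]
        with pytest.raises(ValueError, match="at least 2 subjects"):
            FoSRModel([days[0]], make_covariates([0]), basis=basis288)
        # sex constant across subjects -> collinear with the intercept
        covs = make_covariates([0, 1], sexes=[1, 1])
        with pytest.raises(ValueError, match="sex"):
            FoSRModel(days, covs, basis=basis288, formula=("group", "sex"))
        with pytest.raises(ValueError, match="without covariates"):
            FoSRModel(days, make_covariates([0]), basis=basis288)


@pytest.fixture(scope="module")
def fitted():
    basis = build_basis()
    cohort = simulate_cohort(
        SimulationConfig(n_subjects_per_group=10, days_per_subject=3, seed=30)
    )
    return fit_fosr(cohort.days, cohort.covariates, basis=basis)


class TestInference:
    def test_bonferroni_adjustment_by_basis_count(self, fitted):
        curve = pointwise_inference(fitted, "group")
        assert curve.bonferroni_factor == 18
        assert np.allclose(curve.p_adj, np.minimum(1.0, 18 * curve.p_raw))
        assert np.all(curve.p_adj >= curve.p_raw)

    def test_band_level_raised_to_one_minus_alpha_over_18(self, fitted):
        from scipy import stats

        curve = fitted.effect_curve("group", alpha=0.05)
        zcrit = stats.norm.ppf(1 - 0.05 / (2 * 18))
        assert np.allclose(curve.ci_hi - curve.estimate, zcrit * curve.se)
        assert np.all(curve.ci_lo <= curve.estimate)
        assert np.all(curve.estimate <= curve.ci_hi)
        # nominal band level 1 - 0.05/18 ~ 0.99722
        assert 1 - 0.05 / 18 == pytest.approx(0.997222, abs=1e-6)

    def test_se_matches_quadratic_form(self, fitted):
        curve = fitted.effect_curve("group")
        k = fitted.covariate_names.index("group")
        K = fitted.basis.k
        block = fitted.gamma_cov[k * K : (k + 1) * K, k * K : (k + 1) * K]
        direct = np.sqrt(
            np.diag(fitted.basis.matrix @ block @ fitted.basis.matrix.T)
        )
        assert np.allclose(curve.se, direct, atol=1e-12)
        assert np.all(curve.relative > -1)

    def test_unknown_covariate_and_bad_alpha(self, fitted):
        with pytest.raises(KeyError):
            fitted.effect_curve("bmi")
        with pytest.raises(ValueError):
            fitted.effect_curve("group", alpha=1.5)

    def test_summary_mentions_variance_components(self, fitted):
        text = fitted.summary()
        assert "tau^2" in text and "sigma^2" in text
        assert "Bonferroni factor: 18" in text


class TestRelativeActivity:
    def test_reference_values(self):
        assert relative_activity(0.0) == 0.0
        assert relative_activity(np.log(2.0)) == pytest.approx(100.0)
        assert relative_activity(-0.5) == pytest.approx(-39.347, abs=5e-4)

    def test_strictly_increasing_and_bounded_below(self, rng):
        x = np.sort(rng.normal(0, 2, 100))
        y = relative_activity(x)
        assert np.all(np.diff(y) > 0)
        assert np.all(y > -100)


def _curve_from_p(p_adj, relative=None):
    p_adj = np.asarray(p_adj, dtype=float)
    est = np.log1p(relative) if relative is not None else np.zeros(N_EPOCHS)
    return EffectCurve(
        covariate="group",
        estimate=est,
        se=np.ones(N_EPOCHS),
        ci_lo=est - 1.0,
        ci_hi=est + 1.0,
        p_raw=p_adj / 18,
        p_adj=p_adj,
        relative=np.expm1(est),
        alpha=0.05,
        bonferroni_factor=18,
    )


class TestSignificantPeriods:
    def test_no_significant_epochs_gives_empty(self):
        assert extract_significant_periods(_curve_from_p(np.ones(N_EPOCHS))) == []

    def test_single_run_with_extreme_at_0605(self):
        p = np.ones(N_EPOCHS)
        p[68:77] = 0.01
        rel = np.zeros(N_EPOCHS)
        rel[68:77] = -0.2
        rel[73] = -0.413  # deepest relative difference at 06:05
        periods = extract_significant_periods(_curve_from_p(p, rel))
        assert len(periods) == 1
        period = periods[0]
        assert (period.start_epoch, period.end_epoch) == (68, 76)
        assert (period.start_clock, period.end_clock) == ("05:40", "06:20")
        assert period.extreme_epoch == 73
        assert period.extreme_clock == "06:05"
        assert period.extreme_relative == pytest.approx(-41.3, abs=0.01)
        assert not period.wrapped

    def test_two_runs_ordered_by_start(self):
        p = np.ones(N_EPOCHS)
        p[68:77] = 0.01
        p[253:270] = 0.01
        rel = np.full(N_EPOCHS, -0.1)
        periods = extract_significant_periods(_curve_from_p(p, rel))
        assert [(q.start_epoch, q.end_epoch) for q in periods] == [
            (68, 76),
            (253, 269),
        ]

    def test_run_wrapping_midnight_reported_once(self):
        p = np.ones(N_EPOCHS)
        p[280:] = 0.01
        p[:6] = 0.01
        rel = np.zeros(N_EPOCHS)
        rel[282] = 0.5
        periods = extract_significant_periods(_curve_from_p(p, rel))
        assert len(periods) == 1
        period = periods[0]
        assert period.wrapped
        assert (period.start_epoch, period.end_epoch) == (280, 5)
        assert period.extreme_epoch == 282

    def test_tie_breaks_to_earliest_epoch(self):
        p = np.ones(N_EPOCHS)
        p[100:110] = 0.01
        rel = np.zeros(N_EPOCHS)
        rel[100:110] = -0.3  # constant |relative| across the run
        periods = extract_significant_periods(_curve_from_p(p, rel))
        assert periods[0].extreme_epoch == 100

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            extract_significant_periods(_curve_from_p(np.ones(N_EPOCHS)), threshold=0)


def test_permuting_group_labels_destroys_detection(basis288):
    """A detected group period disappears for nearly all label permutations."""
    from dataclasses import replace as dc_replace

    t = np.arange(N_EPOCHS)
    dist = np.minimum(np.abs(t - 73), N_EPOCHS - np.abs(t - 73))
    strong_dip = np.log(0.4) * np.exp(-0.5 * (dist / 4.25) ** 2)  # -60% morning
    cohort = simulate_cohort(
        SimulationConfig(
            n_subjects_per_group=25,
            days_per_subject=3,
            group_effect_profile=strong_dip,
            seed=61,
        )
    )
    res = fit_fosr(cohort.days, cohort.covariates, basis=basis288)
    assert res.significant_periods("group")  # the injected dips are found

    rng = np.random.default_rng(62)
    groups = np.array([c.group for c in cohort.covariates])
    destroyed = 0
    n_perm = 100
    for _ in range(n_perm):
        permuted = rng.permutation(groups)
        covs = [
            dc_replace(c, group=int(g)) for c, g in zip(cohort.covariates, permuted)
        ]
        perm_res = fit_fosr(cohort.days, covs, basis=basis288)
        if not perm_res.significant_periods("group"):
            destroyed += 1
    assert destroyed / n_perm >= 0.95
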