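"""Function-on-scalar regression for daily activity curves.

Model
-----
For subject ``i`` (``i = 1..N``), recording day ``j`` (``j = 1..j_i``) and
5-minute epoch ``t`` (``t = 0..287``), the log-transformed activity record
follows

    x_ij(t) = b_i + beta0(t) + sum_k beta_k(t) xi_ik + eps_ij(t)

with scalar covariates ``xi_ik`` (group indicator, age, sex), a subject
random intercept ``b_i ~ N(0, tau^2)`` capturing the correlation of a
subject's repeated days, and iid residuals ``eps_ij(t) ~ N(0, sigma^2)``.
Each coefficient function is expanded in the K (default 18) periodic wavelet
basis functions that form the columns of the low-pass matrix ``Y``:

    beta_k = gamma_k @ Y.T

so the fixed-effect design of a day is the Kronecker product of the
covariate row with ``Y``, and ``K * (p+1)`` scalar coefficients are
estimated.

Estimation
----------
REML.  Because the basis columns are orthonormal and the constant vector
(the random-intercept loading) lies in their span, each day's 288
observations reduce without loss to its K basis coordinates plus a residual
sum of squares from the orthogonal complement; the restricted likelihood
then profiles analytically over sigma^2, leaving a one-dimensional search
over the variance ratio lambda = tau^2/sigma^2.  This makes a fit on
hundreds of subject-days essentially instantaneous and exactly equivalent to
REML on the full stacked system.

Inference
---------
Large-sample Wald statistics per epoch: ``se(t)^2 = y_t' Cov(gamma_k) y_t``
with ``y_t`` the basis row at epoch ``t``.  To control multiplicity across
the day, p-values are Bonferroni-adjusted by the number of basis functions
(18 by default) and confidence bands are widened from level ``1 - alpha`` to
``1 - alpha/18``.  Effects are also reported as relative activity on the
1+count scale, ``(exp(beta) - 1) * 100%``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .basis import WaveletBasis, build_basis
from .preprocess import N_EPOCHS, CovariateRow, EpochDay, epoch_to_clock

__all__ = [
    "FoSRModel",
    "FoSRResults",
    "EffectCurve",
    "SignificantPeriod",
    "fit_fosr",
    "pointwise_inference",
    "extract_significant_periods",
    "relative_activity",
]

DEFAULT_FORMULA = ("group", "age", "sex")


def relative_activity(beta_value) -> np.ndarray | float:
    """Relative activity difference in percent on the 1+count scale.

    ``(exp(beta) - 1) * 100``: 0 at beta = 0, +100% at beta = ln 2, bounded
    below by -100%.  Strictly increasing.
    """
    return np.expm1(beta_value) * 100.0


@dataclass
class EffectCurve:
    """Pointwise inference for one covariate's effect curve beta_k(t)."""

    covariate: str
    estimate: np.ndarray  # (288,) log-scale effect
    se: np.ndarray
    ci_lo: np.ndarray  # band at level 1 - alpha/m
    ci_hi: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray  # min(1, m * p_raw)
    relative: np.ndarray  # exp(estimate) - 1, as a fraction
    alpha: float
    bonferroni_factor: int

    def to_frame(self):
        import pandas as pd

        epochs = np.arange(N_EPOCHS)
        return pd.DataFrame(
            {
                "covariate": self.covariate,
                "epoch": epochs,
                "clock": [epoch_to_clock(t) for t in epochs],
                "estimate": self.estimate,
                "se": self.se,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
                "relative_pct": self.relative * 100.0,
            }
        )


@dataclass(frozen=True)
class SignificantPeriod:
    """A maximal run of epochs where an effect is significant throughout.

    ``extreme_*`` fields describe the epoch of largest absolute relative
    difference inside the run (the single number reported per period).
    Periods may wrap across midnight (the day is circular); a wrapped period
    has ``start_epoch > end_epoch`` and ``wrapped=True``.
    """

    covariate: str
    start_epoch: int
    end_epoch: int
    start_clock: str
    end_clock: str
    extreme_epoch: int
    extreme_relative: float  # percent
    extreme_ci: tuple[float, float]  # percent
    extreme_p: float
    wrapped: bool = False

    @property
    def extreme_clock(self) -> str:
        return epoch_to_clock(self.extreme_epoch)


def extract_significant_periods(
    curve: EffectCurve, threshold: float = 0.05
) -> list[SignificantPeriod]:
    """Maximal circular runs with adjusted p below ``threshold`` everywhere.

    Each run reports the epoch of maximum ``|relative|`` (earliest such epoch
    along the run on ties), its relative difference, the CI endpoints mapped
    through the same ``exp(.)-1`` transform, and its adjusted p.  Runs are
    ordered by start epoch.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    sig = np.asarray(curve.p_adj) < threshold
    n = sig.size
    if not sig.any():
        return []
    if sig.all():
        runs = [np.arange(n)]
    else:
        # boundaries of runs on the circle: scan from the first non-sig epoch
        start0 = int(np.argmin(sig))
        order = (np.arange(n) + start0) % n
        runs, current = [], []
        for t in order:
            if sig[t]:
                current.append(t)
            elif current:
                runs.append(np.array(current))
                current = []
        if current:
            runs.append(np.array(current))
    periods = []
    for run in runs:
        rel = np.abs(curve.relative[run])
        extreme = int(run[int(np.argmax(rel))])
        periods.append(
            SignificantPeriod(
                covariate=curve.covariate,
                start_epoch=int(run[0]),
                end_epoch=int(run[-1]),
                start_clock=epoch_to_clock(int(run[0])),
                end_clock=epoch_to_clock(int(run[-1])),
                extreme_epoch=extreme,
                extreme_relative=float(relative_activity(curve.estimate[extreme])),
                extreme_ci=(
                    float(relative_activity(curve.ci_lo[extreme])),
                    float(relative_activity(curve.ci_hi[extreme])),
                ),
                extreme_p=float(curve.p_adj[extreme]),
                wrapped=bool(run[0] > run[-1]),
            )
        )
    periods.sort(key=lambda p: p.start_epoch)
    return periods


class FoSRModel:
    """Function-on-scalar regression model for a cohort of subject-days.

    Parameters
    ----------
    days
        EpochDay records (QC-screened); every subject id must appear in
        ``covariates``.
    covariates
        One CovariateRow per subject.
    basis
        Wavelet basis; defaults to the 288x18 periodic d10 level-4 basis.
    formula
        Covariate names entering the fixed effects besides the intercept,
        in order; default ``("group", "age", "sex")``.
    presmooth
        If True the response is projected onto the basis span before
        fitting.  The coefficient estimates at a fixed variance ratio are
        unchanged (the design lies in the span); only the residual variance
        estimate differs.
    """

    def __init__(
        self,
        days: list[EpochDay],
        covariates: list[CovariateRow],
        basis: WaveletBasis | None = None,
        formula: tuple[str, ...] = DEFAULT_FORMULA,
        presmooth: bool = False,
    ) -> None:
        if basis is None:
            basis = build_basis()
        self.basis = basis
        self.formula = tuple(formula)
        self.presmooth = presmooth
        self.covariate_names = ("intercept",) + self.formula

        cov_by_id = {c.subject_id: c for c in covariates}
        missing = sorted({d.subject_id for d in days} - set(cov_by_id))
        if missing:
            raise ValueError(f"days reference subjects without covariates: {missing}")
        days = [d for d in days if d.valid]
        if not days:
            raise ValueError("no valid days to fit")
        subject_ids = sorted({d.subject_id for d in days})
        if len(subject_ids) < 2:
            raise ValueError(
                f"need at least 2 subjects, got {len(subject_ids)}"
            )
        self.subject_ids = subject_ids
        index = {s: i for i, s in enumerate(subject_ids)}

        P = len(self.covariate_names)
        C = np.empty((len(subject_ids), P))
        C[:, 0] = 1.0
        for j, name in enumerate(self.formula):
            C[:, 1 + j] = [getattr(cov_by_id[s], name) for s in subject_ids]
        rank = np.linalg.matrix_rank(C)
        if rank < P:
            # pivoted QR names the columns beyond the numerical rank
            _, _, piv = linalg.qr(C, pivoting=True, mode="economic")
            bad = [self.covariate_names[i] for i in sorted(piv[rank:])]
            raise ValueError(
                f"covariate design is rank deficient (rank {rank} < {P}); "
                f"collinear or constant columns: {bad}"
            )
        self.exog_subjects = C

        # reduce each day to its K basis coordinates + orthogonal-part RSS
        Y = np.stack([d.log_counts for d in days])  # (n_days, 288)
        Cf = Y @ basis.matrix  # (n_days, K)
        self._subject_of_day = np.array([index[d.subject_id] for d in days])
        self.n_days_total = len(days)
        self.n_subjects = len(subject_ids)
        if presmooth:
            self._ss_perp = 0.0
            self._obs_per_day = basis.k
        else:
            self._ss_perp = float(np.sum(Y * Y) - np.sum(Cf * Cf))
            self._obs_per_day = basis.n

        nsub = self.n_subjects
        K = basis.k
        self._j = np.bincount(self._subject_of_day, minlength=nsub).astype(float)
        S = np.zeros((nsub, K))
        np.add.at(S, self._subject_of_day, Cf)
        self._S = S
        self._ssc = float(np.sum(Cf * Cf))
        self._a = basis.matrix.T @ np.ones(basis.n)  # random-intercept loading
        self._a_norm2 = float(self._a @ self._a)  # = 288 (constants in span)
        self._ats = S @ self._a  # per-subject a' sum_j c_ij

    # -- restricted-likelihood machinery ------------------------------------

    def _normal_equations(self, lam: float):
        """X'W^-1X, X'W^-1c, c'W^-1c for W = I + lam * (1 j_i x a)(...)'."""
        C, S, j, a = self.exog_subjects, self._S, self._j, self._a
        K = self.basis.k
        denom = 1.0 + lam * self._a_norm2 * j
        A1 = C.T @ (j[:, None] * C)
        XtWX = np.kron(A1, np.eye(K))
        T1 = (C.T @ S).ravel()
        if lam > 0:
            w2 = lam * j**2 / denom
            A2 = C.T @ (w2[:, None] * C)
            XtWX -= np.kron(A2, np.outer(a, a))
            g = lam * j / denom
            T1 = T1 - np.kron(C.T @ (g * self._ats), a)
            ctWc = self._ssc - float(np.sum(lam / denom * self._ats**2))
        else:
            ctWc = self._ssc
        return XtWX, T1, ctWc, denom

    def _profile(self, lam: float):
        XtWX, XtWc, ctWc, denom = self._normal_equations(lam)
        cho = linalg.cho_factor(XtWX, lower=True, check_finite=False)
        theta = linalg.cho_solve(cho, XtWc, check_finite=False)
        q = XtWc.size
        quad = max(ctWc - float(theta @ XtWc), 0.0) + self._ss_perp
        n_obs = self._obs_per_day * self.n_days_total
        dof = n_obs - q
        logdet_xtwx = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logdet_w = float(np.sum(np.log(denom)))
        if quad <= 0:
            neg2 = -np.inf  # degenerate exact fit
        else:
            neg2 = dof * np.log(quad) + logdet_w + logdet_xtwx
        return neg2, theta, quad, dof, XtWX

    def fit(
        self,
        method: str = "reml",
        tau2: float | None = None,
        sigma2: float | None = None,
    ) -> "FoSRResults":
        """Estimate gamma and the variance components.

        ``method="reml"`` (default) maximises the restricted likelihood over
        ``(tau^2, sigma^2)``.  Supplying both ``tau2`` and ``sigma2`` fixes
        the variance components and returns the GLS solution at those values
        (used for oracle comparisons).
        """
        if (tau2 is None) != (sigma2 is None):
            raise ValueError("fix both tau2 and sigma2 or neither")
        if tau2 is not None:
            if tau2 < 0 or sigma2 <= 0:
                raise ValueError("fixed components require tau2 >= 0, sigma2 > 0")
            lam = tau2 / sigma2
            XtWX, XtWc, _, _ = self._normal_equations(lam)
            theta = linalg.solve(XtWX, XtWc, assume_a="pos")
            cov = sigma2 * linalg.inv(XtWX)
            return self._package(theta, cov, tau2, sigma2, lam, method="fixed")
        if method != "reml":
            raise ValueError(f"unknown method {method!r}")

        def objective(psi: float) -> float:
            return self._profile(float(np.exp(psi)))[0]

        neg2_zero = self._profile(0.0)[0]
        if not np.isfinite(neg2_zero):
            # exact interpolation (e.g. identical constant days): sigma^2 -> 0
            _, theta, quad, dof, XtWX = self._profile(0.0)
            sigma2_hat = quad / dof
            cov = sigma2_hat * linalg.pinvh(XtWX)
            return self._package(theta, cov, 0.0, sigma2_hat, 0.0, method="reml")
        res = optimize.minimize_scalar(
            objective, bounds=(-20.0, 12.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        neg2_lam = self._profile(lam)[0]
        if neg2_zero <= neg2_lam:
            lam = 0.0
        _, theta, quad, dof, XtWX = self._profile(lam)
        sigma2_hat = quad / dof
        tau2_hat = lam * sigma2_hat
        cov = sigma2_hat * linalg.inv(XtWX)
        return self._package(theta, cov, tau2_hat, sigma2_hat, lam, method="reml")

    def _package(self, theta, cov, tau2, sigma2, lam, method) -> "FoSRResults":
        K = self.basis.k
        P = len(self.covariate_names)
        gamma = theta.reshape(P, K)
        return FoSRResults(
            model=self,
            gamma=gamma,
            gamma_cov=cov,
            tau2=float(tau2),
            sigma2=float(sigma2),
            lambda_=float(lam),
            method=method,
        )


@dataclass
class FoSRResults:
    """REML (or fixed-component GLS) estimates of the FoSR mixed model."""

    model: FoSRModel
    gamma: np.ndarray  # (p+1, K)
    gamma_cov: np.ndarray  # (K(p+1), K(p+1)), covariate-major blocks
    tau2: float
    sigma2: float
    lambda_: float
    method: str
    beta_curves: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.beta_curves = self.gamma @ self.model.basis.matrix.T

    # convenience passthroughs
    @property
    def basis(self) -> WaveletBasis:
        return self.model.basis

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return self.model.covariate_names

    @property
    def n_subjects(self) -> int:
        return self.model.n_subjects

    @property
    def n_days_total(self) -> int:
        return self.model.n_days_total

    def _index_of(self, covariate: str) -> int:
        try:
            return self.covariate_names.index(covariate)
        except ValueError:
            raise KeyError(
                f"unknown covariate {covariate!r}; have {self.covariate_names}"
            ) from None

    def effect_curve(self, covariate: str, alpha: float = 0.05) -> EffectCurve:
        """Pointwise Wald inference for one coefficient curve.

        Standard errors are ``se(t)^2 = y_t' Cov(gamma_k) y_t`` with ``y_t``
        the basis row at epoch ``t``; p-values are Bonferroni-adjusted by the
        number of basis functions and the confidence band level is raised
        from ``1 - alpha`` to ``1 - alpha/K``.
        """
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        k = self._index_of(covariate)
        K = self.basis.k
        block = self.gamma_cov[k * K : (k + 1) * K, k * K : (k + 1) * K]
        Y = self.basis.matrix
        estimate = self.beta_curves[k]
        var = np.einsum("tk,kl,tl->t", Y, block, Y)
        se = np.sqrt(np.maximum(var, 0.0))
        z = np.zeros_like(estimate)
        pos = se > 0
        z[pos] = estimate[pos] / se[pos]
        z[~pos & (estimate != 0)] = np.inf
        p_raw = 2.0 * stats.norm.sf(np.abs(z))
        m = K
        p_adj = np.minimum(1.0, m * p_raw)
        zcrit = stats.norm.ppf(1.0 - alpha / (2.0 * m))
        return EffectCurve(
            covariate=covariate,
            estimate=estimate,
            se=se,
            ci_lo=estimate - zcrit * se,
            ci_hi=estimate + zcrit * se,
            p_raw=p_raw,
            p_adj=p_adj,
            relative=np.expm1(estimate),
            alpha=alpha,
            bonferroni_factor=m,
        )

    def significant_periods(
        self, covariate: str, alpha: float = 0.05, threshold: float = 0.05
    ) -> list[SignificantPeriod]:
        return extract_significant_periods(
            self.effect_curve(covariate, alpha=alpha), threshold=threshold
        )

    def curves_frame(self, alpha: float = 0.05):
        """Tidy table of all effect curves (one row per covariate x epoch)."""
        import pandas as pd

        return pd.concat(
            [self.effect_curve(c, alpha).to_frame() for c in self.covariate_names],
            ignore_index=True,
        )

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Function-on-scalar regression (wavelet basis, random intercept)",
            "=" * 64,
            f"Basis: {self.basis.filter_name}, level {self.basis.level}, "
            f"{self.basis.k} functions on {self.basis.n} epochs (periodic)",
            f"Subjects: {self.n_subjects}   days: {self.n_days_total}   "
            f"method: {self.method.upper()}",
            f"Variance components: tau^2 = {self.tau2:.4f} "
            f"(between-subject), sigma^2 = {self.sigma2:.4f} (residual)",
            f"Bonferroni factor: {self.basis.k}   band level: "
            f"{1 - alpha / self.basis.k:.5f}",
            "-" * 64,
            f"{'covariate':<12}{'min beta':>10}{'max beta':>10}"
            f"{'min rel%':>10}{'max rel%':>10}{'sig epochs':>12}",
        ]
        for name in self.covariate_names:
            curve = self.effect_curve(name, alpha)
            nsig = int(np.sum(curve.p_adj < 0.05))
            lines.append(
                f"{name:<12}{curve.estimate.min():>10.3f}"
                f"{curve.estimate.max():>10.3f}"
                f"{100 * curve.relative.min():>10.1f}"
                f"{100 * curve.relative.max():>10.1f}{nsig:>12d}"
            )
        lines.append("-" * 64)
        for name in self.covariate_names[1:]:
            for period in self.significant_periods(name, alpha):
                wrap = " (wraps midnight)" if period.wrapped else ""
                lines.append(
                    f"{name}: significant {period.start_clock}-{period.end_clock}"
                    f"{wrap}; extreme {period.extreme_relative:+.1f}% at "
                    f"{period.extreme_clock} "
                    f"(CI {period.extreme_ci[0]:.1f} to {period.extreme_ci[1]:.1f}%, "
                    f"p = {period.extreme_p:.3g})"
                )
        return "\n".join(lines)

    def fit_summary_dict(self) -> dict:
        return {
            "covariates": list(self.covariate_names),
            "gamma": self.gamma.tolist(),
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "n_subjects": self.n_subjects,
            "n_days_total": self.n_days_total,
            "basis": {
                "filter": self.basis.filter_name,
                "level": self.basis.level,
                "n": self.basis.n,
                "k": self.basis.k,
            },
            "method": self.method,
        }

    def plot_effect(self, covariate: str, alpha: float = 0.05, ax=None):
        """Relative-activity band figure for one covariate."""
        import matplotlib.pyplot as plt

        curve = self.effect_curve(covariate, alpha)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        hours = np.arange(N_EPOCHS) * 5 / 60
        ax.plot(hours, 100 * curve.relative, color="C0", label="relative activity")
        ax.fill_between(
            hours,
            100 * np.expm1(curve.ci_lo),
            100 * np.expm1(curve.ci_hi),
            alpha=0.25,
            color="C0",
            label=f"{100 * (1 - alpha / curve.bonferroni_factor):.1f}% band",
        )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("hour of day")
        ax.set_ylabel("relative difference (%)")
        ax.set_title(f"Effect of {covariate}")
        ax.set_xlim(0, 24)
        ax.legend(loc="best", fontsize=8)
        return ax


# ----------------------------------------------------------------------------
# functional wrappers mirroring the operation names used across the package


def fit_fosr(
    days: list[EpochDay],
    covariates: list[CovariateRow],
    basis: WaveletBasis | None = None,
    formula: tuple[str, ...] = DEFAULT_FORMULA,
    **fit_kwargs,
) -> FoSRResults:
    """Build and fit the FoSR mixed model in one call."""
    return FoSRModel(days, covariates, basis=basis, formula=formula).fit(**fit_kwargs)


def pointwise_inference(
    fit: FoSRResults, covariate: str, alpha: float = 0.05
) -> EffectCurve:
    return fit.effect_curve(covariate, alpha=alpha)
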