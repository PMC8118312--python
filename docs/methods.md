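# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data conditions under which the package validates itself.

## Model and assumptions

The response is the log(1+count)-transformed daily activity curve on a fixed
grid of 288 five-minute epochs, `t = 0..287`, with epoch `t` covering clock
time `[5t, 5t+5)` minutes after midnight. For subject `i` and day `j`,

    x_ij(t) = b_i + beta0(t) + sum_k beta_k(t) xi_ik + eps_ij(t),

with subject random intercepts `b_i ~ N(0, tau^2)`, iid residuals
`eps_ij(t) ~ N(0, sigma^2)`, and scalar covariates `xi_ik` (a binary group
indicator, age in years, binary sex; the adjustment set is configurable).
Assumptions worth spelling out:

* the random effect is a single scalar per subject — no functional random
  slopes, so day-to-day correlation is constant across epochs;
* residuals are independent across epochs within a day — any within-day
  autocorrelation beyond the smooth mean structure is not modelled;
* coefficient functions lie exactly in the span of the wavelet basis; the
  part of a true effect orthogonal to the span is invisible to the model.

## The incomplete wavelet basis

The coefficient functions are expanded in the synthesis vectors of the
level-4 **scaling** (approximation) subspace of a *periodized* orthonormal
DWT with the 10-tap Daubechies filter ("d10" in classic filter-length
naming; `db5` in PyWavelets' vanishing-moment naming). Retaining only the
scaling subspace makes the transform an orthogonal projection — a low-pass
smoother `x_sm = Y Y^T x` — with `K = 288/2^4 = 18` basis functions.

Choices and their rationale:

* **Periodic boundary.** The basis functions then have period exactly one
  day, the smoother commutes with circular shifts at the retained scale, and
  midnight is not a boundary artefact — the natural convention for circadian
  curves.
* **Level-4 scaling subspace.** The 288 → 18 dimension arithmetic identifies
  the retained set uniquely as the depth-4 approximation space; one level-1
  d10 function spans 10 epochs = 50 minutes.
* **Explicit 288×18 matrix** rather than fast transforms: n is tiny, and an
  explicit matrix makes the Kronecker regression design and the tests
  transparent. Orthonormality, reproduction of constants, idempotence and
  the rank of the projector are asserted to 1e-8 in the test suite against
  an independent full-DWT route.
* Daubechies, least-asymmetric (`la*`) and Coiflet (`c*`) families are
  selectable; the "best localized" family is not exposed (no orthogonal
  implementation available in the underlying wavelet library).

## Estimation

The stacked model over all subject-days is an ordinary linear mixed model:
fixed-effect design = (covariate row) ⊗ (basis evaluated at t), i.e.
`18·(p+1)` coefficients `gamma`, plus one random intercept per subject.
It is fitted by **REML** with a structure-exploiting reduction:

1. Each day's 288 observations are projected onto the basis (18 coordinates)
   plus an orthogonal-complement residual sum of squares. Because the basis
   is orthonormal and the constant vector (the random-intercept loading)
   lies in its span, this reduction is lossless for the likelihood.
2. At a fixed variance ratio `lambda = tau^2/sigma^2`, the GLS solution and
   the restricted likelihood are available in closed form via rank-one
   Woodbury identities per subject; `sigma^2` profiles out analytically.
3. REML reduces to a bounded one-dimensional minimisation over
   `log(lambda)` (scipy `minimize_scalar`, `xatol = 1e-8`, bounds
   `exp(-20)..exp(12)`), with the `lambda = 0` boundary checked explicitly.

This is exactly REML on the full system — verified in the tests against
statsmodels `MixedLM` (agreement ~1e-6 on fixed effects) and against dense
brute-force GLS at fixed variance components (1e-8). A fit on 500
subject-days takes tens of milliseconds, which is what makes the
Monte-Carlo validation cheap.

Degenerate inputs: if the data are interpolated exactly (e.g. identical
constant days), the quadratic form vanishes; the fit then returns
`tau2 = 0`, `sigma2 -> 0` and a pseudo-inverse covariance instead of
failing. A rank-deficient covariate design (including a covariate constant
across subjects) raises an error naming the offending columns, identified
by pivoted QR.

An optional pre-smoothing of the response (projecting each day onto the
basis span before fitting) changes only the residual variance estimate, not
the coefficient estimates at a fixed variance ratio — a consequence of
projection orthogonality that the tests assert; its residual degrees of
freedom then count 18 observations per day.

## Inference and reporting

* Pointwise standard errors: `se(t)^2 = y_t' Cov(gamma_k) y_t`, Wald z
  statistics, two-sided normal p-values. Large-sample inference only; no
  small-sample degrees-of-freedom correction (a documented limitation —
  with hundreds of epochs per day the stacked sample is large, but
  variance-component uncertainty is ignored).
* Multiplicity: fixed Bonferroni factor equal to the number of basis
  functions (18 by default) — `p_adj = min(1, 18 p_raw)` — and confidence
  bands at level `1 - alpha/18` (0.99722 at alpha = 0.05). The factor
  follows the effective dimension of the fitted curve, not the 288 display
  epochs.
* Relative activity: effects are mapped to the 1+count ratio scale as
  `(exp(beta) - 1)·100 %`; CI endpoints are transformed by the same map.
* Periods: maximal runs of epochs with `p_adj` below the threshold (default
  0.05) are reported with the epoch of largest |relative difference| (ties
  broken to the earliest epoch for determinism), its CI and adjusted p.
  The day is treated as circular: a run crossing midnight is reported once,
  flagged `wrapped`, with `start_epoch > end_epoch`.

## Synthetic cohorts — what they emulate and what they do not

The generator simulates the model forward on the log scale and
back-transforms with `counts = max(round(exp(y) - 1), 0)`, so the fitted
model is correctly specified up to integer rounding. Defaults define the
validation conditions:

| parameter | default | why |
|---|---|---|
| subjects per group | 50 | typical of small clinical cohorts |
| days per subject | 5 | within the 1–8 days a device is worn |
| nocturnal plateau (log scale) | 2.0 (~1.2 counts/min) | low but nonzero sleep movement; keeps the count-rounding bias of the back-transform below ~0.005 on the log scale (at near-zero nocturnal counts rounding alone would distort group contrasts by ~0.1) |
| daytime plateau (log scale) | 7.3 (~300 counts/min) | light-activity dominated waking day; night ~23:20–07:40 with 30-min raised-cosine transitions and a gentle midday crest |
| group effect | two Gaussian dips (sd ≈ 12 min) at 06:05 and 21:40, depth log(1−0.4) | localized morning/evening deficits of −40 % relative activity |
| age, sex effects | −0.01 per year; +0.15 | small log-scale shifts |
| tau, sigma | 0.3, 0.5 | moderate subject heterogeneity; epoch noise |
| age, sex distributions | N(67, 7) truncated to [50, 90]; Bernoulli(1/2) | older-adult cohort |

By default the true curves are projected onto the wavelet basis
(`snap_to_basis`), so exact `gamma_true` exist; the narrow default dips are
substantially attenuated by the 18-function resolution (centre depth
≈ −0.23 after projection), which is faithful to what the method can resolve.

Not emulated: non-wear artefacts (beyond what the QC screen is tested with),
within-day residual autocorrelation, device-specific count scaling,
overdispersion beyond the log-normal-plus-rounding mechanism, and seasonal
or weekday structure. Passing recovery/coverage tests therefore shows the
estimator is correct *under its own assumptions*, not that real recordings
satisfy those assumptions.

## Preprocessing and QC

* 60-second exports are aggregated to the 5-minute grid by summation
  (conserving daily totals exactly; mean aggregation is a switch).
* Only days with complete 24-hour coverage enter the model; partial days
  are dropped with a warning.
* A day is invalid when more than half of its epochs in the 08:00–22:00
  window are zero — an operationalisation of excluding recordings with
  implausible zero runs scattered through waking hours; both the window and
  the threshold are configurable, and a subject is excluded only when all
  of their days fail.
* Whether counts are vertical-axis or vector-magnitude is not fixed by the
  CSV format; the single `count` column is taken as-is.

## Validation results computed by the suite

The test suite (not this document) computes: exact agreement of the fixed-
component fit with dense GLS; REML agreement with an independent mixed-model
implementation; shrinkage of `mean |gamma_hat - gamma_true|` from 10 to 50
subjects per group; empirical pointwise band coverage ≥ 0.95 at nominal
0.99722 (200 replicates); family-wise error ≤ 0.081 under a null group
effect (200 replicates); power ≥ 0.8 against a −60 % dip ten epochs wide
(100 replicates); and ≥ 95 % destruction of a detected period under group-
label permutation. Replicate counts and cohort sizes were chosen to keep
each study in the seconds-to-a-minute range while leaving Monte-Carlo error
well inside the asserted margins.

## Known limitations

* The Bonferroni-by-18 correction is conservative for the correlated
  pointwise tests; no FDR alternative is offered.
* Variance-component uncertainty is not propagated into the bands.
* The comparator sum-score regression treats per-subject day means as
  independent observations (as is conventional), ignoring day counts.
* Sum-score cut-points are per-minute; when only 5-minute epochs exist the
  pipeline distributes counts evenly over minutes, which cannot create
  vigorous minutes out of bursts shorter than the epoch.
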