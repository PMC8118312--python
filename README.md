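# circafosr

Function-on-scalar regression with a periodic wavelet basis for 24-hour
accelerometer count data.

## The problem

Wearable accelerometers summarise bodily movement as non-negative "activity
counts" per epoch. Conventional analyses collapse a week of recording into a
handful of sum scores (percent time sedentary, average counts per day) and
lose *when* during the day two groups differ. `circafosr` treats each
subject-day as a function of clock time and asks, epoch by epoch, whether a
scalar covariate — typically a clinical group indicator — shifts the
circadian activity profile, while adjusting for age and sex. It is aimed at
biostatisticians and clinical researchers comparing rest–activity rhythms
between groups (e.g. healthy older adults versus people with mild cognitive
impairment).

## The model

Each day is aggregated to 288 five-minute epochs (24 h = 1440 min = 288 × 5)
and log-transformed. For subject *i*, day *j* and epoch *t* = 0,…,287:

```
x_ij(t) = b_i + β₀(t) + Σ_k β_k(t) ξ_ik + ε_ij(t)
```

* `x_ij(t)` — log(1 + count) in epoch *t*;
* `ξ_ik` — scalar covariates (group, age, sex);
* `b_i ~ N(0, τ²)` — subject random intercept (repeated days are correlated);
* `ε_ij(t) ~ N(0, σ²)` — iid residuals.

Every coefficient function is expanded in the columns of the low-pass matrix
`Y_lp` of an **incomplete periodic discrete wavelet transform**: only the
level-4 scaling coefficients of a periodized Daubechies-10 ("d10") DWT of
the 288-point daily grid are retained, giving 288/2⁴ = **18 orthonormal,
day-periodic basis functions** (one level-1 d10 function spans 50 minutes of
clock time):

```
β_k = γ_k Y_lpᵀ,        x_sm = Y_lp Y_lpᵀ x   (the projection smoother)
```

The stacked model is a linear mixed model with 18·(p+1) fixed coefficients
and one random intercept per subject; it is fitted by REML (profiled
analytically down to a one-dimensional search over τ²/σ²). Pointwise Wald
inference uses `se(t)² = y_tᵀ Cov(γ̂_k) y_t`; p-values are Bonferroni-adjusted
by the number of basis functions (×18) and confidence bands are widened from
level 1−α to 1−α/18. Effects are reported as relative activity
`(exp(β)−1)·100 %`, and maximal runs of epochs that stay significant are
reported as periods with the largest relative difference, its CI and p.

Because no recordings ship with the package, a first-class synthetic cohort
generator simulates the model forward (counts = `round(exp(y)−1)` clipped at
0) so recovery, coverage and error-rate properties are all testable.

## Worked example

```python
from circafosr import SimulationConfig, simulate_cohort, FoSRModel

cohort = simulate_cohort(SimulationConfig(seed=3))   # 50/group, 5 days each
results = FoSRModel(cohort.days, cohort.covariates).fit()
print(results.summary())
```

```
Function-on-scalar regression (wavelet basis, random intercept)
================================================================
Basis: d10, level 4, 18 functions on 288 epochs (periodic)
Subjects: 100   days: 500   method: REML
Variance components: tau^2 = 0.0802 (between-subject), sigma^2 = 0.2531 (residual)
Bonferroni factor: 18   band level: 0.99722
----------------------------------------------------------------
covariate     min beta  max beta  min rel%  max rel%  sig epochs
intercept        1.446     7.887     324.4  266136.5         288
group           -0.330    -0.060     -28.1      -5.9          45
age             -0.010    -0.006      -1.0      -0.6           0
sex              0.175     0.233      19.1      26.2         287
----------------------------------------------------------------
group: significant 05:20-07:00; extreme -28.1% at 06:10 (CI -39.6 to -14.4%, p = 2.62e-07)
group: significant 21:00-22:55; extreme -24.8% at 22:05 (CI -36.8 to -10.5%, p = 1.74e-05)
sex: significant 05:00-04:50 (wraps midnight); extreme +26.2% at 10:35 (CI 6.0 to 50.3%, p = 0.00115)
```

The generator injected two localized group dips (morning ≈ 06:05, evening
≈ 21:40, −40 % at the centre before basis smoothing); the fit recovers both
as significant periods with the correct timing, attenuated by the 18-function
resolution. τ̂² and σ̂² are close to the generating values (0.09, 0.25). The
wrapped sex period illustrates circular (across-midnight) run handling.

Variance components, estimates and bands are also available programmatically
(`results.tau2`, `results.effect_curve("group")`,
`results.significant_periods("group")`), and `results.plot_effect("group")`
draws the relative-activity band figure.

A command-line pipeline covers the same ground:

```
circafosr simulate --out sim --seed 1 --epoch-seconds 60
circafosr preprocess --in sim/epochs.csv --epoch-seconds 60 --out clean.csv
circafosr fit --epochs clean.csv --covariates sim/covariates.csv --out fit_out
circafosr sumscores --in sim/epochs.csv --covariates sim/covariates.csv --out sums.csv
circafosr run --demo --out demo_out
```

`sumscores` provides the conventional comparator: Troiano cut-point
classification (sedentary ≤ 99 counts/min, light 100–2019, moderate
2020–5998, vigorous ≥ 5999), percent time per level, and an age/sex-adjusted
OLS group comparison of average counts per minute.

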