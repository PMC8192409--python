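# Methods

## The model

Exhaustive constant-intensity exercise above the heavy/severe boundary is
described by a two-parameter hyperbola.  For running, the parameters are
the critical speed CS (m/s) — the asymptote of the speed–duration curve,
the highest speed for which tolerance is not predictably limited — and
d′ (m), the finite distance that can be covered above CS before
exhaustion.  The same relationship can be written with any of four
variable pairs on the axes:

    t(s) = d′ / (s − CS)
    d(s) = s · d′ / (s − CS)
    s(t) = d′ / t + CS
    d(t) = d′ + CS · t

with t the time to exhaustion (s), s the running speed (m/s) and
d = s·t the distance (m).  The four forms are algebraically equivalent:
given exact data they all determine the same (CS, d′), and the package
treats this equivalence as a testable invariant (all four fits recover
the generating parameters to ≤1e−8 relative error on noiseless data).

Canonical internal units are m/s, s, m.  Incremental-test speeds in
km/h are converted at the boundary (exact factor 1000/3600).  The peak
speed of an incremental test is the last fully completed stage speed
plus the completed fraction of the next stage times the increment.

## Why the fitted form matters

Although the forms are equivalent algebraically, least squares
minimises error along the vertical axis only, so the choice of form is
a statistical commitment about where the error lives.  In a fixed-speed
protocol, speed carries no error; time to exhaustion is the measured,
error-carrying variable, and distance inherits its error exactly
(distance error = speed × time error, since d = s·t with exact s).
Consequently:

* **t(s), d(s)** — appropriate dependent variables.  Because the time
  error is heteroscedastic (variance proportional to the time itself),
  weighted least squares is used with inverse-variance weights:
  w ∝ 1/t for t(s) and w ∝ 1/(s²t) for d(s), from Var(d) = s²·Var(t).
* **s(t)** — the wrong dependent variable: speed was set by the
  experimenter, so minimising speed residuals misattributes the error.
  Noise in t enters the regressor 1/t, which attenuates the estimated
  slope (d′ biased low) and inflates the intercept (CS biased high) —
  the classic errors-in-variables direction.
* **d(t)** — both axes carry errors and those errors are perfectly
  correlated (endogeneity); no standard regression method is valid.
  The package still fits it (ordinary LS), because quantifying the
  behaviour of frequently used but inappropriate procedures is part of
  the point; the selector's classification travels with every result.

The selector generalises this to any design: a directed form y(x) is
WLS-appropriate iff x is the fixed variable; wrong-dependent iff y is
the fixed variable; endogenous otherwise.  For each of the three
designs (fixed speed, fixed distance, fixed time) the six directed
forms split exactly 2/2/2.  At extremely high ergometer power or when
cycling outdoors, power itself becomes error-carrying; the selector
then reports geometric mean regression as the recommendation and does
not implement it.

### A consequence of exact inverse-variance weights

With w ∝ 1/(s²t) on the distance residuals, the d(s)-WLS objective is
algebraically identical to the t(s)-WLS one: each distance residual is
the speed times the time residual, and the s² in the weight cancels it.
The two statistically appropriate procedures therefore return
bit-identical estimates here, and their Bland–Altman comparison is
degenerate (zero-variance differences, flagged as such).  Published
analyses that report a small nonzero difference between these two
procedures are implicitly using weights that are not exactly s²-scaled;
`build_weights(..., scheme="time")` (w ∝ 1/t on distance residuals)
reproduces that behaviour and is provided as a sensitivity switch.
This exact equivalence is the strongest form of the expectation that
appropriate procedures should agree.

## Fitting

Minimisation is Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`) on weighted residuals √w·(y − ŷ), with analytic
Jacobians.  Choices:

* **Initialisation** — the closed-form OLS line of d on t (always
  defined for distinct times; a crude through-the-origin fallback
  covers the all-times-equal corner that only the hyperbolic variants
  can fit).
* **Constraint** — the hyperbolic variants have a genuine singularity
  at s = CS, so CS is kept strictly below the smallest trial speed via
  the reparameterisation CS = s_lim − exp(θ), s_lim = min(s)·(1−1e−6).
  The transform is smooth and unbounded, so LM runs unconstrained.
  Optima with CS ≤ 0 or d′ ≤ 0 are returned as-is with
  `params_valid=False`.
* **Convergence** — relative tolerances (xtol/ftol/gtol) default to
  1e−12, with a generous evaluation cap; non-convergence is reported in
  the result, never raised.  For the two linear-in-parameter variants
  (d(t); s(t) is linear in (CS, d′) with regressor 1/t) LM reaches the
  normal-equations solution essentially exactly (tested to 1e−10).
* **Degenerate designs** — repeated trial speeds are rejected at
  construction; all-equal times make s(t)/d(t) singular and raise.

### Fit-quality metrics

* **SEE** of each parameter: square roots of the diagonal of
  s²(JᵀWJ)⁻¹, with J the Jacobian of model predictions w.r.t.
  (CS, d′) at the optimum, W the weight matrix (identity for LS) and
  s² the weighted RSS over n − 2 degrees of freedom.  This is the
  standard curve-fit covariance estimate; it is undefined (NaN, and an
  error from the accessor) for n ≤ 2.
* **%SEE** = 100·SEE_CS/CS + 100·SEE_d′/d′ — a single relative
  fit-quality number combining both parameters.
* **RSE** = √(RSS/(n − 2)) on *raw* residuals, in the units of the
  fitted vertical axis (s, m, or m/s).  Raw rather than weighted
  residuals are used so that RSE magnitudes retain their natural units;
  the weighted variance enters only the SEEs.  RSE values are not
  comparable across procedures with different vertical axes — a fit
  that puts speed on the vertical axis reports a deceptively small RSE.

## Agreement battery

For paired per-subject estimates (a_i, b_i) of one quantity from two
procedures, with d_i = a_i − b_i and m_i = (a_i + b_i)/2:

* systematic bias = mean(d), tested by a paired two-sided t-test;
* random error = 1.6 × SD(d) by default — the multiplier is
  configurable, with 1.96 giving conventional 95% limits of agreement;
* proportional bias = OLS slope of d on m, with its residual standard
  error √(RSS/(n−2)) and two-sided slope test;
* gates: Shapiro–Wilk normality of d, and the Durbin–Watson statistic
  of the proportional-bias regression residuals with the 1.5–2.5
  acceptance window.  Durbin–Watson is order-sensitive; the input
  (cohort table) order is used and documented as such.
* zero-variance differences (identical procedures) are a degenerate
  case: bias and random error are exact zeros and the tests are
  reported NaN with a flag rather than fabricated.

For three or more procedures, a one-way repeated-measures ANOVA is run
(via pingouin), with Mauchly's test gating a Greenhouse–Geisser df
correction at p ≤ 0.05 (both corrected and uncorrected p are kept) and
Holm-adjusted paired t-tests for all pairs.  Incomplete designs are
rejected, never imputed.

## Synthetic cohorts

The generator emulates a fixed-speed treadmill study:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 16 | runners per cohort |
| cs_mean ± cs_sd | 4.39 ± 0.41 m/s | truncated-normal truth for CS |
| dprime_mean ± dprime_sd | 226 ± 57 m | truncated-normal truth for d′ |
| pct_ps | 0.9, 1.0, 1.1, 1.2 | trial intensities as fractions of PS |
| t100_mean ± t100_sd | 356 ± 72 s | true time at 100% PS |
| noise_cv | 0.05 | CV of observed time at the 100% PS trial |
| noise_family | gamma | positive-support noise (lognormal optional) |

Peak speed is anchored through the 100%-PS time rather than drawn
independently: PS = CS + d′/t100.  This keeps simulated durations in
the physiological range (≈15 min at 90% PS down to ≈1.7 min at 120%)
and guarantees every configured intensity exceeds CS; infeasible draws
are rejected and resampled with a cap.

Observed times have mean t_true and variance c·t_true with
c = noise_cv²·t100, i.e. exactly the Var(t) ∝ t law the WLS weights
assume, with noise_cv the CV of the 100%-PS trial (longer trials have
larger absolute SD but smaller CV).  The gamma family is the default
because it is positive-supported; the lognormal alternative is
moment-matched.  True parameters are written only in clearly suffixed
`true_*` columns so recovery checks cannot leak into real-data
workflows.

What the generator does **not** emulate: day-to-day (test–retest)
variability, familiarisation effects, treadmill speed resolution, or
model misspecification (three-parameter or exponential truths).
Passing recovery tests therefore show correctness of the estimator
under the stated noise law, not robustness of the model on real
athletes.

### Bias-direction behaviour

Across many simulated cohorts the wrong-dependent s(t)-LS procedure
overestimates CS and underestimates d′ relative to t(s)-WLS — the
attenuation direction described above, and the sign pattern reported
for real cohorts.  The *magnitude* of that bias scales with the square
of the noise CV while its cohort-to-cohort sampling spread scales
linearly, so at the default 5% CV the direction is guaranteed only in
expectation (it holds in roughly three cohorts out of four; the grand
mean over 200 cohorts is reliably signed).  Near-unanimous per-cohort
direction requires noise CVs around 10–15%, which is where published
test–retest variability of time to exhaustion actually lies.  The
suite asserts the strict per-cohort-consistency form of this property
at the default noise level and it is expected to fail there; the
sign-of-the-mean form is asserted separately and holds.

## Problem sizes

The test suite and the reproduction script use: 100 noiseless subjects
for the equivalence check; 1,000 random designs for the
normal-equations cross-check; 500 cohorts (16 × 4 trials) for recovery
at the default noise plus 150-cohort grids for the noise sweep; 200
cohorts for bias direction; 2,000 null replicates (16 subjects each)
for the type-I-error calibration of the systematic-bias test, whose
empirical rejection rate at α = 0.05 lands within 5% ± 1.5%.
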