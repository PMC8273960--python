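# Methods

## The model

A waking day of fixed length is partitioned into sedentary behaviour
(SB), light-intensity physical activity (LIPA) and moderate-to-vigorous
physical activity (MVPA).  The three daily durations carry only relative
information: adding time to one behaviour necessarily removes it from
another.  `movecox` therefore treats the triple as a composition on the
2-simplex, closed to a 16-h (960-min) waking day, and maps it to two
unconstrained coordinates with the pivot isometric log-ratio (ilr)
transform.  For pivot order (a, b, c),

    z1 = sqrt(2/3) * ln( a / sqrt(b*c) ),    z2 = sqrt(1/2) * ln( b / c ).

Three *rotations* of the pivot put SB, LIPA or MVPA first:

| rotation | pivot order | z1 reads as | z2 reads as |
|---|---|---|---|
| SB_FIRST | (SB, LIPA, MVPA) | SB vs both activities | LIPA vs MVPA |
| LIPA_FIRST | (LIPA, SB, MVPA) | LIPA vs SB and MVPA | SB vs MVPA |
| MVPA_FIRST | (MVPA, SB, LIPA) | MVPA vs SB and LIPA | SB vs LIPA |

The rotations are orthogonal reparameterisations of one model: the Cox
partial likelihood, linear predictors, and every downstream hazard-ratio
contrast are identical across them (asserted to 1e-6 in the tests); only
the pair (beta_z1, beta_z2) rotates.

Incident cardiovascular disease is modelled with a cause-specific Cox
proportional-hazards regression on (z1, z2) plus covariates,

    h(t | z, x) = h0(t) exp(beta_z1 z1 + beta_z2 z2 + gamma' x),

with non-CVD death treated as censoring and the Efron approximation for
tied event times (follow-up is recorded in days, so ties occur).  The
partial-likelihood maximisation is delegated to lifelines; the
compositional layer, contrasts and diagnostics are implemented here.
Two named adjustment sets mirror the usual staged adjustment:
`model-1` (sociodemographic + lifestyle) and `model-2` (additionally
cardiometabolic risk factors and a multimorbidity count).

## Reallocation contrasts

The fitted model is interrogated through hypothetical time
reallocations: move `delta` minutes from one behaviour to another,
holding the third behaviour and the waking total fixed, starting from a
labelled reference composition.  Because covariates are held at the
reference, the contrast depends only on the ilr displacement:

    log HR = beta_z . dz,    dz = ilr(reallocated) - ilr(reference),
    se(log HR) = sqrt(dz' Sigma_z dz),

with `Sigma_z` the (z1, z2) block of the coefficient covariance (delta
method; covariate terms cancel exactly).  95% intervals use the normal
quantile 1.959964.  A displacement that would drive a behaviour to zero
or below raises an "infeasible" signal which the report tables render as
missing cells rather than numbers.

Reference compositions come in two families:

* MVPA-anchored (labels A/B/C): MVPA fixed at 10 min, the daily
  guideline equivalent `round(150/7) = 21` min, or 30 min; SB takes a
  stated share (default 77%) of the remaining waking time and LIPA the
  rest.  The published reference durations rounded to h:min are not all
  exactly recoverable from a single 77% share, so the package keeps
  exact fractional minutes and leaves rounding to display code.
* SB-anchored (labels 1/2): SB fixed (e.g. 9 h and 14 h, the 5th and
  95th percentiles), MVPA fixed at 10 min, LIPA the remainder.

`hr_surface` evaluates the same contrast over a simplex grid (default
step 5 min) restricted to the observed behaviour ranges, and
`plotting.plot_hr_surface` renders it as a barycentric (ternary) heatmap
with the reference composition marked; colour clipping at [0.8, 1.3] is
display-only.

Reallocations are asymmetric by construction: log-ratios change faster
when a behaviour shrinks than when it grows, so with protective MVPA
coefficients removing 10 min of MVPA raises the hazard more than adding
10 min lowers it — the qualitative pattern the analysis is designed to
expose.  As delta -> 0 the contrast is first-order antisymmetric.

## Zero imputation (lrEM)

Daily durations of exactly zero (in practice zero MVPA) are below the
measurement resolution of one 60-s epoch, not structural zeros.  They
are treated as left-censored below a detection limit (default 1 min/day)
in additive log-ratio coordinates: with a reference behaviour observed
in every subject, alr coordinates are modelled as bivariate normal and
censored cells contribute `y < ln(DL / x_ref)`.  EM alternates truncated
normal conditional moments with normal MLEs, starting from a
multiplicative replacement at 0.65·DL; convergence is declared when no
parameter moves by more than 1e-8 (cap 500 iterations, exceeding it is
an error carrying diagnostics).  Imputed cells are the conditional
truncated means — guaranteed inside (0, DL) — and each row is re-closed
to its original total.  The observed-data log-likelihood is
non-decreasing across iterations (property-tested), and the imputation
matches a brute-force univariate censored-normal EM when the coordinates
are independent (oracle test).

## Epoch aggregation

60-s epochs of average acceleration (ENMO, milligravity) within waking
wear time are classified with half-open intensity intervals —
SB `[0, 40)`, LIPA `[40, 100)`, MVPA `[100, inf)` mg, with a 45-mg
SB/LIPA boundary as a sensitivity set — so the bands are exhaustive and
disjoint at any fractional value.  A day is valid when wear covers at
least 2/3 of waking time; a subject needs at least 2 valid weekdays and
2 valid weekend days, otherwise it is excluded (a logged signal, not an
error).  With 7 valid days the plain mean is used, otherwise weekday and
weekend stratum means are recombined with the calendar weights 5/7 and
2/7; with a full 5+2 week the two rules coincide (tested).  Non-wear
epochs are excluded from counting; wear and waking flags are inputs —
sleep detection and non-wear imputation are upstream concerns outside
this package.

## Synthetic cohort generator

Real cohort data of this kind are access-restricted, so the generator
reproduces the statistical structure the analysis assumes and every
stage is exercised on it:

* **Compositions** are logistic-normal: bivariate normal in SB-pivot ilr
  coordinates, back-transformed and closed to 960 min.  The default
  mean `(1.58582, 1.00010)` and covariance
  `[[0.197633, 0.097465], [0.097465, 0.141925]]` were moment-matched by
  simulation (400k draws, Nelder-Mead on relative squared moment errors)
  to the published sample moments — means 692.1/209.5/58.4 and SDs
  88.4/65.1/37.6 min/day — and reproduce them to the printed precision.
  The published table gives no between-behaviour covariances; the
  closure constraint itself then forces strong negative SB-activity
  correlations (about -0.92 with LIPA, -0.75 with MVPA), which we
  document as an assumption rather than a calibration target.
* **Covariates** follow the published prevalences (mean age 68.9 (5.6),
  26.7% women, 46.1% hypertensive, 11.1% diabetic, BMI 26.3 (4.2) with
  derived overweight/obese indicators, a 0/1/2+ multimorbidity count,
  ...), drawn independently of the composition.  Their log-hazard
  effects (`default_gamma`) are plausible epidemiological magnitudes
  chosen to give the adjustment sets something to do; they are not
  published estimates.
* **Event times** use inverse-transform sampling from a Weibull
  baseline (default exponential, scale 78 years) scaled by
  `exp(beta_z . z + gamma . x)` with empirically centred predictors;
  competing non-CVD death is an independent exponential (rate 0.012/y)
  and administrative censoring is uniform on 6.0-7.5 years (staggered
  entry against a fixed end of follow-up).  The scale was solved by
  bisection so the default configuration yields ~9% cumulative
  incidence (≈299 events in 3319 subjects) and a mean follow-up of
  ≈6.2 years; observed follow-up SD is ≈1.55 y, slightly above the
  published 1.3, a known simplification.  Follow-up is rounded to whole
  days so ties exercise the Efron machinery.  Default
  `beta_z = (ln 1.24, ln 1.16)` matches the direction and size of the
  fully adjusted SB-pivot coefficients.
* **Zeros**: each subject's MVPA is recorded as 0 with probability 1%
  (the zero-MVPA prevalence is not published; the rate is a config
  knob), with the true underlying composition still driving the hazard,
  so recorded zeros behave like measurement censoring.
* **Epoch streams** emit 960 one-minute waking epochs per day with
  behaviour-conditional uniform ENMO draws (SB [0,40), LIPA [40,100),
  MVPA [100,300) mg) in exact or multinomial counts, with optional
  wear-dropped days for testing the validity rules.

What passing tests on these data do *not* show: robustness to
posture-misclassification between SB and LIPA, informative censoring,
composition-covariate confounding (off by default; a knob exists via
covariate-shifted simulation), or seasonal/within-week structure in real
accelerometer traces.

## Proportional-hazards diagnostics

The Grambsch-Therneau test is implemented as the score test for a
time-varying coefficient `beta_j(t) = beta_j + theta_j g(t)`: with
Schoenfeld residual sums and per-event-time risk-set information
contributions, the global statistic is `U' W^{-1} U ~ chi2(p)` where `W`
is the Schur-complement variance (see `CompositionalCoxResults.ph_test`
docstring).  The classical shortcut that replaces per-time risk-set
variances by the averaged information was measurably anticonservative
under day-rounded ties (≈6.6-6.8% rejection at the 5% level in null
simulations), so the exact construction is used; its null level is
≈5% in 500-rep simulations and per-term values agree with a brute-force
loop reimplementation to 1e-8.  Transforms: `rank` (default),
`identity`, `log`, `km`, applied to all follow-up times and centred at
the event mean.

Effect modification is tested by adding `modifier*z1` and `modifier*z2`
to the fully adjusted model and jointly Wald-testing the two
interaction coefficients (2 df); the per-term Wald tests are reported
alongside, since with a single ilr pair either convention is defensible.
Under the study-calibrated ilr variance and ~300 events, this test has
limited power: ≈30% against a 0.4 shift of the stratum z1 coefficient
and >50% only from ≈0.8 — the power test in the suite asserts the
computed 0.8 figure.

## Numerical choices and problem sizes

* Closure sets the third part by subtraction so totals are exact in
  floating point; internal units are fractional minutes, no rounding
  inside computations.
* Collinear or constant covariate columns are rejected before fitting,
  naming the offending terms (SVD with a 1e-8 relative threshold).
* CI level fixed at 95% (quantile 1.959964).
* Monte-Carlo suite sizes: the rotation-invariance and asymmetry checks
  use one cohort of n=3319; parameter recovery uses 200 cohorts of
  n=3319 (bias band 0.03, coverage band [91%, 98%]); the type-I-error
  study uses 500 cohorts of n=1500 — the level of the Wald, interaction
  and PH tests does not depend on n at these event counts, and the
  measured rates match those at n=3319 — with "≈5%" operationalised as
  ±3 binomial SE for the PH test.  All simulation tests are seeded;
  property tests run a derandomised hypothesis profile.

## Known limitations

* Cause-specific hazards only; no Fine-Gray subdistribution model.
* Three behaviours only — sleep is outside the composition, and no
  amalgamations beyond the three pivot rotations are offered.
* Single-record input per subject (no time-varying covariates,
  counting-process data or frailties).
* The delta-method CI for reallocation contrasts conditions on the
  covariate values cancelling; a bootstrap cross-check is a natural
  extension and is not implemented.
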