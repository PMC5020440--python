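# Methods

## Model and procedure

The package tests a rank-based social-norms model of intoxication
judgments.  Respondents surveyed in night-time drinking environments are
partitioned into reference groups, one per gender × location cell, on
the assumption that these are the people a drinker compares themselves
with.  For a respondent in a group of size *n* with `below` members at
strictly lower BrAC and `above` at strictly higher, the relative rank is

    R = below / (n − 1)

and the asymmetrically weighted rank is

    SR(η) = 1/2 + (below − η·above) / (2·(below + η·above)),   η > 0,

which reduces algebraically to R at η = 1.  η captures comparison bias:
η < 1 up-weights more-sober comparators (a "downward" bias), η > 1
more-intoxicated ones.

The substantive test is a ladder of OLS regressions per judgment
outcome (four 1–10 ratings: perceived drunkenness, extreme drinking,
long-term health risk, cirrhosis risk): BrAC alone, R alone, both
jointly with a central-tendency control (the distance between the
respondent's BrAC and their group's mean BrAC), and finally a covariate
sensitivity set (session duration, after-11pm flag, gender, FAST, age).
Under a rank mechanism the joint models retain only the rank
coefficient.  η is then estimated per outcome by exhaustive grid search
(0.01 to 5.00 in steps of 0.01), selecting the η whose simple
`outcome ~ SR(η)` regression maximizes R².

### Assumptions

- Judgments are linear in the chosen predictor with additive Gaussian
  error; inference is normal-theory OLS.
- The comparison set is the full same-gender, same-location survey pool
  (judgment respondents are ranked against everyone surveyed there, not
  just against other judgment respondents).
- Zero-BrAC respondents are present in the environment and therefore
  count as comparators and enter the group mean, but are themselves
  excluded from judgment analyses (the hypotheses concern drinkers).
- Ties: "strictly lower" is read literally — tied members count in
  neither direction.  A mid-rank option ((below + ties/2)/(n − 1)) is
  provided for sensitivity but is not the default.  A member tied with
  all comparators gets R = SR = 0.5 (the symmetric limit); members of
  singleton groups get missing ranks and a logged warning.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| η grid | 0.01–5.00 step 0.01 | — | exhaustive scan; argmax selected, ties to the smallest η at 1e-12 R² tolerance; no interpolation and no uncertainty interval (a seed-resampling spread is available as a diagnostic) |
| pool size | 1,862 | persons | the surveyed-population scale the analysis assumes |
| judgment subsample | 400 | persons | the analysis-sample scale; Model 4 power is calibrated to it |
| male fraction | 0.632 | — | pool composition |
| BrAC targets | M 52.3 (SD 30.0), F 43.0 (SD 27.8) | μg/100 ml | per-gender *observed* moments of the generated distribution |
| location offsets | −8, −3, +3, +8 | μg/100 ml | between-group mean variation, large enough that rank and absolute BrAC are meaningfully different measures |
| location scales | 0.56, 0.80, 1.08, 1.31 | × gender SD | within-group spread heterogeneity (see below) |
| zero-BrAC fraction | 0.05 | — | sober passers-by; share not documented, set to a small plausible value |
| mechanism noise | per outcome | rating units | residual SD implied by each outcome's published simple-rank R² and rating SD (e.g. 1.98·√(1−0.22) ≈ 1.75 for perceived drunkenness) |

## The synthetic-data generator

BrAC is drawn per gender × location cell from a normal truncated below
at zero.  The configured mean/SD are treated as targets for the
*truncated* distribution, and the latent (μ, σ) are solved by a 1-D
root find (the ratio sd/(mean − lower) is strictly monotone in the
standardized truncation point); naive truncation of N(52.3, 30²) would
inflate the observed mean to ≈ 55.  Targets with SD ≥ mean are
infeasible for a lower-truncated normal and are rejected with a clear
error.

Location enters the BrAC distribution twice: an additive mean offset
and a multiplicative SD scale.  The scale heterogeneity is deliberate.
In a homoscedastic design, within-group rank is essentially a monotone
(probit-shaped) function of the distance to the group mean, so the
three joint-model predictors {BrAC, R, distance} become nearly
collinear (auxiliary R² ≈ 0.95, VIF ≳ 20) and the joint models lose the
power the study's own diagnostics imply.  With the default scales the
cohort reproduces the study's published collinearity structure —
Spearman ρ(BrAC, R) ≈ 0.95 and VIF near 8 for the rank term — while the
pooled within-gender SDs stay at their configured targets.  Offsets and
scales pair low-mean with low-spread locations so every cell remains a
feasible truncated-normal target.

Judgment ratings are generated as
`intercept + slope·predictor (+ covariate effects) + N(0, noise_sd)`,
with the predictor R, SR(η), or raw BrAC.  Ratings are continuous by
default so OLS refits are unbiased; an optional discretize flag rounds
and clips onto the 1–10 instrument scale at the cost of a small
attenuation.  The `noise_sd_for_target_r2` helper calibrates noise so a
simple regression attains a requested population R².  A judgment
request larger than the eligible pool is served by sampling with
replacement (independent noise per draw) when explicitly enabled;
otherwise it is an error.

Covariates (session duration, after-11pm flag, FAST, age) are generated
independently of BrAC at the published summary-table means/SDs, with
simple truncation/clipping rather than moment matching — their observed
moments therefore shift slightly (e.g. ages truncated at 18 average
≈ 29 rather than 26.3).  Only BrAC, whose moments the analysis pins, is
moment-matched.

### What the generator does and does not emulate

It reproduces the group structure, gender/location BrAC differences,
the BrAC–rank collinearity, realistic noise levels, and mechanisms that
generate judgments from rank, weighted rank, or absolute BrAC.  It does
**not** emulate right skew in the BrAC tail (the study's top decile is
far above a truncated normal's), venue-level social clustering,
covariate–BrAC dependence (an optional correlation is out of scope), or
group sizes as unbalanced as the study's (142–343); locations are
assigned uniformly.  Passing tests therefore show the *estimators* are
correct and well-calibrated at the study's scales, not that real street
surveys satisfy the generator's assumptions.  One consequence: uniform
subsampling of drinkers yields a judgment-subsample mean BrAC of ≈ 48.9
(the gender-weighted average of the per-gender means), about 1.6
μg/100 ml above the published subsample mean — the real subsample was
evidently slightly soberer than the pool average, a selection feature
the generator does not model.

## Numerical choices

- OLS via statsmodels; standardized β by refitting on z-scored
  variables (n − 1 denominator; binaries z-scored like continuous).
  A constant outcome returns zero slopes and R² = 0 rather than NaN.
- VIF by explicit auxiliary regressions, `1/(1 − R²_i)`; perfect
  collinearity reports `inf` (an exception is reserved for the *design*
  matrix of a model fit, which names the collinear columns).
- The η-scan R² is computed as the squared Pearson correlation of
  SR(η) with the outcome — identical to the simple-OLS R² — so a
  500-point scan over thousands of rows is a vectorized pass.
- Grid argmax ties resolve to the smallest η (compared at 1e-12).
- Degenerate inputs: all-tied groups → 0.5; singleton groups → missing
  rank with a warning; zero-variance SR → R² = 0; schema violations in
  survey CSVs → per-row diagnostics and (in the CLI) nonzero exit.
- Determinism: every stochastic step takes one integer seed through
  `numpy.random.default_rng`; identical config + seed reproduces the
  survey table byte-for-byte and the report payload exactly
  (timestamps excluded).  Experiment replicates derive their seeds from
  a single base seed.

## Design choices where the design was open

- The joint models use the *signed distance* (BrAC − group mean) as the
  central-tendency control rather than the raw group mean; the two span
  the same column space with BrAC, so R² is identical either way, and a
  flag switches the regressor.  The group mean includes all members,
  zero-BrAC and self included.
- The η scan regresses on SR alone; a covariate-adjusted scan exists
  behind a flag but is not the default procedure.
- Model 4's listwise deletion mirrors the study-style attrition
  accounting; every filtering step logs counts in/out.
- Time of survey is stored only as the before/after-11pm dichotomy.

## Problem sizes in the test and acceptance runs

Recovery experiments run at the scales the analysis targets: η recovery
uses 20 replicates of 2,000 judgments over a 1,862-person pool and a
500-point grid; Model 4 recovery uses 100 replicates of 400-person
subsamples; generator calibration uses one 50,000-person draw (3
Monte-Carlo SEs ≈ ±0.41 μg/100 ml).  The full suite and the acceptance
script each complete in well under a minute on a single CPU.

## Known limitations

- No inferential uncertainty for the η argmax; the grid profile is
  typically flat near its maximum at realistic noise (single-replicate
  argmaxes at η\* = 0.70, R² = 0.22 range roughly 0.5–0.95), which is
  why recovery is assessed on the median across replicates.
- The 20-replicate median still carries Monte-Carlo error (SD ≈ 0.035
  at η\* = 0.70); occasional realizations fall just outside a ±0.10
  band around the generating value.
- Normal-theory CIs are not robust to heteroscedastic or discretized
  outcomes; with the discretize flag on, refit slopes attenuate
  slightly.
- The mechanism-identification signature has asymmetric power: on
  rank-generated data the rank coefficient survives in ≥ 90 % of
  400-person replicates, but on absolute-BrAC-generated data the BrAC
  coefficient survives in only ~70 % (its standard error is inflated
  more by the BrAC–distance collinearity).
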