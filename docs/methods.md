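# Methods

This note records the modelling conventions, numerical choices and design
decisions behind `lexisurv`, and what the synthetic-data studies do and do
not establish.

## The relative-survival transformation

**Hazard convention.** Reference rates are central mortality rates (deaths
per person-year) used directly as hazards, on a grid of single years of
age by single calendar years. Within each 1×1 Lexis cell the hazard is
constant; a subject crosses an age boundary on their fractional birthday
and a calendar boundary at new year, so Λ*(t) is piecewise linear and is
integrated exactly by splitting the diagonal at both kinds of boundary.
All dates are decimal years (365.25-day year); no calendar-exact date
arithmetic is attempted. Cohort files that give integer entry ages are
read as mid-year ages (age + 0.5), the unbiased convention under uniformly
distributed birthdays.

**Extrapolation policy.** Percentile predictions routinely leave the
observed rate grid: a 25-year-old entrant's 95th percentile lies past age
100, and the 1 January 1965 anchor predates a grid that starts in 1966.
The policy is explicit and configurable on `RateTable`: calendar years
outside the span reuse the nearest edge column; ages above the grid are
extended log-linearly (a Gompertz tail fitted per sex and calendar year to
the top 10 grid ages), capped at 1.0/yr and ending at an attained-age
ceiling (default 130). A query beyond the ceiling raises a saturation
error rather than silently capping; with extrapolation disabled any
off-grid query names the missing (sex, age, year) cell.

**Event frames.** The analysis frame is mortality before attained age 90:
follow-up beyond the 90th birthday is truncated there with the event
indicator cleared (this also covers subjects who embarked after 90).
Cause-specific analyses censor deaths from other causes at the death time
and use the cause-specific rate table — the cause-specific-hazard
convention that keeps the Cox partial likelihood well defined. The
transformation itself is status-agnostic: censoring only flips the event
indicator.

## Covariate encodings

* Smoking grade bands: 0 → never, 1–14 → light, 15–24 → medium, ≥25 →
  heavy cigarettes/day; a "former smoker" flag overrides consumption.
* Time in industry enters as a continuous decades term (years/10), not
  banded categories, so one coefficient reads "per decade worked".
* Lung function enters as deficits per 10% reduction:
  `fev1_deficit = (100 − FEV1%pred)/10` and, by default,
  `ratio_deficit = (100 − 100·FEV1/FVC)/10`, so a ratio of 0.9 scores +1
  and the fitted HR reads "per 10% reduction". The opposite sign
  convention (`ratio_sign="printed"`, `(100·FEV1/FVC − 100)/10`) is
  selectable; the two differ only in the sign of one coefficient. The
  default is the one under which "increased hazard per 10% reduction" is
  the literal reading of HR > 1.
* Interaction schemes: `rrr4` forms one female×grade indicator per smoking
  grade; `rrr3` pools medium and heavy before forming interactions (for
  cause-specific analyses with fewer deaths). Main-effect grade columns
  are identical between schemes, so switching schemes never changes the
  never/light/former rows.
* `log_height` optionally adds log(height) as an allometric size
  covariate.

## Model fitting

**Cox.** Newton–Raphson on the partial likelihood with step-halving,
converged when the score max-norm is below 1e−9; Efron tie handling by
default (transformed times are continuous, but file rounding can create
ties), Breslow selectable. Rank deficiency of the design is detected
up-front via QR and names the collinear columns; a coefficient escaping
|β| > 20 is reported as monotone likelihood (separation) naming the
covariate. The covariance is the inverse observed information. Because
the partial likelihood depends on times only through ranks, fits on Y, Z
or any strictly increasing re-expression are identical — asserted to
1e−8 in the tests.

**Weibull PH.** Parameterised as a proportional-hazards model,
h(z|x) = kλz^{k−1}e^{xβ}, so β is directly comparable with the Cox
coefficients (an AFT parameterisation would need β_PH = −k·β_AFT).
Fitted by Newton–Raphson on (β, log λ, log k) with analytic gradient and
Hessian, step-halving, and a BFGS fallback for awkward curvature; the
shape can be fixed (k = 1 gives the exponential model). The Y scale is
refused for the parametric family: a bounded measure cannot carry a
Weibull hazard, and all predictions live on Z.

Confidence intervals are Wald on the log scale throughout (exp(β ±
1.96·SE)); no profile likelihood. Model comparison ranks by
log-likelihood with ties broken by fewer parameters, then input order,
and refuses fits whose data hashes differ.

**PH diagnostics.** Raw Schoenfeld residuals are the case's covariates
minus the risk-set weighted mean; under Efron ties the tied events share
the average of the Efron-adjusted means, so columns still sum to the
(zero) score. Scaled residuals premultiply by (number of events)·Var(β̂).
The test statistic is the Pearson correlation ρ of each scaled-residual
column with the event times on the identity-Z axis (a rank transform is
available), with a p-value from the t distribution on (events − 2)
degrees of freedom. Under the package's own cohort-like conditions
(realistic censoring near 50%) the pooled type-I error sits near the
nominal 5% (measured 0.058 over 1000 replicates at n = 1000); in heavily
uncensored, strongly skewed-time settings the approximation runs
conservative — a known property of correlation-based PH tests with an
identity time axis, worth remembering when follow-up is complete.

## Prediction

Percentiles invert the closed-form Weibull quantile
z_p = [−log(1−p)/(λe^{xβ})]^{1/k} through Λ*⁻¹ along the scenario's Lexis
diagonal anchored at (entry age, 1 January 1965); scenario covariate
vectors set sex, grade and their interaction, with all confounders at
reference zero. Cells whose quantile exceeds the hazard attainable at the
extrapolation ceiling are flagged, not capped, and refuse further
arithmetic. Years-of-life-lost contrasts are differences of median
predicted ages at death reported to one decimal; the gender gap
differences the two reported (already-rounded) contrasts, matching how
such tables are read.

The package ships one data fixture: the published residual-lifetime
percentile table for a UK cotton-industry cohort (Weibull model with
gender, smoking grade and four RRRs, anchored 1 Jan 1965), used for the
worked-example arithmetic. It is encoded verbatim; two cells of the
45-year-old heavy-smoking women column violate percentile monotonicity in
the source (5% = 90.50, 95% = 53.75, apparently transposed). The
monotonicity check flags them and the YLL arithmetic uses medians only;
no correction is guessed.

## The synthetic-data generator

`make_rate_table` builds rate(age, year, sex) = exp(a + b·age −
c·(year−1966) + d·male): log-linear in age (default slope 0.0866/yr, a
doubling every ~8 years; intercept −10), improving by c = 0.015 log-units
per calendar year, with a constant male excess d = 0.45. These defaults
give mid-adult hazards of a realistic order for the period without
attempting to emulate any actual national surface.

`simulate_cohort` draws a cohort with the demographic structure of a
1960s cotton-industry workforce: n = 3459 with 1548/3459 men; entry ages
truncated-normal per sex (men 41.5 ± 15.6, women 45.6 ± 12.2, truncated
to [15, 75]); entry dates uniform over 1966–1970; per-sex smoking-grade
frequencies from the workforce's baseline table (men 333/589/445/91/90
and women 856/615/337/54/49 across never/light/medium/heavy/former).
Confounder generators (byssinosis 8%, cough & phlegm 22%, years in
industry 22 ± 12, FEV1 %pred 93 ± 13, FEV1/FVC 0.76 ± 0.07, sex-specific
FVC and height) are plausible-scale choices, not estimates. Effects act
multiplicatively on the transformed-scale hazard: Z* ~ Weibull(k,
λe^{xβ_true}) with default k = λ = 1 and β_true the published all-cause
hazard-ratio pattern (grade HRs 1.21/1.68/1.99/0.89, female 1.07, RRRs
1.35/1.15/1.00/1.10, confounders near 1); death time is Λ*⁻¹(Z*).
Censoring: an independent exponential embarkation clock (7.5·10⁻⁴/yr,
matching ~90 embarkations over the follow-up), administrative end of
follow-up at 2008.0, and the age-90 rule at analysis time. A single seed
fixes everything; the same seed reproduces the cohort byte for byte.

Placing the generative effects on the Z scale makes the analysis model
exactly correctly specified, so the recovery studies test the pipeline's
correctness — transformation, design, likelihood, covariance — not
robustness to misspecification. Real data differ in ways the generator
does not emulate: covariates are drawn independently (no
smoking–lung-function correlation), the rate surface is smooth, reported
ages and dates are exact, and competing causes are not structurally
modelled. Passing tests therefore establish that the machinery is right,
not that the model fits any particular cohort.

Sparse interaction cells (heavy-smoking and former-smoking women are ~3%
of women) can yield a separated Cox fit in small replicates; the
replicated experiments record such replicates as failures (aborting above
10%) rather than forcing estimates.

## Problem sizes used in the checks

The replicated studies run at: null calibration n = 5000 (uncensored);
recovery 200 replicates of the full n = 3459 pipeline (Cox and Weibull,
per-parameter coverage); PH-test calibration 1000 replicates at n = 1000;
prediction round trip 20000 simulated subjects per scenario cell. These
sizes put Monte-Carlo error well inside the asserted bands while keeping
a full run in minutes on one core.

## Known limitations

* Weibull (and exponential) are the only parametric families; the module
  interface admits others.
* No frailty, time-varying covariates, penalised fits, or multiple
  imputation of missing covariates.
* The delayed-entry structure is encoded entirely in the transformation's
  entry anchoring; there is no separate left-truncation machinery.
* Cause-specific runs need a rate table per cause; the package does not
  map ICD codes across revisions.
* The correlation PH test's null approximation degrades for uncensored,
  heavily skewed transformed times (see above).
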