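# lexisurv

Individual relative-survival analysis of cohort mortality with long
follow-up.

`lexisurv` is for epidemiologists analysing occupational or population
cohorts recruited decades ago, where entry ages span half a century and
background mortality improved substantially during follow-up. Comparing
such subjects on the raw time axis confounds exposure effects with age and
calendar era. The package instead transforms each subject's observed
follow-up through a reference life table and models the transformed times.

## The method

Let μ(sex, a, y) be the reference-population mortality rate at single year
of age *a* in calendar year *y*. A subject entering at exact age a₀ on
decimal date y₀ moves along the 45° diagonal of the Lexis plane; their
expected cumulative hazard after *t* years is

    Λ*(t) = ∫₀ᵗ μ(sex, a₀+s, y₀+s) ds,

evaluated exactly under a piecewise-constant hazard in each 1-year × 1-year
Lexis cell. The two individual relative-survival measures are

    Z = Λ*(t_obs),        Y = 1 − exp(−Z) = 1 − S*(t_obs),

with Z = −log(1−Y). If a subject dies like the reference population, Z is
unit exponential and Y uniform, so subjects of any entry age and era are
comparable on one scale. The transformed times are modelled with
proportional hazards:

* **Cox regression** (partial likelihood, Newton–Raphson, Efron ties) —
  identical coefficients on the Y and Z scales, since the partial
  likelihood sees only ranks;
* **Weibull PH regression** h(z|x) = kλz^{k−1}·exp(xβ) — fully parametric
  on Z, hence invertible into predictions.

The design carries smoking grade (never / light 1–14 / medium 15–24 /
heavy ≥25 cigarettes per day / former), a female indicator, and
female×grade interactions whose exponentiated coefficients are the
**female-to-male relative risk ratios (RRRs)** — the ratio of the female
smoker-vs-never hazard ratio to the male one — plus confounders
(byssinosis, cough & phlegm, decades in industry, and two lung-function
deficits scaled per 10% reduction). Proportionality is checked by the
correlation ρ between scaled Schoenfeld residuals and the transformed
times. A fitted Weibull model is inverted back to the age scale —
age at death = a₀ + Λ*⁻¹(z_p) — giving conditional residual-lifetime
percentiles, mortality curves, and median years-of-life-lost contrasts.

No reference life table or cohort is distributable, so
`lexisurv.simulate` generates both: a Gompertz-style national rate surface
and a cohort shaped like a 1960s UK cotton-industry workforce (3459
workers, entry 1966–1970, sex-specific age and smoking-grade structure),
with known multiplicative effects on the transformed-hazard scale —
the exact generative inverse of the transformation.

## Worked example

```python
from lexisurv import (SimulationConfig, make_rate_table, simulate_cohort,
                      transform_cohort, build_design, fit_cox, fit_weibull,
                      extract_rrr, proportional_hazards_test,
                      residual_lifetime_table, years_of_life_lost)
from lexisurv.transform import subjects_from_frame

config = SimulationConfig(seed=11)          # 3459 subjects, 1960s entry window
table = make_rate_table(config)             # synthetic national rate surface
cohort, truth = simulate_cohort(config, table)

records, summary = transform_cohort(subjects_from_frame(cohort), table)
print("follow-up accounting:", summary)

X = build_design(cohort, scheme="rrr4", confounders="full")
fit = fit_cox(records, X)
print(extract_rrr(fit).round(2))

ph = proportional_hazards_test(fit, records, X)
print("max |rho|:", ph.table["rho"].abs().max().round(3))

wfit = fit_weibull(records, build_design(cohort, confounders="none"))
pt = residual_lifetime_table(wfit, table, anchor_year=1965.0, entry_ages=(45,))
print("YLL light, men:", years_of_life_lost(pt, "light", "male"),
      "women:", years_of_life_lost(pt, "light", "female"))
```

prints

```
follow-up accounting: {'n': 3459, 'died_before_90': 1499,
 'embarked_before_90': 79, 'censored_at_90': 370, 'alive_under_90': 1511}
         rrr  ci_low  ci_high     p
grade
light   1.55    1.19     2.02  0.00
medium  1.47    1.11     1.95  0.01
heavy   1.75    1.07     2.86  0.02
former  1.36    0.74     2.51  0.32
max |rho|: 0.043
YLL light, men: 1.5 women: 7.5
```

The accounting partitions the cohort by exit type (deaths and exits after
attained age 90 are censored at the 90th birthday). The RRR table shows
the estimated female-to-male relative risk ratios with Wald 95% intervals
(this draw was simulated with true RRRs 1.35/1.15/1.00/1.10). All
|ρ| < 0.05 means no evidence against proportional hazards. The final line
differences the median predicted ages at death (never-smoked minus light
smoker, within sex) for a person aged 45 at 1 January 1965.

The same pipeline is scriptable from the shell:

```sh
lexisurv simulate --seed 11 --out cohort.csv --rates rates.csv
lexisurv run --config run.yaml          # transform → fit → diagnose → predict
```

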