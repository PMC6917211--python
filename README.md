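# cardiocost

Microsimulation of the annual healthcare costs of cardiometabolic disease
(CMD — coronary heart disease, stroke, and type 2 diabetes) attributable to
suboptimal intake of ten dietary factors: fruits, vegetables, nuts/seeds,
whole grains, unprocessed red meat, processed meat, sugar-sweetened
beverages (SSBs), polyunsaturated fats, seafood omega-3 fats, and sodium.

The package is aimed at health-economics and nutrition-policy modelers. It
couples three pieces:

1. **A synthetic population generator** that emulates a US-representative
   adult cohort (ages 35–85): demographic category shares, cardiometabolic
   risk-factor moments, disease-history prevalences, and right-skewed daily
   intakes calibrated so that the mean, SD, *and* fraction at-or-better-than
   the optimal intake level of every factor match published marginals
   simultaneously.
2. **A yearly-cycle CVD/diabetes microsimulation.** Each person's annual CVD
   risk is a logistic function of age, sex, systolic blood pressure, total
   and HDL cholesterol, smoking, and diabetes, split into CHD events
   (myocardial infarction, angina, cardiac arrest) and stroke. Diet acts
   multiplicatively on cause-specific hazards through log-linear
   dose–response relative risks: a factor with per-unit relative risk `r`
   (reference unit size `u`) and intake gap `g` from its optimal level
   contributes `exp(a(age) · ln r · g / u)`, with `a(age)` a piecewise
   age attenuation. Competing risks resolve by a single multinomial draw
   per person-year; entrant cohorts of 35-year-olds join each cycle; the
   first and last of the 5 cycles get half-cycle person-time weights.
3. **Cost accounting and attribution.** Events and person-years convert to
   discounted (3%/year) 2018-USD costs in four additive components — acute
   hospitalization, chronic CVD care, chronic diabetes care, drugs — and
   the attributable cost is the difference between the observed-diet run
   and a counterfactual run with intakes moved to optimal (per factor and
   jointly), computed under common random numbers, scaled nationally,
   stratified (sex, age, race, education, BMI, insurance), and allocated
   to ultimate cost-bearers (household / government / third party).

Relative risks, unit costs, and parts of the payer mix ship as clearly
marked **synthetic defaults** (see `src/cardiocost/data/*.yaml`); dollar
outputs scale with them and a real analysis replaces them in config.

## Worked example

```python
from cardiocost.config import load_config
from cardiocost.pipeline import pipeline

cfg = load_config(None, n=20000, seed=7)   # bundled defaults
summary = pipeline(cfg, "demo_out", seed=7)
print(round(summary["per_capita_total"], 2))
print({k: round(v, 2) for k, v in summary["per_capita_components"].items()})
print({k: round(v, 2) for k, v in summary["factor_per_capita"].items()})
```

prints (deterministically, for this seed and the synthetic default inputs):

```
547.04
{'acute': 351.23, 'chronic': 193.02, 'chronic_cvd': 91.99,
 'chronic_diabetes': 101.02, 'drug': 2.79}
{'fruits': 109.92, 'vegetables': 149.53, 'nuts_seeds': 88.22,
 'whole_grains': 148.64, 'red_meat': 13.61, 'processed_meat': 76.88,
 'ssb': 132.54, 'pufa': 41.44, 'omega3': 79.92, 'sodium': 39.49}
```

Reading: under the synthetic default effect sizes and unit costs, moving
all ten intakes to their optimal levels would avert about $547 per person
per year, dominated by acute hospitalization costs ($351); single-factor
counterfactuals sum to more than the joint figure because multiplicative
relative risks make factor benefits overlap (sub-additivity). Red meat is
the smallest contributor ($14, almost entirely chronic diabetes care —
its only configured causal pathway), and sodium is the only factor moving
drug costs (its effect is routed through systolic blood pressure, hence
antihypertensive treatment). The same run writes `attributable_costs.csv`,
`factor_shares.csv`, `national_costs.csv`, `strata.csv`,
`bearer_allocation.csv`, `summary.json`, and a reproducibility manifest to
`demo_out/`.

The same pipeline is scriptable from the shell:

```sh
cardiocost demo --n 20000 --seed 7 --out demo_out
cardiocost generate --n 200000 --seed 7 --out pop.csv
cardiocost run --pop pop.csv --scenario optimal_all --seed 11 --out run/
cardiocost attribute --n 20000 --seed 7 --out results/
cardiocost report --results results/
```

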