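# Methods

This note documents the model, its assumptions, the synthetic inputs, and
the numerical choices, in the order the pipeline uses them.

## Synthetic population

The generator produces adults aged 35–85 with independent marginals
(optionally correlated via config in future work; the bundled spec is
marginal-only because only marginal summaries are published for the
population it emulates):

* **Ages** are drawn from three band shares (35–49: 38.7%, 50–64: 37.8%,
  ≥65: 23.5%) with a uniform spread within each band — band shares are the
  published granularity, and a within-band density is not identified.
* **Continuous risk factors** (BMI, SBP, total and HDL cholesterol) are
  truncated normals whose location/scale are solved numerically so the
  *post-truncation* mean and SD equal the published values (the naive
  parameters are biased when a bound is near; e.g. BMI at its lower bound).
* **Dietary intakes** use three families:
  * *Side-mixture gamma* (fruits, vegetables, nuts/seeds, whole grains,
    red meat, seafood omega-3, sodium): a base gamma is split at the
    factor's optimal level and the two truncated sides are remixed so the
    at-or-better-than-optimal fraction equals the published percentage
    exactly; the gamma shape and scale are then solved (2 equations, 2
    unknowns, `fsolve` on partial gamma moments) so the mixture's mean and
    SD also match. This is the only family we found that pins all three
    published quantities at once; a zero-inflated gamma has no solution
    for nuts or omega-3.
  * *Zero-inflated gamma* (SSBs, processed meat): the point mass at zero
    *is* the optimal fraction (optimal intake is "none"); the consumer
    gamma is moment-matched so the overall mean/SD hold exactly.
  * *Truncated normal* (PUFA, % energy on [0, 100]): moment-matched. Its
    realized at-or-above-11% tail is 11.8% against a published 11.4% — a
    two-parameter family cannot also pin the tail, and we prefer exact
    moments since the tail enters the analysis only through gap sizes.
* **Sampling weights** are gamma-distributed with mean 1 (shape 4),
  standing in for survey design weights; `resample_weighted` draws with
  replacement proportional to weight and resets weights to 1, as a
  survey-to-model-population step.

Randomness: one named stream per output column, derived from the master
seed via sha256-tagged `SeedSequence`s — vectorized, order-independent,
and byte-reproducible. (Per-person substreams would buy nothing here
because generation is columnar.)

What the generator does *not* emulate: intra-person correlation between
diet and risk factors (a real cohort's nut eaters have lower BMI), survey
measurement-error corrections, and geographic/household structure. Tests
passing on this population therefore validate the *machinery* (calibration,
accounting, attribution algebra), not the real-world dollar levels.

## Diet relative risks

Log-linear dose–response in the intake gap: `RR = exp(a(age)·ln(r)·g/u)`,
the standard comparative-risk-assessment form, with no extra benefit
beyond the optimal level (gap floored at zero, matching the pooling of
"optimal or better" consumers). Per-factor RRs multiply across factors
within a disease. Age attenuation is piecewise constant (1.0 at 35–44
declining to 0.40 at 75+ by default) since effect sizes attenuate with
age; the schedule is fully config-driven. Intakes are truncated at the
population 99th percentile before gap computation so a handful of extreme
recalls cannot dominate, and each factor's RR is capped (default 10).

The bundled per-unit RRs are **synthetic defaults** in the range reported
by diet–disease meta-analyses, oriented so `r > 1` is the risk at a
one-unit gap. Red meat is configured with a diabetes-only pathway (its
published attributable cost is chronic-only, consistent with no direct
CHD/stroke link in the source model). Sodium defaults to a blood-pressure
route (`mode: bp`, 1.2 mmHg per g/day): its excess shifts SBP inside the
risk equation and drives antihypertensive initiation, which is what makes
sodium the only factor with a drug-cost column; a direct-RR mode is one
config switch away.

RR uncertainty: `draw_rr_set` redraws each RR as `exp(N(ln r, se²))`,
floored at 1 to preserve orientation (the floor is ≥3 SE from every
default point estimate, so the truncation is immaterial).

## Microsimulation

Annual cycles over a 5-year horizon. Baseline annual CVD probability is
logistic in (age, sex, SBP, total chol, HDL, smoking, diabetes) with
Framingham-style default coefficients — documented substitutes for a
calibrated policy model's risk equation, exposed in `sim.yaml`. The CVD
probability is split on the hazard scale (CHD share 0.70; CHD split
MI/angina/cardiac-arrest 0.45/0.40/0.15), multiplied by the diet RR for
the matching disease and by a post-event hazard multiplier (2.0) for
people in post-event states, and mapped back to probabilities via
`1 − exp(−h)`. Diabetes onset is logistic in age and BMI times the diet
diabetes RR; background non-CVD mortality is a Gompertz-like toy life
table. If a person's probabilities sum past 1 they are rescaled
proportionally and a warning is logged (a handful of persons per 20,000 at
the defaults).

Competing risks resolve with **one multinomial draw per person-year** over
{MI, angina, cardiac arrest, stroke, diabetes onset, background death,
nothing} in a fixed slot order — order-independent within a cycle and the
key to common-random-numbers monotonicity (raising a CHD RR only widens
the CHD slots, so CHD event counts are non-decreasing draw-by-draw).
Fatality is a second uniform against event-type case fatality. Survivor
transitions: MI/cardiac-arrest → post-MI (or post-MI-and-stroke if a
stroke history exists), stroke symmetric, angina only promotes from
"well"; dead states are absorbing; the death row carries a `fatal` flag on
the causal event. Risk factors then drift linearly (age +1, SBP +0.4
mmHg/yr, total chol +0.5 mg/dL/yr by default).

Entrants: cohorts of 35-year-olds (`entrant_fraction` = 1.5% of baseline
per year, growing 0.5%/yr, rounded half-up) join from cycle 1, drawn from
the population spec with age forced to 35 and event history cleared (the
source's separate 35-year-old table is unpublished; this stand-in is
synthetic). Entrant attributes and all uniforms are scenario-independent,
so scenario pairs on the same population and seed are differenced under
common random numbers; an independent-streams flag exists for variance
studies.

Half-cycle correction: person-time in the first and last cycle is
weighted 0.5, so a 5-cycle survivor contributes 4.0 weighted person-years.

## Costs

Four additive components, all in 2018 USD discounted at 3%/yr to cycle 0:
acute per-event hospitalization cost booked in the event's cycle (fatal
events included, never person-time weighted), chronic CVD cost per
post-event state person-year, chronic diabetes cost per diabetic
person-year, and drug cost per treated person-year. Chronic costs start
the cycle *after* the event because the panel records each cycle's opening
state. The per-person-year ledger stores discounted, unweighted amounts
beside the half-cycle weight; 5-year totals apply the weight to the
person-time components. Annualized per-capita figures come from the final
cross-sectional year at full person-time (the cross-section stands for one
calendar year) divided by persons alive that year, keeping the
accumulated discounting; components sum to the total exactly at every
aggregation level. The bundled unit costs are synthetic order-of-magnitude
defaults. Reporting rounds per-capita dollars to cents in the CSVs and
leaves internal math unrounded.

## Attribution

Attributable cost = observed-run per-capita annual cost minus
counterfactual-run cost, by component, under common random numbers; the
sweep produces one single-factor-optimal counterfactual per factor plus
the all-optimal run. Because RRs multiply, the joint cost is bounded above
by the sum of single-factor costs (verified on every tested population).
National totals scale by a configured adult population (default 167.4M);
the attributable share is expressed against a configured total direct CMD
cost (default $276.3B/yr). Strata (sex; age 35–49/50–64/≥65 at the final
cross-section; race; education; BMI <30/≥30; insurance) are person-level
means of the final-year cost differences, so the person-weighted stratum
mean reconstructs the overall mean exactly; note the headline per-capita
figure is the difference of two ratios whose denominators (survivors per
scenario) differ by a few per 10,000, so it can differ from the
person-level mean in the third decimal. Cost-bearer allocation multiplies
per-insurance costs by a row-stochastic household/government/third-party
matrix (totals conserved to 1e-9); the public-program government shares
default to published payment-flow values and the remaining split is
synthetic.

95% CIs are percentile intervals over Monte-Carlo RR redraws, the full
two-scenario simulation rerun per draw. The pipeline default is 0 draws
(point estimates); the documented analysis choice for interval estimates
is O(10²) draws, set via `ci_draws` — each draw costs two full runs, and
percentile CIs stabilize well before the draw count where runtime becomes
the binding concern at the default population size.

## Default problem sizes

The package's documented defaults: population n = 20,000 with 1.5%
entrant cohorts, 5 cycles, 10 + 2 scenario runs per sweep; generator
calibration checks at n = 200,000 over 20 seeds; oracle comparisons at
50,000 replicates. These sizes give Monte-Carlo SEs a small fraction of
the quantities checked while keeping a full sweep in seconds on one core.

## Known limitations

* All effect sizes, costs, risk-equation coefficients, drift and
  case-fatality schedules are synthetic or substitute defaults; headline
  dollar figures are illustrative until replaced with validated inputs.
* Independent marginals understate real diet–risk-factor correlation, so
  stratified contrasts (e.g. by BMI) are flatter than reality.
* No heart failure, atrial fibrillation, or renal outcomes; no indirect or
  intervention costs; no treatment modeling beyond the hypertension flag.
* The null-scenario zero is exact only for a closed cohort: entrants join
  with freshly drawn diets, so an optimal counterfactual still improves
  *their* intakes even when the baseline population is fully optimal.
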