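# Default synthetic-population spec: US adults aged 35-85.
# Marginals follow published NHANES 2009-2012 summary statistics for this
# age range (category shares, risk-factor means/SDs, disease prevalences,
# dietary intake means/SDs and fractions at-or-better-than optimal).
# The joint distribution is synthetic: marginals are drawn independently.
age_bands:
  - [35, 50, 0.387]
  - [50, 65, 0.378]
  - [65, 85, 0.235]
female_share: 0.527
race: {white: 0.722, black: 0.101, hispanic: 0.117, other: 0.060}
education: {"<HS": 0.175, "HS": 0.511, "college": 0.314}
insurance:
  private: 0.557
  medicare: 0.195
  medicaid: 0.033
  dual: 0.013
  other_gov: 0.053
  none: 0.149
continuous:
  bmi: {mean: 29.2, sd: 6.6, lo: 13.0, hi: 75.0}
  sbp: {mean: 123.8, sd: 17.5, lo: 75.0, hi: 260.0}
  total_chol: {mean: 202.3, sd: 42.5, lo: 80.0, hi: 500.0}
  hdl: {mean: 54.1, sd: 16.8, lo: 10.0, hi: 160.0}
prevalence:
  smoker: 0.166
  diabetes: 0.114
  htn_treated: 0.351
  angina: 0.026
  mi: 0.043
  stroke: 0.033
intakes:
  fruits:
    {family: side_mixture_gamma, mean: 120.6, sd: 145.5, optimal: 300.0,
     direction: protective, optimal_mass: 0.092}
  vegetables:
    {family: side_mixture_gamma, mean: 188.2, sd: 153.4, optimal: 400.0,
     direction: protective, optimal_mass: 0.079}
  nuts_seeds:
    {family: side_mixture_gamma, mean: 12.5, sd: 29.0, optimal: 20.2,
     direction: protective, optimal_mass: 0.195}
  whole_grains:
    {family: side_mixture_gamma, mean: 21.9, sd: 26.1, optimal: 125.0,
     direction: protective, optimal_mass: 0.007}
  red_meat:
    {family: side_mixture_gamma, mean: 46.9, sd: 51.0, optimal: 14.3,
     direction: harmful, optimal_mass: 0.357}
  processed_meat:
    {family: zero_inflated_gamma, mean: 30.7, sd: 38.3, optimal: 0.0,
     direction: harmful, optimal_mass: 0.321}
  ssb:
    {family: zero_inflated_gamma, mean: 1.0, sd: 1.5, optimal: 0.0,
     direction: harmful, optimal_mass: 0.481}
  pufa:
    {family: truncated_normal, mean: 7.8, sd: 2.7, optimal: 11.0,
     direction: protective, lo: 0.0, hi: 100.0}
  omega3:
    {family: side_mixture_gamma, mean: 98.1, sd: 187.8, optimal: 250.0,
     direction: protective, optimal_mass: 0.091}
  sodium:
    {family: side_mixture_gamma, mean: 3481.5, sd: 965.7, optimal: 2000.0,
     direction: harmful, optimal_mass: 0.024}
weight_gamma_shape: 4.0
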