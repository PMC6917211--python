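# Cost parameters, 2018 USD.  SYNTHETIC DEFAULTS: order-of-magnitude values
# typical of US cost-of-illness inputs (acute hospitalization per event,
# annual chronic disease-management by state, annual drug cost per treated
# person-year).  A real analysis replaces them with validated cost inputs;
# dollar outputs scale with these values.
acute_cost:
  mi: 24000.0
  angina: 9000.0
  cardiac_arrest: 18000.0
  stroke: 16000.0
  diabetes_onset: 0.0
  other_death: 0.0
chronic_cvd_cost:
  well: 0.0
  angina: 2200.0
  post_mi: 3500.0
  post_stroke: 4500.0
  post_mi_and_stroke: 6000.0
chronic_diabetes_cost: 2800.0
drug_cost:
  antihypertensive: 350.0
base_year: 2018
inflation_multiplier:
  2018: 1.0
discount_rate: 0.03
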