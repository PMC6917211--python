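# Microsimulation configuration.
#
# The annual cardiovascular event risk is a logistic function of the
# classic risk factors (age, sex, systolic blood pressure, total and HDL
# cholesterol, smoking, diabetes) with Framingham-style coefficients;
# these, the CHD/stroke split, case fatality, drift, and background
# mortality are package substitutes for a calibrated policy model's inputs
# and are fully replaceable here.
horizon_years: 5
discount_rate: 0.03
growth_rate: 0.005
half_cycle: true
# entrant cohort of 35-year-olds added each year, as a fraction of the
# baseline cohort size (conservative population growth)
entrant_fraction: 0.015
risk_logistic:
  intercept: -9.8
  age: 0.08          # per year of age
  male: 0.45
  sbp: 0.018         # per mmHg above 120
  total_chol: 0.004  # per mg/dL above 200
  hdl: -0.012        # per mg/dL above 50
  smoker: 0.50
  diabetes: 0.60
chd_share: 0.70      # CVD risk split between CHD events and stroke
chd_split: {mi: 0.45, angina: 0.40, cardiac_arrest: 0.15}
case_fatality: {mi: 0.25, angina: 0.0, cardiac_arrest: 0.90, stroke: 0.20}
post_event_hazard_multiplier: 2.0
diabetes_logistic:
  intercept: -4.6    # annual onset odds at age 55, BMI 29
  age: 0.015         # per year of age over 55
  bmi: 0.09          # per kg/m2 over 29
background_mortality:
  rate_at_35: 0.0008
  log_slope: 0.075   # Gompertz-like increase per year of age
drift:               # annual risk-factor drift, per year
  sbp: 0.4
  total_chol: 0.5
  hdl: 0.0
htn_treatment:
  sbp_threshold: 140.0
  annual_start_prob: 0.3
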