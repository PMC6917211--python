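# Dietary-factor definitions: units, optimal intake levels, and per-unit
# relative risks by disease.
#
# Optimal levels are the published consumption levels at which disease risk
# is lowest (fruits 300 g/day; vegetables 400 g/day; nuts/seeds 20.2 g/day;
# whole grains 125 g/day; unprocessed red meat 14.3 g/day; processed meat
# and SSBs no intake; PUFA 11 %energy; seafood omega-3 250 mg/day; sodium
# 2000 mg/day).
#
# The relative risks are SYNTHETIC DEFAULTS: plausible per-unit values in
# the range reported by diet-disease meta-analyses, oriented so rr > 1 is
# the risk at a one-unit-size intake gap relative to optimal.  They are
# placeholders for the etiologic effect sizes a real analysis would supply
# in this file, and headline dollar outputs depend on them.
rr_cap: 10.0
intake_cap_quantile: 0.99
# multiplier on log-RR by age band: effect sizes attenuate with age
age_attenuation:
  - [35, 45, 1.00]
  - [45, 55, 0.85]
  - [55, 65, 0.70]
  - [65, 75, 0.55]
  - [75, 121, 0.40]
factors:
  - name: fruits
    unit: g/day
    unit_size: 100.0
    direction: protective
    optimal: 300.0
    rr_per_unit: {CHD: 1.053, stroke: 1.220}
    rr_log_se: {CHD: 0.016, stroke: 0.040}
  - name: vegetables
    unit: g/day
    unit_size: 100.0
    direction: protective
    optimal: 400.0
    rr_per_unit: {CHD: 1.120, stroke: 1.150}
    rr_log_se: {CHD: 0.025, stroke: 0.030}
  - name: nuts_seeds
    unit: g/day
    unit_size: 28.35
    direction: protective
    optimal: 20.2
    rr_per_unit: {CHD: 1.350, diabetes: 1.120}
    rr_log_se: {CHD: 0.040, diabetes: 0.050}
  - name: whole_grains
    unit: g/day
    unit_size: 50.0
    direction: protective
    optimal: 125.0
    rr_per_unit: {CHD: 1.090, diabetes: 1.280}
    rr_log_se: {CHD: 0.020, diabetes: 0.040}
  - name: red_meat
    unit: g/day
    unit_size: 100.0
    direction: harmful
    optimal: 14.3
    rr_per_unit: {diabetes: 1.170}
    rr_log_se: {diabetes: 0.030}
  - name: processed_meat
    unit: g/day
    unit_size: 50.0
    direction: harmful
    optimal: 0.0
    rr_per_unit: {CHD: 1.260, diabetes: 1.190}
    rr_log_se: {CHD: 0.045, diabetes: 0.040}
  - name: ssb
    unit: servings/day
    unit_size: 1.0
    direction: harmful
    optimal: 0.0
    rr_per_unit: {CHD: 1.170, stroke: 1.070, diabetes: 1.260}
    rr_log_se: {CHD: 0.030, stroke: 0.025, diabetes: 0.035}
  - name: pufa
    unit: "%energy"
    unit_size: 5.0
    direction: protective
    optimal: 11.0
    rr_per_unit: {CHD: 1.110}
    rr_log_se: {CHD: 0.030}
  - name: omega3
    unit: mg/day
    unit_size: 250.0
    direction: protective
    optimal: 250.0
    rr_per_unit: {CHD: 1.270}
    rr_log_se: {CHD: 0.040}
  - name: sodium
    unit: mg/day
    unit_size: 1000.0
    direction: harmful
    optimal: 2000.0
    # routed through systolic blood pressure by default (mode: bp), which
    # links excess sodium to antihypertensive drug costs; switching mode to
    # "direct" uses the per-1000mg relative risks instead
    mode: bp
    bp_mmhg_per_gram: 1.2
    rr_per_unit: {CHD: 1.120, stroke: 1.170}
    rr_log_se: {CHD: 0.030, stroke: 0.035}
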