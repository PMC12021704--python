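# Default run configuration.
#
# Baseline cohort moments mirror the published trial baseline table; the
# correlation structure, noise models and the cost/utility catalogue are
# package defaults (see docs/methods.md) and are all user-overridable.

seed: 12345

cohort:
  n: 100000
  continuous:
    age:        {mean: 59.8,  sd: 12.6, lower: 18.0, upper: 95.0}   # years
    bmi:        {mean: 34.6,  sd: 6.8,  lower: 25.0, upper: 70.0}   # kg/m2; eligibility >= 25
    weight:     {mean: 97.8,  sd: 20.5, lower: 40.0, upper: 250.0}  # kg
    hba1c:      {mean: 53.9,  sd: 13.6, lower: 30.0, upper: 130.0}  # mmol/mol
    sbp:        {mean: 134.5, sd: 17.3, lower: 80.0, upper: 220.0}  # mmHg
    dbp:        {mean: 80.8,  sd: 10.0, lower: 40.0, upper: 130.0}  # mmHg
    total_chol: {mean: 4.74,  sd: 1.1,  lower: 2.0,  upper: 12.0}   # mmol/l
    hdl:        {mean: 1.25,  sd: 0.5,  lower: 0.5,  upper: 4.0}    # mmol/l
    ldl:        {mean: 2.53,  sd: 0.9,  lower: 0.5,  upper: 8.0}    # mmol/l
  binary:
    is_male: 0.478
    smoker: 0.15
    on_glucose_med: 0.60
    on_statin: 0.55
    on_antihypertensive: 0.50
  imd_probs: [0.155, 0.159, 0.243, 0.222, 0.222]
  duration_under1_prob: 0.545   # diagnosed less than 1 year ago
  correlation:
    default: 0.1
    pairs:
      - {a: weight, b: bmi, r: 0.9}
      - {a: bmi, b: sbp, r: 0.2}

trial:
  n: 577
  attrition: 0.31
  weight_change_sd: 4.0       # kg, individual 6/12-month change noise
  hba1c_change_sd: 8.0        # mmol/mol
  control_weight_change: {m6: -0.5, m12: -0.3}
  control_hba1c_change: {m6: -1.0, m12: -0.5}
  cost_gamma_shape: 1.5
  cost_base_per_6m: 250.0     # GBP healthcare use per 6-month window
  cost_hba1c_slope: 6.0       # GBP per mmol/mol above 48
  utility:
    base_disutility: 0.08
    bmi_slope: 0.006
    hba1c_slope: 0.002
    concentration: 20.0
    scale: 1.594
  missingness: mcar           # mcar | mnar

# Arm differences at 12 months (intervention minus control; negative = benefit)
effects:
  hba1c_effect_12m: -0.84     # mmol/mol
  weight_effect_12m_kg: -1.38 # kg, converted to BMI units via mean height
  hba1c_decay_horizon: 5.0    # years; effect exactly 0 from here on
  bmi_decay_horizon: 10.0
  shape: linear               # linear | exponential

# Common natural trajectory, annual additive drift
drift:
  hba1c: 0.5      # mmol/mol per year
  bmi: 0.0
  sbp: 0.5        # mmHg per year
  chol_hdl_ratio: 0.0

intervention_costs: {DEW: 325.0, DE: 158.0}

scenarios:
  - {name: "Mixed F2F and online delivery", de_cost: 158.0}
  - {name: "F2F only service delivery", de_cost: 265.0}
  - {name: "Online only service delivery", de_cost: 12.0}
  - {name: "Optimistic DESMOND uptake, full F2F capacity", de_cost: 96.0}

costing:
  vat_rate: 0.20
  dew_base_cost: 271.0        # commercial price before VAT
  de_f2f_cost: 265.0
  de_online_cost: 12.0
  f2f_share: 0.576
  optimistic_f2f_cost: 160.53
  optimistic_online_cost: 8.48

catalogue:
  discount_rate: 0.035
  management_cost: 1000.0     # GBP per year alive with diabetes
  medication_cost: 300.0      # GBP per year, removed in remission years
  utility_intercept: 0.92     # EQ-5D index at reference age 60
  utility_age_slope: -0.003
  utility_male: 0.02
  utility_reference_age: 60.0
  bmi_disutility_per_unit: 0.006   # per kg/m2 above 25
  event_costs:                # GBP {first event year, each subsequent year}
    mi:            {first_year: 6000,  subsequent: 800}
    stroke:        {first_year: 5500,  subsequent: 1500}
    chf:           {first_year: 3500,  subsequent: 1200}
    ihd:           {first_year: 3000,  subsequent: 900}
    amputation:    {first_year: 9000,  subsequent: 2500}
    blindness:     {first_year: 2500,  subsequent: 500}
    ulcer:         {first_year: 2000,  subsequent: 400}
    renal_failure: {first_year: 25000, subsequent: 20000}
    death:         {first_year: 0,     subsequent: 0}
  utility_decrements:
    mi: 0.055
    stroke: 0.16
    chf: 0.10
    ihd: 0.09
    amputation: 0.28
    blindness: 0.07
    ulcer: 0.17
    renal_failure: 0.26
    death: 0.0

# null -> packaged illustrative equations (data/risk_equations.yaml)
risk_equations_file: null

thresholds: [13000, 20000, 30000]   # GBP per QALY
max_age: 100.0
lifetime_n: 20000                   # persons for desk-scale deterministic runs

psa:
  n_samples: 2000
  seed: 777
  thresholds: [13000, 20000, 30000]
  distributions:
    "effects.hba1c_effect_12m":             {family: normal,    mean: -0.84,  sd: 1.10}
    "effects.weight_effect_12m_kg":         {family: normal,    mean: -1.38,  sd: 0.60}
    "catalogue.management_cost":            {family: gamma,     mean: 1000.0, sd: 100.0}
    "catalogue.medication_cost":            {family: gamma,     mean: 300.0,  sd: 45.0}
    "catalogue.event_costs.mi.first_year":  {family: gamma,     mean: 6000.0, sd: 900.0}
    "catalogue.event_costs.stroke.first_year": {family: gamma,  mean: 5500.0, sd: 850.0}
    "catalogue.utility_decrements.mi":      {family: beta,      mean: 0.055,  sd: 0.010}
    "catalogue.utility_decrements.stroke":  {family: beta,      mean: 0.16,   sd: 0.030}
    "catalogue.bmi_disutility_per_unit":    {family: beta,      mean: 0.006,  sd: 0.001}
    "risk_equations.mi.treatment_rr.statin": {family: lognormal, mean: 0.75,  sd: 0.05}
    "risk_equations.stroke.treatment_rr.antihypertensive": {family: lognormal, mean: 0.75, sd: 0.05}
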