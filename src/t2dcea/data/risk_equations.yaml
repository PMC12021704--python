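# ILLUSTRATIVE risk-equation parameter set.
#
# These coefficients are NOT a published equation system (in particular they
# are not the UKPDS Outcomes Model, whose coefficients are licensed and not
# redistributable). They are plausible-magnitude placeholders demonstrating
# each supported functional form; replace this file with published
# coefficients for substantive analyses. Annual hazards at typical baseline
# states fall in the 0.05-2% range per outcome and ~1.5%/year mortality at
# age 60, rising with age.
#
# Covariate names: age, hba1c, bmi, sbp, chol_hdl_ratio, duration, is_male,
# smoker, imd_quintile, history_<outcome>; special key "shape" for the
# weibull-in-duration / gompertz-in-age forms; treatment RRs apply when the
# matching on_<treatment> flag is set.

mi:
  form: exponential
  coefficients:
    intercept: -11.5
    age: 0.035
    is_male: 0.4
    hba1c: 0.025
    sbp: 0.012
    chol_hdl_ratio: 0.12
    smoker: 0.5
    history_stroke: 0.3
  calibration_multiplier: 1.0
  treatment_rr: {statin: 0.75, antihypertensive: 0.85}

stroke:
  form: exponential
  coefficients:
    intercept: -12.5
    age: 0.05
    is_male: 0.2
    sbp: 0.02
    hba1c: 0.01
    smoker: 0.5
    history_mi: 0.3
  calibration_multiplier: 1.0
  treatment_rr: {statin: 0.85, antihypertensive: 0.75}

chf:
  form: weibull-in-duration
  coefficients:
    intercept: -9.0
    shape: 1.4
    age: 0.04
    bmi: 0.03
    hba1c: 0.01
    history_mi: 0.6
  treatment_rr: {antihypertensive: 0.85}

ihd:
  form: exponential
  coefficients:
    intercept: -10.0
    age: 0.04
    chol_hdl_ratio: 0.15
    hba1c: 0.01
    smoker: 0.4
  treatment_rr: {statin: 0.8}

amputation:
  form: exponential
  coefficients:
    intercept: -10.0
    hba1c: 0.04
    smoker: 0.7
    duration: 0.05
    history_ulcer: 1.0

blindness:
  form: logistic
  coefficients:
    intercept: -6.5
    hba1c: 0.02
    duration: 0.03

ulcer:
  form: exponential
  coefficients:
    intercept: -10.0
    hba1c: 0.05
    duration: 0.1

renal_failure:
  form: weibull-in-duration
  coefficients:
    intercept: -11.0
    shape: 1.6
    sbp: 0.015
    hba1c: 0.02

death:
  form: gompertz-in-age
  coefficients:
    intercept: -10.5
    shape: 0.092
    hba1c: 0.012
    smoker: 0.4
    history_mi: 0.5
    history_stroke: 0.5
    history_chf: 0.7
    history_renal_failure: 0.9
    history_amputation: 0.5
  treatment_rr: {statin: 0.9, antihypertensive: 0.95}
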