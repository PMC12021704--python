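# t2dcea

Patient-level cost-effectiveness modelling for structured type 2 diabetes
education programmes, comparing **DEW** (diabetes education plus commercial
behavioural weight management) against **DE** (standard structured diabetes
education, DESMOND-style) from a UK NHS/PSS perspective.

The package is aimed at health-economic modellers and trial statisticians.
It provides, as one pipeline or as independent components:

- a **synthetic-cohort generator** (truncated-normal marginals, moment-matched
  under eligibility truncation, coupled by a Gaussian copula) standing in for
  the restricted trial dataset, plus a synthetic two-arm trial generator with
  stratified block randomisation (gender × diabetes duration, block size 6);
- **trial design** calculations: ANCOVA-style sample size
  `n/group = 2(z₁₋α/₂+z_power)²·(σ√(1−r²)/Δ)²` inflated for attrition,
  categorical outcome summaries, unadjusted risk ratios, and the
  pattern-mixture **delta adjustment** (imputed values × (1 + f/100));
- **programme costing** under face-to-face/online delivery-mix scenarios;
- a **within-trial cost-utility analysis**: QALYs by trapezoidal utility AUC,
  incremental net monetary benefit NMB(λ) = λ·ΔQALY − ΔCost, cost per
  mmol/mol HbA1c and per kg, and a person-level bootstrap CEAC;
- a **lifetime annual-cycle microsimulation**: risk-factor trajectories with
  intervention effects decaying to zero by 5 years (HbA1c) and 10 years
  (BMI); configurable parametric risk equations (exponential, Weibull in
  diabetes duration, Gompertz in age, logistic) with calibration multipliers
  and treatment relative risks, `p = 1 − exp(−H)`; diabetes remission
  (HbA1c < 48 mmol/mol from year 1, ending permanently once HbA1c rises to
  ≥ 48) with medication-cost offsets; costs and QALYs discounted at 3.5%;
- **probabilistic sensitivity analysis** (beta/gamma/lognormal/normal
  parameter distributions, common random numbers across arms and draws) and
  subgroup runs by diabetes duration, BMI band and IMD quintile.

The shipped risk-equation file is an **illustrative parameter set** — the
published UKPDS Outcomes Model coefficients are licensed and not
redistributable — so absolute lifetime costs/QALYs are demonstration values;
the machinery accepts any published coefficient system via a YAML file.

## Worked example

```python
from t2dcea.design import PowerSpec, required_sample_size
from t2dcea.model import load_config, run_lifetime, scenario_report

required_sample_size(PowerSpec(3.0, 16.0, 0.8, power=0.90, alpha=0.05, attrition=0.25))
# 576  -> total participants to randomise: 432 inflated for 25% attrition

cfg = load_config()                      # packaged defaults
run = run_lifetime(cfg, seed=20260930, n=20_000)
print(scenario_report(run, cfg))
```

which prints (abridged; 20,000 persons per arm, illustrative parameters):

```
                      scenario  incremental_cost  incremental_qalys      icer
 Mixed F2F and online delivery          145.0247             0.0193  7514.011
     F2F only service delivery           38.0247             0.0193  1970.134
  Online only service delivery          291.0247             0.0193 15078.552
Optimistic DESMOND uptake, ...          207.0247             0.0193 10726.350
```

Read: under mixed delivery the intervention arm costs £145 more per person
over a lifetime and gains 0.0193 discounted QALYs, an ICER of ~£7,500 per
QALY — cost-effective at the usual £20,000 threshold (NMB ≈ £241). Only the
DE programme cost differs between scenarios, so the QALY gain is shared and
the ICER moves with the programme-cost difference.

The numbered scripts under `analysis/` run the full narrative — design
(`01`), synthetic cohort (`02`), programme costing (`03`), within-trial CEA
(`04`), lifetime model (`05`), PSA and subgroups (`06`) — writing tables
under `results/`. The same pipeline is available from the shell:

```bash
t2dcea run-all --seed 1 --n 2000 --n-samples 50 --out results/run1
t2dcea design power --delta 3 --sd 16 --corr 0.8 --power 0.9 --attrition 0.25
```

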