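# Methods

This note documents the models, the default parameter choices and their
rationale, the numerical conventions, and the limits of what the synthetic
data can show.

## Synthetic baseline population

The generator emulates the joint distribution of baseline characteristics of
a newly-diagnosed (≤ 3 years) type 2 diabetes cohort with overweight or
obesity (BMI ≥ 25 kg/m²). Continuous risk factors (age, BMI, weight, HbA1c,
SBP, DBP, lipids) use truncated-normal marginals whose underlying normal
parameters are **moment-matched** so that the truncated distribution — not
the untruncated latent one — has the configured mean and SD. This matters:
with BMI truncated at 25 against a mean of 34.6 (SD 6.8), a naive truncated
normal located at the target mean would be biased upward by about one BMI
unit. Matching is a two-parameter least-squares solve per marginal, done
once at generation.

Marginals are coupled by a **Gaussian copula**. The latent correlation
matrix is configurable; the default sets weight–BMI 0.9, BMI–SBP 0.2 and
0.1 elsewhere, because participant-level correlations are not published for
this population. The matrix is validated symmetric PSD; a non-PSD
configuration is rejected rather than silently repaired.

Discrete characteristics (sex, smoking, medication flags, IMD quintile) are
independent draws at the configured frequencies; diabetes duration is a
two-part mixture (54.5% uniform on [0, 1) year, the rest uniform on
[1, 3]), reflecting the published under-one-year share. Smoking prevalence
(0.15) and medication prevalences (glucose-lowering 0.60, statin 0.55,
antihypertensive 0.50) are not published at baseline and were set once to
values typical of UK type 2 diabetes audits.

**What the generator does not emulate:** skewness and heavy tails of real
metabolic variables (HbA1c in particular is right-skewed), item-level
missingness at baseline, measurement error, and any residual dependence
beyond a Gaussian copula. Tests that pass on these data show the *machinery*
is correct under the stated distributional assumptions, not that real-data
estimates would be unbiased.

## Synthetic trial

Allocation is 1:1, stratified by gender and diabetes duration (< 1 vs 1–3
years) in randomly permuted blocks of 6, so every complete-block prefix is
exactly balanced within stratum. Six- and twelve-month outcomes are the
baseline value plus a control-arm secular change, plus (intervention arm)
the profile effect at t = 0.5 and t = 1, plus independent normal noise
(weight SD 4 kg, HbA1c SD 8 mmol/mol — chosen to give realistic
change-score dispersion). The default arm differences are −1.38 kg and
−0.84 mmol/mol at 12 months. Utilities are 1 minus a beta-distributed
disutility (concentration 20, scaled by 1.594 so the index spans
[−0.594, 1]) whose mean rises with BMI above 25 and HbA1c above 48;
healthcare costs per 6-month window are gamma (shape 1.5) with a mean
increasing in baseline HbA1c. Attrition at 12 months is
missing-completely-at-random at rate 0.31 by default; an optional
outcome-dependent (MNAR) mechanism makes dropout probability increase with
12-month weight gain, for exercising the delta-adjustment sensitivity
analysis. Baseline and 6-month values are always observed; only the
12-month triplet can be missing.

## Sample size

The calculation assumes a baseline-adjusted (ANCOVA-type) analysis of a
continuous outcome: per-group
n = 2(z₁₋α/₂ + z_power)² (σ√(1 − r²)/Δ)², with σ the follow-up SD, r the
baseline–follow-up correlation, Δ the detectable difference. The total is
rounded up per group, doubled, divided by (1 − attrition) and rounded up to
an even integer. With Δ = 3 mmol/mol, σ = 16, r = 0.8, 90% power, α = 0.05
and 25% attrition this gives 432 → 576. The normal approximation (rather
than the t-based iteration) is used because it reproduces the published
design exactly and the difference is negligible at these sizes.

## Lifetime model

**Trajectories.** Each risk factor follows a common linear annual drift from
its individual baseline (defaults: HbA1c +0.5 mmol/mol/year, SBP +0.5
mmHg/year, BMI and cholesterol ratio flat). The intervention arm carries an
additive offset: a linear ramp from 0 at entry to the full 12-month effect
at year 1, then linear decay to exactly zero at the horizon (5 years HbA1c,
10 years BMI) and zero thereafter. Linear decay is the simplest shape
consistent with a fixed removal horizon; an exponential-to-zero variant
(rate 3/(horizon−1), hard zero at the horizon) is available by config. The
weight effect in kg converts to BMI units through the height implied by the
cohort's mean weight and BMI (−1.38 kg ≈ −0.49 kg/m²). Whether effects
should enter as offsets or multiplicative factors is not identifiable from
the available description; offsets were chosen and are flagged as a
modelling assumption.

**Events.** Nine outcomes (MI, stroke, CHF, IHD, amputation, blindness,
foot ulcer, renal failure, death) are drawn annually, first-occurrence
only, in a fixed order (alphabetical with death last) so runs are
reproducible. The annual probability is p = 1 − exp(−H) with
H = calibration × Π(treatment RRs) × base hazard; four base-hazard forms
are supported (exponential, Weibull in diabetes duration, Gompertz in age,
logistic converted to a hazard). History flags (`history_mi`, …) are
covariates, so incident events raise subsequent hazards. Treatment RRs
(statin, antihypertensive) apply to MI, stroke, CHF and mortality by
default; other outcomes default to RR 1. Event uniforms come from a
counter-based stream keyed by (seed, year, outcome, **person id**), which
gives common random numbers across arms, across PSA draws, and across
population subsets — this is what makes degenerate-PSA equality, arm
convergence under null effects, and exact stratum-weighted recomposition of
subgroup results hold to floating precision.

**Calibration.** A bisection on the hazard multiplier (geometric midpoints
on [10⁻⁴, 10⁴]) matches a target cumulative incidence over a horizon,
simulating the outcome in isolation with a fixed uniform stream so
incidence is monotone in the multiplier. The tolerance should respect
Monte-Carlo granularity (≈ 3/n); unreachable targets raise rather than
return the nearest bound. Calibration targets are config inputs.

**Risk-equation coefficients.** The shipped file is an illustrative,
clearly-labelled non-published set with plausible hazard magnitudes
(≈ 1.5%/year mortality at age 60 doubling every ~7.5 years; 0.05–1%/year
per complication). Published systems such as the UKPDS Outcomes Model are
licensed and cannot be redistributed; any such system can be supplied as a
YAML file with named coefficients. Consequently the package's absolute
lifetime costs and QALYs are demonstrations of the machinery, not
reproductions of published absolute values; incremental arithmetic,
dominance logic and NMB identities are exact and tested.

**Economics.** Each year alive (accrual at year start, no half-cycle
correction; a config flag documents the choice) contributes management cost
(£1,000) plus medication cost (£300, removed in remission years) plus
event costs (first-year vs subsequent, e.g. MI £6,000/£800, renal failure
£25,000/£20,000), all illustrative 2023-GBP magnitudes in the range of UK
costing studies. Utility is an age/sex baseline (0.92 at 60, −0.003/year,
+0.02 male) minus additive complication decrements (e.g. MI 0.055, stroke
0.16, amputation 0.28) and a BMI disutility of 0.006 per kg/m² above 25,
floored at −0.594 (the EQ-5D-5L index minimum). Additive combination
follows common outcomes-model convention; multiplicative combination would
give slightly higher utilities in multimorbid person-years. Costs and QALYs
are discounted at 3.5% per UK guidance; the programme cost enters once,
undiscounted, at entry.

**Remission.** Simulated remission begins at year 1 if HbA1c(1) < 48
mmol/mol (strict inequality) and ends permanently at the first year with
HbA1c ≥ 48; only medication costs respond to remission — complication
hazards see HbA1c itself, not the remission flag. Under the default drift
(+0.5/year) remissions starting well below 48 can last beyond the ~4-year
durations reported for real cohorts; this is a known artefact of the linear
drift and disappears with steeper post-remission drift or published
trajectory equations.

## Within-trial analysis

Complete-case by default (a mean-imputation switch exists); QALYs by
trapezoidal AUC over the 0/6/12-month utilities; arm means compared without
baseline regression adjustment (the adjustment specification behind the
published within-trial estimates is not described in enough detail to
reproduce, and a config flag marks where it would plug in). Uncertainty:
5,000 paired person-level bootstrap resamples within arm, seeded. Cost per
mmol/mol and per kg count a *decrease* as positive and flag dominance when
the intervention is cheaper and clinically better.

## Probabilistic sensitivity analysis

Distribution families follow standard health-economics practice: normal
for effect sizes, gamma for costs, beta for probabilities/decrements
(mean/SD converted to the natural hyperparameters), lognormal for relative
risks. Effect-size SDs (0.60 kg, 1.10 mmol/mol) are the standard errors
implied by the published 95% CIs of the 12-month effects; cost and
decrement SDs are set at 15% and ~20% of the mean respectively, a common
default when second moments are unreported. Draws are independent across
parameters (no published correlation structure); all distributions are
validated before any simulation. The configured default is 2,000 draws;
desk-scale analyses in `analysis/` and `scripts/acceptance.py` use 200
draws on 2,000 persons, which bounds the Monte-Carlo SE of the CEAC value
at ≈ 0.035 and keeps the full run near a minute.

## Subgroups

BMI bands are half-open [lower, upper) — [28, 30), [30, 35), [35, 40) and
[40, ∞), plus a "<28" band so the partition is exhaustive (the eligible
population extends down to BMI 25); duration splits at 1 year; IMD uses
the five quintiles. Empty strata are reported as missing rows. Because the
event stream is person-keyed, stratum results weighted by stratum size
recompose the whole-population increments exactly.

## Problem sizes and determinism

Default desk-scale sizes: 20,000 persons for deterministic lifetime runs
(per-arm Monte-Carlo error on mean QALYs ≈ 0.02), 2,000 persons × 200 draws
for PSA, 10,000 for moment-recovery and survival checks, 5,000 for
calibration demonstrations. The configured population default remains
100,000. One global seed fans out to stage seeds via SHA-256 of
`"<seed>:<stage>"` (mod 2³¹); identical seeds give byte-identical outputs,
and every written table carries the seed and a config digest in a comment
header.

## Known limitations

- Illustrative risk equations and unit costs: absolute results are not
  comparable to published absolute values (incremental logic is).
- Linear unbounded drift trajectories; no insulin initiation; no
  HbA1c-lowering feedback from incident complications.
- Gaussian-copula synthetic data understate real-world skewness; adjusted
  regression estimates (mixed models, MICE internals) are intentionally out
  of scope — only the delta adjustment applied to imputed values is
  implemented.
- One event of each type per lifetime (first occurrence), per the standard
  outcomes-model structure; recurrent events are not modelled.
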