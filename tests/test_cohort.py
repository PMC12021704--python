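"""Synthetic population and trial generation."""

import numpy as np
import pandas as pd
import pytest

from t2dcea.cohort import (
    CohortSpec,
    ContinuousSpec,
    generate_population,
    generate_trial,
    stratified_block_randomise,
)
from t2dcea.errors import ConfigurationError
from t2dcea.trajectories import ARM_CONTROL, ARM_INTERVENTION, InterventionEffectProfile


def _mini_spec(n=2000, seed=0, **overrides):
    base = dict(
        n=n,
        continuous={
            "age": ContinuousSpec(59.8, 12.6, 18.0, 95.0),
            "bmi": ContinuousSpec(34.6, 6.8, 25.0, 70.0),
            "weight": ContinuousSpec(97.8, 20.5, 40.0, 250.0),
            "hba1c": ContinuousSpec(53.9, 13.6, 30.0, 130.0),
            "sbp": ContinuousSpec(134.5, 17.3, 80.0, 220.0),
            "dbp": ContinuousSpec(80.8, 10.0, 40.0, 130.0),
            "total_chol": ContinuousSpec(4.74, 1.1, 2.0, 12.0),
            "hdl": ContinuousSpec(1.25, 0.5, 0.5, 4.0),
            "ldl": ContinuousSpec(2.53, 0.9, 0.5, 8.0),
        },
        binary={
            "is_male": 0.478,
            "smoker": 0.15,
            "on_glucose_med": 0.6,
            "on_statin": 0.55,
            "on_antihypertensive": 0.5,
        },
        imd_probs=[0.155, 0.159, 0.243, 0.222, 0.221],
        duration_under1_prob=0.545,
        correlation_pairs={("weight", "bmi"): 0.9, ("bmi", "sbp"): 0.2},
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


class TestPopulation:
    def test_eligibility_invariants_enforced(self):
        pop = generate_population(_mini_spec(n=3000, seed=3))
        assert (pop["age"] >= 18).all()
        assert (pop["bmi"] >= 25).all()
        assert (pop["diabetes_duration"] <= 3).all()
        assert (pop["hba1c"] > 0).all()
        assert pop["imd_quintile"].isin([1, 2, 3, 4, 5]).all()

    def test_degenerate_sds_collapse_to_mean_vector(self):
        spec = _mini_spec(n=50, seed=1)
        spec.continuous = {k: ContinuousSpec(v.mean, 0.0) for k, v in spec.continuous.items()}
        spec.binary = {k: 1.0 for k in spec.binary}
        pop = generate_population(spec)
        for name, m in spec.continuous.items():
            assert (pop[name] == m.mean).all()

    def test_seed_determinism_is_byte_identical(self):
        a = generate_population(_mini_spec(seed=9)).to_csv(index=False)
        b = generate_population(_mini_spec(seed=9)).to_csv(index=False)
        assert a == b
        c = generate_population(_mini_spec(seed=10)).to_csv(index=False)
        assert a != c

    def test_copula_preserves_requested_correlation(self):
        pop = generate_population(_mini_spec(n=8000, seed=4))
        r = np.corrcoef(pop["weight"], pop["bmi"])[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)

    def test_non_psd_correlation_rejected(self):
        spec = _mini_spec(
            correlation_pairs={
                ("weight", "bmi"): 0.9,
                ("bmi", "sbp"): 0.9,
                ("weight", "sbp"): -0.9,
            }
        )
        with pytest.raises(ConfigurationError, match="positive semi-definite"):
            generate_population(spec)

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ConfigurationError, match="truncation"):
            ContinuousSpec(50.0, 5.0, lower=60.0, upper=40.0)
        with pytest.raises(ConfigurationError, match="bounds"):
            ContinuousSpec(50.0, 5.0, lower=60.0, upper=70.0)


@pytest.fixture(scope="module")
def effects():
    return InterventionEffectProfile(-0.84, -0.49)


class TestTrial:

    def test_no_attrition_means_no_missing_12m(self, effects):
        trial = generate_trial(_mini_spec(n=300, seed=5), effects, 0.0, seed=6)
        assert trial["completed_12m"].all()
        assert trial[["weight_12", "hba1c_12", "utility_12"]].notna().all().all()

    def test_completers_near_binomial_mean(self, effects):
        # 577 randomised at 31% attrition: expect ~398 completers
        trial = generate_trial(_mini_spec(n=577, seed=7), effects, 0.31, seed=8)
        n, p = 577, 0.69
        sd = np.sqrt(n * p * (1 - p))
        assert abs(trial["completed_12m"].sum() - n * p) < 3 * sd
        missing = ~trial["completed_12m"]
        assert trial.loc[missing, "weight_12"].isna().all()
        assert trial.loc[~missing, "weight_12"].notna().all()

    def test_null_effects_leave_arms_indistinguishable(self):
        trial = generate_trial(
            _mini_spec(n=4000, seed=11), InterventionEffectProfile(0.0, 0.0), 0.0, seed=12
        )
        change = trial["weight_12"] - trial["weight_0"]
        by_arm = change.groupby(trial["arm"])
        diff = by_arm.mean()[ARM_INTERVENTION] - by_arm.mean()[ARM_CONTROL]
        se = np.sqrt(sum(by_arm.var() / by_arm.count()))
        assert abs(diff) < 3 * se

    def test_intervention_effect_recovered_at_12m(self, effects):
        trial = generate_trial(_mini_spec(n=8000, seed=13), effects, 0.0, seed=14)
        change = trial["weight_12"] - trial["weight_0"]
        by_arm = change.groupby(trial["arm"])
        diff = by_arm.mean()[ARM_INTERVENTION] - by_arm.mean()[ARM_CONTROL]
        se = np.sqrt(sum(by_arm.var() / by_arm.count()))
        # kg effect implied by the BMI effect and mean height
        expected = effects.bmi_effect_12m * (97.8 / 34.6)
        assert diff == pytest.approx(expected, abs=3 * se)

    def test_utilities_within_index_range(self, effects):
        trial = generate_trial(_mini_spec(n=1000, seed=15), effects, 0.2, seed=16)
        for col in ("utility_0", "utility_6", "utility_12"):
            vals = trial[col].dropna()
            assert ((vals >= -0.594) & (vals <= 1.0)).all()

    def test_stratified_blocks_balance_every_complete_prefix(self):
        pop = generate_population(_mini_spec(n=700, seed=17))
        rng = np.random.default_rng(0)
        arms = pd.Series(stratified_block_randomise(pop, rng), index=pop.index)
        strata = pop.groupby([pop["is_male"], pop["diabetes_duration"] < 1.0])
        for _, idx in strata.groups.items():
            seq = arms.loc[idx].to_numpy()
            for k in range(6, len(seq) + 1, 6):
                prefix = seq[:k]
                assert (prefix == ARM_INTERVENTION).sum() == k // 2
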