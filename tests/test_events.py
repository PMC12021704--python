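"""Risk-equation evaluation, event simulation and hazard calibration."""

import numpy as np
import pandas as pd
import pytest

from t2dcea.errors import CalibrationError, ConfigurationError
from t2dcea.events import (
    RiskEquation,
    annual_probability,
    calibrate,
    cumulative_incidence,
    simulate_cohort,
    simulate_person,
)
from t2dcea.trajectories import ARM_CONTROL, null_profile, simulate_trajectories

DRIFT0 = {"hba1c": 0.0, "bmi": 0.0, "sbp": 0.0, "chol_hdl_ratio": 0.0}


def toy_baseline(n=100, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "age": rng.uniform(45, 75, n),
            "is_male": rng.random(n) < 0.5,
            "diabetes_duration": rng.uniform(0, 3, n),
            "bmi": rng.uniform(26, 45, n),
            "weight": rng.uniform(70, 130, n),
            "hba1c": rng.uniform(40, 90, n),
            "sbp": rng.uniform(110, 170, n),
            "dbp": rng.uniform(65, 100, n),
            "total_chol": rng.uniform(3.5, 6.5, n),
            "hdl": rng.uniform(0.8, 2.0, n),
            "ldl": rng.uniform(1.5, 4.0, n),
            "smoker": rng.random(n) < 0.15,
            "imd_quintile": rng.integers(1, 6, n),
            "on_glucose_med": rng.random(n) < 0.6,
            "on_statin": rng.random(n) < 0.5,
            "on_antihypertensive": rng.random(n) < 0.5,
        }
    )


def flat_covariates(n=1, **overrides):
    cov = {
        "age": np.full(n, 60.0),
        "hba1c": np.full(n, 54.0),
        "bmi": np.full(n, 34.0),
        "sbp": np.full(n, 134.0),
        "chol_hdl_ratio": np.full(n, 3.8),
        "duration": np.full(n, 1.0),
        "is_male": np.zeros(n, bool),
        "smoker": np.zeros(n, bool),
        "on_statin": np.zeros(n, bool),
        "on_antihypertensive": np.zeros(n, bool),
    }
    cov.update(overrides)
    return cov


class TestAnnualProbability:
    def test_unit_hazard_gives_1_minus_e_inverse(self):
        eq = RiskEquation("mi", "exponential", {"intercept": 0.0})
        p = annual_probability(eq, flat_covariates())
        assert p[0] == pytest.approx(1.0 - np.exp(-1.0))

    def test_calibration_multiplier_scales_hazard_exactly(self):
        eq1 = RiskEquation("mi", "exponential", {"intercept": -2.0})
        eq2 = RiskEquation("mi", "exponential", {"intercept": -2.0}, calibration_multiplier=0.5)
        h1 = -np.log(1.0 - annual_probability(eq1, flat_covariates())[0])
        h2 = -np.log(1.0 - annual_probability(eq2, flat_covariates())[0])
        assert h2 == pytest.approx(h1 / 2.0)

    def test_statin_rr_multiplies_hazard_when_on_treatment(self):
        eq = RiskEquation(
            "mi", "exponential", {"intercept": float(np.log(0.02))}, treatment_rr={"statin": 0.75}
        )
        on = annual_probability(eq, flat_covariates(on_statin=np.ones(1, bool)))[0]
        off = annual_probability(eq, flat_covariates())[0]
        assert on == pytest.approx(1.0 - np.exp(-0.015))
        assert off == pytest.approx(1.0 - np.exp(-0.02))

    def test_missing_covariate_error_names_it(self):
        eq = RiskEquation("mi", "exponential", {"intercept": 0.0, "egfr": 0.1})
        with pytest.raises(ConfigurationError, match="egfr"):
            annual_probability(eq, flat_covariates())

    def test_small_hazard_limit(self):
        eq = RiskEquation("mi", "exponential", {"intercept": float(np.log(1e-4))})
        p = annual_probability(eq, flat_covariates())[0]
        assert abs(p - 1e-4) < 1e-6

    def test_monotone_in_positively_signed_coefficient(self):
        ps = []
        for coef in (0.0, 0.01, 0.02, 0.05):
            eq = RiskEquation("mi", "exponential", {"intercept": -6.0, "hba1c": coef})
            ps.append(annual_probability(eq, flat_covariates())[0])
        assert np.all(np.diff(ps) >= 0)

    @pytest.mark.parametrize("form", ["weibull-in-duration", "gompertz-in-age", "logistic"])
    def test_all_forms_give_valid_probabilities(self, form):
        eq = RiskEquation("mi", form, {"intercept": -5.0, "shape": 1.3, "hba1c": 0.01})
        p = annual_probability(eq, flat_covariates(n=5))
        assert np.all((p >= 0) & (p <= 1))

    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigurationError, match="form"):
            RiskEquation("mi", "cauchy", {"intercept": 0.0})


class TestSimulation:
    def test_zero_hazard_survives_to_max_age(self):
        baseline = toy_baseline(20, seed=1)
        eqs = {"death": RiskEquation("death", "exponential", {"intercept": -60.0})}
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 60)
        hist = simulate_cohort(baseline, eqs, traj, seed=0, max_age=100.0)
        assert hist["alive"].all()
        assert hist["death_year"].isna().all()

    def test_certain_death_in_first_year(self):
        baseline = toy_baseline(20, seed=2)
        eqs = {
            "death": RiskEquation("death", "exponential", {"intercept": 20.0}),
            "mi": RiskEquation("mi", "exponential", {"intercept": -60.0}),
        }
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 10)
        hist = simulate_cohort(baseline, eqs, traj, seed=0)
        assert (hist["death_year"] == 1).all()
        assert hist["mi_year"].isna().all()
        assert hist["age_at_death"].to_numpy() == pytest.approx(
            baseline["age"].to_numpy() + 1
        )

    def test_death_requires_equation(self):
        baseline = toy_baseline(5)
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 5)
        with pytest.raises(ConfigurationError, match="death"):
            simulate_cohort(baseline, {"mi": RiskEquation("mi", "exponential", {})}, traj, seed=0)

    def test_single_person_wrapper_agrees_with_cohort(self):
        baseline = toy_baseline(1, seed=3)
        eqs = {"death": RiskEquation("death", "exponential", {"intercept": -2.0})}
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 50)
        a = simulate_person(baseline.iloc[0].to_dict(), eqs, traj, seed=5)
        b = simulate_cohort(baseline, eqs, traj, seed=5).iloc[0]
        assert a.equals(b)

    def test_same_seed_reproduces_histories(self):
        baseline = toy_baseline(200, seed=4)
        eqs = {"death": RiskEquation("death", "exponential", {"intercept": -3.0})}
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 40)
        a = simulate_cohort(baseline, eqs, traj, seed=7)
        b = simulate_cohort(baseline, eqs, traj, seed=7)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def setting():
    baseline = toy_baseline(2000, seed=5)
    eq = RiskEquation("mi", "exponential", {"intercept": -4.0, "hba1c": 0.01})
    return baseline, eq


class TestCalibration:

    def test_fixed_point_multiplier_near_one(self, setting):
        baseline, eq = setting
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 10)
        target = cumulative_incidence(eq, baseline, traj, horizon=10, seed=3)
        mult = calibrate(eq, baseline, target, horizon=10, tol=2e-3, seed=3)
        # re-simulation at the calibrated multiplier reproduces the target
        achieved = cumulative_incidence(eq, baseline, traj, 10, seed=3, multiplier=mult)
        assert abs(achieved - target) <= 2e-3

    def test_half_target_reached_within_tolerance(self, setting):
        baseline, eq = setting
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 10)
        target = cumulative_incidence(eq, baseline, traj, horizon=10, seed=3) / 2.0
        mult = calibrate(eq, baseline, target, horizon=10, tol=3e-3, seed=3)
        assert mult < 1.0
        achieved = cumulative_incidence(eq, baseline, traj, 10, seed=3, multiplier=mult)
        assert abs(achieved - target) <= 3e-3

    def test_incidence_monotone_in_multiplier_under_crn(self, setting):
        baseline, eq = setting
        traj = simulate_trajectories(baseline, DRIFT0, null_profile(), ARM_CONTROL, 10)
        incs = [
            cumulative_incidence(eq, baseline, traj, 10, seed=3, multiplier=m)
            for m in (0.1, 0.5, 1.0, 2.0, 10.0)
        ]
        assert np.all(np.diff(incs) >= 0)

    def test_zero_target_unreachable(self, setting):
        baseline, eq = setting
        with pytest.raises(CalibrationError):
            calibrate(eq, baseline, 0.0, horizon=10, seed=3)

    def test_target_above_reachable_range_raises(self, setting):
        baseline, eq = setting
        strong = RiskEquation("mi", "exponential", {"intercept": -30.0})
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate(strong, baseline.head(50), 0.999999, horizon=2, tol=1e-9, seed=3)
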