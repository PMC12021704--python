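"""Discounting, remission accounting, accrual and CEA summaries."""

import numpy as np
import pandas as pd
import pytest

from t2dcea.econ import (
    CostUtilityCatalogue,
    accrue,
    discount,
    remission_status,
    summarize,
)
from t2dcea.errors import ConfigurationError
from t2dcea.utils import round_sig


class TestDiscount:
    @pytest.mark.parametrize(
        "amount,year,rate,expected",
        [(100.0, 0, 0.035, 100.0), (100.0, 1, 0.035, 96.618), (100.0, 2, 0.0, 100.0)],
    )
    def test_present_values(self, amount, year, rate, expected):
        assert discount(amount, year, rate) == pytest.approx(expected, abs=5e-4)

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(ConfigurationError):
            discount(100.0, 1, -1.5)


class TestRemission:
    def test_entry_then_relapse(self):
        # below 48 at years 1-2, rises to 49 at year 3: remission years 1-2 only
        flags = remission_status([55.0, 47.0, 47.5, 49.0, 47.0])
        assert flags.tolist() == [False, True, True, False, False]

    def test_boundary_48_is_not_remission(self):
        assert not remission_status([55.0, 48.0, 45.0]).any()

    def test_constant_low_hba1c_stays_in_remission(self):
        flags = remission_status([50.0, 45.0, 45.0, 45.0])
        assert flags.tolist() == [False, True, True, True]

    def test_year_zero_never_remission(self):
        assert not remission_status([30.0, 45.0])[0]

    def test_matrix_form_matches_per_person(self):
        h = np.array([[55.0, 47.0, 49.0], [55.0, 50.0, 40.0]])
        flags = remission_status(h)
        assert flags[0].tolist() == [False, True, False]
        assert flags[1].tolist() == [False, False, False]


def _catalogue(**kw):
    defaults = dict(
        event_costs={"mi": (5000.0, 800.0)},
        utility_decrements={"mi": 0.055},
        management_cost=0.0,
        medication_cost=0.0,
        utility_intercept=0.8,
        utility_age_slope=0.0,
        utility_male=0.0,
        bmi_disutility_per_unit=0.0,
        discount_rate=0.0,
    )
    defaults.update(kw)
    return CostUtilityCatalogue(**defaults)


def _toy(n_years, hba1c=55.0, n=1, death_year=np.nan, mi_year=np.nan):
    histories = pd.DataFrame(
        {"id": range(n), "mi_year": [mi_year] * n, "death_year": [death_year] * n}
    )
    t = n_years + 1
    trajectories = {
        "hba1c": np.full((n, t), hba1c),
        "bmi": np.full((n, t), 25.0),
        "age": np.tile(60.0 + np.arange(t), (n, 1)),
    }
    baseline = pd.DataFrame({"is_male": [False] * n})
    return histories, trajectories, baseline


class TestAccrue:
    def test_constant_utility_two_years_undiscounted(self):
        h, traj, base = _toy(2)
        costs, qalys = accrue(h, traj, _catalogue(), base)
        assert qalys[0] == pytest.approx(1.6)
        assert costs[0] == 0.0

    def test_no_accrual_at_or_after_death(self):
        h, traj, base = _toy(5, death_year=1.0)
        cat = _catalogue(management_cost=100.0)
        costs, qalys = accrue(h, traj, cat, base)
        assert qalys[0] == pytest.approx(0.8)  # year 0 only
        assert costs[0] == pytest.approx(100.0)

    def test_first_year_event_cost_discounted(self):
        # accrual covers years 0..3; MI in year 2 costs 5000 then 800
        h, traj, base = _toy(4, mi_year=2.0)
        cat = _catalogue(discount_rate=0.035)
        costs, _ = accrue(h, traj, cat, base)
        assert costs[0] == pytest.approx(5000.0 / 1.035**2 + 800.0 / 1.035**3)

    def test_event_decrement_applies_from_event_year(self):
        h, traj, base = _toy(4, mi_year=2.0)
        _, qalys = accrue(h, traj, _catalogue(), base)
        assert qalys[0] == pytest.approx(0.8 * 4 - 0.055 * 2)

    def test_intervention_cost_enters_once_undiscounted(self):
        h, traj, base = _toy(2)
        costs, _ = accrue(h, traj, _catalogue(discount_rate=0.035), base, arm_intervention_cost=325.0)
        assert costs[0] == pytest.approx(325.0)

    def test_medication_cost_removed_in_remission_years(self):
        h, traj, base = _toy(3, hba1c=45.0)
        traj["hba1c"][:, 0] = 55.0  # not in remission at entry year
        cat = _catalogue(medication_cost=300.0)
        costs, _ = accrue(h, traj, cat, base)
        assert costs[0] == pytest.approx(300.0)  # year 0 only

    def test_disabling_remission_never_decreases_cost(self):
        h, traj, base = _toy(6, hba1c=45.0)
        cat = _catalogue(medication_cost=300.0)
        with_rem, _ = accrue(h, traj, cat, base, apply_remission=True)
        without, _ = accrue(h, traj, cat, base, apply_remission=False)
        assert without[0] >= with_rem[0]

    def test_discounted_totals_bounded_by_undiscounted(self):
        h, traj, base = _toy(10, mi_year=3.0)
        cat0 = _catalogue(management_cost=500.0, discount_rate=0.0)
        cat35 = _catalogue(management_cost=500.0, discount_rate=0.035)
        c0, q0 = accrue(h, traj, cat0, base)
        c35, q35 = accrue(h, traj, cat35, base)
        assert c35[0] <= c0[0] and q35[0] <= q0[0]


class TestSummarize:
    def test_published_increments_reproduce_icer_2290(self):
        # arms engineered to differ by dCost=81, dQALY=0.0353
        res = summarize(([1000.0], [8.7008]), ([1081.0], [8.7361]), thresholds=[20_000.0])
        assert res.icer_status == "icer"
        assert round_sig(res.icer, 3) == 2290
        assert res.nmb[20_000.0] == pytest.approx(625.0)

    def test_cheaper_and_better_is_dominant(self):
        res = summarize(([1000.0], [8.7008]), ([974.0], [8.7361]))
        assert res.icer_status == "dominant" and res.icer is None

    def test_costlier_and_worse_is_dominated(self):
        res = summarize(([1000.0], [8.74]), ([1100.0], [8.70]))
        assert res.icer_status == "dominated"

    def test_identical_arms_undefined(self):
        res = summarize(([1000.0], [8.7]), ([1000.0], [8.7]))
        assert res.icer_status == "undefined" and res.icer is None

    def test_nmb_identity_for_every_threshold(self):
        res = summarize(
            ([900.0, 1100.0], [8.0, 9.0]),
            ([950.0, 1150.0], [8.1, 9.05]),
            thresholds=[13_000.0, 20_000.0, 30_000.0],
        )
        for lam, nmb in res.nmb.items():
            assert nmb == pytest.approx(lam * res.delta_qaly - res.delta_cost, abs=1e-9)

    def test_empty_arm_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize(([], []), ([1.0], [1.0]))
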