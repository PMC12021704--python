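"""Lifetime discounted cost and QALY accrual and cost-effectiveness summaries.

Each simulated life-year alive contributes a management cost, a diabetes
medication cost (removed during remission years), and complication costs
(first-year vs subsequent-year); utility is an age/sex baseline minus
additive decrements for incurred complications and excess BMI, floored at
the EQ-5D index minimum. Both streams are discounted annually; the
programme cost enters once, undiscounted, at entry. No half-cycle
correction is applied (accrual at year start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trajectories import ARM_CONTROL, ARM_INTERVENTION
from .within_trial import incremental_nmb

REMISSION_HBA1C = 48.0  # mmol/mol (6.5%)
UTILITY_FLOOR = -0.594

DEFAULT_DISCOUNT_RATE = 0.035


def discount(amount: float, year: int, rate: float = DEFAULT_DISCOUNT_RATE) -> float:
    """Present value of ``amount`` accrued at the start of ``year`` (year 0 undiscounted)."""
    if rate <= -1.0:
        raise ConfigurationError("discount rate must exceed -1")
    if np.any(np.asarray(year) < 0):
        raise ConfigurationError("year must be non-negative")
    return amount / (1.0 + rate) ** year


def remission_status(hba1c_trajectory, year: int | None = None):
    """Diabetes remission flags from an HbA1c trajectory.

    Remission begins at year 1 if HbA1c(1) < 48 mmol/mol and ends — for
    good — at the first subsequent year with HbA1c >= 48. Year 0 is never a
    remission year. Accepts a 1-D trajectory (returns a flag per year, or a
    single flag when ``year`` is given) or a 2-D ``(n_persons, n_years+1)``
    array.
    """
    h = np.atleast_2d(np.asarray(hba1c_trajectory, dtype=float))
    flags = np.zeros_like(h, dtype=bool)
    if h.shape[1] > 1:
        below = h[:, 1:] < REMISSION_HBA1C
        flags[:, 1:] = np.cumprod(below, axis=1).astype(bool)
    if np.asarray(hba1c_trajectory).ndim == 1:
        flags = flags[0]
        if year is not None:
            return bool(flags[year])
    elif year is not None:
        return flags[:, year]
    return flags


@dataclass
class CostUtilityCatalogue:
    """Unit costs, utility model and discounting for the lifetime analysis."""

    event_costs: dict[str, tuple[float, float]]  # outcome -> (first year, subsequent)
    utility_decrements: dict[str, float]
    management_cost: float  # annual diabetes management, GBP
    medication_cost: float  # annual glucose-lowering medication, GBP
    utility_intercept: float = 0.92  # EQ-5D index at the reference age
    utility_age_slope: float = -0.003  # per year of age beyond the reference
    utility_male: float = 0.02
    utility_reference_age: float = 60.0
    bmi_disutility_per_unit: float = 0.006  # per kg/m2 above 25
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    utility_floor: float = UTILITY_FLOOR

    def __post_init__(self) -> None:
        if self.management_cost < 0 or self.medication_cost < 0:
            raise ConfigurationError("annual costs must be non-negative")
        for o, (c1, c2) in self.event_costs.items():
            if c1 < 0 or c2 < 0:
                raise ConfigurationError(f"negative event cost for {o!r}")
        for o, d in self.utility_decrements.items():
            if d < 0:
                raise ConfigurationError(f"negative utility decrement for {o!r}")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "CostUtilityCatalogue":
        return cls(
            event_costs={
                o: (float(d["first_year"]), float(d["subsequent"]))
                for o, d in cfg["event_costs"].items()
            },
            utility_decrements={o: float(v) for o, v in cfg["utility_decrements"].items()},
            management_cost=float(cfg["management_cost"]),
            medication_cost=float(cfg["medication_cost"]),
            utility_intercept=float(cfg.get("utility_intercept", 0.92)),
            utility_age_slope=float(cfg.get("utility_age_slope", -0.003)),
            utility_male=float(cfg.get("utility_male", 0.02)),
            utility_reference_age=float(cfg.get("utility_reference_age", 60.0)),
            bmi_disutility_per_unit=float(cfg.get("bmi_disutility_per_unit", 0.006)),
            discount_rate=float(cfg.get("discount_rate", DEFAULT_DISCOUNT_RATE)),
        )

    def baseline_utility(self, age, is_male):
        return (
            self.utility_intercept
            + self.utility_age_slope * (np.asarray(age, float) - self.utility_reference_age)
            + self.utility_male * np.asarray(is_male, float)
        )


def accrue(
    histories: pd.DataFrame,
    trajectories: Mapping[str, np.ndarray],
    catalogue: CostUtilityCatalogue,
    baseline: pd.DataFrame,
    arm_intervention_cost: float = 0.0,
    apply_remission: bool = True,
    max_age: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-person discounted lifetime costs and QALYs.

    A person accrues in year ``t`` iff ``t < death_year`` (no accrual in or
    after the death year) and their age is below ``max_age``. Medication
    costs are zeroed in remission years when ``apply_remission``; the
    programme cost is added once at year 0. Returns ``(costs, qalys)``
    arrays aligned with ``histories``.
    """
    n = len(histories)
    n_years = trajectories["hba1c"].shape[1] - 1
    death_year = histories["death_year"].to_numpy(float)
    is_male = baseline["is_male"].to_numpy(float)

    outcomes = [c[: -len("_year")] for c in histories.columns if c.endswith("_year") and c != "death_year"]
    ev_years = {o: histories[f"{o}_year"].to_numpy(float) for o in outcomes}

    if apply_remission:
        remission = remission_status(trajectories["hba1c"])
    else:
        remission = np.zeros_like(trajectories["hba1c"], dtype=bool)

    disc = (1.0 + catalogue.discount_rate) ** -np.arange(n_years + 1)
    costs = np.full(n, float(arm_intervention_cost))
    qalys = np.zeros(n)
    for t in range(n_years):
        alive = (np.isnan(death_year) | (t < death_year)) & (
            trajectories["age"][:, t] < max_age
        )
        if not alive.any():
            break
        cost_t = np.full(n, catalogue.management_cost)
        cost_t += np.where(remission[:, t], 0.0, catalogue.medication_cost)
        for o in outcomes:
            ey = ev_years[o]
            c1, c2 = catalogue.event_costs.get(o, (0.0, 0.0))
            cost_t += np.where(ey == t, c1, 0.0) + np.where(ey < t, c2, 0.0)
        util_t = catalogue.baseline_utility(trajectories["age"][:, t], is_male)
        util_t = util_t - catalogue.bmi_disutility_per_unit * np.clip(
            trajectories["bmi"][:, t] - 25.0, 0.0, None
        )
        for o in outcomes:
            dec = catalogue.utility_decrements.get(o, 0.0)
            util_t = util_t - dec * (ev_years[o] <= t)
        util_t = np.clip(util_t, catalogue.utility_floor, 1.0)

        costs += np.where(alive, cost_t * disc[t], 0.0)
        qalys += np.where(alive, util_t * disc[t], 0.0)
    return costs, qalys


@dataclass
class CEAResult:
    """Cost-effectiveness summary for intervention vs control."""

    mean_cost: dict[str, float]
    mean_qalys: dict[str, float]
    delta_cost: float
    delta_qaly: float
    icer: float | None
    icer_status: str  # "icer" | "dominant" | "dominated" | "undefined"
    nmb: dict[float, float] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "cost_DE": self.mean_cost[ARM_CONTROL],
            "cost_DEW": self.mean_cost[ARM_INTERVENTION],
            "qalys_DE": self.mean_qalys[ARM_CONTROL],
            "qalys_DEW": self.mean_qalys[ARM_INTERVENTION],
            "incremental_cost": self.delta_cost,
            "incremental_qalys": self.delta_qaly,
            "icer": self.icer,
            "icer_status": self.icer_status,
        }
        for lam, v in self.nmb.items():
            row[f"nmb_{int(lam)}"] = v
        return row


def summarize(
    control: tuple[np.ndarray, np.ndarray],
    intervention: tuple[np.ndarray, np.ndarray],
    thresholds=(20_000.0,),
) -> CEAResult:
    """Summarise per-person (cost, QALY) accruals of the two arms.

    ICER is ``delta_cost / delta_QALY``; "dominant" marks lower cost with
    more QALYs, "dominated" the reverse, and a zero QALY difference leaves
    the ICER undefined.
    """
    c0, q0 = (np.asarray(a, float) for a in control)
    c1, q1 = (np.asarray(a, float) for a in intervention)
    if c0.size == 0 or c1.size == 0:
        raise ConfigurationError("both arms must be non-empty")
    delta_cost = float(c1.mean() - c0.mean())
    delta_qaly = float(q1.mean() - q0.mean())
    if delta_qaly == 0.0:
        icer, status = None, "undefined"
    elif delta_cost < 0 and delta_qaly > 0:
        icer, status = None, "dominant"
    elif delta_cost > 0 and delta_qaly < 0:
        icer, status = None, "dominated"
    else:
        icer, status = delta_cost / delta_qaly, "icer"
    return CEAResult(
        mean_cost={ARM_CONTROL: float(c0.mean()), ARM_INTERVENTION: float(c1.mean())},
        mean_qalys={ARM_CONTROL: float(q0.mean()), ARM_INTERVENTION: float(q1.mean())},
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        icer_status=status,
        nmb={float(lam): incremental_nmb(delta_cost, delta_qaly, lam) for lam in thresholds},
        n={ARM_CONTROL: int(c0.size), ARM_INTERVENTION: int(c1.size)},
    )
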