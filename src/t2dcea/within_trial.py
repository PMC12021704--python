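"""Within-trial (12-month) cost-utility analysis from an NHS/PSS perspective.

QALYs are trapezoidal areas under linearly interpolated EQ-5D utilities at
0, 6 and 12 months; costs combine observed healthcare use with the per-arm
programme cost. Uncertainty comes from a nonparametric person-level
bootstrap (paired resampling within arm), summarised as a CEAC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trajectories import ARM_CONTROL, ARM_INTERVENTION

DEFAULT_THRESHOLDS = (13_000.0, 20_000.0, 30_000.0)  # GBP per QALY


def qaly_auc(utilities, months=(0.0, 6.0, 12.0)) -> float:
    """QALYs accrued over the follow-up window.

    Trapezoidal area under the linear interpolant of utility against time in
    years. Raises if any utility is missing: imputation or exclusion is the
    caller's decision.
    """
    u = np.asarray(utilities, dtype=float)
    t = np.asarray(months, dtype=float) / 12.0
    if u.shape != t.shape:
        raise ConfigurationError("utilities and months must align")
    if np.any(np.isnan(u)):
        raise ValueError("missing utility; impute or drop before computing QALYs")
    return float(np.trapezoid(u, t))


def incremental_nmb(delta_cost: float, delta_qaly: float, threshold: float) -> float:
    """Incremental net monetary benefit ``threshold * dQALY - dCost``."""
    return threshold * delta_qaly - delta_cost


def ceac(draws, thresholds) -> dict[float, float]:
    """Probability of positive incremental NMB at each threshold.

    ``draws`` is a sequence of ``(delta_cost, delta_qaly)`` pairs from a
    bootstrap or PSA; the curve value at each threshold is the fraction of
    draws with ``NMB > 0``.
    """
    arr = np.asarray(list(draws), dtype=float)
    if arr.size == 0:
        raise ConfigurationError("CEAC requires at least one draw")
    dc, dq = arr[:, 0], arr[:, 1]
    return {
        float(lam): float(np.mean(lam * dq - dc > 0.0)) for lam in thresholds
    }


@dataclass(frozen=True)
class CostPerUnit:
    """Cost per unit of outcome improvement with dominance/undefined flags.

    ``delta_outcome_decrease`` follows the convention that a *decrease* in
    the clinical outcome (HbA1c, weight) is counted positive.
    """

    value: float | None
    status: str  # "ratio" | "dominant" | "undefined"


def cost_per_unit(delta_cost: float, delta_outcome_decrease: float) -> CostPerUnit:
    if delta_outcome_decrease == 0:
        return CostPerUnit(None, "undefined")
    if delta_cost < 0 and delta_outcome_decrease > 0:
        # cheaper and clinically better
        return CostPerUnit(delta_cost / delta_outcome_decrease, "dominant")
    return CostPerUnit(delta_cost / delta_outcome_decrease, "ratio")


@dataclass
class WithinTrialResult:
    """Arm-level and incremental results of the within-trial analysis."""

    n_analysed: dict[str, int]
    mean_cost: dict[str, float]
    mean_qalys: dict[str, float]
    delta_cost: float
    delta_qaly: float
    nmb: dict[float, float]
    cost_per_mmol_mol: CostPerUnit
    cost_per_kg: CostPerUnit
    ceac: dict[float, float]
    bootstrap_draws: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "n_analysed_DEW": self.n_analysed[ARM_INTERVENTION],
            "n_analysed_DE": self.n_analysed[ARM_CONTROL],
            "mean_cost_DEW": self.mean_cost[ARM_INTERVENTION],
            "mean_cost_DE": self.mean_cost[ARM_CONTROL],
            "mean_qalys_DEW": self.mean_qalys[ARM_INTERVENTION],
            "mean_qalys_DE": self.mean_qalys[ARM_CONTROL],
            "incremental_cost": self.delta_cost,
            "incremental_qalys": self.delta_qaly,
            "cost_per_mmol_mol": self.cost_per_mmol_mol.value,
            "cost_per_mmol_mol_status": self.cost_per_mmol_mol.status,
            "cost_per_kg": self.cost_per_kg.value,
            "cost_per_kg_status": self.cost_per_kg.status,
        }
        for lam, v in self.nmb.items():
            rows[f"nmb_{int(lam)}"] = v
        for lam, p in self.ceac.items():
            rows[f"p_cost_effective_{int(lam)}"] = p
        return pd.DataFrame({"quantity": list(rows), "value": list(rows.values())})


def analyze_within_trial(
    trial: pd.DataFrame,
    intervention_costs: dict[str, float],
    thresholds=DEFAULT_THRESHOLDS,
    n_bootstrap: int = 5000,
    seed: int = 0,
    missing: str = "complete-case",
) -> WithinTrialResult:
    """Run the trial-based cost-utility analysis on a trial table.

    Costs per person are total observed healthcare costs plus the arm's
    programme cost; QALYs are per-person utility AUCs. ``missing`` selects
    complete-case analysis (default) or arm-level mean imputation of the
    12-month utility and outcomes.
    """
    if missing not in ("complete-case", "mean-impute"):
        raise ConfigurationError(f"unknown missing-data handling: {missing!r}")
    df = trial.copy()
    if missing == "mean-impute":
        for col in ("utility_12", "hba1c_12", "weight_12"):
            df[col] = df[col].fillna(df.groupby("arm")[col].transform("mean"))
    else:
        df = df[df["completed_12m"]].copy()

    df["total_cost"] = (
        df["healthcare_cost_0to6"]
        + df["healthcare_cost_6to12"]
        + df["arm"].map(intervention_costs)
    )
    df["qalys"] = np.trapezoid(
        df[["utility_0", "utility_6", "utility_12"]].to_numpy(float),
        np.array([0.0, 0.5, 1.0]),
        axis=1,
    )
    df["hba1c_decrease"] = df["hba1c_0"] - df["hba1c_12"]
    df["weight_decrease"] = df["weight_0"] - df["weight_12"]

    groups = {arm: sub for arm, sub in df.groupby("arm")}
    for arm in (ARM_INTERVENTION, ARM_CONTROL):
        if arm not in groups or groups[arm].empty:
            raise ConfigurationError(f"no analysable participants in arm {arm}")

    def _means(sub: pd.DataFrame) -> pd.Series:
        return sub[["total_cost", "qalys", "hba1c_decrease", "weight_decrease"]].mean()

    m1, m0 = _means(groups[ARM_INTERVENTION]), _means(groups[ARM_CONTROL])
    delta_cost = float(m1["total_cost"] - m0["total_cost"])
    delta_qaly = float(m1["qalys"] - m0["qalys"])

    rng = np.random.default_rng(seed)
    draws = np.empty((n_bootstrap, 2))
    arm_arrays = {
        arm: groups[arm][["total_cost", "qalys"]].to_numpy(float)
        for arm in (ARM_INTERVENTION, ARM_CONTROL)
    }
    for b in range(n_bootstrap):
        means = {}
        for arm, arr in arm_arrays.items():
            idx = rng.integers(0, len(arr), len(arr))
            means[arm] = arr[idx].mean(axis=0)
        draws[b] = means[ARM_INTERVENTION] - means[ARM_CONTROL]
    draws_df = pd.DataFrame(draws, columns=["delta_cost", "delta_qaly"])

    return WithinTrialResult(
        n_analysed={arm: len(sub) for arm, sub in groups.items()},
        mean_cost={arm: float(_means(sub)["total_cost"]) for arm, sub in groups.items()},
        mean_qalys={arm: float(_means(sub)["qalys"]) for arm, sub in groups.items()},
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        nmb={float(lam): incremental_nmb(delta_cost, delta_qaly, lam) for lam in thresholds},
        cost_per_mmol_mol=cost_per_unit(
            delta_cost, float(m1["hba1c_decrease"] - m0["hba1c_decrease"])
        ),
        cost_per_kg=cost_per_unit(
            delta_cost, float(m1["weight_decrease"] - m0["weight_decrease"])
        ),
        ceac=ceac(draws, thresholds),
        bootstrap_draws=draws_df,
    )
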