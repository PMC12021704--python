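"""Lifetime model assembly: configuration to simulated arms.

Bridges the configuration mapping to the trajectory, event and economic
engines. Both arms run on the same synthetic population with common random
numbers (the same counter-based uniform stream keyed by the simulation
seed), so arm differences reflect only the intervention effect profile and
the programme costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, generate_population
from .econ import CEAResult, CostUtilityCatalogue, accrue, summarize
from .errors import ConfigurationError
from .events import RiskEquation, load_equations, simulate_cohort
from .trajectories import (
    ARM_CONTROL,
    ARM_INTERVENTION,
    InterventionEffectProfile,
    simulate_trajectories,
)
from .utils import stage_seed

_DATA = resources.files("t2dcea") / "data"


def default_config_path() -> Path:
    return Path(str(_DATA / "default_config.yaml"))


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run configuration (the packaged default if no path given)."""
    cfg_path = Path(path) if path is not None else default_config_path()
    if not cfg_path.exists():
        raise ConfigurationError(f"configuration file not found: {cfg_path}")
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    if "risk_equations" not in cfg:
        eq_file = cfg.get("risk_equations_file")
        if eq_file:
            eq_path = Path(eq_file)
            if not eq_path.is_absolute():
                eq_path = cfg_path.parent / eq_path
            if not eq_path.exists():
                raise ConfigurationError(f"risk-equation file not found: {eq_path}")
            with open(eq_path) as fh:
                cfg["risk_equations"] = yaml.safe_load(fh)
        else:
            with (_DATA / "risk_equations.yaml").open() as fh:
                cfg["risk_equations"] = yaml.safe_load(fh)
    return cfg


def build_profile(cfg: Mapping) -> InterventionEffectProfile:
    """Intervention effect profile from config; weight effect in kg is
    converted to BMI units via the height implied by the cohort's mean
    weight and BMI."""
    eff = cfg["effects"]
    mean_height_sq = cfg["cohort"]["continuous"]["weight"]["mean"] / cfg["cohort"]["continuous"]["bmi"]["mean"]
    return InterventionEffectProfile.from_weight_effect(
        hba1c_effect_12m=float(eff["hba1c_effect_12m"]),
        weight_effect_12m_kg=float(eff["weight_effect_12m_kg"]),
        mean_height_m=float(np.sqrt(mean_height_sq)),
        hba1c_decay_horizon=float(eff.get("hba1c_decay_horizon", 5.0)),
        bmi_decay_horizon=float(eff.get("bmi_decay_horizon", 10.0)),
        shape=eff.get("shape", "linear"),
    )


def build_equations(cfg: Mapping) -> dict[str, RiskEquation]:
    return load_equations(cfg["risk_equations"])


def build_catalogue(cfg: Mapping) -> CostUtilityCatalogue:
    return CostUtilityCatalogue.from_config(cfg["catalogue"])


@dataclass
class LifetimeRun:
    """Per-arm accruals and the summary of one lifetime model run.

    ``healthcare`` accruals exclude programme costs so delivery-mix
    scenarios can be layered on without re-simulating.
    """

    population: pd.DataFrame
    healthcare: dict[str, tuple[np.ndarray, np.ndarray]]  # arm -> (costs, qalys)
    result: CEAResult

    def scenario_result(
        self, intervention_costs: Mapping[str, float], thresholds=(20_000.0,)
    ) -> CEAResult:
        """Re-summarise with a different pair of per-person programme costs."""
        c0, q0 = self.healthcare[ARM_CONTROL]
        c1, q1 = self.healthcare[ARM_INTERVENTION]
        return summarize(
            (c0 + intervention_costs[ARM_CONTROL], q0),
            (c1 + intervention_costs[ARM_INTERVENTION], q1),
            thresholds,
        )


def run_lifetime(
    cfg: Mapping,
    population: pd.DataFrame | None = None,
    seed: int | None = None,
    n: int | None = None,
) -> LifetimeRun:
    """Run the lifetime microsimulation for both arms.

    The horizon covers every person to ``max_age``. ``seed`` keys both the
    population draw (when no population is passed) and the event uniform
    stream; the latter is shared between arms (common random numbers).
    """
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    if population is None:
        spec = CohortSpec.from_config(cfg["cohort"], n=n, seed=stage_seed(seed, "population"))
        population = generate_population(spec)

    profile = build_profile(cfg)
    equations = build_equations(cfg)
    catalogue = build_catalogue(cfg)
    drift = {k: float(v) for k, v in cfg["drift"].items()}
    max_age = float(cfg.get("max_age", 100.0))
    n_years = int(np.ceil(max_age - population["age"].min()))
    sim_seed = stage_seed(seed, "events")
    thresholds = [float(t) for t in cfg.get("thresholds", [20_000.0])]
    intervention_costs = {k: float(v) for k, v in cfg["intervention_costs"].items()}

    healthcare: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for arm in (ARM_CONTROL, ARM_INTERVENTION):
        traj = simulate_trajectories(population, drift, profile, arm, n_years)
        histories = simulate_cohort(population, equations, traj, seed=sim_seed, max_age=max_age)
        healthcare[arm] = accrue(histories, traj, catalogue, population, max_age=max_age)

    result = summarize(
        (
            healthcare[ARM_CONTROL][0] + intervention_costs[ARM_CONTROL],
            healthcare[ARM_CONTROL][1],
        ),
        (
            healthcare[ARM_INTERVENTION][0] + intervention_costs[ARM_INTERVENTION],
            healthcare[ARM_INTERVENTION][1],
        ),
        thresholds,
    )
    return LifetimeRun(population=population, healthcare=healthcare, result=result)


def scenario_report(run: LifetimeRun, cfg: Mapping) -> pd.DataFrame:
    """Delivery-mix scenario table (per-arm costs, QALYs, increments, NMB, ICER)."""
    thresholds = [float(t) for t in cfg.get("thresholds", [20_000.0])]
    dew_cost = float(cfg["intervention_costs"][ARM_INTERVENTION])
    rows = []
    for sc in cfg["scenarios"]:
        res = run.scenario_result(
            {ARM_INTERVENTION: dew_cost, ARM_CONTROL: float(sc["de_cost"])}, thresholds
        )
        rows.append({"scenario": sc["name"], "de_programme_cost": sc["de_cost"], **res.to_row()})
    return pd.DataFrame(rows)
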