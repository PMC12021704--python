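"""Annual-cycle complication and mortality simulation.

Each complication is governed by a configurable parametric risk equation
producing an annual hazard from the person's current risk-factor state and
event history; the annual event probability is ``1 - exp(-H)`` where the
hazard ``H`` is scaled by a calibration multiplier and by relative-risk
modifiers for active preventive treatments. Events are first occurrences;
history flags feed back into subsequent hazards.

The engine is deliberately coefficient-agnostic: equation forms and named
coefficients come from a plain-text parameter file, so any published
equation system (e.g. the UKPDS Outcomes Model, whose coefficients are not
redistributable) can be dropped in. The packaged parameter file is an
illustrative set with plausible magnitudes, not a published system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import CalibrationError, ConfigurationError
from .trajectories import simulate_trajectories, null_profile, ARM_CONTROL

OUTCOMES = (
    "amputation",
    "blindness",
    "chf",
    "death",
    "ihd",
    "mi",
    "renal_failure",
    "stroke",
    "ulcer",
)

_FORMS = ("exponential", "weibull-in-duration", "gompertz-in-age", "logistic")

#: Multiplier bounds searched during calibration.
CALIBRATION_BOUNDS = (1e-4, 1e4)


@dataclass
class RiskEquation:
    """Parametric annual-hazard specification for one complication.

    ``coefficients`` maps covariate names (plus ``intercept`` and, for the
    Weibull/Gompertz forms, the special key ``shape``) to values. The
    linear predictor is ``intercept + sum(coef * covariate)``; the base
    hazard then depends on ``form``:

    - ``exponential``: ``H = exp(lp)``
    - ``weibull-in-duration``: ``H = exp(lp) * shape * duration**(shape-1)``
    - ``gompertz-in-age``: ``H = exp(lp) * exp(shape * age)``
    - ``logistic``: ``p0 = expit(lp)`` converted to ``H = -log(1 - p0)``
    """

    outcome: str
    form: str
    coefficients: dict[str, float]
    calibration_multiplier: float = 1.0
    treatment_rr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ConfigurationError(f"unknown risk-equation form: {self.form!r}")
        if self.calibration_multiplier <= 0:
            raise ConfigurationError("calibration multiplier must be positive")
        for name, rr in self.treatment_rr.items():
            if not 0.0 < rr <= 1.0:
                raise ConfigurationError(f"treatment RR for {name!r} must be in (0, 1]")


def _linear_predictor(eq: RiskEquation, covariates: Mapping[str, np.ndarray]) -> np.ndarray:
    lp = np.asarray(float(eq.coefficients.get("intercept", 0.0)))
    for name, coef in eq.coefficients.items():
        if name in ("intercept", "shape"):
            continue
        if name not in covariates:
            raise ConfigurationError(
                f"risk equation for {eq.outcome!r} needs covariate {name!r}, "
                "which is not present in the simulation state"
            )
        lp = lp + coef * np.asarray(covariates[name], dtype=float)
    if lp.ndim == 0 and covariates:
        # intercept-only equations still evaluate per person
        n = np.asarray(next(iter(covariates.values()))).shape
        lp = np.broadcast_to(lp, n).copy()
    return lp


def annual_probability(eq: RiskEquation, covariates: Mapping[str, np.ndarray]) -> np.ndarray:
    """Annual event probability for the current state.

    ``covariates`` must contain every covariate the equation names, plus
    treatment flags ``on_<treatment>`` for any treatment RR modifiers.
    """
    lp = _linear_predictor(eq, covariates)
    if eq.form == "exponential":
        hazard = np.exp(lp)
    elif eq.form == "weibull-in-duration":
        shape = float(eq.coefficients.get("shape", 1.0))
        if "duration" not in covariates:
            raise ConfigurationError(
                f"risk equation for {eq.outcome!r} needs covariate 'duration'"
            )
        dur = np.clip(np.asarray(covariates["duration"], float), 1e-6, None)
        hazard = np.exp(lp) * shape * dur ** (shape - 1.0)
    elif eq.form == "gompertz-in-age":
        shape = float(eq.coefficients.get("shape", 0.0))
        if "age" not in covariates:
            raise ConfigurationError(
                f"risk equation for {eq.outcome!r} needs covariate 'age'"
            )
        hazard = np.exp(lp) * np.exp(shape * np.asarray(covariates["age"], float))
    else:  # logistic
        hazard = -np.log1p(-np.clip(expit(lp), 0.0, 1.0 - 1e-12))

    modifier = eq.calibration_multiplier
    for treatment, rr in eq.treatment_rr.items():
        flag_name = f"on_{treatment}"
        if flag_name not in covariates:
            raise ConfigurationError(
                f"risk equation for {eq.outcome!r} needs treatment flag {flag_name!r}"
            )
        active = np.asarray(covariates[flag_name], dtype=bool)
        modifier = modifier * np.where(active, rr, 1.0)
    return np.clip(1.0 - np.exp(-hazard * modifier), 0.0, 1.0)


def load_equations(source: Mapping) -> dict[str, RiskEquation]:
    """Build risk equations from a parsed parameter mapping (outcome -> spec)."""
    eqs = {}
    for outcome, spec in source.items():
        eqs[outcome] = RiskEquation(
            outcome=outcome,
            form=spec["form"],
            coefficients={k: float(v) for k, v in spec["coefficients"].items()},
            calibration_multiplier=float(spec.get("calibration_multiplier", 1.0)),
            treatment_rr={k: float(v) for k, v in spec.get("treatment_rr", {}).items()},
        )
    return eqs


def _uniforms(seed: int, year: int, outcome_index: int, ids: np.ndarray) -> np.ndarray:
    # counter-based stream keyed by person id: identical across arms, PSA
    # draws and population subsets (common random numbers) without storing
    # the full uniform tensor
    pool = np.random.default_rng([int(seed), int(year), int(outcome_index)]).random(
        int(ids.max()) + 1
    )
    return pool[ids]


def simulate_cohort(
    baseline: pd.DataFrame,
    equations: Mapping[str, RiskEquation],
    trajectories: Mapping[str, np.ndarray],
    seed: int,
    max_age: float = 100.0,
) -> pd.DataFrame:
    """Simulate first-occurrence event histories for a whole cohort.

    Annual loop over the trajectory horizon: within each year, outcomes are
    drawn in a fixed order (alphabetical, death last) by comparing a
    counter-based uniform against the annual probability evaluated at the
    start-of-year state. Simulation of a person stops at death or when they
    reach ``max_age``. Returns one row per person with ``<outcome>_year``
    columns (NaN if never), ``death_year``, ``age_at_death`` and ``alive``.
    """
    if "death" not in equations:
        raise ConfigurationError("equation set must cover 'death'")
    n = len(baseline)
    n_years = trajectories["hba1c"].shape[1] - 1
    order = sorted([o for o in equations if o != "death"]) + ["death"]

    event_year = {o: np.full(n, np.nan) for o in order}
    ids = baseline["id"].to_numpy(int)
    alive = np.ones(n, dtype=bool)
    static = {
        "is_male": baseline["is_male"].to_numpy(bool),
        "smoker": baseline["smoker"].to_numpy(bool),
        "on_statin": baseline["on_statin"].to_numpy(bool),
        "on_antihypertensive": baseline["on_antihypertensive"].to_numpy(bool),
        "imd_quintile": baseline["imd_quintile"].to_numpy(float),
    }
    duration0 = baseline["diabetes_duration"].to_numpy(float)

    for year in range(1, n_years + 1):
        start = year - 1
        at_risk = alive & (trajectories["age"][:, start] < max_age)
        if not at_risk.any():
            break
        covariates = {
            "age": trajectories["age"][:, start],
            "hba1c": trajectories["hba1c"][:, start],
            "bmi": trajectories["bmi"][:, start],
            "sbp": trajectories["sbp"][:, start],
            "chol_hdl_ratio": trajectories["chol_hdl_ratio"][:, start],
            "duration": duration0 + start,
            **static,
        }
        for o in order:
            covariates[f"history_{o}"] = (~np.isnan(event_year[o])).astype(float)
        for idx, o in enumerate(order):
            candidates = at_risk & np.isnan(event_year[o])
            if not candidates.any():
                continue
            p = annual_probability(equations[o], covariates)
            u = _uniforms(seed, year, idx, ids)
            hit = candidates & (u < p)
            event_year[o][hit] = year
        # events drawn earlier in the cycle than death stand; later cycles
        # are blocked for the dead via `at_risk`
        alive &= np.isnan(event_year["death"])

    out = pd.DataFrame({f"{o}_year": event_year[o] for o in order})
    out.insert(0, "id", baseline["id"].to_numpy())
    out["death_year"] = event_year["death"]
    out["alive"] = np.isnan(event_year["death"])
    out["age_at_death"] = np.where(
        out["alive"], np.nan, baseline["age"].to_numpy(float) + event_year["death"]
    )
    return out


def simulate_person(
    person: Mapping,
    equations: Mapping[str, RiskEquation],
    trajectories: Mapping[str, np.ndarray],
    max_age: float = 100.0,
    seed: int = 0,
) -> pd.Series:
    """Single-person wrapper around :func:`simulate_cohort`."""
    row = pd.DataFrame([dict(person)])
    return simulate_cohort(row, equations, trajectories, seed=seed, max_age=max_age).iloc[0]


def cumulative_incidence(
    eq: RiskEquation,
    baseline: pd.DataFrame,
    trajectories: Mapping[str, np.ndarray],
    horizon: int,
    seed: int,
    multiplier: float | None = None,
) -> float:
    """Fraction of the cohort with a first event within ``horizon`` years.

    Simulates the single outcome in isolation (no competing mortality) with
    a fixed uniform stream, so the incidence is monotone non-decreasing in
    the calibration multiplier — the property the bisection relies on.
    """
    eq_run = RiskEquation(
        outcome=eq.outcome,
        form=eq.form,
        coefficients=dict(eq.coefficients),
        calibration_multiplier=multiplier if multiplier is not None else eq.calibration_multiplier,
        treatment_rr=dict(eq.treatment_rr),
    )
    n = len(baseline)
    ids = baseline["id"].to_numpy(int)
    event = np.zeros(n, dtype=bool)
    static = {
        "is_male": baseline["is_male"].to_numpy(bool),
        "smoker": baseline["smoker"].to_numpy(bool),
        "on_statin": baseline["on_statin"].to_numpy(bool),
        "on_antihypertensive": baseline["on_antihypertensive"].to_numpy(bool),
        "imd_quintile": baseline["imd_quintile"].to_numpy(float),
    }
    duration0 = baseline["diabetes_duration"].to_numpy(float)
    for year in range(1, horizon + 1):
        start = year - 1
        covariates = {
            "age": trajectories["age"][:, start],
            "hba1c": trajectories["hba1c"][:, start],
            "bmi": trajectories["bmi"][:, start],
            "sbp": trajectories["sbp"][:, start],
            "chol_hdl_ratio": trajectories["chol_hdl_ratio"][:, start],
            "duration": duration0 + start,
            **static,
            **{f"history_{o}": np.zeros(n) for o in OUTCOMES},
        }
        p = annual_probability(eq_run, covariates)
        u = _uniforms(seed, year, 0, ids)
        event |= ~event & (u < p)
    return float(event.mean())


def calibrate(
    eq: RiskEquation,
    cohort: pd.DataFrame,
    target_cum_incidence: float,
    horizon: int,
    tol: float = 2e-3,
    natural_drift: Mapping[str, float] | None = None,
    seed: int = 0,
    max_iter: int = 100,
) -> float:
    """Bisect the calibration multiplier to hit a target cumulative incidence.

    Uses common random numbers across iterations so incidence is monotone in
    the multiplier. The tolerance should respect the Monte-Carlo
    granularity (one event is ``1/len(cohort)``). Raises
    :class:`CalibrationError` if the target is unreachable within
    ``CALIBRATION_BOUNDS``.
    """
    if not 0.0 < target_cum_incidence < 1.0:
        raise CalibrationError("target cumulative incidence must lie in (0, 1)")
    if len(cohort) == 0:
        raise ConfigurationError("calibration cohort is empty")
    drift = natural_drift or {v: 0.0 for v in ("hba1c", "bmi", "sbp", "chol_hdl_ratio")}
    traj = simulate_trajectories(cohort, drift, null_profile(), ARM_CONTROL, horizon)

    def inc(mult: float) -> float:
        return cumulative_incidence(eq, cohort, traj, horizon, seed, multiplier=mult)

    lo, hi = CALIBRATION_BOUNDS
    inc_lo, inc_hi = inc(lo), inc(hi)
    if not inc_lo - tol <= target_cum_incidence <= inc_hi + tol:
        raise CalibrationError(
            f"target {target_cum_incidence:.4g} unreachable within multiplier "
            f"bounds {CALIBRATION_BOUNDS} (incidence range "
            f"[{inc_lo:.4g}, {inc_hi:.4g}])"
        )
    best_mult, best_gap = None, np.inf
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric midpoint: multipliers act on log scale
        val = inc(mid)
        gap = abs(val - target_cum_incidence)
        if gap < best_gap:
            best_mult, best_gap = mid, gap
        if gap <= tol:
            return float(mid)
        if val < target_cum_incidence:
            lo = mid
        else:
            hi = mid
    if best_gap <= tol:
        return float(best_mult)
    raise CalibrationError(
        f"bisection did not reach target within tol={tol} "
        f"(closest incidence gap {best_gap:.4g}); consider a larger cohort or tol"
    )
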