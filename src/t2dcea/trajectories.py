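"""Annual risk-factor trajectories with decaying intervention effects.

Both study arms share a common natural trajectory for each metabolic risk
factor (linear annual drift from the individual baseline). The intervention
arm additionally carries a time-varying offset for HbA1c and BMI: the full
trial effect at the end of year 1, declining to exactly zero at the
variable-specific horizon (5 years for HbA1c, 10 years for BMI by default)
and zero thereafter. The decay shape is linear by default; an
exponential-to-zero alternative is available, truncated to zero at the
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

ARM_INTERVENTION = "DEW"
ARM_CONTROL = "DE"

#: Risk factors a drift configuration must cover.
DRIFT_VARIABLES = ("hba1c", "bmi", "sbp", "chol_hdl_ratio")

_EFFECT_VARIABLES = ("hba1c", "bmi")


@dataclass(frozen=True)
class InterventionEffectProfile:
    """Arm-level effects on HbA1c and BMI with finite decay horizons.

    Effects are arm differences (intervention minus control) at 12 months,
    so a beneficial effect is negative. Horizons are in years from model
    entry; the effect is exactly zero at and beyond the horizon.
    """

    hba1c_effect_12m: float  # mmol/mol
    bmi_effect_12m: float  # kg/m2
    hba1c_decay_horizon: float = 5.0
    bmi_decay_horizon: float = 10.0
    shape: str = "linear"  # "linear" | "exponential"

    def __post_init__(self) -> None:
        for name in ("hba1c_decay_horizon", "bmi_decay_horizon"):
            if getattr(self, name) <= 1.0:
                raise ConfigurationError(
                    f"{name} must exceed 1 year (the effect onset), got "
                    f"{getattr(self, name)}"
                )
        if self.shape not in ("linear", "exponential"):
            raise ConfigurationError(f"unknown decay shape: {self.shape!r}")

    @classmethod
    def from_weight_effect(
        cls,
        hba1c_effect_12m: float,
        weight_effect_12m_kg: float,
        mean_height_m: float,
        **kwargs,
    ) -> "InterventionEffectProfile":
        """Build a profile from a weight effect in kg via a mean height."""
        if mean_height_m <= 0:
            raise ConfigurationError("mean height must be positive")
        return cls(
            hba1c_effect_12m=hba1c_effect_12m,
            bmi_effect_12m=weight_effect_12m_kg / mean_height_m**2,
            **kwargs,
        )

    def effect_at(self, variable: str, t) -> np.ndarray | float:
        """Arm effect for ``variable`` at time ``t`` years after entry.

        Ramps linearly from zero at entry to the full 12-month effect at
        t=1, then decays to zero at the variable's horizon. Accepts scalars
        or arrays.
        """
        if variable not in _EFFECT_VARIABLES:
            raise ConfigurationError(
                f"unknown effect variable {variable!r}; expected one of "
                f"{_EFFECT_VARIABLES}"
            )
        full = getattr(self, f"{variable}_effect_12m")
        horizon = getattr(self, f"{variable}_decay_horizon")
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        ramp = np.clip(t, 0.0, 1.0)
        if self.shape == "linear":
            decay = np.clip((horizon - t) / (horizon - 1.0), 0.0, 1.0)
        else:
            # exponential-to-zero: rate set so the effect has fallen to ~5%
            # of full just before the horizon, then hard zero at the horizon
            rate = 3.0 / (horizon - 1.0)
            decay = np.where(t < horizon, np.exp(-rate * np.clip(t - 1.0, 0.0, None)), 0.0)
        frac = np.where(t <= 1.0, ramp, decay)
        out = full * frac
        return float(out) if out.ndim == 0 else out


def null_profile() -> InterventionEffectProfile:
    """A profile with zero effects (both arms identical)."""
    return InterventionEffectProfile(0.0, 0.0)


@dataclass
class TrajectoryState:
    """Current risk-factor state of one person (or a vectorised cohort)."""

    hba1c: np.ndarray | float
    bmi: np.ndarray | float
    sbp: np.ndarray | float
    chol_hdl_ratio: np.ndarray | float
    smoker: np.ndarray | bool
    age: np.ndarray | float
    year: int = 0
    arm: str = ARM_CONTROL
    profile: InterventionEffectProfile = field(default_factory=null_profile)


def advance_year(
    state: TrajectoryState,
    natural_drift: Mapping[str, float],
    profile: InterventionEffectProfile | None = None,
    arm: str | None = None,
) -> TrajectoryState:
    """Advance a trajectory state by one annual cycle.

    The configured drift applies to the common (no-effect) trajectory; the
    arm's decayed effect is then re-applied as an offset, so the two arms
    share a common path and differ only by ``effect_at``. Deterministic.
    """
    missing = [v for v in DRIFT_VARIABLES if v not in natural_drift]
    if missing:
        raise ConfigurationError(f"drift configuration missing variables: {missing}")
    profile = profile if profile is not None else state.profile
    arm = arm if arm is not None else state.arm
    t0, t1 = state.year, state.year + 1
    apply_effect = arm == ARM_INTERVENTION

    new_values: dict[str, np.ndarray | float] = {}
    for var in DRIFT_VARIABLES:
        value = getattr(state, var)
        if apply_effect and var in _EFFECT_VARIABLES:
            value = value - profile.effect_at(var, t0) + profile.effect_at(var, t1)
        new_values[var] = value + natural_drift[var]
    return replace(
        state,
        **new_values,
        age=state.age + 1,
        year=t1,
        arm=arm,
        profile=profile,
    )


def simulate_trajectories(
    baseline: pd.DataFrame,
    natural_drift: Mapping[str, float],
    profile: InterventionEffectProfile,
    arm: str,
    n_years: int,
) -> dict[str, np.ndarray]:
    """Closed-form trajectories for a baseline cohort over ``n_years`` cycles.

    Returns arrays of shape ``(n_persons, n_years + 1)`` for each drifting
    variable plus ``age``; column ``t`` is the state at the start of year
    ``t``. Equivalent to iterating :func:`advance_year`.
    """
    missing = [v for v in DRIFT_VARIABLES if v not in natural_drift]
    if missing:
        raise ConfigurationError(f"drift configuration missing variables: {missing}")
    n = len(baseline)
    t = np.arange(n_years + 1, dtype=float)
    apply_effect = arm == ARM_INTERVENTION

    base0 = {
        "hba1c": baseline["hba1c"].to_numpy(float),
        "bmi": baseline["bmi"].to_numpy(float),
        "sbp": baseline["sbp"].to_numpy(float),
        "chol_hdl_ratio": (
            baseline["total_chol"].to_numpy(float) / baseline["hdl"].to_numpy(float)
        ),
    }
    out: dict[str, np.ndarray] = {}
    for var in DRIFT_VARIABLES:
        path = base0[var][:, None] + natural_drift[var] * t[None, :]
        if apply_effect and var in _EFFECT_VARIABLES:
            path = path + np.asarray(profile.effect_at(var, t))[None, :]
        out[var] = path
    # physiological floors; the drift model is linear and unbounded otherwise
    out["hba1c"] = np.maximum(out["hba1c"], 20.0)
    out["bmi"] = np.maximum(out["bmi"], 10.0)
    out["age"] = baseline["age"].to_numpy(float)[:, None] + t[None, :]
    return out
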