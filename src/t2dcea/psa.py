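"""Probabilistic sensitivity analysis and subgroup scenario runs.

Parameter uncertainty is propagated by sampling each uncertain parameter
from a distribution matched to its support (normal for effect sizes, gamma
for costs, beta for probabilities/decrements, lognormal for relative risks)
and re-running both arms of the lifetime model per draw. The population and
the event uniform stream are held fixed across arms and draws (common
random numbers), so between-draw variation isolates parameter uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .econ import CEAResult, summarize
from .errors import ConfigurationError
from .model import LifetimeRun, run_lifetime
from .trajectories import ARM_CONTROL, ARM_INTERVENTION
from .utils import with_overrides
from .within_trial import incremental_nmb

_FAMILIES = ("normal", "lognormal", "beta", "gamma")


@dataclass(frozen=True)
class ParameterDistribution:
    """Mean/SD-parameterised sampling distribution for one model parameter."""

    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family: {self.family!r}")
        if self.sd < 0:
            raise ConfigurationError("distribution SD must be non-negative")
        if self.sd > 0:
            if self.family == "gamma" and self.mean <= 0:
                raise ConfigurationError("gamma distribution requires a positive mean")
            if self.family == "lognormal" and self.mean <= 0:
                raise ConfigurationError("lognormal distribution requires a positive mean")
            if self.family == "beta":
                m = abs(self.mean)
                if not 0.0 < m < 1.0:
                    raise ConfigurationError("beta distribution requires |mean| in (0, 1)")
                if self.sd**2 >= m * (1.0 - m):
                    raise ConfigurationError("beta distribution SD too large for its mean")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        if self.family == "normal":
            return float(rng.normal(self.mean, self.sd))
        if self.family == "gamma":
            shape = (self.mean / self.sd) ** 2
            return float(rng.gamma(shape, self.sd**2 / self.mean))
        if self.family == "lognormal":
            sigma2 = np.log1p((self.sd / self.mean) ** 2)
            mu = np.log(self.mean) - sigma2 / 2.0
            return float(rng.lognormal(mu, np.sqrt(sigma2)))
        # beta; negative means (signed decrements) sample on |mean| and re-sign
        sign = -1.0 if self.mean < 0 else 1.0
        m = abs(self.mean)
        nu = m * (1.0 - m) / self.sd**2 - 1.0
        return float(sign * rng.beta(m * nu, (1.0 - m) * nu))


@dataclass
class PSASpec:
    """Sampling plan for the probabilistic sensitivity analysis."""

    n_samples: int = 2000
    distributions: dict[str, ParameterDistribution] = field(default_factory=dict)
    seed: int = 0
    thresholds: tuple[float, ...] = (13_000.0, 20_000.0, 30_000.0)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be at least 1")

    @classmethod
    def from_config(cls, cfg: Mapping, n_samples: int | None = None, seed: int | None = None) -> "PSASpec":
        dists = {
            path: ParameterDistribution(d["family"], float(d["mean"]), float(d["sd"]))
            for path, d in cfg.get("distributions", {}).items()
        }
        return cls(
            n_samples=int(n_samples if n_samples is not None else cfg.get("n_samples", 2000)),
            distributions=dists,
            seed=int(seed if seed is not None else cfg.get("seed", 0)),
            thresholds=tuple(float(t) for t in cfg.get("thresholds", (13_000.0, 20_000.0, 30_000.0))),
        )


def run_psa(
    spec: PSASpec,
    model_config: Mapping,
    population: pd.DataFrame,
    sim_seed: int | None = None,
) -> pd.DataFrame:
    """Per-draw incremental costs and QALYs of the lifetime model.

    All distributions are validated up front (before any simulation). Each
    draw samples one value per uncertain parameter, applies it to a copy of
    the configuration by dotted path, and re-runs both arms on the shared
    ``population`` with a fixed simulation seed.
    """
    for path, dist in spec.distributions.items():
        if not isinstance(dist, ParameterDistribution):
            raise ConfigurationError(f"invalid distribution for {path!r}")
    rng = np.random.default_rng(spec.seed)
    sim_seed = int(sim_seed if sim_seed is not None else model_config.get("seed", 0))

    records = []
    for draw in range(spec.n_samples):
        overrides = {path: dist.sample(rng) for path, dist in spec.distributions.items()}
        cfg_i = with_overrides(model_config, overrides)
        run = run_lifetime(cfg_i, population=population, seed=sim_seed)
        records.append(
            {"draw": draw, "delta_cost": run.result.delta_cost, "delta_qaly": run.result.delta_qaly}
        )
    return pd.DataFrame(records)


def probability_cost_effective(draws: pd.DataFrame, threshold: float) -> float:
    """Fraction of draws with positive incremental NMB at ``threshold``."""
    if len(draws) == 0:
        raise ConfigurationError("need at least one PSA draw")
    nmb = threshold * draws["delta_qaly"].to_numpy() - draws["delta_cost"].to_numpy()
    return float(np.mean(nmb > 0.0))


def expected_nmb_table(draws: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Expected incremental NMB and CEAC value per threshold."""
    rows = []
    for lam in thresholds:
        nmb = incremental_nmb(draws["delta_cost"].to_numpy(), draws["delta_qaly"].to_numpy(), lam)
        rows.append(
            {
                "threshold": float(lam),
                "expected_nmb": float(np.mean(nmb)),
                "probability_cost_effective": probability_cost_effective(draws, lam),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroups

BMI_BANDS = ((-np.inf, 28.0), (28.0, 30.0), (30.0, 35.0), (35.0, 40.0), (40.0, np.inf))


def _bmi_band_label(lo: float, hi: float) -> str:
    if np.isinf(lo):
        return "<28"
    if np.isinf(hi):
        return ">=40"
    return f"{lo:g}-{hi:g}"


def partition(population: pd.DataFrame, grouping: str) -> dict[str, pd.DataFrame]:
    """Partition a population by the stated subgroup cut-points.

    BMI bands are half-open ``[lower, upper)``; diabetes duration splits at
    1 year; IMD uses the five quintiles. The partition is exhaustive so
    stratum-weighted results recompose the whole-population run.
    """
    if grouping == "bmi_category":
        return {
            _bmi_band_label(lo, hi): population[(population["bmi"] >= lo) & (population["bmi"] < hi)]
            for lo, hi in BMI_BANDS
        }
    if grouping == "diabetes_duration":
        under = population["diabetes_duration"] < 1.0
        return {"<1 year": population[under], "1-3 years": population[~under]}
    if grouping == "imd_quintile":
        return {f"IMD {q}": population[population["imd_quintile"] == q] for q in range(1, 6)}
    raise ConfigurationError(f"unknown grouping: {grouping!r}")


def subgroup_run(
    model_config: Mapping,
    population: pd.DataFrame,
    grouping: str,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full lifetime pipeline per subgroup stratum.

    Empty strata are reported as missing rows rather than raised.
    """
    rows = []
    for label, sub in partition(population, grouping).items():
        row: dict = {"grouping": grouping, "subgroup": label, "n": len(sub)}
        if len(sub) == 0:
            rows.append(row)
            continue
        run = run_lifetime(model_config, population=sub.reset_index(drop=True), seed=seed)
        rows.append({**row, **run.result.to_row()})
    return pd.DataFrame(rows)
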