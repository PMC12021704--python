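"""Trial design and descriptive statistics.

Covers the sample-size calculation for a baseline-adjusted continuous
outcome, simple categorical outcome summaries (proportions and unadjusted
risk ratios), and the pattern-mixture delta-adjustment used to probe
departures from the missing-at-random assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .utils import round_half_up


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs for a two-arm comparison of a continuous outcome.

    The analysis is assumed baseline-adjusted (ANCOVA-style), so the
    follow-up SD is deflated by sqrt(1 - r^2) where ``r`` is the
    baseline-to-follow-up correlation.
    """

    detectable_difference: float  # minimal clinically important difference
    sd_followup: float
    baseline_correlation: float
    power: float = 0.90
    alpha: float = 0.05  # two-sided
    attrition: float = 0.0

    def __post_init__(self) -> None:
        if self.detectable_difference == 0:
            raise ConfigurationError("detectable difference of zero implies infinite n")
        if self.sd_followup <= 0:
            raise ConfigurationError("follow-up SD must be positive")
        if not 0.0 <= self.baseline_correlation < 1.0:
            raise ConfigurationError(
                "baseline correlation must lie in [0, 1); r=1 gives zero adjusted variance"
            )
        if not 0.0 < self.power < 1.0 or not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("power and alpha must lie in (0, 1)")
        if not 0.0 <= self.attrition < 1.0:
            raise ConfigurationError("attrition must lie in [0, 1)")


def required_sample_size(spec: PowerSpec) -> int:
    """Total participants to randomise, inflated for attrition.

    Normal-approximation formula per group
    ``2 (z_{1-alpha/2} + z_power)^2 (sigma sqrt(1-r^2) / delta)^2``,
    rounded up; the randomised total is then divided by ``1 - attrition``
    and rounded up to an even integer so both arms can be equal.
    """
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    sigma_adj = spec.sd_followup * math.sqrt(1.0 - spec.baseline_correlation**2)
    per_group = 2.0 * (z_a + z_b) ** 2 * (sigma_adj / abs(spec.detectable_difference)) ** 2
    total = 2 * math.ceil(per_group)
    inflated = math.ceil(total / (1.0 - spec.attrition))
    return inflated + (inflated % 2)


def proportion(events: int, denom: int) -> float:
    """Percentage ``100 * events / denom`` rounded to one decimal."""
    if denom <= 0:
        raise ConfigurationError("denominator must be positive")
    if not 0 <= events <= denom:
        raise ConfigurationError("event count must lie in [0, denominator]")
    return round_half_up(100.0 * events / denom, 1)


@dataclass(frozen=True)
class RiskRatio:
    """Unadjusted risk ratio with a log-normal 95% CI."""

    rr: float
    ci_lower: float
    ci_upper: float
    ci_defined: bool

    def __iter__(self):
        return iter((self.rr, self.ci_lower, self.ci_upper))


def unadjusted_risk_ratio(e1: int, n1: int, e0: int, n0: int, level: float = 0.95) -> RiskRatio:
    """Risk ratio of arm 1 vs arm 0 from a 2x2 table of events/denominators.

    The CI uses the standard log-scale standard error
    ``sqrt(1/e1 - 1/n1 + 1/e0 - 1/n0)``; with zero events in either arm the
    point estimate is returned with the CI flagged undefined.
    """
    if min(n1, n0) <= 0 or e1 < 0 or e0 < 0 or e1 > n1 or e0 > n0:
        raise ConfigurationError("invalid 2x2 table counts")
    if e0 == 0:
        return RiskRatio(math.inf if e1 > 0 else math.nan, math.nan, math.nan, False)
    rr = (e1 / n1) / (e0 / n0)
    if e1 == 0:
        return RiskRatio(0.0, math.nan, math.nan, False)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1.0 / e1 - 1.0 / n1 + 1.0 / e0 - 1.0 / n0)
    return RiskRatio(rr, rr * math.exp(-z * se), rr * math.exp(z * se), True)


def delta_adjust(values, imputed, factor: float) -> np.ndarray:
    """Pattern-mixture delta adjustment of imputed values.

    Every value flagged in ``imputed`` is multiplied by ``1 + factor/100``
    (``factor`` a signed percentage, e.g. -30 ... +30); observed values are
    returned untouched. ``factor=0`` corresponds to the MAR analysis.
    """
    values = np.asarray(values, dtype=float)
    imputed = np.asarray(imputed, dtype=bool)
    if values.shape != imputed.shape:
        raise ConfigurationError("values and imputed flags must align")
    return np.where(imputed, values * (1.0 + factor / 100.0), values)
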