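"""Per-participant programme costs under delivery-mix scenarios.

The intervention programme cost is a commercial price plus VAT; the
comparator structured-education programme is a weighted average of
face-to-face and online delivery costs, with the face-to-face share and the
component prices varying across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .utils import round_half_up

#: UK standard VAT rate.
DEFAULT_VAT_RATE = 0.20


@dataclass(frozen=True)
class CostScenario:
    """One delivery-mix costing scenario for a group-education programme."""

    name: str
    f2f_cost: float  # GBP per person, face-to-face delivery
    online_cost: float  # GBP per person, online delivery
    f2f_share: float  # proportion delivered face-to-face
    vat_rate: float = DEFAULT_VAT_RATE

    def __post_init__(self) -> None:
        if not 0.0 <= self.f2f_share <= 1.0:
            raise ConfigurationError("f2f_share must be a proportion")
        if self.f2f_cost < 0 or self.online_cost < 0:
            raise ConfigurationError("component costs must be non-negative")


def cost_with_vat(base: float, vat_rate: float = DEFAULT_VAT_RATE) -> int:
    """Add VAT to a net price and round to the nearest pound."""
    if base < 0 or vat_rate < 0:
        raise ConfigurationError("cost and VAT rate must be non-negative")
    return int(round_half_up(base * (1.0 + vat_rate)))


def weighted_programme_cost(scenario: CostScenario) -> int:
    """Delivery-mix weighted per-person cost, rounded to the nearest pound."""
    exact = scenario.f2f_share * scenario.f2f_cost + (1.0 - scenario.f2f_share) * scenario.online_cost
    return int(round_half_up(exact))


def scenario_table(scenarios: list[CostScenario]) -> pd.DataFrame:
    """Per-scenario cost summary (one row per scenario)."""
    return pd.DataFrame(
        {
            "scenario": [s.name for s in scenarios],
            "f2f_cost": [s.f2f_cost for s in scenarios],
            "online_cost": [s.online_cost for s in scenarios],
            "f2f_share": [s.f2f_share for s in scenarios],
            "per_person_cost": [weighted_programme_cost(s) for s in scenarios],
        }
    )
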