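#!/usr/bin/env python
"""Intervention costing stage: per-participant programme costs by scenario.

The DEW programme cost is the commercial price plus VAT; the comparator
structured-education cost is a face-to-face/online weighted average under
current-care, single-mode and optimistic-uptake scenarios.
"""

from pathlib import Path

from t2dcea.costing import CostScenario, cost_with_vat, scenario_table
from t2dcea.model import load_config

OUT = Path(__file__).resolve().parent.parent / "results" / "costing"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    c = load_config()["costing"]

    dew = cost_with_vat(c["dew_base_cost"], c["vat_rate"])
    print(f"DEW programme per participant: £{dew} (£{c['dew_base_cost']:.0f} + VAT)")

    scenarios = [
        CostScenario("Mixed F2F and online", c["de_f2f_cost"], c["de_online_cost"], c["f2f_share"]),
        CostScenario("F2F only", c["de_f2f_cost"], c["de_online_cost"], 1.0),
        CostScenario("Online only", c["de_f2f_cost"], c["de_online_cost"], 0.0),
        CostScenario(
            "Optimistic uptake, full F2F capacity",
            c["optimistic_f2f_cost"],
            c["optimistic_online_cost"],
            c["f2f_share"],
        ),
    ]
    table = scenario_table(scenarios)
    table.to_csv(OUT / "programme_costs.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
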