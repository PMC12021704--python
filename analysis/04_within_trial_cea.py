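#!/usr/bin/env python
"""Within-trial cost-utility analysis on the synthetic trial dataset.

Twelve-month costs (healthcare use plus programme cost) and QALYs (utility
AUC) per arm, incremental NMB at the three reference thresholds, cost per
mmol/mol HbA1c and per kg weight, and a bootstrap CEAC. Also illustrates
the pattern-mixture delta adjustment on mean-imputed 12-month HbA1c.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from t2dcea.cohort import CohortSpec, generate_trial
from t2dcea.design import delta_adjust
from t2dcea.model import build_profile, load_config
from t2dcea.utils import stage_seed
from t2dcea.within_trial import analyze_within_trial

SEED = 20260930
OUT = Path(__file__).resolve().parent.parent / "results" / "within_trial"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = load_config()
    trial = generate_trial(
        CohortSpec.from_config(cfg["cohort"], n=577, seed=stage_seed(SEED, "trial")),
        build_profile(cfg),
        attrition_rate=float(cfg["trial"]["attrition"]),
        seed=stage_seed(SEED, "trial-outcomes"),
        options=cfg["trial"],
    )

    res = analyze_within_trial(
        trial,
        intervention_costs={k: float(v) for k, v in cfg["intervention_costs"].items()},
        thresholds=[float(t) for t in cfg["thresholds"]],
        seed=stage_seed(SEED, "bootstrap"),
    )
    report = res.to_frame()
    report.to_csv(OUT / "within_trial_report.csv", index=False)
    res.bootstrap_draws.to_csv(OUT / "bootstrap_draws.csv", index=False)
    print(report.to_string(index=False))

    # delta adjustment of mean-imputed missing 12-month HbA1c (MNAR probe)
    values = trial["hba1c_12"].to_numpy(float)
    imputed = np.isnan(values)
    values = np.where(imputed, np.nanmean(values), values)
    rows = []
    for factor in (-30, -20, -10, 0, 10, 20, 30):
        adjusted = delta_adjust(values, imputed, factor)
        diff = pd.Series(adjusted).groupby(trial["arm"]).mean()
        rows.append({"factor_pct": factor, "arm_difference_mmol_mol": diff["DEW"] - diff["DE"]})
    sens = pd.DataFrame(rows)
    sens.to_csv(OUT / "delta_adjustment.csv", index=False)
    print("\npattern-mixture sensitivity of the 12-month HbA1c arm difference:")
    print(sens.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
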