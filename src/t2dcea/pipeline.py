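"""End-to-end orchestration: seeded runs from config to report bundle.

One global seed fans out to per-stage child seeds through
:func:`t2dcea.utils.stage_seed` (a SHA-256 hash of ``"<seed>:<stage>"``), so
any stage can be re-run in isolation and reproduce exactly. Every output
table carries comment-header metadata (seed, config digest, package
version) and a machine-readable manifest records the full provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_population, generate_trial
from .costing import CostScenario, cost_with_vat, scenario_table
from .model import build_profile, load_config, run_lifetime, scenario_report
from .psa import PSASpec, expected_nmb_table, run_psa, subgroup_run
from .trajectories import ARM_CONTROL, ARM_INTERVENTION
from .utils import config_digest, stage_seed
from .within_trial import analyze_within_trial

log = logging.getLogger("t2dcea")


def _write_table(df: pd.DataFrame, path: Path, seed: int, digest: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# t2dcea v{__version__} seed={seed} config_digest={digest}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: str | Path | Mapping | None,
    out_dir: str | Path,
    seed: int | None = None,
    n_population: int | None = None,
    n_psa: int | None = None,
) -> dict[str, Path]:
    """Run the full analysis chain and write the report bundle.

    Stages: synthetic cohort -> synthetic trial -> within-trial CEA ->
    lifetime microsimulation (delivery-mix scenario table) -> PSA (CEAC and
    expected NMB) -> run manifest. Returns the paths written, keyed by
    stage. ``n_population``/``n_psa`` override config sizes for desk-scale
    runs.
    """
    cfg = load_config(config) if config is None or isinstance(config, (str, Path)) else dict(config)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    digest = config_digest(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name: str) -> int:
        child = stage_seed(seed, name)
        log.info("stage %s (child seed %d)", name, child)
        return child

    # synthetic cohort for the lifetime model
    n_pop = int(n_population if n_population is not None else cfg.get("lifetime_n", cfg["cohort"]["n"]))
    pop_spec = CohortSpec.from_config(cfg["cohort"], n=n_pop, seed=stage("population"))
    population = generate_population(pop_spec)
    paths["population"] = out / "population.csv"
    _write_table(population, paths["population"], seed, digest)

    # synthetic trial and within-trial CEA
    profile = build_profile(cfg)
    trial_spec = CohortSpec.from_config(cfg["cohort"], n=int(cfg["trial"]["n"]), seed=stage("trial"))
    trial = generate_trial(
        trial_spec,
        profile,
        attrition_rate=float(cfg["trial"]["attrition"]),
        seed=stage("trial-outcomes"),
        options=cfg["trial"],
    )
    paths["trial"] = out / "trial.csv"
    _write_table(trial, paths["trial"], seed, digest)

    thresholds = [float(t) for t in cfg.get("thresholds", [20_000.0])]
    wt = analyze_within_trial(
        trial,
        intervention_costs={k: float(v) for k, v in cfg["intervention_costs"].items()},
        thresholds=thresholds,
        seed=stage("within-trial-bootstrap"),
    )
    paths["within_trial"] = out / "within_trial_report.csv"
    _write_table(wt.to_frame(), paths["within_trial"], seed, digest)

    # programme-costing scenario table
    ccfg = cfg["costing"]
    scenarios = [
        CostScenario("F2F only", ccfg["de_f2f_cost"], ccfg["de_online_cost"], 1.0),
        CostScenario("Online only", ccfg["de_f2f_cost"], ccfg["de_online_cost"], 0.0),
        CostScenario("Mixed delivery", ccfg["de_f2f_cost"], ccfg["de_online_cost"], ccfg["f2f_share"]),
        CostScenario(
            "Optimistic uptake", ccfg["optimistic_f2f_cost"], ccfg["optimistic_online_cost"], ccfg["f2f_share"]
        ),
    ]
    cost_df = scenario_table(scenarios)
    cost_df.loc[len(cost_df)] = {
        "scenario": "DEW programme (price + VAT)",
        "f2f_cost": ccfg["dew_base_cost"],
        "online_cost": ccfg["dew_base_cost"],
        "f2f_share": 1.0,
        "per_person_cost": cost_with_vat(ccfg["dew_base_cost"], ccfg["vat_rate"]),
    }
    paths["costing"] = out / "programme_costs.csv"
    _write_table(cost_df, paths["costing"], seed, digest)

    # lifetime model and scenario accounting
    run = run_lifetime(cfg, population=population, seed=seed)
    lifetime_df = scenario_report(run, cfg)
    paths["lifetime"] = out / "lifetime_report.csv"
    _write_table(lifetime_df, paths["lifetime"], seed, digest)

    # probabilistic sensitivity analysis
    psa_spec = PSASpec.from_config(cfg.get("psa", {}), n_samples=n_psa, seed=stage("psa"))
    draws = run_psa(psa_spec, cfg, population, sim_seed=seed)
    paths["psa_draws"] = out / "psa_draws.csv"
    _write_table(draws, paths["psa_draws"], seed, digest)
    paths["ceac"] = out / "ceac.csv"
    _write_table(expected_nmb_table(draws, psa_spec.thresholds), paths["ceac"], seed, digest)

    manifest = {
        "package": "t2dcea",
        "version": __version__,
        "seed": seed,
        "config_digest": digest,
        "n_population": n_pop,
        "n_trial": int(cfg["trial"]["n"]),
        "n_psa_samples": psa_spec.n_samples,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def run_subgroups(
    config: str | Path | Mapping | None,
    out_dir: str | Path,
    seed: int | None = None,
    n_population: int | None = None,
    groupings=("diabetes_duration", "bmi_category", "imd_quintile"),
) -> Path:
    """Subgroup lifetime analyses written as one stacked table."""
    cfg = load_config(config) if config is None or isinstance(config, (str, Path)) else dict(config)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    n_pop = int(n_population if n_population is not None else cfg.get("lifetime_n", cfg["cohort"]["n"]))
    spec = CohortSpec.from_config(cfg["cohort"], n=n_pop, seed=stage_seed(seed, "population"))
    population = generate_population(spec)
    tables = [subgroup_run(cfg, population, g, seed=seed) for g in groupings]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "subgroups.csv"
    _write_table(pd.concat(tables, ignore_index=True), path, seed, config_digest(cfg))
    return path
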