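"""Config-driven orchestration: simulate -> preprocess -> fit -> compare ->
report.

A run is a pure file-to-file transform: a seeded config produces trial
CSVs, fit JSONs, pace tables, model-comparison summaries and a plain-text
log, deterministically. The single global seed is expanded into per-stage
seeds through a documented counter scheme (SeedSequence(seed, spawn_key=
(stage,))), so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import generalization as gen
from . import io as reaim_io
from . import mixture, pace, population, synthetic
from .circular import BinSpec, assign_rt_bins, cycle_median_rts, \
    exclude_outliers

__all__ = ["PipelineConfig", "run", "load_config", "stage_seed"]

logger = logging.getLogger("reaim")

EXPERIMENTS = ("exp1", "free", "forced2", "forced3", "exp4")

_STAGES = {"simulate": 0, "analyze": 1, "report": 2}


@dataclasses.dataclass
class PipelineConfig:
    experiment: str = "forced2"
    strategy: str = synthetic.MR
    n_subjects: int = 32
    seed: int = 0
    out_dir: str = "reaim_out"
    n_starts: int = 50
    rotation_deg: float = 90.0
    verbose: bool = False

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"config key 'experiment' must be one of {EXPERIMENTS}, "
                f"got {self.experiment!r}")
        if self.strategy not in (synthetic.MR, synthetic.RC):
            raise ValueError(
                f"config key 'strategy' must be MR or RC, got "
                f"{self.strategy!r}")
        if self.seed is None:
            raise ValueError("config key 'seed' is mandatory")


def load_config(path) -> PipelineConfig:
    """Read a flat YAML key-value config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "seed" not in raw:
        raise ValueError("config key 'seed' is mandatory")
    return PipelineConfig(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence(seed, spawn_key=(stage index,))."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _cohort_config(config: PipelineConfig) -> synthetic.CohortConfig:
    set_size = {"exp1": 12, "free": 4, "forced2": 12, "forced3": 2,
                "exp4": 2 if config.strategy == synthetic.RC else 8}
    params = synthetic.StrategyParams(strategy=config.strategy,
                                      solution_deg=config.rotation_deg)
    schedule = synthetic.ScheduleSpec(set_size=set_size[config.experiment])
    return synthetic.CohortConfig(
        n_subjects=config.n_subjects, schedule=schedule,
        strategy_params=params,
        seed=stage_seed(config.seed, "simulate"))


def simulate(config: PipelineConfig, out_dir: Path) -> Path:
    cohort = _cohort_config(config)
    sim = {
        "exp1": synthetic.simulate_exp1_cohort,
        "free": synthetic.simulate_free_cohort,
        "forced2": synthetic.simulate_forced_cohort,
        "forced3": synthetic.simulate_forced_cohort,
        "exp4": lambda c: synthetic.simulate_generalization_cohort(
            c, rotation_deg=45.0),
    }[config.experiment]
    trials = sim(cohort)
    path = out_dir / f"trials_{config.experiment}.csv"
    reaim_io.write_trials(trials, path)
    logger.info("simulate: %d trials -> %s (seed %d)",
                len(trials), path, cohort.seed)
    return path


def analyze(config: PipelineConfig, trials_path: Path, out_dir: Path) -> dict:
    trials = reaim_io.read_trials(trials_path)
    summary: dict = {"experiment": config.experiment,
                     "strategy": config.strategy}
    if config.experiment in ("forced2", "forced3"):
        summary.update(_analyze_forced(config, trials, out_dir))
    elif config.experiment == "free":
        summary.update(_analyze_free(trials, out_dir))
    elif config.experiment == "exp1":
        summary.update(_analyze_exp1(trials))
    else:
        summary.update(_analyze_exp4(config, trials))
    with open(out_dir / f"summary_{config.experiment}.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonify)
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _analyze_forced(config, trials, out_dir):
    binspec = BinSpec()
    trials = trials[trials["on_time"] & ~trials["is_catch"]].copy()
    trials, n_excluded = exclude_outliers(trials, by="rt")
    trials["rt_bin"] = assign_rt_bins(trials["rt_ms"], binspec)
    crit = pace.detect_critical_bin(trials, binspec)
    fit_cfg = mixture.FitConfig(
        n_starts=config.n_starts, seed=stage_seed(config.seed, "analyze"))
    fits = mixture.fit_all_bins(trials, binspec, fit_cfg)
    comparison = mixture.compare_models(fits[mixture.FREE_MU],
                                        fits[mixture.FIXED_MU])
    records = [f.to_record() for v in fits.values() for f in v]
    with open(out_dir / f"fits_{config.experiment}.json", "w") as fh:
        json.dump(records, fh, indent=2, default=_jsonify)
    paces = pace.estimate_pace_forced(
        trials, crit.first_nonrandom_bin if crit.defined
        else mixture.default_start_bin(binspec), binspec)
    _write_pace_table(paces, out_dir / f"paces_{config.experiment}.csv")
    defined = [p.pace_ms_per_deg for p in paces if p.defined]
    return {
        "n_rt_outliers_excluded": n_excluded,
        "critical_bin": crit.first_nonrandom_bin if crit.defined else None,
        "model_comparison": {k: v for k, v in comparison.items()
                             if k != "per_bin"},
        "mean_pace_ms_per_deg": float(np.mean(defined)) if defined else None,
        "n_paces_defined": len(defined),
    }


def _analyze_free(trials, out_dir):
    executions = synthetic.free_execution_trials(trials)
    paces = pace.estimate_pace_free(executions)
    _write_pace_table(paces, out_dir / "paces_free.csv")
    defined = [p.pace_ms_per_deg for p in paces if p.defined]
    acc = [p.extra["accuracy_slope"] for p in paces if p.defined and p.extra]
    return {"mean_pace_ms_per_deg": float(np.mean(defined)),
            "mean_accuracy_slope": float(np.mean(acc)),
            "n_paces_defined": len(defined)}


def _analyze_exp1(trials):
    out = {}
    rot = trials[trials["block"] == "rotation"]
    for (set_size, rotation), cell in rot.groupby(["set_size",
                                                   "rotation_deg"]):
        cycles = 2 if set_size == 2 else 12
        summary = cycle_median_rts(cell, cycles)
        out[f"{set_size}T_{int(rotation)}"] = {
            "early_rt_ms": float(summary["early_rt_ms"].mean()),
            "late_rt_ms": float(summary["late_rt_ms"].mean()),
        }
    return {"cells": out}


def _analyze_exp4(config, trials):
    set_size = int(trials["set_size"].iloc[0])
    training = synthetic.exp4_training_targets(set_size)
    train = trials[trials["block"] == "rotation"]
    retained, crit_table = gen.learning_criterion_filter(train, set_size)
    probes = trials[(trials["block"] == "generalization")
                    & (~trials["feedback"])
                    & trials["subject_id"].isin(retained)]
    results = gen.fit_generalization_regression(probes, training)
    betas = np.array([r.betas["distance"] for r in results])
    betas = betas[np.isfinite(betas)]
    return {"n_retained": len(retained),
            "n_excluded": int((~crit_table["retained"]).sum()),
            "mean_distance_beta": float(betas.mean()) if betas.size else None}


def _write_pace_table(paces, path):
    import pandas as pd

    pd.DataFrame([p.to_record() for p in paces]).to_csv(path, index=False)


def report(config: PipelineConfig, out_dir: Path) -> Path:
    """Model-level population-vector predictions alongside the run summary."""
    pop_cfg = population.PopulationConfig()
    t = np.linspace(0.0, 250.0, 101)
    mr_state = population.simulate_mr_population(pop_cfg, 2.5, t)
    rs_state = population.simulate_rs_population(
        pop_cfg, np.clip(t / 250.0, 0.0, 1.0), t)
    table = population.predict_speed_profiles(mr_state, rs_state)
    path = out_dir / "population_predictions.csv"
    table.to_csv(path, index=False)
    return path


def run(config: PipelineConfig) -> dict:
    """Full deterministic pipeline for one experiment/strategy setting."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if not config.verbose else logging.DEBUG)
    try:
        logger.info("run: %s", dataclasses.asdict(config))
        trials_path = simulate(config, out_dir)
        summary = analyze(config, trials_path, out_dir)
        report(config, out_dir)
        logger.info("done")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
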