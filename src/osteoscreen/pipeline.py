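"""Whole-pipeline orchestration: config, seed fan-out, staged execution.

One :class:`PipelineConfig` drives the full analysis: load (or
generate) the dataset, tune hyperparameters, select the architecture,
train the winning type as an ensemble on the full dataset, screen the
feasible combinations and score/rank them. Every stage writes its
artifacts into the run directory and a single master seed fans out
deterministically to all stage seeds, so a run is reproducible from
its config alone. The numbered drivers under ``analysis/`` expose the
stages individually.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .datasets import (FACTOR_NAMES, OUTCOME_NAMES, Dataset, fit_scaling,
                       load_dataset, save_dataset)
from .efficacy import (EfficacyConfig, efficacy_scores, pairwise_correlations,
                       rank_combinations, top_bottom_tables)
from .networks import NetworkSpec, candidate_network_specs
from .screening import (build_screen_grid, embed_combinations,
                        enumerate_combinations, predict_ensemble)
from .training import (DEFAULT_BATCH_GRID, DEFAULT_LR_GRID, SplitPlan,
                       TrainConfig, _derive_seeds, select_architecture,
                       selection_table, train_ensemble, tune_hyperparameters)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    ``profile`` picks the scale: "paper" runs the full protocol
    (50,000 presentations, 10 repeats, 10-member ensemble, 175/50
    splits over all 16 types); "test" is a desk-scale profile on the
    same code paths.
    """

    dataset_path: str | None = None          # None -> synthetic
    synthetic_patterns: int = 225
    profile: str = "test"
    master_seed: int = 0
    outdir: str = "results/run"
    # stage scales (filled from the profile unless overridden)
    iterations: int | None = None
    n_repeats: int | None = None
    ensemble_size: int | None = None
    candidate_depths: tuple[int, ...] | None = None
    tune_architecture: str = "ff2+ae"
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID
    batch_grid: tuple[int, ...] = DEFAULT_BATCH_GRID
    top_k: int = 200
    skip_tuning: bool = False
    learning_rate: float = 1.0
    batch_size: int = 4

    PROFILES = {
        "paper": dict(iterations=50_000, n_repeats=10, ensemble_size=10,
                      candidate_depths=(0, 1, 2, 3, 5, 7, 10)),
        "test": dict(iterations=5_000, n_repeats=2, ensemble_size=3,
                     candidate_depths=(0, 2)),
    }

    def __post_init__(self) -> None:
        if self.profile not in self.PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        for key, value in self.PROFILES[self.profile].items():
            if getattr(self, key) is None:
                setattr(self, key, value)
        if self.master_seed is None:
            raise ValueError("master_seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("lr_grid", "batch_grid", "candidate_depths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for key in ("lr_grid", "batch_grid", "candidate_depths"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def split_plan_for(config: PipelineConfig, n: int) -> SplitPlan:
    """175/50 splits at full scale, proportional splits otherwise."""
    if n >= 225:
        n_train, n_test = 175, 50
    else:
        n_test = max(1, round(n * 50 / 225))
        n_train = n - n_test
    return SplitPlan(n_train, n_test, config.n_repeats, seed=0)


def _stage(log: list, name: str):
    logger.info("stage: %s", name)
    log.append({"stage": name, "time": time.time()})


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the self-describing run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    seeds = _derive_seeds(config.master_seed, 4, tag=100)
    log: list[dict] = []
    summary: dict = {"master_seed": config.master_seed,
                     "stage_seeds": seeds, "profile": config.profile}
    try:
        _stage(log, "load")
        if config.dataset_path:
            ds = load_dataset(config.dataset_path)
        else:
            spec = synthetic.default_spec(config.synthetic_patterns,
                                          seed=seeds[0])
            ds = synthetic.generate_dataset(spec)
            (outdir / "synthetic_spec.json").write_text(
                json.dumps(spec.to_dict(), indent=1))
        save_dataset(ds, outdir / "dataset.csv")
        summary["n_patterns"] = ds.n_patterns
        plan = split_plan_for(config, ds.n_patterns)

        winner_spec = _parse_architecture(config.tune_architecture)
        _stage(log, "tune")
        if config.skip_tuning:
            cfg = TrainConfig(config.learning_rate, config.batch_size,
                              config.iterations)
        else:
            cfg, tune_report = tune_hyperparameters(
                winner_spec, config.lr_grid, config.batch_grid, ds,
                SplitPlan(plan.n_train, plan.n_test, plan.n_repeats,
                          seed=seeds[1]),
                iterations=config.iterations)
            tune_report.to_csv(outdir / "tuning.csv", index=False)
        summary["train_config"] = {"learning_rate": cfg.learning_rate,
                                   "batch_size": cfg.batch_size,
                                   "iterations": cfg.iterations}

        _stage(log, "select")
        candidates = []
        for ae in (None, 50):
            for depth in config.candidate_depths:
                candidates.append(
                    (NetworkSpec("feedforward", depth, autoencoder_units=ae),
                     cfg))
        reports = select_architecture(
            candidates, ds,
            SplitPlan(plan.n_train, plan.n_test, plan.n_repeats,
                      seed=seeds[2]))
        table = selection_table(reports)
        table.to_csv(outdir / "selection.csv", index=False)
        best_spec = reports[0].spec
        summary["selected_network"] = best_spec.label
        summary["selection_mean_rms"] = reports[0].mean

        _stage(log, "train-ensemble")
        ensemble = train_ensemble(best_spec, cfg, ds,
                                  config.ensemble_size, master_seed=seeds[3])

        _stage(log, "screen")
        grid = build_screen_grid()
        combos = enumerate_combinations(grid)
        X = embed_combinations(combos, ds.factor_names)
        scaled_mean, unscaled_mean = predict_ensemble(
            ensemble.members, X, ensemble.scaling)
        preds = pd.concat(
            [combos,
             pd.DataFrame(unscaled_mean, columns=list(ds.outcome_names))],
            axis=1)
        preds.to_csv(outdir / "screen_predictions.csv", index=False)
        summary["n_combinations"] = len(combos)

        _stage(log, "analyze")
        scores = efficacy_scores(scaled_mean, ds.outcome_names)
        ranked = rank_combinations(combos, scores)
        ranked.to_csv(outdir / "ranked_combinations.csv", index=False)
        top, bottom = top_bottom_tables(ranked, 10)
        top.to_csv(outdir / "top10.csv", index=False)
        bottom.to_csv(outdir / "bottom10.csv", index=False)
        corr = pairwise_correlations(ranked, config.top_k,
                                     factor_names=tuple(combos.columns))
        corr.to_csv(outdir / "correlations.csv", index=False)
        summary["efficacy_range"] = [float(scores.min()), float(scores.max())]
        summary["best_combination"] = {
            k: float(v) for k, v in ranked.iloc[0].items() if k != "rank"}
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(
            f"pipeline stage {log[-1]['stage']!r} failed: {exc}") from exc
    finally:
        (outdir / "stages.json").write_text(json.dumps(log, indent=1))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return outdir


def _parse_architecture(label: str) -> NetworkSpec:
    """Parse labels like 'ff2', 'ff2+ae', 'recurrent+ae'."""
    ae = 50 if label.endswith("+ae") else None
    core = label.removesuffix("+ae")
    if core == "recurrent":
        return NetworkSpec("recurrent", 1, autoencoder_units=ae)
    if core.startswith("ff"):
        return NetworkSpec("feedforward", int(core[2:]), autoencoder_units=ae)
    raise ValueError(f"cannot parse architecture label {label!r}")
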