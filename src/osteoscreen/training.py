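"""Fixed-budget training, hyperparameter sweeps, generalization and ensembles.

The assessment protocol: a network type, with its tuned learning rate
and batch size, is trained for a fixed budget of single-pattern
presentations (50,000 at full scale) on a random 175-pattern training
split and evaluated by RMS error over the held-out 50 patterns; this
is repeated over fresh random splits (10 at full scale) and the type
with the lowest mean test RMS wins. Scaling is refitted on each
training split so the held-out error is leakage-free. The winning type
is finally retrained on the full dataset as an ensemble of
independently initialised members whose outputs are averaged at
screening time.

A "batch size" of b means gradients are averaged over b consecutive
presentations per weight update; the iteration budget counts
presentations, not updates. Presentations are drawn uniformly at
random with replacement (an epoch/fixed-shuffle mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import Dataset, ScalingRecord, apply_scaling, fit_scaling
from .networks import (NetworkSpec, WeightSet, forward, init_network,
                       loss_and_gradient, apply_gradient,
                       pretrain_autoencoder)

#: Full-scale protocol constants.
PAPER_ITERATIONS = 50_000
PAPER_SPLIT = dict(n_train=175, n_test=50, n_repeats=10)
PAPER_ENSEMBLE_SIZE = 10

#: Default hyperparameter grids ("about 10 values" each).
DEFAULT_LR_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.geomspace(1e-3, 1.0, 10).round(6))
DEFAULT_BATCH_GRID: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128, 175)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.5
    batch_size: int = 8
    iterations: int = PAPER_ITERATIONS
    seed: int = 0
    sampling: str = "random"        # "random" | "epoch"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.iterations < 0:
            raise ValueError("batch_size >= 1 and iterations >= 0 required")
        if self.sampling not in ("random", "epoch"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")


@dataclass(frozen=True)
class SplitPlan:
    n_train: int = 175
    n_test: int = 50
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_train < 1 or self.n_test < 1:
            raise ValueError("split sizes and repeats must be positive")


@dataclass
class GeneralizationReport:
    spec: NetworkSpec
    config: TrainConfig
    test_rms: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.test_rms))

    @property
    def std(self) -> float:
        return float(np.std(self.test_rms, ddof=1)) if len(self.test_rms) > 1 else 0.0


def _derive_seeds(seed: int, n: int, tag: int = 0) -> list[int]:
    """Deterministic child seeds, kept below 2**31."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag])
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def train(spec: NetworkSpec, dataset: Dataset, config: TrainConfig,
          *, pretrained_encoder: tuple[np.ndarray, np.ndarray] | None = None,
          ) -> WeightSet:
    """Train one network on an already-scaled dataset.

    Consumes exactly ``config.iterations`` presentations; a weight
    update fires every ``batch_size`` presentations (the trailing
    partial batch, if any, updates with the mean over its own size).
    For autoencoder specs the encoder is pretrained on this dataset's
    inputs (same budget and learning rate) unless one is supplied, and
    is frozen throughout.
    """
    if dataset.n_patterns == 0:
        raise ValueError("empty dataset")
    init_seed, ae_seed, order_seed = _derive_seeds(config.seed, 3)
    ws = init_network(spec, init_seed)
    if spec.autoencoder_units:
        if pretrained_encoder is None:
            pretrained_encoder = pretrain_autoencoder(
                dataset.X, spec.autoencoder_units,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                iterations=config.iterations, seed=ae_seed)
        ws.encoder = (pretrained_encoder[0].copy(), pretrained_encoder[1].copy())

    n = dataset.n_patterns
    Y = np.where(dataset.mask, dataset.Y, 0.0)
    rng = np.random.default_rng(order_seed)
    if config.sampling == "random":
        order = rng.integers(0, n, size=config.iterations)
    else:
        reps = -(-config.iterations // n)
        order = np.concatenate([rng.permutation(n) for _ in range(reps)])
        order = order[:config.iterations]
    for start in range(0, config.iterations, config.batch_size):
        idx = order[start:start + config.batch_size]
        _, grad = loss_and_gradient(ws, dataset.X[idx], Y[idx],
                                    dataset.mask[idx])
        apply_gradient(ws, grad, config.learning_rate)
    return ws


def rms_error(ws: WeightSet, dataset: Dataset) -> float:
    """Root mean square error over the observed output cells."""
    if dataset.n_patterns == 0:
        raise ValueError("empty pattern list")
    if not dataset.mask.any():
        raise ValueError("all outcome cells are masked out; RMS undefined")
    out = forward(ws, dataset.X).output
    diff = (out - np.where(dataset.mask, dataset.Y, 0.0))[dataset.mask]
    return float(np.sqrt(np.mean(diff ** 2)))


def random_split(n: int, plan: SplitPlan, rng: np.random.Generator,
                 ) -> tuple[np.ndarray, np.ndarray]:
    if plan.n_train + plan.n_test > n:
        raise ValueError("split larger than dataset")
    perm = rng.permutation(n)
    return perm[:plan.n_train], perm[plan.n_train:plan.n_train + plan.n_test]


def assess_generalization(spec: NetworkSpec, config: TrainConfig,
                          dataset: Dataset, plan: SplitPlan,
                          ) -> GeneralizationReport:
    """Mean held-out RMS over repeated random splits.

    Per repeat: fresh seeded split, scaling fitted on the training
    portion only, fresh initialisation, fixed-budget training, RMS on
    the scaled test split (test values outside the training range are
    clipped into [0, 1]).
    """
    split_seeds = _derive_seeds(plan.seed, plan.n_repeats, tag=1)
    train_seeds = _derive_seeds(plan.seed, plan.n_repeats, tag=2)
    errors = []
    for r in range(plan.n_repeats):
        rng = np.random.default_rng(split_seeds[r])
        tr_idx, te_idx = random_split(dataset.n_patterns, plan, rng)
        tr, te = dataset.subset(tr_idx), dataset.subset(te_idx)
        record = fit_scaling(tr)
        tr_s = apply_scaling(tr, record, clip=False)
        te_s = apply_scaling(te, record, clip=True)
        ws = train(spec, tr_s, replace(config, seed=train_seeds[r]))
        errors.append(rms_error(ws, te_s))
    return GeneralizationReport(spec, config, errors)


def tune_hyperparameters(spec: NetworkSpec, lr_grid, batch_grid,
                         dataset: Dataset, plan: SplitPlan,
                         iterations: int = PAPER_ITERATIONS,
                         default_batch: int | None = None,
                         full_grid: bool = False,
                         ) -> tuple[TrainConfig, pd.DataFrame]:
    """Select (learning rate, batch size) by held-out RMS.

    Default mode sweeps the two parameters independently — the learning
    rate at a fixed default batch size, then the batch size at the best
    learning rate — reflecting their observed non-interaction, and
    costs |lr_grid| + |batch_grid| - 1 evaluations. ``full_grid``
    evaluates the full Cartesian product instead for verification.
    Returns the winning config and a tidy report of every evaluation.
    """
    lr_grid, batch_grid = list(lr_grid), list(batch_grid)
    if not lr_grid or not batch_grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    cache: dict[tuple[float, int], GeneralizationReport] = {}

    def evaluate(lr: float, b: int) -> float:
        key = (lr, b)
        if key not in cache:
            cfg = TrainConfig(lr, b, iterations, seed=0)
            cache[key] = assess_generalization(spec, cfg, dataset, plan)
            rows.append({"learning_rate": lr, "batch_size": b,
                         "mean_rms": cache[key].mean, "std_rms": cache[key].std})
        return cache[key].mean

    if full_grid:
        for lr in lr_grid:
            for b in batch_grid:
                evaluate(lr, b)
        best = min(cache, key=lambda k: cache[k].mean)
    else:
        b0 = default_batch if default_batch is not None else batch_grid[0]
        best_lr = min(lr_grid, key=lambda lr: evaluate(lr, b0))
        best_b = min(batch_grid, key=lambda b: evaluate(best_lr, b))
        best = (best_lr, best_b)
    report = pd.DataFrame(rows)
    return TrainConfig(best[0], best[1], iterations, seed=0), report


def select_architecture(candidates: list[tuple[NetworkSpec, TrainConfig]],
                        dataset: Dataset, plan: SplitPlan,
                        ) -> list[GeneralizationReport]:
    """Rank candidate (spec, config) pairs by mean held-out RMS.

    Ties (within exact equality of the mean) are broken toward fewer
    trainable parameters.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    reports = [assess_generalization(spec, cfg, dataset, plan)
               for spec, cfg in candidates]
    return sorted(reports, key=lambda r: (r.mean, r.spec.n_parameters()))


def selection_table(reports: list[GeneralizationReport]) -> pd.DataFrame:
    return pd.DataFrame([
        {"network": r.spec.label, "mean_rms": r.mean, "std_rms": r.std,
         "n_parameters": r.spec.n_parameters(),
         "learning_rate": r.config.learning_rate,
         "batch_size": r.config.batch_size,
         "repeats": len(r.test_rms)}
        for r in reports])


@dataclass
class Ensemble:
    """Independently trained members plus the scaling they were trained under."""

    spec: NetworkSpec
    members: list[WeightSet]
    scaling: ScalingRecord

    def __len__(self) -> int:
        return len(self.members)


def train_ensemble(spec: NetworkSpec, config: TrainConfig, dataset: Dataset,
                   n_members: int, master_seed: int) -> Ensemble:
    """Train ``n_members`` networks on the *full* (unscaled) dataset.

    Scaling is fitted on the whole dataset; member seeds derive
    deterministically from the master seed, so members differ only in
    initialisation and presentation order.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    record = fit_scaling(dataset)
    scaled = apply_scaling(dataset, record, clip=False)
    seeds = _derive_seeds(master_seed, n_members, tag=3)
    members = [train(spec, scaled, replace(config, seed=s)) for s in seeds]
    return Ensemble(spec, members, record)
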