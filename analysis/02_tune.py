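"""Hyperparameter sweep for the reference network type.

Sweeps learning rate and batch size independently (they do not
interact over this dataset) for the autoencoder + two-hidden-layer
network, scoring each value by mean held-out RMS over repeated random
splits, and reports the winning pair.

Usage: python analysis/02_tune.py [--iterations 5000] [--repeats 2]
"""

import argparse
from pathlib import Path

from osteoscreen.datasets import load_dataset
from osteoscreen.pipeline import _parse_architecture, split_plan_for, PipelineConfig
from osteoscreen.training import SplitPlan, tune_hyperparameters


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", default="results/train_dataset.csv")
    ap.add_argument("--architecture", default="ff2+ae")
    ap.add_argument("--iterations", type=int, default=5000)
    ap.add_argument("--repeats", type=int, default=2)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    ds = load_dataset(args.dataset)
    plan = SplitPlan(175, 50, args.repeats, seed=args.seed) \
        if ds.n_patterns >= 225 else \
        SplitPlan(ds.n_patterns - max(1, ds.n_patterns // 5),
                  max(1, ds.n_patterns // 5), args.repeats, seed=args.seed)
    spec = _parse_architecture(args.architecture)
    lr_grid = (0.1, 0.2, 0.5, 1.0, 2.0)
    batch_grid = (1, 2, 4, 8, 16)
    best, report = tune_hyperparameters(spec, lr_grid, batch_grid, ds, plan,
                                        iterations=args.iterations)
    Path(args.outdir).mkdir(exist_ok=True)
    report.to_csv(Path(args.outdir) / "tuning.csv", index=False)
    print(report.to_string(index=False))
    print(f"\nbest: learning_rate={best.learning_rate} "
          f"batch_size={best.batch_size} "
          f"({len(report)} evaluations = |lr|+|batch|-1)")


if __name__ == "__main__":
    main()
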