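"""Generalization assessment and architecture selection.

Trains each candidate network type for a fixed presentation budget on
repeated random train/test splits and ranks the types by mean held-out
RMS. At full scale this covers all 16 types (feedforward depths 0, 1,
2, 3, 5, 7, 10 and a recurrent circuit, each with and without the
50-unit autoencoder); the default here is a reduced candidate set and
budget that runs in about a minute.

Usage: python analysis/03_select_architecture.py [--full] [--iterations N]
"""

import argparse
from pathlib import Path

from osteoscreen.datasets import load_dataset
from osteoscreen.networks import NetworkSpec, candidate_network_specs
from osteoscreen.training import (SplitPlan, TrainConfig, select_architecture,
                                  selection_table)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", default="results/train_dataset.csv")
    ap.add_argument("--iterations", type=int, default=5000)
    ap.add_argument("--repeats", type=int, default=3)
    ap.add_argument("--learning-rate", type=float, default=1.0)
    ap.add_argument("--batch-size", type=int, default=4)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--full", action="store_true",
                    help="all 16 types (slow) instead of a reduced set")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    ds = load_dataset(args.dataset)
    cfg = TrainConfig(args.learning_rate, args.batch_size, args.iterations,
                      seed=args.seed)
    if args.full:
        specs = candidate_network_specs()
    else:
        specs = [NetworkSpec("feedforward", d, autoencoder_units=ae)
                 for ae in (None, 50) for d in (0, 1, 2)]
    n_test = 50 if ds.n_patterns >= 225 else max(1, ds.n_patterns // 5)
    plan = SplitPlan(ds.n_patterns - n_test, n_test, args.repeats,
                     seed=args.seed)
    reports = select_architecture([(s, cfg) for s in specs], ds, plan)
    table = selection_table(reports)
    Path(args.outdir).mkdir(exist_ok=True)
    table.to_csv(Path(args.outdir) / "selection.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nselected: {reports[0].spec.label} "
          f"(mean test RMS {reports[0].mean:.4f})")


if __name__ == "__main__":
    main()
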