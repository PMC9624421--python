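"""Train the prediction ensemble on the full dataset.

Trains several independently initialised copies of the selected
network type (default: autoencoder + two hidden layers) on all
patterns; screening averages their outputs to damp the run-to-run
variability of stochastic training. Member weights are written as a
JSON artifact for the screening stage.

Usage: python analysis/04_train_ensemble.py [--members 3] [--iterations N]
"""

import argparse
import json
from pathlib import Path

from osteoscreen.datasets import load_dataset
from osteoscreen.pipeline import _parse_architecture
from osteoscreen.training import TrainConfig, train_ensemble


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", default="results/train_dataset.csv")
    ap.add_argument("--architecture", default="ff2+ae")
    ap.add_argument("--members", type=int, default=3)
    ap.add_argument("--iterations", type=int, default=20000)
    ap.add_argument("--learning-rate", type=float, default=1.0)
    ap.add_argument("--batch-size", type=int, default=4)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    ds = load_dataset(args.dataset)
    spec = _parse_architecture(args.architecture)
    cfg = TrainConfig(args.learning_rate, args.batch_size, args.iterations)
    ens = train_ensemble(spec, cfg, ds, args.members, master_seed=args.seed)
    artifact = {
        "scaling": ens.scaling.to_dict(),
        "members": [m.to_dict() for m in ens.members],
    }
    out = Path(args.outdir) / "ensemble.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(artifact))
    print(f"trained {len(ens)} x {spec.label} on {ds.n_patterns} patterns "
          f"({cfg.iterations} presentations each); wrote {out}")


if __name__ == "__main__":
    main()
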