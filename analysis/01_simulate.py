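"""Generate the working datasets.

Writes the packaged 225-row synthetic stand-in (the desk-scale
emulation of the curated bone-healing literature table) and records
its planted generator parameters, so every later stage can be rerun
and checked against the known ground truth.

Usage: python analysis/01_simulate.py [--seed 0] [--outdir results]
"""

import argparse
import json
from pathlib import Path

from osteoscreen import synthetic
from osteoscreen.datasets import save_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0,
                    help="seed for the auxiliary training dataset")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref = synthetic.reference_dataset()
    save_dataset(ref, outdir / "synthetic_reference_dataset.csv")
    spec = synthetic.default_spec(225, seed=args.seed)
    (outdir / "synthetic_spec.json").write_text(
        json.dumps(spec.to_dict(), indent=1))
    save_dataset(synthetic.generate_dataset(spec), outdir / "train_dataset.csv")

    obs = ref.mask.mean()
    print(f"reference dataset: {ref.n_patterns} patterns, "
          f"{ref.X.shape[1]} factors, {ref.Y.shape[1]} outcomes, "
          f"{obs:.0%} of outcome cells observed")
    import numpy as np
    print(f"observed outcome range: {np.nanmin(ref.Y):.0f} .. "
          f"{np.nanmax(ref.Y):.0f}")
    print(f"wrote {outdir}/synthetic_reference_dataset.csv, "
          f"train_dataset.csv, synthetic_spec.json")


if __name__ == "__main__":
    main()
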