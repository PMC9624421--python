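"""Screen the 2400 feasible factor combinations through the ensemble.

Enumerates the quantized 9-factor grid under the two feasibility
constraints (no pulsed ultrasound with electrical stimulation, no BMAC
with PRP), embeds each combination into the 17-dim input with the 8
non-screened inputs at zero, and records the ensemble-averaged 26
predicted outcomes per combination.

Usage: python analysis/05_screen_combinations.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from osteoscreen.datasets import FACTOR_NAMES, OUTCOME_NAMES, ScalingRecord
from osteoscreen.networks import WeightSet
from osteoscreen.screening import (build_screen_grid, embed_combinations,
                                   enumerate_combinations, predict_ensemble)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--ensemble", default="results/ensemble.json")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    artifact = json.loads(Path(args.ensemble).read_text())
    members = [WeightSet.from_dict(d) for d in artifact["members"]]
    scaling = ScalingRecord.from_dict(artifact["scaling"])

    combos = enumerate_combinations(build_screen_grid())
    X = embed_combinations(combos, FACTOR_NAMES)
    scaled_mean, unscaled_mean = predict_ensemble(members, X, scaling)
    preds = pd.concat(
        [combos, pd.DataFrame(unscaled_mean, columns=list(OUTCOME_NAMES))],
        axis=1)
    out = Path(args.outdir) / "screen_predictions.csv"
    preds.to_csv(out, index=False)
    print(f"screened {len(combos)} feasible combinations "
          f"({len(members)}-member ensemble); wrote {out}")


if __name__ == "__main__":
    main()
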