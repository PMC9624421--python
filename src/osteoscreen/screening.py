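"""Combinatorial screen: factor grid, feasibility constraints, enumeration.

Nine of the 17 input factors are surgically combinable and are screened
over quantized dose levels: BMP2 (4 levels, mg), BMP7 (2, mg), OG
(4, ug), PDGF (5, ug), PU (4, treatment-days), the presence/absence
adjuncts ES, BMAC and PRP, and the common delivery vehicle EBG which is
present in every combination. Two feasibility rules prune the Cartesian
product: pulsed ultrasound and electrical stimulation are not combined,
and neither are BMAC and PRP (both require intra-operative harvesting).
The pruned grid contains exactly 2400 combinations, including the null
combination (vehicle only) and every single-factor-plus-vehicle row.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Screened factors in canonical (enumeration) order.
SCREEN_FACTORS: tuple[str, ...] = (
    "BMP2", "BMP7", "OG", "PDGF", "PU", "ES", "BMAC", "PRP", "EBG")


@dataclass(frozen=True)
class ForbidBothActive:
    """Constraint: the two factors may not both be nonzero."""

    factor_a: str
    factor_b: str

    def violated(self, levels: dict[str, float]) -> bool:
        return levels[self.factor_a] > 0 and levels[self.factor_b] > 0


@dataclass(frozen=True)
class FactorGrid:
    """Ordered level sets for the screened factors plus feasibility rules."""

    factors: tuple[tuple[str, tuple[float, ...]], ...]
    constraints: tuple[ForbidBothActive, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def levels(self, name: str) -> tuple[float, ...]:
        return dict(self.factors)[name]

    def to_dict(self) -> dict:
        return {
            "factors": {name: list(lv) for name, lv in self.factors},
            "constraints": [[c.factor_a, c.factor_b] for c in self.constraints],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorGrid":
        return cls(
            tuple((name, tuple(map(float, lv))) for name, lv in d["factors"].items()),
            tuple(ForbidBothActive(a, b) for a, b in d.get("constraints", ())),
        )


def build_screen_grid() -> FactorGrid:
    """The published screening grid.

    Level-set extremes come from the reported best/worst combination
    tables (BMP2 max 15 mg, BMP7 5 mg, OG 150 ug, PDGF 200 ug, PU 150
    days); interior dose levels not printed there (BMP2 5/10, OG 50/100)
    are evenly spaced over [0, max]. The 2400 feasible-combination count
    is invariant to the interior spacing.
    """
    return FactorGrid(
        factors=(
            ("BMP2", (0.0, 5.0, 10.0, 15.0)),
            ("BMP7", (0.0, 5.0)),
            ("OG", (0.0, 50.0, 100.0, 150.0)),
            ("PDGF", (0.0, 50.0, 100.0, 150.0, 200.0)),
            ("PU", (0.0, 50.0, 100.0, 150.0)),
            ("ES", (0.0, 1.0)),
            ("BMAC", (0.0, 1.0)),
            ("PRP", (0.0, 1.0)),
            ("EBG", (1.0,)),
        ),
        constraints=(
            ForbidBothActive("PU", "ES"),
            ForbidBothActive("BMAC", "PRP"),
        ),
    )


def enumerate_combinations(grid: FactorGrid) -> pd.DataFrame:
    """All feasible level assignments, one row per combination.

    Deterministic lexicographic order: factors in grid order, levels
    ascending, the last factor varying fastest.
    """
    names = grid.names
    for name, lv in grid.factors:
        if len(lv) == 0:
            raise ValueError(f"empty level set for factor {name}")
    rows = []
    for combo in itertools.product(*(lv for _, lv in grid.factors)):
        levels = dict(zip(names, combo))
        if any(c.violated(levels) for c in grid.constraints):
            continue
        rows.append(combo)
    return pd.DataFrame(rows, columns=list(names))


def embed_combinations(combos: pd.DataFrame,
                       factor_names: tuple[str, ...]) -> np.ndarray:
    """Place screened levels into the full factor vector, zero elsewhere.

    The 8 non-screened inputs take value 0 for every screened
    combination.
    """
    missing = [c for c in combos.columns if c not in factor_names]
    if missing:
        raise KeyError(f"screened factor(s) not in schema: {missing}")
    X = np.zeros((len(combos), len(factor_names)))
    for name in combos.columns:
        X[:, factor_names.index(name)] = combos[name].to_numpy(dtype=float)
    return X


def project_combinations(X: np.ndarray, factor_names: tuple[str, ...],
                         screen_names: tuple[str, ...] = SCREEN_FACTORS,
                         ) -> pd.DataFrame:
    """Inverse of :func:`embed_combinations` on the screened columns."""
    cols = {name: X[:, factor_names.index(name)] for name in screen_names}
    return pd.DataFrame(cols)


def predict_ensemble(members, X: np.ndarray, scaling) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-averaged outputs for raw (unscaled) factor vectors.

    Inputs are scaled with the training record (out-of-range values are
    clipped), passed through every member network, and the 26 output
    activations averaged arithmetically across members. Returns
    ``(scaled_mean, unscaled_mean)`` where the second applies the
    inverse output scaling to the mean activation.
    """
    from .datasets import invert_outputs, scale_inputs
    from .networks import forward

    if not members:
        raise ValueError("ensemble needs at least one member")
    Xs = scale_inputs(np.atleast_2d(X), scaling, clip=True)
    mean = np.mean([forward(m, Xs).output for m in members], axis=0)
    return mean, invert_outputs(mean, scaling)
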