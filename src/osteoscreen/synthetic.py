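"""Synthetic datasets with a planted factor->outcome ground truth.

The generator emulates the statistical structure of the curated
bone-healing literature table: mostly single-agent rows with the bone
graft vehicle always present, factor doses drawn from the same
quantized level sets the combination screen uses, 26 outcomes on
heterogeneous positive scales, and sparse outcome reporting. The
planted mapping is

    y_k(x) = base_k + sum_i M[i, k] * x_i
             + sum_(i,j,k,c) c * x_i * x_j + N(0, noise_sd)

with per-outcome intercepts ``base``, a 17x26 main-effect matrix ``M``
on raw factor levels, and explicit pairwise synergy terms. Because the
mapping is known in closed form, a ground-truth efficacy oracle is
available for ranking-recovery experiments.

The default design encodes a plausible pharmacology: the three
bone-morphogenic proteins (BMP2, BMP7, OG/BMP3) help strongly, PDGF is
mildly counterproductive at high dose, physical adjuncts help modestly,
a BMP2xBMP7 synergy boosts fusion-related outcomes, and an OGxPDGF
trade-off penalises their combination. Lower-is-better outcomes (times
to union, failure counts) receive mirrored signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import (FACTOR_NAMES, N_FACTORS, N_OUTCOMES, OUTCOME_NAMES,
                       Dataset)
from .efficacy import EfficacyConfig, efficacy_scores
from .screening import SCREEN_FACTORS, build_screen_grid, embed_combinations

#: Seed of the packaged 225-row synthetic stand-in dataset.
REFERENCE_SEED = 76562

#: Level sets for the 8 non-screened context factors.
CONTEXT_LEVELS: dict[str, tuple[float, ...]] = {
    "ZA": (0.0, 4.0),
    "ALLOGRAFT": (0.0, 1.0), "DBM": (0.0, 1.0),
    "COLLAGEN": (0.0, 1.0), "CERAMIC": (0.0, 1.0),
    "HUMAN": (0.0, 1.0), "RODENT": (0.0, 1.0), "LARGE_ANIMAL": (0.0, 1.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted generator.

    ``main_effects`` acts on raw factor levels; ``synergies`` is a list
    of (factor_i, factor_j, outcome_k, coefficient) tuples by name,
    contributing ``coefficient * x_i * x_j`` to outcome k. ``noise_sd``
    is the standard deviation of additive Gaussian noise on the raw
    outcome scale.
    """

    n_patterns: int
    base: tuple[float, ...]
    main_effects: tuple[tuple[float, ...], ...]   # (17, 26), row = factor
    synergies: tuple[tuple[str, str, str, float], ...] = ()
    noise_sd: float = 0.0
    single_agent_fraction: float = 0.75
    outcome_report_prob: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        M = np.asarray(self.main_effects, dtype=float)
        if M.shape != (N_FACTORS, N_OUTCOMES):
            raise ValueError(f"main_effects must be {N_FACTORS}x{N_OUTCOMES}")
        if not np.all(np.isfinite(M)) or not np.all(np.isfinite(self.base)):
            raise ValueError("coefficients must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.single_agent_fraction <= 1.0):
            raise ValueError("single_agent_fraction must lie in [0, 1]")
        if not (0.0 < self.outcome_report_prob <= 1.0):
            raise ValueError("outcome_report_prob must lie in (0, 1]")
        for i, j, k, _ in self.synergies:
            if i not in FACTOR_NAMES or j not in FACTOR_NAMES:
                raise ValueError(f"unknown synergy factor in ({i}, {j})")
            if k not in OUTCOME_NAMES:
                raise ValueError(f"unknown synergy outcome {k!r}")

    @property
    def M(self) -> np.ndarray:
        return np.asarray(self.main_effects, dtype=float)

    def to_dict(self) -> dict:
        return {
            "n_patterns": self.n_patterns, "base": list(self.base),
            "main_effects": [list(r) for r in self.main_effects],
            "synergies": [list(s) for s in self.synergies],
            "noise_sd": self.noise_sd,
            "single_agent_fraction": self.single_agent_fraction,
            "outcome_report_prob": self.outcome_report_prob, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            n_patterns=int(d["n_patterns"]),
            base=tuple(map(float, d["base"])),
            main_effects=tuple(tuple(map(float, r)) for r in d["main_effects"]),
            synergies=tuple((str(a), str(b), str(c), float(x))
                            for a, b, c, x in d.get("synergies", ())),
            noise_sd=float(d.get("noise_sd", 0.0)),
            single_agent_fraction=float(d.get("single_agent_fraction", 0.75)),
            outcome_report_prob=float(d.get("outcome_report_prob", 0.6)),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# Default planted design

# quality weights on [0,1]-normalized factor levels: how much each factor
# contributes to a shared "healing quality" latent
_QUALITY_WEIGHTS: dict[str, float] = {
    "BMP2": 0.32, "BMP7": 0.24, "OG": 0.20, "PDGF": -0.12, "PU": 0.06,
    "ES": 0.14, "BMAC": 0.08, "PRP": 0.02, "EBG": 0.02,
    "ZA": 0.04, "ALLOGRAFT": 0.01, "DBM": 0.02, "COLLAGEN": 0.01,
    "CERAMIC": 0.0, "HUMAN": -0.02, "RODENT": 0.02, "LARGE_ANIMAL": 0.0,
}

# per-outcome (lo, hi, gain, intercept): y spans roughly [lo, hi] as the
# quality latent moves through [0, 1]; gain < 0 marks lower-is-better
# outcomes. Scales are deliberately heterogeneous (global range 2..277).
_OUTCOME_DESIGN: dict[str, tuple[float, float, float, float]] = {
    "DR":     (2.0, 12.0, 0.70, 0.15),
    "BF3":    (10.0, 90.0, 0.80, 0.10),
    "BF6":    (20.0, 95.0, 0.75, 0.15),
    "MV/TV":  (5.0, 60.0, 0.70, 0.15),
    "PLF-FR": (30.0, 95.0, 0.80, 0.10),
    "ODI":    (5.0, 50.0, 0.65, 0.20),
    "FR":     (25.0, 98.0, 0.85, 0.10),
    "FH":     (30.0, 99.0, 0.75, 0.15),
    "OW":     (10.0, 70.0, 0.60, 0.20),
    "RO":     (20.0, 90.0, 0.70, 0.15),
    "HO":     (10.0, 80.0, 0.65, 0.15),
    "IS":     (50.0, 99.0, 0.60, 0.30),
    "TWB/CH": (6.0, 40.0, -0.70, 0.85),
    "TRU":    (8.0, 52.0, -0.80, 0.90),
    "RBG":    (2.0, 30.0, -0.65, 0.80),
    "NH":     (2.0, 45.0, -0.75, 0.85),
    "DY":     (2.0, 25.0, -0.60, 0.80),
    "BMD":    (40.0, 160.0, 0.50, 0.25),
    "TOR":    (30.0, 277.0, 0.55, 0.20),
    "STIFF":  (25.0, 220.0, 0.50, 0.25),
    "CAL":    (15.0, 120.0, 0.40, 0.30),
    "VAS":    (2.0, 10.0, -0.45, 0.75),
    "COST":   (20.0, 200.0, -0.30, 0.65),
    "INF":    (2.0, 20.0, -0.10, 0.45),
    "REOP":   (2.0, 25.0, -0.35, 0.70),
    "ROM":    (30.0, 150.0, 0.35, 0.35),
}

# latent-scale synergy design: positive-direction boost on fusion-related
# outcomes when BMP2 and BMP7 co-occur; penalty when OG and PDGF co-occur
_SYNERGY_DESIGN: tuple[tuple[str, str, str, float], ...] = (
    ("BMP2", "BMP7", "FR", 0.15), ("BMP2", "BMP7", "PLF-FR", 0.12),
    ("BMP2", "BMP7", "BF6", 0.12), ("BMP2", "BMP7", "RO", 0.10),
    ("BMP2", "BMP7", "TRU", -0.12),
    ("OG", "PDGF", "FR", -0.10), ("OG", "PDGF", "BF6", -0.08),
    ("OG", "PDGF", "TRU", 0.08),
)


def factor_level_sets() -> dict[str, tuple[float, ...]]:
    """Sampling level sets: screen grid levels plus context-factor levels."""
    grid = build_screen_grid()
    levels = {name: grid.levels(name) for name in SCREEN_FACTORS}
    levels.update(CONTEXT_LEVELS)
    return levels


def _max_levels() -> np.ndarray:
    levels = factor_level_sets()
    return np.array([max(levels[n]) for n in FACTOR_NAMES])


def default_spec(n_patterns: int = 225, seed: int = 0, *,
                 noise_sd: float = 2.0,
                 synergy_scale: float = 1.0,
                 single_agent_fraction: float = 0.75,
                 outcome_report_prob: float = 0.6) -> SyntheticSpec:
    """The documented default planted design (see module docstring).

    ``synergy_scale`` multiplies the planted interaction coefficients
    (0 removes them; values > 1 strengthen them for interaction-
    detection experiments).
    """
    maxes = _max_levels()
    base = np.empty(N_OUTCOMES)
    M = np.zeros((N_FACTORS, N_OUTCOMES))
    w = np.array([_QUALITY_WEIGHTS[n] for n in FACTOR_NAMES])
    for k, name in enumerate(OUTCOME_NAMES):
        lo, hi, gain, b0 = _OUTCOME_DESIGN[name]
        span = hi - lo
        base[k] = lo + span * b0
        M[:, k] = span * gain * w / maxes
    synergies = []
    for fi, fj, ok, s in _SYNERGY_DESIGN:
        lo, hi, _, _ = _OUTCOME_DESIGN[ok]
        c = (hi - lo) * s * synergy_scale / (
            maxes[FACTOR_NAMES.index(fi)] * maxes[FACTOR_NAMES.index(fj)])
        synergies.append((fi, fj, ok, float(c)))
    return SyntheticSpec(
        n_patterns=n_patterns,
        base=tuple(base),
        main_effects=tuple(map(tuple, M)),
        synergies=tuple(synergies),
        noise_sd=noise_sd,
        single_agent_fraction=single_agent_fraction,
        outcome_report_prob=outcome_report_prob,
        seed=seed,
    )


def linear_spec(n_patterns: int = 200, seed: int = 0) -> SyntheticSpec:
    """Noiseless, synergy-free variant: a purely additive ground truth."""
    return default_spec(n_patterns, seed, noise_sd=0.0, synergy_scale=0.0)


def strong_synergy_spec(n_patterns: int = 400, seed: int = 0) -> SyntheticSpec:
    """Variant with a strong BMP2xBMP7 synergy for interaction detection.

    Uses more multi-agent rows than the default so co-occurrences of the
    interacting factors are actually observed, low noise, and 4x-scaled
    interaction coefficients.
    """
    return default_spec(n_patterns, seed, noise_sd=0.5, synergy_scale=4.0,
                        single_agent_fraction=0.5)


# ---------------------------------------------------------------------------
# Generation


def planted_outcomes(spec: SyntheticSpec, X: np.ndarray) -> np.ndarray:
    """Noiseless planted mapping applied to raw factor vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(spec.base) + X @ spec.M
    for fi, fj, ok, c in spec.synergies:
        i, j = FACTOR_NAMES.index(fi), FACTOR_NAMES.index(fj)
        k = OUTCOME_NAMES.index(ok)
        Y[:, k] += c * X[:, i] * X[:, j]
    return Y


def _sample_factors(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    levels = factor_level_sets()
    agents = [n for n in SCREEN_FACTORS if n != "EBG"]
    X = np.zeros((spec.n_patterns, N_FACTORS))
    X[:, FACTOR_NAMES.index("EBG")] = 1.0

    def nonzero_level(name: str) -> float:
        lv = [v for v in levels[name] if v > 0]
        return float(rng.choice(lv))

    for r in range(spec.n_patterns):
        if rng.uniform() < spec.single_agent_fraction:
            active = [agents[rng.integers(len(agents))]]
        else:
            active = [a for a in agents if rng.uniform() < 0.4]
            # feasibility rules mirror the screen: drop one of each
            # forbidden pair at random
            for a, b in (("PU", "ES"), ("BMAC", "PRP")):
                if a in active and b in active:
                    active.remove(a if rng.uniform() < 0.5 else b)
        for name in active:
            X[r, FACTOR_NAMES.index(name)] = nonzero_level(name)
        # one study-model flag per row
        model = ("HUMAN", "RODENT", "LARGE_ANIMAL")[
            rng.choice(3, p=(0.3, 0.5, 0.2))]
        X[r, FACTOR_NAMES.index(model)] = 1.0
        # at most one carrier context flag
        carrier = rng.choice(5, p=(0.4, 0.2, 0.2, 0.1, 0.1))
        if carrier > 0:
            name = ("ALLOGRAFT", "DBM", "COLLAGEN", "CERAMIC")[carrier - 1]
            X[r, FACTOR_NAMES.index(name)] = 1.0
        if rng.uniform() < 0.1:
            X[r, FACTOR_NAMES.index("ZA")] = nonzero_level("ZA")
    return X


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Draw a dataset from the planted model; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    X = _sample_factors(spec, rng)
    Y = planted_outcomes(spec, X)
    if spec.noise_sd > 0:
        Y = Y + rng.normal(0.0, spec.noise_sd, size=Y.shape)
    mask = rng.uniform(size=Y.shape) < spec.outcome_report_prob
    empty = ~mask.any(axis=1)
    if empty.any():  # every pattern must report at least one outcome
        for r in np.flatnonzero(empty):
            mask[r, rng.integers(N_OUTCOMES)] = True
    Y = np.where(mask, Y, np.nan)
    return Dataset(X, Y, mask,
                   source_ids=tuple(f"synthetic{r}" for r in range(len(X))))


def reference_dataset() -> Dataset:
    """The packaged 225-row synthetic stand-in for the curated table.

    This is *synthetic* data from :func:`default_spec` at a fixed seed,
    constructed to match the published structural summary of the
    curated literature dataset: 225 patterns, 17 inputs, 26 outcomes
    with sparse reporting, and observed outcome values spanning exactly
    2 to 277 (values are clipped into that global range and the extreme
    cells anchored to it).
    """
    ds = generate_dataset(default_spec(n_patterns=225, seed=REFERENCE_SEED))
    Y = ds.Y.copy()
    obs = ds.mask
    Y[obs] = np.clip(Y[obs], 2.0, 277.0)
    flat = np.where(obs, Y, np.nan)
    i_min = np.unravel_index(np.nanargmin(flat), flat.shape)
    i_max = np.unravel_index(np.nanargmax(flat), flat.shape)
    Y[i_min], Y[i_max] = 2.0, 277.0
    return Dataset(ds.X, Y, obs, source_ids=ds.source_ids)


# ---------------------------------------------------------------------------
# Ground-truth efficacy oracle


def planted_efficacy_scores(spec: SyntheticSpec, combinations,
                            config: EfficacyConfig = EfficacyConfig(),
                            ) -> np.ndarray:
    """Ground-truth composite efficacy for a set of screened combinations.

    Applies the noiseless planted mapping to the embedded 17-dim inputs
    and then the same flip / min-max-normalize / average rule the
    pipeline uses, with normalization over the supplied set.
    """
    if len(combinations) == 0:
        raise ValueError("empty combination set: nothing to normalize over")
    X = embed_combinations(combinations, FACTOR_NAMES)
    Y = planted_outcomes(spec, X)
    if len(combinations) == 1:
        # degenerate normalization: every column has zero range -> scores 0
        return np.zeros(1)
    return efficacy_scores(Y, OUTCOME_NAMES, config)


def planted_efficacy(spec: SyntheticSpec, combination, population,
                     config: EfficacyConfig = EfficacyConfig()) -> float:
    """Oracle score of one combination, normalized over ``population``.

    ``combination`` is a mapping of screened factor names to levels;
    ``population`` the combination set (DataFrame) defining the
    normalization extremes.
    """
    import pandas as pd

    row = pd.DataFrame([combination])
    pop = population.reset_index(drop=True)
    merged = pd.concat([row[pop.columns], pop], ignore_index=True)
    return float(planted_efficacy_scores(spec, merged, config)[0])
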