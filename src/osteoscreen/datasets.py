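"""Dataset schema, loading/validation and invertible min-max scaling.

The dataset is a table of experimental results on bone-healing
interventions: each row (a *pattern*) pairs a 17-component treatment
factor vector (agents and doses, physical adjuncts, the delivery vehicle
and study-design context flags) with a 26-component outcome vector.
Outcomes sit on heterogeneous positive scales and most studies report
only a subset of them, so every outcome cell carries an observation
mask. Training and error computation downstream use the mask (masked
loss); a zero-fill view is available for dense display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 17 input factors. The first nine are the agents screened for
#: combination therapy; the remainder are carrier and study-design
#: context factors. Units: BMP2/BMP7 mg, OG/PDGF ug, PU total treatment
#: days, ZA mg; all others are presence/absence flags.
FACTOR_NAMES: tuple[str, ...] = (
    "BMP2", "BMP7", "OG", "PDGF", "PU", "ES", "BMAC", "PRP", "EBG",
    "ZA", "ALLOGRAFT", "DBM", "COLLAGEN", "CERAMIC",
    "HUMAN", "RODENT", "LARGE_ANIMAL",
)

#: Factors constrained to {0, 1}.
BINARY_FACTORS: tuple[str, ...] = (
    "ES", "BMAC", "PRP", "EBG",
    "ALLOGRAFT", "DBM", "COLLAGEN", "CERAMIC",
    "HUMAN", "RODENT", "LARGE_ANIMAL",
)

#: The 26 outcome measures. The first 17 enter the composite efficacy
#: score (12 higher-is-better, 5 lower-is-better; see
#: :mod:`osteoscreen.efficacy`); the final 9 are auxiliary metrics kept
#: for training but excluded from the score.
OUTCOME_NAMES: tuple[str, ...] = (
    "DR", "BF3", "BF6", "MV/TV", "PLF-FR", "ODI", "FR", "FH", "OW",
    "RO", "HO", "IS", "TWB/CH", "TRU", "RBG", "NH", "DY",
    "BMD", "TOR", "STIFF", "CAL", "VAS", "COST", "INF", "REOP", "ROM",
)

#: Alternate spellings seen for outcome columns, normalised on load.
OUTCOME_ALIASES: dict[str, str] = {"TWC/CH": "TWB/CH"}

N_FACTORS = len(FACTOR_NAMES)
N_OUTCOMES = len(OUTCOME_NAMES)


class SchemaError(ValueError):
    """A table does not match the 17-factor / 26-outcome schema."""


@dataclass
class Dataset:
    """An ordered collection of patterns sharing the column schema.

    Attributes
    ----------
    X : (n, 17) float array of factor levels.
    Y : (n, 26) float array of outcomes; cells with ``mask`` False hold NaN.
    mask : (n, 26) bool array; True where the outcome was reported.
    """

    X: np.ndarray
    Y: np.ndarray
    mask: np.ndarray
    factor_names: tuple[str, ...] = FACTOR_NAMES
    outcome_names: tuple[str, ...] = OUTCOME_NAMES
    source_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.source_ids:
            self.source_ids = tuple(f"row{i}" for i in range(len(self.X)))
        validate_dataset(self)

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    def subset(self, indices: np.ndarray) -> "Dataset":
        idx = np.asarray(indices)
        return Dataset(
            self.X[idx], self.Y[idx], self.mask[idx],
            self.factor_names, self.outcome_names,
            tuple(self.source_ids[i] for i in idx),
        )

    def zero_filled(self) -> np.ndarray:
        """Outcome matrix with unobserved cells set to 0 (dense view)."""
        return np.where(self.mask, self.Y, 0.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.factor_names))
        out = pd.DataFrame(np.where(self.mask, self.Y, np.nan),
                           columns=list(self.outcome_names))
        df = pd.concat([df, out], axis=1)
        df.insert(0, "source_id", list(self.source_ids))
        return df


def validate_dataset(ds: Dataset) -> None:
    """Enforce schema invariants, naming the offending column/row."""
    n = ds.X.shape[0]
    if n == 0:
        raise SchemaError("dataset has zero rows")
    if ds.X.shape != (n, N_FACTORS):
        raise SchemaError(f"expected {N_FACTORS} factor columns, got {ds.X.shape[1]}")
    if ds.Y.shape != (n, N_OUTCOMES) or ds.mask.shape != (n, N_OUTCOMES):
        raise SchemaError(f"expected {N_OUTCOMES} outcome columns, got {ds.Y.shape[1]}")
    if len(set(ds.factor_names)) != N_FACTORS or len(set(ds.outcome_names)) != N_OUTCOMES:
        raise SchemaError("column names are not unique")
    if not np.all(np.isfinite(ds.X)):
        i, j = np.argwhere(~np.isfinite(ds.X))[0]
        raise SchemaError(f"non-finite factor value at row {i}, column {ds.factor_names[j]}")
    if np.any(ds.X < 0):
        i, j = np.argwhere(ds.X < 0)[0]
        raise SchemaError(f"negative factor level at row {i}, column {ds.factor_names[j]}")
    for name in BINARY_FACTORS:
        if name in ds.factor_names:
            col = ds.X[:, ds.factor_names.index(name)]
            bad = ~np.isin(col, (0.0, 1.0))
            if bad.any():
                raise SchemaError(
                    f"binary factor {name} takes value {col[bad][0]!r} "
                    f"at row {int(np.flatnonzero(bad)[0])}")
    if not np.all(np.isfinite(ds.Y[ds.mask])):
        raise SchemaError("non-finite observed outcome value")
    rows_empty = ~ds.mask.any(axis=1)
    if rows_empty.any():
        raise SchemaError(
            f"row {int(np.flatnonzero(rows_empty)[0])} reports no outcome at all")


def load_dataset(path: str | Path, format: str | None = None) -> Dataset:
    """Load and validate a dataset table from CSV or XLSX.

    The canonical on-disk dialect is a single table with a header row of
    the 17 factor names followed by the 26 outcome names (an optional
    ``source_id`` provenance column is allowed anywhere). Empty outcome
    cells mean "not reported" and become masked-out entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=0, engine="openpyxl")
    elif fmt == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return dataset_from_frame(df)


def dataset_from_frame(df: pd.DataFrame) -> Dataset:
    df = df.rename(columns=OUTCOME_ALIASES)
    missing = [c for c in FACTOR_NAMES + OUTCOME_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError("dataset has zero rows")
    known = set(FACTOR_NAMES) | set(OUTCOME_NAMES) | {"source_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown column(s): {', '.join(map(str, unknown))}")

    def numeric(cols: list[str], allow_nan: bool) -> np.ndarray:
        block = np.empty((len(df), len(cols)))
        for j, c in enumerate(cols):
            col = pd.to_numeric(df[c], errors="coerce")
            bad = col.isna() & df[c].notna()
            if bad.any():
                raise SchemaError(
                    f"non-numeric cell in column {c} at row {int(bad.idxmax())}")
            if not allow_nan and col.isna().any():
                raise SchemaError(
                    f"missing value in factor column {c} at row {int(col.isna().idxmax())}")
            block[:, j] = col.to_numpy(dtype=float)
        return block

    X = numeric(list(FACTOR_NAMES), allow_nan=False)
    Y = numeric(list(OUTCOME_NAMES), allow_nan=True)
    mask = ~np.isnan(Y)
    sources = (tuple(map(str, df["source_id"])) if "source_id" in df.columns else ())
    return Dataset(X, Y, mask, FACTOR_NAMES, OUTCOME_NAMES, sources)


def save_dataset(ds: Dataset, path: str | Path) -> None:
    ds.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scaling


@dataclass
class ScalingRecord:
    """Per-column min/max for mapping factor and outcome columns to [0, 1].

    Fitted on observed entries only; zero-range (constant) columns are
    flagged degenerate and scale to 0 by convention. The map is
    invertible on non-degenerate columns.
    """

    in_min: np.ndarray
    in_max: np.ndarray
    out_min: np.ndarray
    out_max: np.ndarray

    @property
    def in_degenerate(self) -> np.ndarray:
        return self.in_max <= self.in_min

    @property
    def out_degenerate(self) -> np.ndarray:
        return self.out_max <= self.out_min

    def to_dict(self) -> dict:
        return {
            "in_min": self.in_min.tolist(), "in_max": self.in_max.tolist(),
            "out_min": self.out_min.tolist(), "out_max": self.out_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingRecord":
        return cls(*(np.asarray(d[k], dtype=float)
                     for k in ("in_min", "in_max", "out_min", "out_max")))


def fit_scaling(ds: Dataset) -> ScalingRecord:
    """Column-wise min/max over the dataset (outcomes: observed cells only)."""
    out_min = np.full(N_OUTCOMES, np.nan)
    out_max = np.full(N_OUTCOMES, np.nan)
    for k in range(N_OUTCOMES):
        vals = ds.Y[ds.mask[:, k], k]
        if vals.size:
            out_min[k], out_max[k] = vals.min(), vals.max()
        else:  # never observed: treat as degenerate at 0
            out_min[k] = out_max[k] = 0.0
    return ScalingRecord(ds.X.min(axis=0), ds.X.max(axis=0), out_min, out_max)


def _forward(values: np.ndarray, lo: np.ndarray, hi: np.ndarray,
             clip: bool) -> np.ndarray:
    span = hi - lo
    degenerate = span <= 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (values - lo) / safe_span
    scaled = np.where(degenerate, 0.0, scaled)
    if clip:
        out_of_range = (scaled < 0) | (scaled > 1)
        if np.any(out_of_range & np.isfinite(scaled)):
            logger.warning("clipped %d out-of-range value(s) under reused scaling",
                           int(np.sum(out_of_range & np.isfinite(scaled))))
        scaled = np.clip(scaled, 0.0, 1.0)
    return scaled


def scale_inputs(X: np.ndarray, record: ScalingRecord, clip: bool = True) -> np.ndarray:
    return _forward(np.asarray(X, dtype=float), record.in_min, record.in_max, clip)


def scale_outputs(Y: np.ndarray, record: ScalingRecord, clip: bool = True) -> np.ndarray:
    return _forward(np.asarray(Y, dtype=float), record.out_min, record.out_max, clip)


def invert_outputs(Y_scaled: np.ndarray, record: ScalingRecord) -> np.ndarray:
    return record.out_min + np.asarray(Y_scaled) * (record.out_max - record.out_min)


def invert_inputs(X_scaled: np.ndarray, record: ScalingRecord) -> np.ndarray:
    return record.in_min + np.asarray(X_scaled) * (record.in_max - record.in_min)


def apply_scaling(ds: Dataset, record: ScalingRecord, clip: bool = True) -> Dataset:
    """Return the dataset with all columns mapped to the unit interval.

    With ``clip`` (the default for records reused on new data), values
    outside the fitted range are clipped to [0, 1] with a logged
    warning. Masks are preserved; masked-out cells stay NaN.
    """
    Xs = scale_inputs(ds.X, record, clip)
    # fill masked-out cells with the column minimum before scaling so they
    # cannot trigger spurious out-of-range warnings; they are re-masked after
    filled = np.where(ds.mask, ds.Y, record.out_min)
    Ys = np.where(ds.mask, scale_outputs(filled, record, clip), np.nan)
    return replace(ds, X=Xs, Y=Ys, mask=ds.mask.copy(),
                   source_ids=ds.source_ids)
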