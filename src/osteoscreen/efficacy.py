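"""Composite efficacy score, ranking, extremes tables and correlations.

Seventeen of the 26 predicted outcomes summarise bone healing well
enough to enter a single relative efficacy number: 12 where higher is
better (fusion and formation rates, functional indices) and 5 where
lower is better (times to union/weight-bearing, re-grafting, failure
and dynamization). Each selected outcome is min-max normalized across
the screened combination set, lower-is-better outcomes are flipped as
``1 - normalized``, and the 17 processed values are averaged. A score
of 1 would require every outcome to sit at its best value attained
anywhere in the screen; 0 the worst.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Outcomes where a high predicted value indicates good healing.
POSITIVE_OUTCOMES: tuple[str, ...] = (
    "DR", "BF3", "BF6", "MV/TV", "PLF-FR", "ODI", "FR", "FH", "OW",
    "RO", "HO", "IS")

#: Outcomes where a high predicted value indicates poor healing (flipped).
NEGATIVE_OUTCOMES: tuple[str, ...] = ("TWB/CH", "TRU", "RBG", "NH", "DY")


@dataclass(frozen=True)
class EfficacyConfig:
    positive_outcomes: tuple[str, ...] = POSITIVE_OUTCOMES
    negative_outcomes: tuple[str, ...] = NEGATIVE_OUTCOMES

    def __post_init__(self) -> None:
        overlap = set(self.positive_outcomes) & set(self.negative_outcomes)
        if overlap:
            raise ValueError(f"outcome(s) listed in both directions: {overlap}")

    @property
    def selected(self) -> tuple[str, ...]:
        return self.positive_outcomes + self.negative_outcomes


def normalized_outcomes(outputs: np.ndarray, outcome_names: tuple[str, ...],
                        config: EfficacyConfig = EfficacyConfig()) -> pd.DataFrame:
    """Direction-corrected, min-max normalized selected outcomes.

    Normalization is relative to the maximal and minimal values across
    the supplied result set, so each selected column attains both 0 and
    1. Zero-range columns are logged and set to 0.
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[0] < 1:
        raise ValueError("need at least one result row")
    cols = {}
    for name in config.selected:
        k = outcome_names.index(name)
        col = outputs[:, k]
        span = col.max() - col.min()
        if span <= 0:
            logger.info("degenerate outcome column %s (zero range); scored 0", name)
            norm = np.zeros_like(col)
        else:
            norm = (col - col.min()) / span
        if name in config.negative_outcomes:
            norm = 1.0 - norm if span > 0 else norm
        cols[name] = norm
    return pd.DataFrame(cols)


def efficacy_scores(outputs: np.ndarray, outcome_names: tuple[str, ...],
                    config: EfficacyConfig = EfficacyConfig()) -> np.ndarray:
    """Composite score per row: mean of the 17 processed outcome columns."""
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[0] < 2:
        raise ValueError("normalization needs at least two result rows")
    return normalized_outcomes(outputs, outcome_names, config).mean(axis=1).to_numpy()


def rank_combinations(combos: pd.DataFrame, scores: np.ndarray) -> pd.DataFrame:
    """Attach scores, sort descending and assign ranks 1..N.

    Ties keep the (lexicographic) enumeration order — the sort is
    stable — so ranking is deterministic and idempotent.
    """
    out = combos.reset_index(drop=True).copy()
    out["efficacy"] = np.asarray(scores, dtype=float)
    order = np.argsort(-out["efficacy"].to_numpy(), kind="stable")
    out = out.iloc[order].reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def top_bottom_tables(ranked: pd.DataFrame, k: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The k best and k worst ranked combinations with their factor levels."""
    if k > len(ranked) // 2:
        raise ValueError("k may not exceed half the number of combinations")
    return ranked.head(k).copy(), ranked.tail(k).copy()


def pairwise_correlations(ranked: pd.DataFrame, top_k: int,
                          factor_names: tuple[str, ...] | None = None,
                          alpha: float | None = None,
                          bonferroni: bool = False) -> pd.DataFrame:
    """Pearson correlations between factor levels over the top-k rows.

    p-values are the two-sided t-approximation with n-2 degrees of
    freedom (t = r * sqrt((n-2) / (1-r^2))). Constant factors (e.g. the
    always-present vehicle) have undefined correlation and are reported
    as NaN. With ``alpha`` set, only pairs with p < alpha are returned
    (Bonferroni-adjusted across the tested pairs when requested).
    Values are rounded to 4 decimal places in the returned table.
    """
    if top_k < 3:
        raise ValueError("need at least 3 rows for a correlation")
    if top_k > len(ranked):
        raise ValueError("top_k exceeds the number of ranked combinations")
    if factor_names is None:
        factor_names = tuple(c for c in ranked.columns
                             if c not in ("rank", "efficacy"))
    top = ranked.head(top_k)
    rows = []
    pairs = list(itertools.combinations(factor_names, 2))
    for a, b in pairs:
        x = top[a].to_numpy(dtype=float)
        y = top[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = np.nan, np.nan
        else:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({"factor_1": a, "factor_2": b,
                     "correlation": np.round(r, 4), "p_value": np.round(p, 4),
                     "n": top_k})
    table = pd.DataFrame(rows)
    if alpha is not None:
        cut = alpha / len(pairs) if bonferroni else alpha
        table = table[table["p_value"] < cut].reset_index(drop=True)
    return table


def correlation_matrix(table: pd.DataFrame,
                       factor_names: tuple[str, ...]) -> pd.DataFrame:
    """Symmetric, unit-diagonal matrix view of a pairwise table."""
    m = pd.DataFrame(np.eye(len(factor_names)),
                     index=list(factor_names), columns=list(factor_names))
    for _, row in table.iterrows():
        m.loc[row["factor_1"], row["factor_2"]] = row["correlation"]
        m.loc[row["factor_2"], row["factor_1"]] = row["correlation"]
    return m
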