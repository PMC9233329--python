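"""Indicative 0-1 anchored preference weight sets for capability states.

The weight set turns the 16 mean relative importance scores into a 16 x 5
matrix of level weights: item k's weight span is RIS_k / 100 and the five
answer levels carry multiplication factors 0, 0.25, 0.5, 0.75, 1 from worst
to best capability (the proportional-level assumption).  For reverse-coded
items answer level 1 is the best capability, so the factors run 1 down to 0.
A capability state is scored by summing its level weights; with scores that
sum to 100 the scale is anchored at 0 (no capability on any item) and ~1
(full capability on every item).

The equal-weight comparator is the instrument's standard sum score: levels
re-oriented so higher is better, summed, and standardised by
100 * (raw - min) / range, i.e. 100 * (raw - 16) / 64 for the OxCAP-MH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import DEFAULT_SPEC, InstrumentSpec

__all__ = [
    "DEFAULT_LEVEL_FACTORS",
    "WeightSet",
    "build_weight_set",
    "score_state",
    "equal_weight_score",
    "weight_set_frame",
    "weight_set_from_frame",
]

#: Multiplication factors for answer levels from worst to best capability.
#: The proportional spacing is a working assumption, exposed as configuration.
DEFAULT_LEVEL_FACTORS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class WeightSet:
    """Per-item, per-level preference weights anchored 0-1.

    ``weights[k, l]`` is the weight of answer level l+1 on item k+1, at full
    precision; exports round to 4 decimals.  Each row spans 0 to
    ris_mean_k / 100 and is equally spaced under the default factors.
    """

    weights: np.ndarray
    spec: InstrumentSpec
    level_factors: tuple[float, ...] = DEFAULT_LEVEL_FACTORS

    @property
    def n_items(self) -> int:
        return self.weights.shape[0]

    def rounded(self, decimals: int = 4) -> np.ndarray:
        return np.round(self.weights, decimals)


def build_weight_set(
    ris_mean: np.ndarray,
    spec: InstrumentSpec = DEFAULT_SPEC,
    level_factors: tuple[float, ...] = DEFAULT_LEVEL_FACTORS,
) -> WeightSet:
    """Scale mean RIS values into the anchored level-weight matrix.

    For non-reversed items answer level 1 carries factor 0 and level
    ``n_levels`` factor 1; reverse-coded items run the factors the other way
    (their level 1 is the best capability).  Computation stays at full
    precision; round only on export.
    """
    ris = np.asarray(ris_mean, dtype=float)
    if ris.shape != (spec.n_items,):
        raise ValueError(
            f"expected {spec.n_items} mean RIS values, got shape {ris.shape}"
        )
    if np.any(ris < 0):
        raise ValueError("mean RIS values must be non-negative")
    if len(level_factors) != spec.n_levels:
        raise ValueError(
            f"need {spec.n_levels} level factors, got {len(level_factors)}"
        )
    fwd = np.asarray(level_factors, dtype=float)
    w = np.empty((spec.n_items, spec.n_levels))
    for k in range(1, spec.n_items + 1):
        factors = fwd[::-1] if spec.is_reversed(k) else fwd
        w[k - 1] = ris[k - 1] / 100.0 * factors
    return WeightSet(weights=w, spec=spec, level_factors=tuple(level_factors))


def _check_levels(levels: np.ndarray, spec: InstrumentSpec) -> np.ndarray:
    levels = np.asarray(levels)
    if levels.shape != (spec.n_items,):
        raise ValueError(f"expected {spec.n_items} answer levels")
    bad = np.flatnonzero((levels < 1) | (levels > spec.n_levels))
    if len(bad):
        raise ValueError(
            f"answer level out of range 1..{spec.n_levels} for item(s) "
            f"{[int(k) for k in bad + 1]}"
        )
    return levels.astype(int)


def score_state(levels: np.ndarray, weights: WeightSet) -> float:
    """Preference-weighted score of one capability state (16 answer levels).

    Sum over items of the weight at the answered level.  0 when every item is
    at its worst capability level; the sum of the mean RIS over 100 when every
    item is at its best.
    """
    levels = _check_levels(levels, weights.spec)
    return float(weights.weights[np.arange(weights.n_items), levels - 1].sum())


def equal_weight_score(
    levels: np.ndarray, spec: InstrumentSpec = DEFAULT_SPEC
) -> float:
    """Standardised equal-weight sum score on the 0-100 scale.

    Levels are first re-oriented so that higher always means better
    capability (reverse-coded items flipped); then
    100 * (sum - min_raw) / range.
    """
    levels = _check_levels(levels, spec)
    oriented = spec.orient_levels(levels)
    raw = int(oriented.sum())
    return 100.0 * (raw - spec.min_raw_score) / spec.score_range


def weight_set_frame(ws: WeightSet, decimals: int = 4) -> pd.DataFrame:
    """Export a weight set as the published-style table.

    Columns: item_number, question_number, label, reversed,
    answer_level_1..n; weights rounded to ``decimals``.
    """
    spec = ws.spec
    w = ws.rounded(decimals)
    rows = []
    for k in range(1, spec.n_items + 1):
        row = {
            "item_number": k,
            "question_number": spec.question_numbers[k - 1],
            "label": spec.item_labels[k - 1],
            "reversed": int(spec.is_reversed(k)),
        }
        for lvl in range(1, spec.n_levels + 1):
            row[f"answer_level_{lvl}"] = w[k - 1, lvl - 1]
        rows.append(row)
    return pd.DataFrame(rows)


def weight_set_from_frame(
    frame: pd.DataFrame, spec: InstrumentSpec = DEFAULT_SPEC
) -> WeightSet:
    """Rebuild a weight set from its exported table (at export precision)."""
    frame = frame.sort_values("item_number")
    cols = [f"answer_level_{lvl}" for lvl in range(1, spec.n_levels + 1)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"weight table is missing columns: {missing}")
    w = frame[cols].to_numpy(dtype=float)
    if w.shape != (spec.n_items, spec.n_levels):
        raise ValueError(f"expected a {spec.n_items} x {spec.n_levels} table")
    return WeightSet(weights=w, spec=spec)
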