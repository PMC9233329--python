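"""The OxCAP-MH capability instrument: items, levels, coding and reference scores.

The OxCAP-MH is a 16-item self-reported capability wellbeing questionnaire for
mental health, grounded in the capability approach (Sen/Nussbaum).  Each item is
rated on a 1-5 Likert scale.  Eleven items are reverse coded: for those, answer
level 1 denotes the *highest* level of capability.  Under equal weighting the
total raw score (16..80) is standardised to 0..100.

This module also ships the published Austrian full-cohort mean relative
importance scores (RIS) for the German OxCAP-MH, elicited by an object-case
best-worst scaling survey across psychiatric patients, mental-health experts
and primary-care patients.  They serve as the default preference profile of the
synthetic-cohort generator and as the input of the indicative preference
weight set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_ITEMS = 16
N_LEVELS = 5

#: Items whose answer level 1 represents the highest capability.
REVERSED_ITEMS = frozenset({2, 4, 6, 9, 10, 11, 12, 13, 14, 15, 16})

#: (item number, question number, short label, Nussbaum central capability)
ITEMS = (
    (1, "1", "Limitation in daily activities", "Bodily health"),
    (2, "2", "Social networks", "Affiliation"),
    (3, "3", "Losing sleep over worry", "Emotions"),
    (4, "4", "Enjoying social and recreational activities", "Play"),
    (5, "5", "Having suitable accommodation", "Bodily health"),
    (6, "6", "Feeling safe", "Bodily integrity"),
    (7, "7", "Likelihood of assault", "Bodily integrity"),
    (8, "8", "Likelihood of discrimination", "Affiliation"),
    (9, "9a", "Influencing local decisions", "Control over one's environment"),
    (10, "9b", "Freedom of expression", "Senses, imagination & thought"),
    (11, "9c", "Appreciating nature", "Species"),
    (12, "9d", "Respecting and valuing people", "Affiliation"),
    (13, "9e", "Enjoying friendship and support", "Emotions"),
    (14, "9f", "Self-determination", "Practical reason"),
    (15, "9g", "Imagination and creativity", "Senses, imagination & thought"),
    (16, "9h", "Access to interesting activities or employment",
     "Control over one's environment"),
)

ITEM_LABELS = tuple(label for _, _, label, _ in ITEMS)
QUESTION_NUMBERS = tuple(q for _, q, _, _ in ITEMS)

#: Published Austrian full-cohort mean (and SD of) relative importance scores,
#: one per item in item-number order.  The 16 means sum to 100.01 at the
#: printed 2-decimal precision.
REFERENCE_MEAN_RIS = (
    10.48, 5.89, 2.48, 3.73, 3.85, 4.41, 9.92, 8.71,
    0.76, 6.76, 3.22, 6.89, 9.02, 15.72, 3.47, 4.70,
)
REFERENCE_SD_RIS = (
    7.43, 5.14, 3.84, 4.78, 5.04, 4.97, 6.71, 6.65,
    1.92, 5.75, 4.13, 5.58, 6.10, 4.74, 5.34, 5.03,
)


@dataclass(frozen=True)
class InstrumentSpec:
    """Structural description of a Likert-style capability instrument.

    Defaults describe the OxCAP-MH: 16 items with 5 answer levels each, giving
    5**16 distinct capability states, a minimum raw score of 16 and a range of
    64 for the equal-weight standardised score.
    """

    n_items: int = N_ITEMS
    n_levels: int = N_LEVELS
    reversed_items: frozenset[int] = REVERSED_ITEMS
    item_labels: tuple[str, ...] = ITEM_LABELS
    question_numbers: tuple[str, ...] = QUESTION_NUMBERS

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_levels < 2:
            raise ValueError("need at least one item and two levels")
        bad = [k for k in self.reversed_items if not 1 <= k <= self.n_items]
        if bad:
            raise ValueError(f"reversed item numbers out of range: {bad}")
        if len(self.item_labels) != self.n_items:
            raise ValueError("item_labels length must equal n_items")

    @property
    def min_raw_score(self) -> int:
        return self.n_items

    @property
    def max_raw_score(self) -> int:
        return self.n_items * self.n_levels

    @property
    def score_range(self) -> int:
        return self.max_raw_score - self.min_raw_score

    def is_reversed(self, item: int) -> bool:
        return item in self.reversed_items

    def orient_levels(self, levels: np.ndarray) -> np.ndarray:
        """Re-orient raw answer levels so that higher always means better.

        Reverse-coded items are flipped (level -> n_levels + 1 - level); the
        result is suitable for equal-weight sum scoring.
        """
        levels = np.asarray(levels)
        flipped = self.n_levels + 1 - levels
        rev = np.array([self.is_reversed(k) for k in range(1, self.n_items + 1)])
        return np.where(rev, flipped, levels)


def n_capability_states(n_items: int = N_ITEMS, n_levels: int = N_LEVELS) -> int:
    """Number of distinct capability states the instrument can describe.

    For the OxCAP-MH this is 5**16 = 152,587,890,625 -- far too many for any
    direct state-valuation exercise, which is why item weights are elicited by
    object-case best-worst scaling instead.
    """
    if n_items < 0 or n_levels < 1:
        raise ValueError("n_items must be >= 0 and n_levels >= 1")
    return n_levels ** n_items


DEFAULT_SPEC = InstrumentSpec()
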