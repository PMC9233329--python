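"""Cohort comparisons of item importance: ranks, Kruskal-Wallis tests, correlations.

Rank orders summarise each cohort's mean relative importance scores (1 = most
important).  Differences across cohorts are tested per item with the
Kruskal-Wallis equality-of-populations rank test on individual-level RIS
values, using midranks with the standard tie correction and the chi-square
approximation with (groups - 1) degrees of freedom.  P-values are not
corrected for multiplicity: all 16 tests are always reported.  Between-item
structure is summarised by pairwise Pearson correlations of the respondents'
individual RIS vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConstantColumnWarning",
    "SmallCohortWarning",
    "rank_items",
    "kruskal_wallis_by_cohort",
    "cohort_rank_table",
    "pearson_matrix",
]


class ConstantColumnWarning(UserWarning):
    """A correlation involves a constant column; the coefficient is undefined."""


class SmallCohortWarning(UserWarning):
    """A cohort has fewer than 2 respondents; rank tests are unreliable."""


def rank_items(values: np.ndarray) -> np.ndarray:
    """Descending-value ranks, 1 = largest; ties broken by item index.

    With the index tie-break the result is always a permutation of
    1..n_items.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or not np.all(np.isfinite(values)):
        raise ValueError("rank_items expects a 1-d vector of finite values")
    order = np.lexsort((np.arange(len(values)), -values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def kruskal_wallis_by_cohort(
    ris_individual: np.ndarray, cohorts: np.ndarray
) -> pd.DataFrame:
    """Kruskal-Wallis H and p per item across cohort groups.

    ``ris_individual`` is (n_respondents, n_items); ``cohorts`` a label per
    respondent.  H uses midranks with the tie correction; p comes from the
    chi-square approximation with (n_groups - 1) df.  Emits
    :class:`SmallCohortWarning` when any cohort has fewer than 2 members.
    """
    ris = np.asarray(ris_individual, dtype=float)
    cohorts = np.asarray(cohorts)
    if ris.shape[0] != len(cohorts):
        raise ValueError("cohort labels must align with RIS rows")
    labels = pd.unique(cohorts)
    if len(labels) < 2:
        raise ValueError("need at least 2 cohorts to compare")
    groups_idx = [np.flatnonzero(cohorts == g) for g in labels]
    for g, idx in zip(labels, groups_idx):
        if len(idx) < 2:
            warnings.warn(
                f"cohort {g!r} has {len(idx)} respondent(s); the rank test "
                "is unreliable", SmallCohortWarning, stacklevel=2,
            )
    out = []
    for k in range(ris.shape[1]):
        samples = [ris[idx, k] for idx in groups_idx]
        if np.ptp(np.concatenate(samples)) == 0:
            h, p = 0.0, 1.0  # all values identical: no evidence of difference
        else:
            h, p = stats.kruskal(*samples)
        out.append({"item": k + 1, "H": float(h), "p": float(p)})
    return pd.DataFrame(out)


def cohort_rank_table(
    ris_individual: np.ndarray, cohorts: np.ndarray
) -> pd.DataFrame:
    """Per-cohort mean RIS and rank per item, with the Kruskal-Wallis test.

    Long-format frame: item, cohort, mean_ris, rank, H, p.  Within each
    cohort the ranks are a permutation of 1..n_items.
    """
    ris = np.asarray(ris_individual, dtype=float)
    cohorts = np.asarray(cohorts)
    kw = kruskal_wallis_by_cohort(ris, cohorts)
    rows = []
    for g in pd.unique(cohorts):
        sub = ris[cohorts == g]
        means = sub.mean(axis=0)
        ranks = rank_items(means)
        for k in range(ris.shape[1]):
            rows.append(
                {
                    "item": k + 1,
                    "cohort": g,
                    "mean_ris": means[k],
                    "rank": int(ranks[k]),
                    "H": kw["H"].iloc[k],
                    "p": kw["p"].iloc[k],
                }
            )
    return pd.DataFrame(rows)


def pearson_matrix(ris_individual: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations between items over respondents.

    Returns an (n_items, n_items) symmetric matrix with unit diagonal.
    Constant columns make the coefficient undefined: those entries are NaN
    and a :class:`ConstantColumnWarning` names the items rather than silently
    zeroing them.
    """
    x = np.asarray(ris_individual, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need at least 3 respondents (rows) for correlations")
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if len(constant):
        warnings.warn(
            f"items {[int(k) for k in constant + 1]} have constant scores; their "
            "correlations are undefined (NaN)",
            ConstantColumnWarning, stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.asarray(c, dtype=float)
    np.fill_diagonal(c, 1.0)
    if len(constant):
        c[constant, :] = np.nan
        c[:, constant] = np.nan
        for k in constant:
            c[k, k] = np.nan
    c = (c + c.T) / 2.0  # exact symmetry against floating-point asymmetry
    return c
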