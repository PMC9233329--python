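"""Per-item regressions of importance scores with jackknife-robust variances.

Each item's continuous relative importance score is regressed on a male
indicator and two cohort indicators (psychiatric and expert, with female and
the general/primary-care population as reference categories) plus an
intercept, by ordinary least squares.  Because the 16 outcomes are estimated
quantities with implicit cross-item correlation, model-based OLS standard
errors are not trusted; instead each participant is omitted in turn, the
utilities are re-estimated, the 16 regressions are re-fitted, and the robust
variance of every coefficient is the jackknife formula

    v_kj = (n - 1) / n * sum_i (beta_kj^(-i) - beta_kj)^2

with s_kj = sqrt(v_kj), t = beta_kj / s_kj and two-sided p-values from a
t-distribution with n - J - 1 degrees of freedom, J being the number of
regression coefficients (four).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COEFFICIENT_NAMES",
    "JackknifeResult",
    "build_covariate_matrix",
    "fit_item_regressions",
    "jackknife_robust",
    "identity_pipeline",
    "hb_ris_pipeline",
    "significance_table",
]

#: Column order of the reported coefficients (reference: female, general
#: population cohort).
COEFFICIENT_NAMES = (
    "male_vs_female",
    "psychiatric_vs_general",
    "expert_vs_general",
    "constant",
)


def build_covariate_matrix(
    covariates: pd.DataFrame,
    reference_cohort: str = "general",
    psychiatric_cohort: str = "psychiatric",
    expert_cohort: str = "expert",
) -> np.ndarray:
    """Design matrix in the reported column order from a covariate table.

    ``covariates`` needs columns ``gender`` (male/female) and ``cohort``.
    Columns: male indicator, psychiatric indicator, expert indicator,
    intercept.
    """
    gender = covariates["gender"].to_numpy()
    cohort = covariates["cohort"].to_numpy()
    known = {reference_cohort, psychiatric_cohort, expert_cohort}
    unknown = set(cohort) - known
    if unknown:
        raise ValueError(f"unknown cohort labels: {sorted(unknown)}")
    x = np.column_stack(
        [
            (gender == "male").astype(float),
            (cohort == psychiatric_cohort).astype(float),
            (cohort == expert_cohort).astype(float),
            np.ones(len(covariates)),
        ]
    )
    return x


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients with an explicit singularity diagnosis.

    ``y`` may hold one outcome per column; returns (J, n_outcomes) or (J,).
    """
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the dependent columns via pivoted QR on the transpose trick
        _, r = np.linalg.qr(x)
        dep = [
            COEFFICIENT_NAMES[j] if j < len(COEFFICIENT_NAMES) else f"col{j}"
            for j in range(x.shape[1])
            if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} of {x.shape[1]}); "
            f"collinear columns: {dep or 'undetermined'}"
        )
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def fit_item_regressions(
    ris_individual: np.ndarray, covariates: pd.DataFrame, **kwargs
) -> np.ndarray:
    """OLS coefficients per item: (n_items, 4) in the reported column order.

    Rows of ``ris_individual`` must align with ``covariates`` rows.
    """
    y = np.asarray(ris_individual, dtype=float)
    if y.shape[0] != len(covariates):
        raise ValueError("RIS rows and covariate rows must align")
    x = build_covariate_matrix(covariates, **kwargs)
    return _ols(x, y).T


@dataclass(frozen=True)
class JackknifeResult:
    """Full-sample coefficients with jackknife-robust inference.

    beta_hat: (n_items, J) full-sample coefficients.
    beta_loo: (n, n_items, J) leave-one-out coefficients, one slice per
        omitted participant.
    v_hat / s_hat: robust variances and standard errors, (n_items, J).
    t_stat / p_value: Wald statistics against a t(n - J - 1) reference.
    """

    beta_hat: np.ndarray
    beta_loo: np.ndarray
    v_hat: np.ndarray
    s_hat: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    n: int
    df: int


def identity_pipeline(ris_individual: np.ndarray) -> Callable:
    """Pipeline stub that returns the observed scores unchanged.

    Replaces the utility re-estimation stage when the scores are taken as
    data; the jackknife then reduces to delete-one OLS refits.
    """
    ris = np.asarray(ris_individual, dtype=float)

    def pipeline(keep_mask: np.ndarray) -> np.ndarray:
        return ris[keep_mask]

    return pipeline


def hb_ris_pipeline(responses, config) -> Callable:
    """Pipeline that re-estimates utilities and RIS on each leave-one-out set.

    Each replicate re-runs the hierarchical Bayes fit on the retained
    respondents with the same MCMC profile and seed, then recomputes the
    individual RIS.  A reduced profile keeps n replicates affordable; the
    profile travels with the result metadata via ``config``.
    """
    from .hb import compute_ris, fit_hb
    from .cohorts import ResponseSet

    def pipeline(keep_mask: np.ndarray) -> np.ndarray:
        resp = responses.respondents.reset_index(drop=True)
        kept = resp[keep_mask]
        ids = set(kept["respondent_id"].tolist())
        sub = ResponseSet(
            respondents=kept.reset_index(drop=True),
            responses=responses.responses[
                responses.responses["respondent_id"].isin(ids)
            ].reset_index(drop=True),
            design=responses.design,
        )
        post = fit_hb(sub, config=config)
        return compute_ris(post).ris_individual

    return pipeline


def jackknife_robust(
    pipeline: Callable,
    covariates: pd.DataFrame,
    checkpoint: "str | None" = None,
    **kwargs,
) -> JackknifeResult:
    """Jackknife-robust variances by leave-one-participant-out re-estimation.

    ``pipeline(keep_mask)`` must return the (n_kept, n_items) score matrix for
    the respondents flagged True, re-running whatever estimation precedes the
    regressions; determinism of the pipeline makes the whole procedure
    deterministic.  Exactly n replicates are run, one per omitted participant.

    ``checkpoint`` names a CSV file persisting each finished replicate's
    coefficients; if a replicate raises, completed replicates survive there
    and a rerun with the same arguments resumes after them.
    """
    n = len(covariates)
    x_full = build_covariate_matrix(covariates, **kwargs)
    j = x_full.shape[1]
    if n < j + 2:
        raise ValueError(f"need at least J + 2 = {j + 2} participants, got {n}")
    full_mask = np.ones(n, dtype=bool)
    ris_full = np.asarray(pipeline(full_mask), dtype=float)
    if ris_full.shape[0] != n:
        raise ValueError("pipeline must return one score row per kept participant")
    beta_hat = _ols(x_full, ris_full).T  # (n_items, J)
    n_items = beta_hat.shape[0]

    import os

    done: dict[int, np.ndarray] = {}
    if checkpoint is not None:
        if os.path.exists(checkpoint):
            saved = pd.read_csv(checkpoint)
            for i, group in saved.groupby("replicate"):
                done[int(i)] = group.sort_values(["item", "coef"])[
                    "value"
                ].to_numpy().reshape(n_items, j)

    beta_loo = np.empty((n, n_items, j))
    for i in range(n):
        if i in done:
            beta_loo[i] = done[i]
            continue
        mask = full_mask.copy()
        mask[i] = False
        try:
            ris_i = np.asarray(pipeline(mask), dtype=float)
            beta_loo[i] = _ols(x_full[mask], ris_i).T
        except Exception as exc:
            raise RuntimeError(
                f"leave-one-out replicate {i} (omitting participant "
                f"{covariates.iloc[i].get('respondent_id', i)}) failed: {exc}; "
                + (f"completed replicates persisted in {checkpoint}"
                   if checkpoint else "no checkpoint file was configured")
            ) from exc
        if checkpoint is not None:
            rows = pd.DataFrame(
                {
                    "replicate": i,
                    "item": np.repeat(np.arange(n_items), j),
                    "coef": np.tile(np.arange(j), n_items),
                    "value": beta_loo[i].ravel(),
                }
            )
            rows.to_csv(checkpoint, mode="a", index=False,
                        header=not os.path.exists(checkpoint))
            done[i] = beta_loo[i]

    dev = beta_loo - beta_hat[None, :, :]
    v_hat = (n - 1) / n * np.sum(dev ** 2, axis=0)
    s_hat = np.sqrt(v_hat)
    df = n - j - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(s_hat > 0, beta_hat / s_hat, np.inf * np.sign(beta_hat))
        t_stat = np.where((s_hat == 0) & (beta_hat == 0), 0.0, t_stat)
    p_value = 2 * stats.t.sf(np.abs(t_stat), df=df)
    return JackknifeResult(
        beta_hat=beta_hat,
        beta_loo=beta_loo,
        v_hat=v_hat,
        s_hat=s_hat,
        t_stat=t_stat,
        p_value=p_value,
        n=n,
        df=df,
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def significance_table(
    result: JackknifeResult,
    ris_individual: np.ndarray,
    item_labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Coefficient table with robust SEs and star annotations.

    One row per item: mean (SD) of the score, then per covariate the
    estimate, robust SE, t, p and stars at p < 0.05 / 0.01 / 0.001 (no
    multiplicity correction).
    """
    ris = np.asarray(ris_individual, dtype=float)
    n_items = result.beta_hat.shape[0]
    rows = []
    for k in range(n_items):
        row = {
            "item": k + 1,
            "label": item_labels[k] if item_labels else f"item_{k + 1}",
            "ris_mean": ris[:, k].mean(),
            "ris_sd": ris[:, k].std(ddof=1),
        }
        for jx, name in enumerate(COEFFICIENT_NAMES):
            row[f"{name}_estimate"] = result.beta_hat[k, jx]
            row[f"{name}_robust_se"] = result.s_hat[k, jx]
            row[f"{name}_t"] = result.t_stat[k, jx]
            row[f"{name}_p"] = result.p_value[k, jx]
            row[f"{name}_stars"] = _stars(result.p_value[k, jx])
        rows.append(row)
    return pd.DataFrame(rows)
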