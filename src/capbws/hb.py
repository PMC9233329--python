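"""Hierarchical Bayes estimation of individual utilities from best-worst choices.

Model.  Respondent i holds a latent utility vector beta_i over the n_items
attributes.  In a task showing set S, the probability of picking item j as
most important is the multinomial logit exp(beta_ij) / sum_{l in S}
exp(beta_il); the least-important pick is then drawn from S minus the best
item with utilities negated (sequential best-then-worst MaxDiff).  The upper
level ties respondents together: beta_i ~ MVN(mu, Sigma) with conjugate
priors mu ~ N(0, 100 I) and Sigma ~ Inverse-Wishart(n_items + 2, I).

Sampling.  (mu, Sigma) are updated by Gibbs steps exploiting normal /
inverse-Wishart conjugacy; each beta_i by a random-walk Metropolis step with
a Sigma-shaped proposal whose scalar step size adapts towards an acceptance
rate of 0.3 during burn-in.  The likelihood is invariant to a constant shift
of beta_i, so reported posterior means are re-centred to the sum-zero
identification used throughout the package.

Fit and scores.  The root likelihood (RLH) is the geometric mean of a
respondent's 2 x n_tasks modelled choice probabilities at the posterior-mean
utilities; the chance level for 6-option tasks is sqrt(1/6 * 1/5) = 1/sqrt(30)
~ 0.183, and respondents below 0.2 are flagged as inconsistent.  Relative
importance scores (RIS) rescale utilities to choice probabilities against
set_size - 1 average competitors, p_k = exp(beta_k) / (exp(beta_k) +
set_size - 1), normalised so each respondent's 16 scores sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import invwishart

from .cohorts import ResponseSet, ris_from_betas
from .design import Design

__all__ = [
    "McmcConfig",
    "Posterior",
    "RISTable",
    "CHANCE_RLH_6",
    "chance_rlh",
    "fit_hb",
    "compute_rlh",
    "filter_inconsistent",
    "compute_ris",
]


def chance_rlh(set_size: int) -> float:
    """RLH of a purely random responder: sqrt(1/k * 1/(k-1)) for k-option tasks."""
    return float(np.sqrt(1.0 / (set_size * (set_size - 1))))


#: Chance-level RLH for the study's 6-attribute tasks, 1/sqrt(30).
CHANCE_RLH_6 = chance_rlh(6)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults (10,000 burn-in, 10,000 kept draws, thinning 10) suit a final
    analysis; :meth:`reduced` returns the short profile used for tests,
    leave-one-out replicates and quick exploration.
    """

    n_burn: int = 10_000
    n_keep: int = 10_000
    thinning: int = 10
    prior_variance: float = 100.0
    df_prior_extra: int = 2
    proposal_scale: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_burn, self.n_keep, self.thinning) < 1:
            raise ValueError("n_burn, n_keep and thinning must be positive")
        if self.proposal_scale <= 0 or self.prior_variance <= 0:
            raise ValueError("proposal_scale and prior_variance must be positive")

    @classmethod
    def reduced(cls, seed: int | None = None) -> "McmcConfig":
        return cls(n_burn=400, n_keep=400, thinning=1, seed=seed)

    def with_seed(self, seed: int | None) -> "McmcConfig":
        return McmcConfig(
            n_burn=self.n_burn,
            n_keep=self.n_keep,
            thinning=self.thinning,
            prior_variance=self.prior_variance,
            df_prior_extra=self.df_prior_extra,
            proposal_scale=self.proposal_scale,
            seed=seed,
        )


@dataclass(frozen=True)
class Posterior:
    """Posterior summaries of the hierarchical MaxDiff model.

    beta_mean: (n_respondents, n_items) posterior-mean utilities, re-centred
        to sum zero per respondent.
    mu_draws / sigma_draws: retained draws of the population mean and
        covariance.
    rlh: per-respondent root likelihood at beta_mean, in (0, 1].
    acceptance_rate: per-respondent Metropolis acceptance over kept sweeps.
    respondents: covariate table aligned with beta_mean rows.
    """

    beta_mean: np.ndarray
    mu_draws: np.ndarray
    sigma_draws: np.ndarray
    rlh: np.ndarray
    acceptance_rate: np.ndarray
    respondents: pd.DataFrame
    set_size: int
    config: McmcConfig

    @property
    def n_respondents(self) -> int:
        return self.beta_mean.shape[0]

    @property
    def n_items(self) -> int:
        return self.beta_mean.shape[1]

    @property
    def mu_mean(self) -> np.ndarray:
        return self.mu_draws.mean(axis=0)

    @property
    def mu_sd(self) -> np.ndarray:
        return self.mu_draws.std(axis=0, ddof=1)

    def mu_effective_sample_size(self) -> np.ndarray:
        """Per-item effective sample size of the retained population-mean draws."""
        import arviz as az

        dataset = az.convert_to_dataset(self.mu_draws[None, ...])
        return np.asarray(az.ess(dataset).to_array()).reshape(-1)


@dataclass(frozen=True)
class RISTable:
    """Relative importance scores, individual and aggregated.

    ris_individual: (n_included, n_items) scores, each row summing to 100.
    summary: per-item DataFrame with mean, SD and dense rank (1 = most
        important, ties broken by item number).
    respondent_ids: ids of the included respondents, aligned with rows.
    """

    ris_individual: np.ndarray
    summary: pd.DataFrame
    respondent_ids: np.ndarray

    @property
    def ris_mean(self) -> np.ndarray:
        return self.summary["ris_mean"].to_numpy()

    @property
    def rank(self) -> np.ndarray:
        return self.summary["rank"].to_numpy()


def _index_responses(responses: ResponseSet):
    """Pack responses into integer arrays for vectorised likelihoods.

    Returns shown (n, T, k) 0-based item indices, best_pos and worst_pos
    (n, T) positions into the shown sets.
    """
    design = responses.design
    n_tasks, set_size = design.n_tasks, design.set_size
    resp = responses.respondents
    n = len(resp)
    shown = np.empty((n, n_tasks, set_size), dtype=np.int64)
    best_pos = np.empty((n, n_tasks), dtype=np.int64)
    worst_pos = np.empty((n, n_tasks), dtype=np.int64)
    by_resp = dict(iter(responses.responses.groupby("respondent_id")))
    for i, (rid, version) in enumerate(zip(resp["respondent_id"], resp["version"])):
        tasks = design.tasks(int(version))
        rows = by_resp.get(rid)
        if rows is None or len(rows) != n_tasks:
            got = 0 if rows is None else len(rows)
            raise ValueError(
                f"respondent {rid} has {got} of {n_tasks} tasks; incomplete "
                "respondents must be excluded before fitting"
            )
        rows = rows.sort_values("task")
        if not np.array_equal(rows["task"].to_numpy(), np.arange(1, n_tasks + 1)):
            raise ValueError(f"respondent {rid}: task numbers must be 1..{n_tasks}")
        shown[i] = tasks - 1
        for t, (best, worst) in enumerate(
            zip(rows["best_item"].to_numpy(), rows["worst_item"].to_numpy())
        ):
            row = tasks[t]
            bw = np.flatnonzero(row == best)
            ww = np.flatnonzero(row == worst)
            if len(bw) != 1 or len(ww) != 1:
                raise ValueError(
                    f"respondent {rid}, task {t + 1}: picked item not in shown set"
                )
            if best == worst:
                raise ValueError(
                    f"respondent {rid}, task {t + 1}: best equals worst"
                )
            best_pos[i, t] = bw[0]
            worst_pos[i, t] = ww[0]
    return shown, best_pos, worst_pos


def _loglik_all(beta, shown, best_pos, worst_pos):
    """Per-respondent log likelihood of the sequential best-worst MNL.

    beta: (n, n_items); returns (n,) summed over tasks.
    """
    n, n_tasks, set_size = shown.shape
    B = np.take_along_axis(
        beta[:, None, :], shown, axis=2
    )  # (n, T, k) utilities of shown items
    lse_best = logsumexp(B, axis=2)
    b_best = np.take_along_axis(B, best_pos[..., None], axis=2)[..., 0]
    ll_best = b_best - lse_best
    M = -B.copy()
    np.put_along_axis(M, best_pos[..., None], -np.inf, axis=2)
    lse_worst = logsumexp(M, axis=2)
    b_worst = np.take_along_axis(M, worst_pos[..., None], axis=2)[..., 0]
    ll_worst = b_worst - lse_worst
    return (ll_best + ll_worst).sum(axis=1)


def fit_hb(responses: ResponseSet, design: Design | None = None,
           config: McmcConfig | None = None) -> Posterior:
    """Fit the hierarchical best-worst MNL by Gibbs-within-Metropolis MCMC.

    ``design`` defaults to the one carried by ``responses`` (passing a
    different one re-indexes the responses against it).  Deterministic for a
    fixed ``config.seed``.
    """
    if design is not None and design is not responses.design:
        responses = ResponseSet(
            respondents=responses.respondents,
            responses=responses.responses,
            design=design,
        )
    config = config or McmcConfig()
    design = responses.design
    n_items = design.n_items
    shown, best_pos, worst_pos = _index_responses(responses)
    n = shown.shape[0]
    rng = np.random.default_rng(config.seed)

    beta = np.zeros((n, n_items))
    mu = np.zeros(n_items)
    sigma = np.eye(n_items)
    step = np.full(n, config.proposal_scale)
    df0 = n_items + config.df_prior_extra
    s0 = np.eye(n_items)
    prior_prec_mu = 1.0 / config.prior_variance

    ll = _loglik_all(beta, shown, best_pos, worst_pos)
    n_iter = config.n_burn + config.n_keep
    kept = 0
    beta_sum = np.zeros_like(beta)
    mu_draws = np.empty((config.n_keep // config.thinning +
                         (config.n_keep % config.thinning > 0), n_items))
    sigma_draws = np.empty((mu_draws.shape[0], n_items, n_items))
    n_kept_draws = 0
    accept_count = np.zeros(n)

    for it in range(n_iter):
        # --- Gibbs: mu | beta, Sigma  (conjugate normal update)
        sigma_inv = np.linalg.inv(sigma)
        post_prec = n * sigma_inv + prior_prec_mu * np.eye(n_items)
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (sigma_inv @ beta.sum(axis=0))
        mu = rng.multivariate_normal(post_mean, post_cov, method="cholesky")

        # --- Gibbs: Sigma | beta, mu  (inverse-Wishart update)
        dev = beta - mu
        scale_post = s0 + dev.T @ dev
        sigma = invwishart.rvs(df=df0 + n, scale=scale_post, random_state=rng)

        # --- Metropolis: beta_i | mu, Sigma, data  (Sigma-shaped random walk)
        chol = np.linalg.cholesky(sigma)
        prop = beta + step[:, None] * (rng.standard_normal((n, n_items)) @ chol.T)
        ll_prop = _loglik_all(prop, shown, best_pos, worst_pos)
        sigma_inv = np.linalg.inv(sigma)
        dev_old = beta - mu
        dev_new = prop - mu
        lp_old = -0.5 * np.einsum("ij,jk,ik->i", dev_old, sigma_inv, dev_old)
        lp_new = -0.5 * np.einsum("ij,jk,ik->i", dev_new, sigma_inv, dev_new)
        log_alpha = (ll_prop + lp_new) - (ll + lp_old)
        accept = np.log(rng.random(n)) < log_alpha
        beta[accept] = prop[accept]
        ll[accept] = ll_prop[accept]

        if it < config.n_burn:
            # multiplicative adaptation; factors chosen so the equilibrium
            # acceptance rate ln(down)/ln(down/up) is 0.3
            step *= np.where(accept, 1.0483, 0.98)
            np.clip(step, 1e-3, 10.0, out=step)
        else:
            accept_count += accept
            beta_sum += beta
            kept += 1
            if (it - config.n_burn) % config.thinning == 0:
                mu_draws[n_kept_draws] = mu
                sigma_draws[n_kept_draws] = sigma
                n_kept_draws += 1

    beta_mean = beta_sum / kept
    beta_mean -= beta_mean.mean(axis=1, keepdims=True)
    ll_mean = _loglik_all(beta_mean, shown, best_pos, worst_pos)
    rlh = np.exp(ll_mean / (2 * design.n_tasks))
    return Posterior(
        beta_mean=beta_mean,
        mu_draws=mu_draws[:n_kept_draws],
        sigma_draws=sigma_draws[:n_kept_draws],
        rlh=rlh,
        acceptance_rate=accept_count / kept,
        respondents=responses.respondents.reset_index(drop=True),
        set_size=design.set_size,
        config=config,
    )


def compute_rlh(beta: np.ndarray, respondent_responses: pd.DataFrame,
                design: Design, version: int) -> float:
    """Root likelihood of one respondent's choices at the supplied utilities.

    Geometric mean of the 2 * n_tasks modelled choice probabilities (one best
    and one worst pick per task), evaluated in the log domain so that extreme
    utilities underflow gracefully rather than to a literal zero.
    """
    beta = np.asarray(beta, dtype=float)
    tasks = design.tasks(version)
    rows = respondent_responses.sort_values("task")
    if len(rows) != design.n_tasks:
        raise ValueError(
            f"expected {design.n_tasks} tasks, got {len(rows)}: "
            "the respondent's response set is incomplete"
        )
    total = 0.0
    for t, (best, worst) in enumerate(
        zip(rows["best_item"].to_numpy(), rows["worst_item"].to_numpy())
    ):
        shown = tasks[t]
        u = beta[shown - 1]
        b_idx = np.flatnonzero(shown == best)
        w_idx = np.flatnonzero(shown == worst)
        if len(b_idx) != 1 or len(w_idx) != 1 or best == worst:
            raise ValueError(f"task {t + 1}: invalid best/worst picks")
        total += u[b_idx[0]] - logsumexp(u)
        m = np.delete(-u, b_idx[0])
        w_in_m = -u[w_idx[0]]
        total += w_in_m - logsumexp(m)
    return float(np.exp(total / (2 * design.n_tasks)))


def filter_inconsistent(posterior: Posterior, threshold: float = 0.2):
    """Partition respondents by the RLH exclusion rule.

    A respondent is excluded iff rlh < threshold (strictly below; a fit
    statistic exactly at the threshold is retained).  Returns (included_ids,
    excluded_ids) as arrays of respondent ids.
    """
    ids = posterior.respondents["respondent_id"].to_numpy()
    excluded = posterior.rlh < threshold
    return ids[~excluded], ids[excluded]


def compute_ris(posterior: Posterior, set_size: int | None = None,
                include_ids: np.ndarray | None = None) -> RISTable:
    """Relative importance scores from posterior-mean utilities.

    Per respondent, p_k = exp(beta_k) / (exp(beta_k) + set_size - 1) and
    RIS_k = 100 p_k / sum_j p_j.  Utilities are re-centred to the sum-zero
    identification before the transform, which makes the scores invariant to
    any common shift of a respondent's utilities.  Means, SDs and ranks are
    computed over the included respondents (default: all in the posterior).
    """
    set_size = set_size or posterior.set_size
    ids = posterior.respondents["respondent_id"].to_numpy()
    if include_ids is None:
        mask = np.ones(len(ids), dtype=bool)
    else:
        mask = np.isin(ids, np.asarray(include_ids))
    beta = posterior.beta_mean[mask]
    beta = beta - beta.mean(axis=1, keepdims=True)
    ris = ris_from_betas(beta, set_size=set_size)
    mean = ris.mean(axis=0)
    sd = ris.std(axis=0, ddof=1) if ris.shape[0] > 1 else np.zeros(ris.shape[1])
    from .compare import rank_items

    summary = pd.DataFrame(
        {
            "item": np.arange(1, beta.shape[1] + 1),
            "ris_mean": mean,
            "ris_sd": sd,
            "rank": rank_items(mean),
        }
    )
    return RISTable(ris_individual=ris, summary=summary, respondent_ids=ids[mask])
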