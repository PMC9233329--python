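"""Hierarchical Bayes estimation: likelihoods, RLH, exclusion rule and RIS."""

import numpy as np
import pandas as pd
import pytest

import capbws as cb
from capbws.design import Design
from capbws.hb import _loglik_all


def toy_design(tasks):
    tasks = np.asarray(tasks)
    return Design(
        n_items=int(tasks.max()), set_size=tasks.shape[1], versions=(tasks,)
    )


def enumerate_loglik(beta, tasks, best, worst):
    """Independent oracle: explicit per-task probability products."""
    total = 0.0
    for t, shown in enumerate(tasks):
        u = np.array([beta[j - 1] for j in shown])
        pb = np.exp(u) / np.exp(u).sum()
        b_idx = list(shown).index(best[t])
        total += np.log(pb[b_idx])
        rest = [j for j in shown if j != best[t]]
        uw = np.array([-beta[j - 1] for j in rest])
        pw = np.exp(uw) / np.exp(uw).sum()
        total += np.log(pw[rest.index(worst[t])])
    return total


class TestLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_vectorised_loglik_matches_enumeration_oracle(self, seed):
        """Sequential best-worst MNL log likelihood on 4-item toy instances."""
        rng = np.random.default_rng(seed)
        tasks = np.array([[1, 2, 3, 4], [2, 1, 4, 3], [4, 3, 2, 1]])
        beta = rng.normal(size=4)
        beta -= beta.mean()
        best = [int(rng.choice(row)) for row in tasks]
        worst = [
            int(rng.choice([j for j in row if j != b]))
            for row, b in zip(tasks, best)
        ]
        shown = tasks[None, :, :] - 1
        best_pos = np.array([[list(row).index(b) for row, b in zip(tasks, best)]])
        worst_pos = np.array([[list(row).index(w) for row, w in zip(tasks, worst)]])
        got = _loglik_all(beta[None, :], shown, best_pos, worst_pos)[0]
        expected = enumerate_loglik(beta, tasks, best, worst)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_choice_probabilities_sum_to_one_per_task(self):
        """exp(loglik) over all (best, worst) patterns of one task sums to 1."""
        beta = np.array([0.7, -0.2, -0.5, 0.0])
        tasks = np.array([[1, 2, 3, 4]])
        total = 0.0
        for b in range(4):
            for w in range(4):
                if b == w:
                    continue
                got = _loglik_all(
                    beta[None, :], tasks[None, :, :] - 1,
                    np.array([[b]]), np.array([[w]]),
                )[0]
                total += np.exp(got)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestComputeRlh:
    def test_flat_utilities_give_chance_level(self):
        """beta = 0 on 6-item tasks: RLH = sqrt(1/6 * 1/5) = 1/sqrt(30)."""
        tasks = np.array([[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]])
        design = toy_design(tasks)
        resp = pd.DataFrame(
            {"task": [1, 2], "best_item": [1, 3], "worst_item": [2, 5]}
        )
        rlh = cb.compute_rlh(np.zeros(6), resp, design, version=1)
        assert rlh == pytest.approx(1 / np.sqrt(30), abs=1e-12)
        assert cb.CHANCE_RLH_6 == pytest.approx(1 / np.sqrt(30), abs=1e-15)
        assert cb.CHANCE_RLH_6 < 0.2  # the exclusion threshold sits above chance

    def test_dominant_item_limit(self):
        """One shown item at +50 always picked best, worst at chance: RLH -> sqrt(1/5)."""
        tasks = np.array([[1, 2, 3, 4, 5, 6]])
        design = toy_design(tasks)
        beta = np.zeros(6)
        beta[0] = 50.0
        resp = pd.DataFrame({"task": [1], "best_item": [1], "worst_item": [4]})
        rlh = cb.compute_rlh(beta, resp, design, version=1)
        assert rlh == pytest.approx(np.sqrt(1 / 5), abs=1e-6)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_hand_enumerated_product_on_two_task_toy(self, seed):
        """RLH equals the 4th root of the product of the four probabilities."""
        rng = np.random.default_rng(seed)
        tasks = np.array([[1, 2, 3], [2, 3, 4]])
        design = toy_design(tasks)
        beta = rng.normal(size=4)
        resp = pd.DataFrame(
            {"task": [1, 2], "best_item": [2, 4], "worst_item": [3, 2]}
        )
        got = cb.compute_rlh(beta, resp, design, version=1)
        loglik = enumerate_loglik(beta, tasks, [2, 4], [3, 2])
        assert got == pytest.approx(np.exp(loglik / 4), abs=1e-12)

    def test_extreme_utilities_stay_positive(self):
        """Underflow-safe: a wildly wrong beta yields a tiny but nonzero RLH."""
        tasks = np.array([[1, 2, 3, 4, 5, 6]])
        design = toy_design(tasks)
        beta = np.array([-50.0, 0, 0, 0, 0, 50.0])
        resp = pd.DataFrame({"task": [1], "best_item": [1], "worst_item": [6]})
        rlh = cb.compute_rlh(beta, resp, design, version=1)
        assert 0 < rlh < 1e-9


def fake_posterior(rlh_values):
    n = len(rlh_values)
    return cb.Posterior(
        beta_mean=np.zeros((n, 16)),
        mu_draws=np.zeros((1, 16)),
        sigma_draws=np.eye(16)[None],
        rlh=np.asarray(rlh_values, dtype=float),
        acceptance_rate=np.full(n, 0.3),
        respondents=pd.DataFrame({"respondent_id": np.arange(1, n + 1)}),
        set_size=6,
        config=cb.McmcConfig.reduced(),
    )


class TestFilterInconsistent:
    def test_strictly_below_threshold_excluded_boundary_retained(self):
        included, excluded = cb.filter_inconsistent(
            fake_posterior([0.35, 0.19, 0.20])
        )
        assert list(included) == [1, 3]
        assert list(excluded) == [2]

    def test_zero_threshold_excludes_nobody(self):
        included, excluded = cb.filter_inconsistent(
            fake_posterior([0.05, 0.5]), threshold=0.0
        )
        assert len(excluded) == 0
        assert len(included) == 2


class TestComputeRis:
    def test_flat_utilities_share_equally(self):
        post = fake_posterior([0.3, 0.3])
        ris = cb.compute_ris(post)
        np.testing.assert_allclose(ris.ris_individual, 6.25)
        np.testing.assert_allclose(ris.ris_mean, 6.25)

    def test_single_elevated_item_matches_rescaling_formula(self):
        """beta = (1, 0, ...): RIS_1 = 100 p1 / (p1 + 15/6) with p1 = e/(e+5)."""
        beta = np.zeros(16)
        beta[0] = 1.0
        ris = cb.ris_from_betas(beta, set_size=6)
        p1 = np.e / (np.e + 5)
        expected = 100 * p1 / (p1 + 15 / 6)
        assert ris[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(12.348, abs=1e-3)

    def test_shift_invariance(self):
        """RIS is unchanged by adding a constant to all of a respondent's betas."""
        rng = np.random.default_rng(4)
        beta = rng.normal(size=(5, 16))
        post = cb.Posterior(**{**fake_posterior([0.3] * 5).__dict__,
                               "beta_mean": beta})
        shifted = cb.Posterior(**{**post.__dict__, "beta_mean": beta + 3.7})
        np.testing.assert_allclose(
            cb.compute_ris(post).ris_individual,
            cb.compute_ris(shifted).ris_individual,
            atol=1e-9,
        )

    def test_individual_scores_sum_to_100(self, reduced_posterior):
        ris = cb.compute_ris(reduced_posterior)
        np.testing.assert_allclose(ris.ris_individual.sum(axis=1), 100, atol=1e-6)
        assert np.all(ris.ris_individual >= 0)
        assert abs(ris.ris_mean.sum() - 100) < 0.01


class TestFitHb:
    def test_posterior_structure(self, reduced_posterior):
        post = reduced_posterior
        assert post.beta_mean.shape == (158, 16)
        np.testing.assert_allclose(post.beta_mean.sum(axis=1), 0, atol=1e-9)
        assert np.all((post.rlh > 0) & (post.rlh <= 1))
        assert 0.05 < post.acceptance_rate.mean() < 0.6

    def test_population_mean_recovery_within_three_posterior_sd(
        self, responses, population
    ):
        """Sum-zero projection of posterior mu covers the simulator's mean."""
        post = cb.fit_hb(
            responses, config=cb.McmcConfig(n_burn=2000, n_keep=2000,
                                            thinning=2, seed=3)
        )
        mu_true = np.vstack([
            np.tile(c.mean_utility, (c.n_respondents, 1))
            for c in population.cohorts
        ]).mean(axis=0)
        mu_true -= mu_true.mean()
        mu_draws = post.mu_draws - post.mu_draws.mean(axis=1, keepdims=True)
        z = (mu_draws.mean(axis=0) - mu_true) / mu_draws.std(axis=0, ddof=1)
        assert np.all(np.abs(z) < 3)

    def test_random_responder_shrunk_with_chance_level_fit(
        self, posterior_with_random_responder
    ):
        """A uniform-random responder ends near chance RLH, far below the rest."""
        post = posterior_with_random_responder
        idx = post.respondents.index[post.respondents["respondent_id"] == 159][0]
        assert post.rlh[idx] < 0.2
        assert abs(post.rlh[idx] - cb.CHANCE_RLH_6) < 0.05
        # shrinkage: the random responder's utilities are pulled towards the
        # population mean, leaving a smaller spread than the typical respondent
        spread = np.ptp(post.beta_mean, axis=1)
        assert spread[idx] < np.median(spread)

    def test_deterministic_given_seed(self, study_design):
        config = cb.PopulationConfig(
            cohorts=(
                cb.CohortSpec(
                    "a", 12, cb.betas_from_ris(np.asarray(cb.REFERENCE_MEAN_RIS))
                ),
            ),
            utility_covariance=np.eye(16),
            seed=2,
        )
        truths = cb.simulate_population(config)
        responses = cb.simulate_responses(study_design, truths, seed=8)
        mcmc = cb.McmcConfig(n_burn=50, n_keep=50, thinning=1, seed=6)
        a = cb.fit_hb(responses, config=mcmc)
        b = cb.fit_hb(responses, config=mcmc)
        np.testing.assert_array_equal(a.beta_mean, b.beta_mean)
        np.testing.assert_array_equal(a.mu_draws, b.mu_draws)

    def test_effective_sample_size_diagnostic(self, reduced_posterior):
        ess = reduced_posterior.mu_effective_sample_size()
        n_draws = reduced_posterior.mu_draws.shape[0]
        assert ess.shape == (16,)
        assert np.all(ess > 1)
        assert np.all(ess <= 2 * n_draws)  # antithetic chains can exceed n

    def test_incomplete_respondent_rejected(self, responses):
        broken = cb.ResponseSet(
            respondents=responses.respondents,
            responses=responses.responses.iloc[:-1],
            design=responses.design,
        )
        with pytest.raises(ValueError, match="incomplete"):
            cb.fit_hb(broken, config=cb.McmcConfig.reduced(seed=0))

    def test_ris_stable_when_kept_draws_doubled(self, responses):
        """Doubling the kept draws moves each mean RIS by less than 0.1."""
        a = cb.compute_ris(cb.fit_hb(
            responses,
            config=cb.McmcConfig(n_burn=4000, n_keep=8000, thinning=8, seed=3),
        ))
        b = cb.compute_ris(cb.fit_hb(
            responses,
            config=cb.McmcConfig(n_burn=4000, n_keep=16000, thinning=8, seed=3),
        ))
        assert np.abs(a.ris_mean - b.ris_mean).max() < 0.1
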