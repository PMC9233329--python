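"""Per-item OLS and jackknife-robust variances against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import capbws as cb
from capbws.regression import COEFFICIENT_NAMES, identity_pipeline


def covariate_table(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "respondent_id": np.arange(1, n + 1),
            "gender": rng.choice(["male", "female"], size=n),
            "cohort": rng.choice(["psychiatric", "general", "expert"], size=n),
        }
    )


def normal_equations(x, y):
    return np.linalg.solve(x.T @ x, x.T @ y)


class TestFitItemRegressions:
    def test_zero_outcome_gives_zero_coefficients(self):
        cov = covariate_table(20)
        beta = cb.fit_item_regressions(np.zeros((20, 3)), cov)
        np.testing.assert_allclose(beta, 0, atol=1e-12)

    def test_matches_normal_equations_oracle_on_hand_dataset(self):
        cov = pd.DataFrame(
            {
                "gender": ["male", "female", "male", "female", "male", "female"],
                "cohort": ["psychiatric", "psychiatric", "general",
                           "general", "expert", "expert"],
            }
        )
        y = np.array([3.0, 1.0, 2.0, 5.0, 4.0, 2.5])[:, None]
        beta = cb.fit_item_regressions(y, cov)
        x = cb.build_covariate_matrix(cov)
        expected = normal_equations(x, y[:, 0])
        np.testing.assert_allclose(beta[0], expected, atol=1e-10)

    def test_planted_cohort_effect_recovered(self):
        """A pure additive cohort effect is estimated without bias."""
        rng = np.random.default_rng(3)
        cov = covariate_table(600, seed=3)
        delta = 2.5
        y = rng.normal(size=600) + delta * (cov["cohort"] == "psychiatric")
        beta = cb.fit_item_regressions(y.to_numpy()[:, None], cov)
        names = dict(zip(COEFFICIENT_NAMES, beta[0]))
        assert names["psychiatric_vs_general"] == pytest.approx(delta, abs=0.3)
        assert names["male_vs_female"] == pytest.approx(0, abs=0.3)

    def test_collinear_design_matrix_named(self):
        cov = covariate_table(20)
        cov["gender"] = "male"  # male column == intercept
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            cb.fit_item_regressions(np.zeros((20, 2)), cov)

    def test_unknown_cohort_label_rejected(self):
        cov = covariate_table(10)
        cov.loc[0, "cohort"] = "martian"
        with pytest.raises(ValueError, match="martian"):
            cb.build_covariate_matrix(cov)


class TestJackknifeRobust:
    def test_constant_leave_one_out_estimates_give_zero_variance(self):
        """All replicate coefficients equal to the full-sample fit: v = 0."""
        cov = covariate_table(12, seed=1)
        x = cb.build_covariate_matrix(cov)
        rng = np.random.default_rng(1)
        coef = rng.normal(size=4)
        y = x @ coef  # exact linear outcome: every subset refit is identical
        result = cb.jackknife_robust(identity_pipeline(y[:, None]), cov)
        np.testing.assert_allclose(result.v_hat, 0, atol=1e-18)
        np.testing.assert_allclose(result.beta_hat[0], coef, atol=1e-10)

    def test_identity_pipeline_matches_direct_delete_one_oracle(self):
        """With the estimation stage stubbed out, SEs equal delete-one OLS refits."""
        rng = np.random.default_rng(5)
        n = 40
        cov = covariate_table(n, seed=5)
        y = rng.normal(size=(n, 2)) + 5
        result = cb.jackknife_robust(identity_pipeline(y), cov)
        x = cb.build_covariate_matrix(cov)
        beta_full = np.column_stack(
            [normal_equations(x, y[:, k]) for k in range(2)]
        ).T
        np.testing.assert_allclose(result.beta_hat, beta_full, atol=1e-10)
        for k in range(2):
            loo = np.array([
                normal_equations(np.delete(x, i, axis=0), np.delete(y[:, k], i))
                for i in range(n)
            ])
            v = (n - 1) / n * ((loo - beta_full[k]) ** 2).sum(axis=0)
            np.testing.assert_allclose(result.v_hat[k], v, atol=1e-10)
            np.testing.assert_allclose(result.s_hat[k], np.sqrt(v), atol=1e-10)
            assert np.all(v > 0)

    def test_variance_formula_matches_naive_loop_exactly(self):
        """v = (n-1)/n * sum of squared deviations, evaluated by a plain loop."""
        rng = np.random.default_rng(9)
        n = 25
        cov = covariate_table(n, seed=9)
        y = rng.normal(size=(n, 1))
        result = cb.jackknife_robust(identity_pipeline(y), cov)
        for j in range(4):
            acc = 0.0
            for i in range(n):
                acc += (result.beta_loo[i, 0, j] - result.beta_hat[0, j]) ** 2
            assert result.v_hat[0, j] == pytest.approx((n - 1) / n * acc,
                                                       rel=1e-12)

    def test_degrees_of_freedom_and_p_values(self):
        """n = 158, J = 4: p-values use a t-distribution with 153 df."""
        rng = np.random.default_rng(2)
        n = 158
        cov = covariate_table(n, seed=2)
        y = rng.normal(size=(n, 1))
        result = cb.jackknife_robust(identity_pipeline(y), cov)
        assert result.n == 158
        assert result.df == 153
        assert result.beta_loo.shape == (158, 1, 4)
        expected_p = 2 * stats.t.sf(np.abs(result.t_stat), df=153)
        np.testing.assert_allclose(result.p_value, expected_p, atol=1e-14)

    def test_deterministic_over_deterministic_pipeline(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(15, 2))
        cov = covariate_table(15, seed=8)
        a = cb.jackknife_robust(identity_pipeline(y), cov)
        b = cb.jackknife_robust(identity_pipeline(y), cov)
        np.testing.assert_array_equal(a.v_hat, b.v_hat)
        np.testing.assert_array_equal(a.beta_loo, b.beta_loo)

    def test_t_statistics_invariant_to_outcome_rescaling(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(30, 1))
        cov = covariate_table(30, seed=6)
        a = cb.jackknife_robust(identity_pipeline(y), cov)
        b = cb.jackknife_robust(identity_pipeline(y * 17.0), cov)
        np.testing.assert_allclose(a.t_stat, b.t_stat, atol=1e-9)

    def test_checkpoint_resumes_after_failure(self, tmp_path):
        """A failing replicate leaves completed ones persisted; rerun resumes."""
        rng = np.random.default_rng(13)
        n = 12
        y = rng.normal(size=(n, 1))
        cov = covariate_table(n, seed=13)
        ck = str(tmp_path / "jackknife.csv")
        calls = []

        def flaky(mask):
            calls.append(mask.sum())
            if len(calls) > 6 and mask.sum() == n - 1:
                raise RuntimeError("replicate diverged")
            return y[mask]

        with pytest.raises(RuntimeError, match="persisted"):
            cb.jackknife_robust(flaky, cov, checkpoint=ck)
        resumed = cb.jackknife_robust(identity_pipeline(y), cov, checkpoint=ck)
        fresh = cb.jackknife_robust(identity_pipeline(y), cov)
        np.testing.assert_allclose(resumed.v_hat, fresh.v_hat, atol=1e-12)
        np.testing.assert_allclose(resumed.beta_loo, fresh.beta_loo, atol=1e-12)

    def test_too_few_participants_rejected(self):
        cov = covariate_table(5)
        with pytest.raises(ValueError, match="J \\+ 2"):
            cb.jackknife_robust(identity_pipeline(np.zeros((5, 1))), cov)


class TestSignificanceTable:
    def test_star_thresholds(self):
        rng = np.random.default_rng(11)
        n = 60
        cov = covariate_table(n, seed=11)
        y = rng.normal(size=(n, 3))
        result = cb.jackknife_robust(identity_pipeline(y), cov)
        table = cb.significance_table(result, y)
        for _, row in table.iterrows():
            for name in COEFFICIENT_NAMES:
                p = row[f"{name}_p"]
                stars = row[f"{name}_stars"]
                if p < 0.001:
                    assert stars == "***"
                elif p < 0.01:
                    assert stars == "**"
                elif p < 0.05:
                    assert stars == "*"
                else:
                    assert stars == ""

    def test_reports_outcome_mean_and_sd(self):
        rng = np.random.default_rng(12)
        y = rng.normal(loc=6.25, size=(40, 2))
        cov = covariate_table(40, seed=12)
        result = cb.jackknife_robust(identity_pipeline(y), cov)
        table = cb.significance_table(result, y)
        assert table["ris_mean"].iloc[0] == pytest.approx(y[:, 0].mean())
        assert table["ris_sd"].iloc[0] == pytest.approx(y[:, 0].std(ddof=1))
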