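"""ARD Bayesian linear regression: posterior, evidence, pruning, prediction."""

import numpy as np
import pytest

from gaitvel import (
    ARDLinearRegression,
    ARDResults,
    design_matrix,
    log_marginal_likelihood,
    posterior,
)


def dense_posterior(Phi, v, beta, alpha):
    """Naive dense-inverse transcription of the posterior equations."""
    Sigma = np.linalg.inv(np.diag(beta) + alpha * Phi.T @ Phi)
    return alpha * Sigma @ Phi.T @ v, Sigma


def dense_log_marginal(Phi, v, beta, alpha):
    """Direct evaluation through the N x N marginal covariance C."""
    C = np.eye(v.size) / alpha + Phi @ np.diag(1.0 / beta) @ Phi.T
    sign, logdet = np.linalg.slogdet(C)
    assert sign > 0
    return -0.5 * (
        v.size * np.log(2 * np.pi) + logdet + v @ np.linalg.solve(C, v)
    )


def random_instance(rng):
    n = int(rng.integers(2, 11))
    d = int(rng.integers(1, 6))
    Phi = rng.normal(size=(n, d))
    v = rng.normal(size=n)
    beta = rng.uniform(0.1, 10.0, size=d)
    alpha = float(rng.uniform(0.1, 10.0))
    return Phi, v, beta, alpha


class TestDesignMatrix:
    def test_ones_column_prepended(self):
        Phi, _, _ = design_matrix(np.array([[2.0], [4.0]]))
        assert np.array_equal(Phi[:, 0], [1.0, 1.0])

    def test_no_features_gives_ones_only(self):
        Phi, _, _ = design_matrix(np.empty((3, 0)))
        assert Phi.shape == (3, 1)
        assert np.array_equal(Phi[:, 0], np.ones(3))

    def test_columns_standardized(self, rng):
        X = rng.normal(loc=5.0, scale=3.0, size=(200, 4))
        Phi, means, sds = design_matrix(X)
        assert np.max(np.abs(Phi[:, 1:].mean(axis=0))) < 1e-12
        assert np.max(np.abs(Phi[:, 1:].std(axis=0) - 1.0)) < 1e-12
        assert np.allclose((X - means) / sds, Phi[:, 1:])

    def test_zero_variance_column_warns_and_kept(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Phi, _, _ = design_matrix(X)
        assert Phi.shape == (10, 3)


class TestPosterior:
    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            Phi, v, beta, alpha = random_instance(rng)
            mu, Sigma = posterior(Phi, v, beta, alpha)
            mu_o, Sigma_o = dense_posterior(Phi, v, beta, alpha)
            assert np.allclose(mu, mu_o, atol=1e-10)
            assert np.allclose(Sigma, Sigma_o, atol=1e-10)
            A = np.diag(beta) + alpha * Phi.T @ Phi
            assert np.allclose(A @ Sigma, np.eye(beta.size), atol=1e-8)

    def test_prior_dominates_at_huge_precision(self, rng):
        Phi = np.column_stack([np.ones(50), rng.normal(size=50)])
        v = rng.normal(size=50)
        mu, _ = posterior(Phi, v, np.full(2, 1e12), 1.0)
        assert np.linalg.norm(mu) < 1e-5

    def test_identifiable_noiseless_limit(self, rng):
        x = rng.normal(size=100)
        Phi = np.column_stack([np.ones(100), x])
        mu, _ = posterior(Phi, 2.0 * x, np.full(2, 1e-4), 1e8)
        assert mu[1] == pytest.approx(2.0, abs=1e-4)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            posterior(np.ones((3, 1)), np.ones(3), np.array([-1.0]), 1.0)
        with pytest.raises(ValueError):
            posterior(np.ones((3, 1)), np.ones(3), np.array([1.0]), 0.0)


class TestLogMarginal:
    def test_scalar_closed_form(self):
        val = log_marginal_likelihood(
            np.array([[1.0]]), np.array([0.0]), np.array([1.0]), 1.0
        )
        assert val == pytest.approx(-0.5 * (np.log(2 * np.pi) + np.log(2.0)))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            Phi, v, beta, alpha = random_instance(rng)
            assert log_marginal_likelihood(Phi, v, beta, alpha) == pytest.approx(
                dense_log_marginal(Phi, v, beta, alpha), abs=1e-10
            )

    def test_irrelevant_feature_with_huge_precision_changes_nothing(self, rng):
        Phi, v, beta, alpha = random_instance(rng)
        extra = np.column_stack([Phi, rng.normal(size=v.size)])
        base = log_marginal_likelihood(Phi, v, beta, alpha)
        with_extra = log_marginal_likelihood(
            extra, v, np.r_[beta, 1e12], alpha
        )
        assert with_extra == pytest.approx(base, abs=1e-8)


class TestFit:
    def test_sparsity_recovery(self):
        """One informative feature plus seven pure-noise features: the noise
        features are pruned and the slope recovered."""
        successes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 8))
            v = 1.5 * X[:, 0] + 0.05 * rng.normal(size=500)
            res = ARDLinearRegression(X, v).fit()
            kept = set(np.flatnonzero(res.active_mask[1:]))
            if kept == {0}:
                successes += 1
                slope = res.mu[1] / res.feature_sds[0]
                se = np.sqrt(res.Sigma[1, 1]) / res.feature_sds[0]
                assert abs(slope - 1.5) < 3 * max(se, 1e-4)
        assert successes >= 9

    def test_constant_target_prunes_everything(self, rng):
        X = rng.normal(size=(100, 5))
        res = ARDLinearRegression(X, np.full(100, 2.0)).fit()
        assert res.n_active == 0
        assert res.predict(rng.normal(size=5)).mean == pytest.approx(2.0, abs=1e-6)

    def test_gait_like_feature_space_reduces_to_eight(self, rng):
        """Sixteen features of which only stride time, stance duration and
        six acceleration harmonics carry signal: the active dimension drops
        to eight."""
        n = 600
        names = ["T_FS", "T_FF", "T_HO", "T_TO"] + [
            f"c{i}" for i in range(12)
        ]
        T = 1.1 + 0.05 * rng.normal(size=n)
        X = np.column_stack(
            [
                T,
                0.12 * T + 0.02 * rng.normal(size=n),
                0.40 * T + 0.02 * rng.normal(size=n),
                0.62 * T + 0.02 * rng.normal(size=n),
                rng.normal(size=(n, 12)) * 0.3 + 1.5,
            ]
        )
        informative = [0, 3] + list(range(4, 10))
        w = np.array([-1.5, -0.8, 0.30, 0.25, 0.20, 0.15, 0.25, 0.20])
        v = 3.0 + X[:, informative] @ w + 0.05 * rng.normal(size=n)
        res = ARDLinearRegression(X, v, feature_names=names).fit()
        assert res.n_active == 8
        assert set(res.active_features) == {names[j] for j in informative}

    def test_fit_is_deterministic(self, rng):
        X = rng.normal(size=(80, 6))
        v = X[:, 0] - 2 * X[:, 3] + 0.1 * rng.normal(size=80)
        model = ARDLinearRegression(X, v)
        r1, r2 = model.fit(), model.fit()
        assert np.array_equal(r1.mu, r2.mu)
        assert np.array_equal(r1.beta, r2.beta)
        assert r1.alpha == r2.alpha

    def test_fixed_point_self_consistency(self, rng):
        X = rng.normal(size=(200, 4))
        v = 0.7 * X[:, 1] + 0.3 * X[:, 2] + 0.05 * rng.normal(size=200)
        res = ARDLinearRegression(X, v).fit()
        assert res.converged
        act = res.active_mask
        mu, gamma, beta = res.mu[act], res.gamma[act], res.beta[act]
        # beta_i mu_i^2 == gamma_i at the fixed point
        assert np.allclose(beta * mu**2, gamma, rtol=1e-3)
        Phi, _, _ = design_matrix(X)
        resid = v - Phi[:, act] @ mu
        alpha_check = (200 - res.gamma.sum()) / (resid @ resid)
        assert res.alpha == pytest.approx(alpha_check, rel=1e-3)

    def test_estimation_error_shrinks_with_sample_size(self):
        rmse = {}
        for n in (50, 200, 800):
            errs = []
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                X = rng.normal(size=(n, 3))
                w = np.array([1.0, -0.5, 0.8])
                v = X @ w + 0.3 * rng.normal(size=n)
                res = ARDLinearRegression(X, v).fit()
                w_hat = res.mu[1:] / res.feature_sds
                errs.append(np.mean((w_hat - w) ** 2))
            rmse[n] = np.sqrt(np.mean(errs))
        assert rmse[800] < rmse[200] < rmse[50]
        # O(1/sqrt(N)): 16x more data should shrink the error ~4x
        assert rmse[50] / rmse[800] > 2.0

    def test_pruning_preserves_evidence(self, rng):
        """Removing a feature whose precision passed the threshold changes
        the evidence only marginally."""
        Phi, v, beta, alpha = random_instance(rng)
        d = beta.size
        extra_phi = np.column_stack([Phi, rng.normal(size=v.size)])
        big = 300.0 * alpha * 1e6
        full = log_marginal_likelihood(extra_phi, v, np.r_[beta, big], alpha)
        pruned = log_marginal_likelihood(Phi, v, beta, alpha)
        assert abs(full - pruned) < 1e-4


class TestPredict:
    def test_zero_weight_model_predicts_bias(self, rng):
        X = rng.normal(size=(100, 3))
        res = ARDLinearRegression(X, np.full(100, 1.2)).fit()
        pred = res.predict(rng.normal(size=(5, 3)))
        assert np.allclose(pred.mean, 1.2, atol=1e-6)

    def test_variance_never_below_noise_floor(self, rng):
        X = rng.normal(size=(100, 3))
        v = X[:, 0] + 0.1 * rng.normal(size=100)
        res = ARDLinearRegression(X, v).fit()
        pred = res.predict(rng.normal(size=(50, 3)) * 10)
        assert np.all(pred.variance >= 1.0 / res.alpha - 1e-15)

    def test_training_points_fit_in_near_noiseless_case(self, rng):
        X = rng.normal(size=(200, 2))
        sigma = 1e-3
        v = 2.0 + X[:, 0] - X[:, 1] + sigma * rng.normal(size=200)
        res = ARDLinearRegression(X, v).fit()
        pred = res.predict(X)
        assert np.max(np.abs(pred.mean - v)) < 3 * sigma * 4

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        res = ARDLinearRegression(X, X[:, 0]).fit()
        with pytest.raises(ValueError, match="features"):
            res.predict(np.ones(4))


class TestResultsInterface:
    def test_serialization_round_trip(self, rng):
        X = rng.normal(size=(100, 4))
        v = X[:, 1] + 0.1 * rng.normal(size=100)
        res = ARDLinearRegression(X, v, feature_names=list("abcd")).fit()
        clone = ARDResults.from_dict(res.to_dict())
        q = rng.normal(size=(7, 4))
        assert np.allclose(res.predict(q).mean, clone.predict(q).mean)
        assert np.allclose(res.predict(q).variance, clone.predict(q).variance)
        assert clone.feature_names == ["a", "b", "c", "d"]

    def test_summary_mentions_features_and_retention(self, rng):
        X = rng.normal(size=(300, 2))
        v = 0.9 * X[:, 0] + 0.05 * rng.normal(size=300)
        res = ARDLinearRegression(X, v, feature_names=["keepme", "dropme"]).fit()
        text = res.summary()
        assert "keepme" in text and "dropme" in text
        assert "retained features" in text

    def test_from_dataframe(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {"a": rng.normal(size=60), "b": rng.normal(size=60)}
        )
        df["y"] = 2 * df["a"] + 0.05 * rng.normal(size=60)
        res = ARDLinearRegression.from_dataframe(df, target="y").fit()
        assert res.feature_names == ["a", "b"]
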