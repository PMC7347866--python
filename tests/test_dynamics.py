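"""VAR fitting, residual diagnostics and the symmetrised-KL dissimilarity."""

import numpy as np
import pytest

from rapidindex.dynamics import (
    DissimilarityMatrix,
    DynamicsModel,
    build_dissimilarity_matrix,
    fit_var,
    fit_var_batch,
    gaussian_kl,
    model_dissimilarity,
    one_step_residuals,
)


def simulate_var1(A, n, noise_sd=0.0, seed=0, intercept=None):
    rng = np.random.default_rng(seed)
    k = A.shape[0]
    c = np.zeros(k) if intercept is None else intercept
    x = np.zeros((n, k))
    x[0] = rng.normal(size=k)
    for t in range(1, n):
        x[t] = c + A @ x[t - 1] + rng.normal(0, noise_sd, size=k)
    return x


def random_model(rng, p=2, k=3) -> DynamicsModel:
    coeffs = rng.normal(0, 0.2, size=(p, k, k))
    L = rng.normal(0, 0.4, size=(k, k))
    return DynamicsModel(
        coeffs=coeffs, intercept=rng.normal(size=k), sigma=L @ L.T + 0.1 * np.eye(k)
    )


class TestFitVar:
    def test_noiseless_var1_recovered(self):
        A = np.array([[0.5, 0.1, 0.0], [0.0, 0.6, 0.2], [0.1, 0.0, 0.4]])
        x = simulate_var1(A, 15)
        m = fit_var(x, order=1)
        np.testing.assert_allclose(m.coeffs[0], A, atol=1e-8)
        np.testing.assert_allclose(m.intercept, 0.0, atol=1e-8)
        np.testing.assert_allclose(m.sigma, 0.0, atol=1e-12)

    def test_recovery_error_vanishes_with_noise(self):
        """Coefficient error -> 0 as the innovation scale shrinks.

        Checked on an AR(1) transient where the deterministic decay
        identifies the coefficient exactly in the noiseless limit; richer
        dimensions are covered by the consistency test below.
        """
        a = 0.8
        errs = []
        for sd in (0.1, 0.001, 1e-5):
            x = simulate_var1(np.array([[a]]), 15, noise_sd=sd, seed=1)
            m = fit_var(x, order=1)
            errs.append(abs(float(m.coeffs[0, 0, 0]) - a))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4

    def test_recovery_consistent_in_sample_size(self):
        """Trivariate coefficient error shrinks as the window grows."""
        A = np.array([[0.5, 0.1, 0.0], [0.0, 0.6, 0.2], [0.1, 0.0, 0.4]])
        errs = []
        for n in (100, 1000, 10_000):
            x = simulate_var1(A, n, noise_sd=0.3, seed=1)
            m = fit_var(x, order=1)
            errs.append(np.abs(m.coeffs[0] - A).max())
        assert errs[0] > errs[2]
        assert errs[2] < 0.03

    def test_white_noise_gives_null_coefficients(self, rng):
        x = rng.normal(size=(5000, 3))
        m = fit_var(x, order=2)
        assert np.abs(m.coeffs).max() < 0.06
        np.testing.assert_allclose(m.sigma, np.cov(x[2:].T, bias=True), atol=0.08)

    def test_constant_input_ridge_fallback(self):
        x = np.full((15, 3), 7.0)
        with pytest.warns(UserWarning, match="ridge"):
            m = fit_var(x, order=2)
        resid, _ = one_step_residuals(m, x)
        np.testing.assert_allclose(resid, 0.0, atol=1e-4)

    def test_too_short_window_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_var(rng.normal(size=(3, 3)), order=2)

    def test_batch_matches_single(self, rng):
        wins = rng.normal(size=(12, 15, 3)).cumsum(axis=1) * 0.1
        coeffs, intercepts, sigmas = fit_var_batch(wins, 2)
        for i in range(12):
            m = fit_var(wins[i], order=2)
            np.testing.assert_allclose(coeffs[i], m.coeffs, atol=1e-8)
            np.testing.assert_allclose(intercepts[i], m.intercept, atol=1e-8)
            np.testing.assert_allclose(sigmas[i], m.sigma, atol=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        """Least-squares VAR coefficients agree with statsmodels."""
        from statsmodels.tsa.api import VAR as SmVAR

        x = simulate_var1(np.diag([0.6, 0.5, 0.4]), 200, noise_sd=0.3, seed=2)
        ours = fit_var(x, order=2)
        sm = SmVAR(x).fit(maxlags=2, trend="c")
        np.testing.assert_allclose(ours.intercept, sm.params[0], atol=1e-6)
        np.testing.assert_allclose(ours.coeffs[0], sm.coefs[0], atol=1e-6)
        np.testing.assert_allclose(ours.coeffs[1], sm.coefs[1], atol=1e-6)


class TestResiduals:
    def test_training_msr_equals_sigma_trace(self, rng):
        x = rng.normal(size=(30, 3)).cumsum(axis=0) * 0.2
        m = fit_var(x, order=2)
        _, msr = one_step_residuals(m, x)
        assert msr == pytest.approx(np.trace(m.sigma), rel=1e-9)

    def test_zero_model_residuals_equal_data(self, rng):
        x = rng.normal(size=(20, 3))
        m = DynamicsModel(
            coeffs=np.zeros((1, 3, 3)), intercept=np.zeros(3), sigma=np.eye(3)
        )
        resid, _ = one_step_residuals(m, x)
        np.testing.assert_allclose(resid, x[1:], atol=1e-12)

    def test_shuffling_destroys_temporal_structure(self, rng):
        x = simulate_var1(np.diag([0.9, 0.85, 0.8]), 60, noise_sd=0.2, seed=5)
        m = fit_var(x, order=1)
        _, msr_orig = one_step_residuals(m, x)
        worse = 0
        for _ in range(100):
            xs = x[rng.permutation(len(x))]
            _, msr_shuf = one_step_residuals(m, xs)
            worse += msr_shuf >= msr_orig
        assert worse >= 90  # on average shuffled series fit worse


class TestDissimilarity:
    def test_identical_models_zero(self, rng):
        m = random_model(rng)
        ref = rng.normal(size=(2, 15, 3))
        assert model_dissimilarity(m, m, list(ref)) == pytest.approx(0.0, abs=1e-12)

    def test_univariate_gaussian_closed_form(self):
        """Unit-variance means 0 and 1: each KL is 1/2, symmetrised mean 1/2."""
        base = dict(coeffs=np.zeros((1, 1, 1)), sigma=np.eye(1))
        m0 = DynamicsModel(intercept=np.zeros(1), **base)
        m1 = DynamicsModel(intercept=np.ones(1), **base)
        ref = [np.zeros((5, 1))]
        assert model_dissimilarity(m0, m1, ref) == pytest.approx(0.5, rel=1e-9)
        assert gaussian_kl(np.zeros(1), np.eye(1), np.ones(1), np.eye(1)) == pytest.approx(0.5)

    def test_matrix_consistent_with_pairwise(self, rng):
        models = [random_model(rng) for _ in range(5)]
        ref = list(rng.normal(size=(3, 10, 3)))
        mat = build_dissimilarity_matrix(models, ref)
        for i in range(5):
            for j in range(i + 1, 5):
                assert mat.values[i, j] == pytest.approx(
                    model_dissimilarity(models[i], models[j], ref), rel=1e-8
                )

    def test_pseudo_metric_axioms_on_random_pairs(self, rng):
        """Non-negativity, symmetry and d(m, m) = 0 across random models."""
        ref = list(rng.normal(size=(3, 12, 3)))
        for _ in range(20):
            m1, m2 = random_model(rng), random_model(rng)
            d12 = model_dissimilarity(m1, m2, ref)
            d21 = model_dissimilarity(m2, m1, ref)
            assert d12 >= 0
            assert d12 == pytest.approx(d21, rel=1e-9)
            assert model_dissimilarity(m1, m1, ref) == pytest.approx(0.0, abs=1e-10)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(ids=("a", "b"), values=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DissimilarityMatrix(ids=("a", "b"), values=np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_singular_covariance_regularized(self, rng):
        m1 = DynamicsModel(
            coeffs=np.zeros((1, 2, 2)), intercept=np.zeros(2), sigma=np.diag([1.0, 0.0])
        )
        m2 = DynamicsModel(
            coeffs=np.zeros((1, 2, 2)), intercept=np.ones(2), sigma=np.eye(2)
        )
        with pytest.warns(UserWarning, match="singular"):
            d = model_dissimilarity(m1, m2, [np.zeros((4, 2))])
        assert np.isfinite(d) and d > 0
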