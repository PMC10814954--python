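import numpy as np
import pytest
from scipy import stats

import prenetmirt as pm
from prenetmirt.polya_gamma import (
    pg_mean,
    posterior_normal_params,
    sample_pg,
    sample_pg_series,
    sample_theta,
    sample_w,
)


class TestPGSampler:
    @pytest.mark.parametrize("c", [0.0, 1.0, 2.0])
    def test_devroye_mean_matches_moment_formula(self, c, rng):
        """E[PG(1,c)] = tanh(c/2)/(2c); sample means agree within 3 SE."""
        n = 100_000
        draws = sample_pg(np.full(n, c), rng)
        assert np.all(draws > 0)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - pg_mean(c)) <= 3 * se

    @pytest.mark.parametrize("c", [0.0, 2.0])
    def test_series_oracle_mean(self, c, rng):
        """The truncated defining sum of gammas reproduces the same means."""
        n = 40_000
        draws = sample_pg_series(np.full(n, c), rng)
        se = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - pg_mean(c)) <= 3.5 * se

    def test_devroye_agrees_with_series_distribution(self, rng):
        """Two-sample KS between the exact sampler and the truncated-series
        oracle at a nonzero tilt."""
        n = 20_000
        d = sample_pg(np.full(n, 1.5), rng)
        s = sample_pg_series(np.full(n, 1.5), rng)
        assert stats.ks_2samp(d, s).pvalue > 0.01

    def test_sign_symmetry(self, rng):
        n = 10_000
        pos = sample_pg(np.full(n, 2.0), rng)
        neg = sample_pg(np.full(n, -2.0), rng)
        assert stats.ks_2samp(pos, neg).pvalue > 0.01

    def test_scalar_and_shape(self, rng):
        x = sample_pg(0.5, rng)
        assert isinstance(x, float) and x > 0
        arr = sample_pg(np.zeros((3, 4)), rng)
        assert arr.shape == (3, 4) and np.all(arr > 0)

    def test_rejects_nonfinite(self, rng):
        with pytest.raises(ValueError):
            sample_pg(np.array([1.0, np.inf]), rng)


class TestAugmentationIdentity:
    @pytest.mark.parametrize("psi", [-2.0, 0.0, 1.5])
    @pytest.mark.parametrize("a", [0, 1])
    def test_logistic_integral_identity(self, psi, a, rng):
        """sigma(psi)^a sigma(-psi)^(1-a) = 2^-1 e^{kappa psi} E[e^{-w psi^2/2}]
        over w ~ PG(1, 0), within Monte-Carlo error."""
        lhs = np.exp(a * psi) / (1 + np.exp(psi))
        n = 40_000
        w = sample_pg_series(np.zeros(n), rng)
        f = np.exp(-w * psi ** 2 / 2.0)
        kappa = a - 0.5
        scale = 0.5 * np.exp(kappa * psi)
        rhs = scale * f.mean()
        tol = max(scale * 3 * f.std() / np.sqrt(n), 1e-12)
        assert abs(lhs - rhs) <= tol


class TestPosteriorNormalParams:
    def test_null_loadings_give_prior(self):
        params = pm.ModelParams(A=np.zeros((4, 3)), b=np.ones(4))
        V, mu = posterior_normal_params(np.array([1, 0, 1, 1]), params, np.full(4, 0.3))
        np.testing.assert_allclose(V, np.eye(3))
        np.testing.assert_allclose(mu, 0.0)

    def test_one_dimensional_hand_case(self):
        # K=1, J=1, a=2, w=1/4, b=0, y=1: V = 1/(4*0.25+1) = 0.5,
        # mu = V * a * w * (kappa/w - b) = 0.5 * 2 * 0.5 = 0.5
        params = pm.ModelParams(A=np.array([[2.0]]), b=np.zeros(1))
        V, mu = posterior_normal_params(np.array([1]), params, np.array([0.25]))
        assert V[0, 0] == pytest.approx(0.5)
        assert mu[0] == pytest.approx(0.5)

    def test_spd_with_ridge_bound(self, rng):
        for _ in range(20):
            A = rng.normal(size=(6, 3))
            params = pm.ModelParams(A=A, b=rng.normal(size=6))
            w = rng.uniform(0.01, 2.0, size=6)
            V, _ = posterior_normal_params(rng.integers(0, 2, size=6), params, w)
            np.testing.assert_allclose(V, V.T, atol=1e-12)
            lam = np.linalg.eigvalsh(V)
            assert lam.min() > 0
            bound = 1.0 / (1.0 + np.linalg.norm(A.T * w @ A, 2))
            assert lam.min() >= bound - 1e-10

    def test_rejects_nonpositive_w(self):
        params = pm.ModelParams(A=np.ones((2, 1)), b=np.zeros(2))
        with pytest.raises(ValueError):
            posterior_normal_params(np.array([1, 0]), params, np.array([0.5, 0.0]))


class TestSampleWTheta:
    def test_w_shape_positive_and_null_mean(self, rng):
        Y = pm.ResponseMatrix(rng.integers(0, 2, size=(50, 8)))
        params = pm.ModelParams(A=np.zeros((8, 2)), b=np.zeros(8))
        Theta = rng.normal(size=(50, 2))
        W = sample_w(Y, params, Theta, rng)
        assert W.shape == (50, 8) and np.all(W > 0)
        # all marginals PG(1, 0): pooled mean ~ 1/4
        assert abs(W.mean() - 0.25) <= 3 * W.std() / np.sqrt(W.size)

    def test_w_does_not_depend_on_responses(self, rng):
        """The auxiliary conditional has no y term: identical seeds give
        identical draws for different response matrices."""
        params = pm.ModelParams(A=np.ones((3, 1)), b=np.zeros(3))
        Theta = np.random.default_rng(3).normal(size=(5, 1))
        Y0 = pm.ResponseMatrix(np.zeros((5, 3), dtype=int))
        Y1 = pm.ResponseMatrix(np.ones((5, 3), dtype=int))
        W0 = sample_w(Y0, params, Theta, np.random.default_rng(9))
        W1 = sample_w(Y1, params, Theta, np.random.default_rng(9))
        np.testing.assert_array_equal(W0, W1)

    def test_theta_prior_recovery(self, rng):
        """With A = O the trait conditional is the standard normal prior."""
        n = 10_000
        Y = pm.ResponseMatrix(rng.integers(0, 2, size=(n, 3)))
        params = pm.ModelParams(A=np.zeros((3, 2)), b=np.zeros(3))
        W = np.full((n, 3), 0.25)
        Theta = sample_theta(Y, params, W, rng)
        assert np.abs(Theta.mean(axis=0)).max() <= 3 / np.sqrt(n)
        cov = np.cov(Theta.T)
        assert np.abs(cov - np.eye(2)).max() <= 5 / np.sqrt(n)

    def test_determinism(self, rng):
        Y = pm.ResponseMatrix(rng.integers(0, 2, size=(10, 4)))
        params = pm.ModelParams(A=rng.normal(size=(4, 2)), b=rng.normal(size=4))
        Theta = rng.normal(size=(10, 2))
        r1, r2 = np.random.default_rng(42), np.random.default_rng(42)
        W1 = sample_w(Y, params, Theta, r1)
        W2 = sample_w(Y, params, Theta, r2)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(sample_theta(Y, params, W1, r1), sample_theta(Y, params, W2, r2))


class TestGibbsStationarity:
    def test_chain_matches_exact_posterior_1d(self, rng):
        """K=1: the W->Theta Gibbs chain reproduces the exact latent-trait
        posterior computed by dense quadrature (mean and KS on thinned draws)."""
        a = np.array([[1.0], [0.8], [1.2]])
        b = np.array([0.3, -0.2, 0.0])
        y = np.array([[1, 0, 1]])
        Y = pm.ResponseMatrix(y)
        params = pm.ModelParams(A=a, b=b)

        # exact posterior on a grid
        grid = np.linspace(-6, 6, 4001)
        eta = grid[:, None] * a.ravel() + b
        p = 1 / (1 + np.exp(-eta))
        lik = np.where(y.ravel() == 1, p, 1 - p).prod(axis=1)
        dens = stats.norm.pdf(grid) * lik
        dens /= np.trapezoid(dens, grid)
        exact_mean = np.trapezoid(grid * dens, grid)
        exact_sd = np.sqrt(np.trapezoid((grid - exact_mean) ** 2 * dens, grid))
        cdf_grid = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        cdf_grid /= cdf_grid[-1]

        n_iter, burn, thin = 6000, 500, 5
        theta = rng.standard_normal((1, 1))
        draws = []
        for t in range(n_iter):
            W = sample_w(Y, params, theta, rng)
            theta = sample_theta(Y, params, W, rng)
            if t >= burn:
                draws.append(theta[0, 0])
        draws = np.asarray(draws)
        thinned = draws[::thin]
        se = exact_sd / np.sqrt(thinned.size)
        assert abs(draws.mean() - exact_mean) <= 3.5 * se
        ks = stats.kstest(thinned, lambda x: np.interp(x, grid, cdf_grid))
        assert ks.pvalue > 0.01
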