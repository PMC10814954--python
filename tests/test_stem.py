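import warnings

import numpy as np
import pytest

import prenetmirt as pm
from prenetmirt.penalties import PenaltySpec
from prenetmirt.stem import StemTrajectory, finalize, m_step, penalized_objective, run_stem


def _theta_and_responses(rng, N=200, K=2, J=6, scale=1.0):
    Theta = rng.normal(size=(N, K))
    A = scale * rng.normal(size=(J, K))
    b = 0.5 * rng.normal(size=J)
    eta = Theta @ A.T + b
    Y = (rng.uniform(size=eta.shape) < 1 / (1 + np.exp(-eta))).astype(int)
    return Theta, pm.ResponseMatrix(Y), A, b


class TestMStep:
    def test_unpenalized_matches_logistic_mle(self, rng):
        """rho = 0 reduces each item to a plain logistic regression of
        y_.j on Theta; compare against the statsmodels MLE."""
        import statsmodels.api as sm

        Theta, Y, *_ = _theta_and_responses(rng, N=200)
        init = pm.ModelParams(A=np.zeros((6, 2)), b=np.zeros(6))
        cfg = pm.StemConfig(inner_max_iter=2000, inner_tol=1e-10)
        out = m_step(Y, Theta, init, PenaltySpec("none"), cfg)
        X = np.column_stack([Theta, np.ones(len(Theta))])
        for j in range(Y.n_items):
            mle = sm.Logit(Y.values[:, j], X).fit(disp=0, tol=1e-12)
            np.testing.assert_allclose(out.A[j], mle.params[:2], atol=1e-4)
            assert out.b[j] == pytest.approx(mle.params[2], abs=1e-4)

    def test_monotone_ascent_per_sweep(self, rng):
        """The penalized objective never decreases across inner iterations."""
        Theta, Y, *_ = _theta_and_responses(rng, N=80)
        penalty = PenaltySpec("prenet", rho=0.5, gamma=0.1)
        params = pm.ModelParams(A=rng.normal(size=(6, 2)), b=rng.normal(size=6))
        one_sweep = pm.StemConfig(inner_max_iter=1, inner_tol=0.0)
        obj = penalized_objective(Y, Theta, params, penalty)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(30):
                params = m_step(Y, Theta, params, penalty, one_sweep)
                new_obj = penalized_objective(Y, Theta, params, penalty)
                assert new_obj >= obj - 1e-10
                obj = new_obj

    def test_l1_large_rho_kills_loadings_keeps_intercepts(self, rng):
        """Huge L1 strength zeroes A exactly while the unpenalized
        intercepts converge to the logit of the item means."""
        Theta, Y, *_ = _theta_and_responses(rng, N=300)
        init = pm.ModelParams(A=0.5 * rng.normal(size=(6, 2)), b=np.zeros(6))
        cfg = pm.StemConfig(inner_max_iter=3000, inner_tol=1e-12)
        out = m_step(Y, Theta, init, PenaltySpec("l1", rho=10.0), cfg)
        assert np.all(out.A == 0.0)
        pbar = Y.values.mean(axis=0)
        np.testing.assert_allclose(out.b, np.log(pbar / (1 - pbar)), atol=1e-6)

    def test_prenet_huge_rho_gives_simple_structure(self, rng):
        """With a very strong prenet penalty every row of the M-step
        solution keeps at most one nonzero loading."""
        Theta, Y, *_ = _theta_and_responses(rng, N=150, scale=1.5)
        init = pm.ModelParams(A=rng.normal(size=(6, 2)), b=np.zeros(6))
        cfg = pm.StemConfig(inner_max_iter=3000, inner_tol=1e-12)
        out = m_step(Y, Theta, init, PenaltySpec("prenet", rho=50.0, gamma=0.1), cfg)
        assert np.all(np.count_nonzero(out.A, axis=1) <= 1)

    def test_column_relabel_near_equivariance(self, rng):
        """Relabeling latent dimensions (permuting Theta and init columns)
        permutes the converged M-step solution, up to solver tolerance."""
        Theta, Y, *_ = _theta_and_responses(rng, N=150)
        init = pm.ModelParams(A=0.3 * rng.normal(size=(6, 2)), b=np.zeros(6))
        cfg = pm.StemConfig(inner_max_iter=5000, inner_tol=1e-12)
        pen = PenaltySpec("prenet", rho=0.3, gamma=0.1)
        out = m_step(Y, Theta, init, pen, cfg)
        perm = [1, 0]
        out_p = m_step(Y, Theta[:, perm], pm.ModelParams(A=init.A[:, perm], b=init.b), pen, cfg)
        np.testing.assert_allclose(out_p.A[:, perm], out.A, atol=1e-6)
        np.testing.assert_allclose(out_p.b, out.b, atol=1e-6)

    def test_nonconvergence_warns_not_raises(self, rng):
        Theta, Y, *_ = _theta_and_responses(rng, N=50)
        init = pm.ModelParams(A=rng.normal(size=(6, 2)), b=np.zeros(6))
        cfg = pm.StemConfig(inner_max_iter=1, inner_tol=1e-12)
        with pytest.warns(RuntimeWarning, match="M-step"):
            m_step(Y, Theta, init, PenaltySpec("none"), cfg)


class TestFinalize:
    def test_median_and_mean_rules(self):
        A_seq = np.array([0.0, 0.0, 0.0, 0.5]).reshape(4, 1, 1)
        b_seq = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1)
        out = finalize(StemTrajectory(A_snapshots=A_seq, b_snapshots=b_seq))
        assert out.A[0, 0] == 0.0  # majority zeros -> exact zero (even m)
        assert out.b[0] == pytest.approx(2.5)
        A_seq = np.array([0.4, 0.5, 0.6]).reshape(3, 1, 1)
        b_seq = np.array([1.0, 2.0, 3.0]).reshape(3, 1)
        out = finalize(StemTrajectory(A_snapshots=A_seq, b_snapshots=b_seq))
        assert out.A[0, 0] == pytest.approx(0.5)
        assert out.b[0] == pytest.approx(2.0)

    def test_majority_zero_is_bit_exact(self, rng):
        m = 10
        vals = rng.normal(size=(m, 3, 2))
        vals[: m // 2 + 1, 1, 0] = 0.0  # > m/2 zeros at one entry
        out = finalize(StemTrajectory(A_snapshots=vals, b_snapshots=np.zeros((m, 3))))
        assert out.A[1, 0] == 0.0

    def test_empty_trajectory_errors(self):
        with pytest.raises(ValueError):
            finalize(StemTrajectory(A_snapshots=np.empty((0, 2, 2)), b_snapshots=np.empty((0, 2))))


class TestRunStem:
    def test_determinism(self):
        Y = pm.simulate_responses(pm.benchmark_true_model(60), rng=3)
        cfg = pm.StemConfig(n_burnin=10, n_average=10, seed=99)
        pen = PenaltySpec("prenet", rho=1.0, gamma=0.1)
        t1, p1 = run_stem(Y, 3, pen, cfg)
        t2, p2 = run_stem(Y, 3, pen, cfg)
        np.testing.assert_array_equal(p1.A, p2.A)
        np.testing.assert_array_equal(p1.b, p2.b)
        np.testing.assert_array_equal(t1.A_snapshots, t2.A_snapshots)

    def test_null_truth_recovered_as_exact_zero(self):
        """Data from A = O, b = 0 with an L1 fit: the finalized loading
        matrix is exactly the zero matrix."""
        model = pm.TrueModel(A=np.zeros((8, 2)), b=np.zeros(8), n_subjects=500)
        Y = pm.simulate_responses(model, rng=21)
        cfg = pm.StemConfig(n_burnin=40, n_average=20, seed=4)
        _, params = run_stem(Y, 2, PenaltySpec("l1", rho=0.3), cfg)
        assert np.all(params.A == 0.0)

    def test_high_rho_prenet_produces_exact_zeros(self):
        Y = pm.simulate_responses(pm.benchmark_true_model(100), rng=5)
        cfg = pm.StemConfig(n_burnin=40, n_average=20, seed=6)
        _, params = run_stem(Y, 3, PenaltySpec("prenet", rho=3.0, gamma=0.1), cfg)
        assert np.any(params.A == 0.0)
        assert params.n_nonzero < params.A.size

    def test_trajectory_length_and_history(self):
        Y = pm.simulate_responses(pm.benchmark_true_model(50), rng=8)
        cfg = pm.StemConfig(n_burnin=5, n_average=7, seed=1)
        traj, _ = run_stem(Y, 3, PenaltySpec("prenet", rho=1.0, gamma=0.1), cfg)
        assert traj.n_snapshots == 7
        assert len(traj.history) == 12
        # history rows: (iteration, penalized objective, nonzero count)
        assert all(len(row) == 3 for row in traj.history)

    def test_single_run_structure_recovery_large_n(self):
        """At N = 1000 a single moderate-rho prenet run already recovers
        most of the benchmark simple structure (CER >= 0.9)."""
        Y = pm.simulate_responses(pm.benchmark_true_model(1000), rng=13)
        cfg = pm.StemConfig(n_burnin=60, n_average=40, seed=13)
        _, params = run_stem(Y, 3, PenaltySpec("prenet", rho=1.0, gamma=0.1), cfg)
        assert pm.cer(pm.benchmark_loading_matrix(), params.A) >= 0.9
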