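"""MM algorithm for the penalized variance-component model.

Oracles: dense linear algebra with explicit inverses/determinants on
small problems, numpy's general polynomial solver for the quartic
update, and closed forms for the iid special case.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vclasso.model import (
    VCProblem,
    fit,
    fit_path,
    entry_lambdas,
    lambda_max,
    loglikelihood,
    penalized_objective,
    update_beta,
    update_sigma,
    _positive_quartic_root,
    build_problem,
)

from conftest import random_psd


def small_problem(rng, n=12, m=2, p=2):
    """Random problem: m penalized PSD kernels + unpenalized identity."""
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    V = [random_psd(rng, n) for _ in range(m)] + [np.eye(n)]
    c = np.array([1.0] * m + [0.0])
    y = rng.standard_normal(n) * 2.0 + 1.0
    return VCProblem(y=y, X=X, V=V, c=c)


class TestLoglikelihood:
    def test_zero_residual_unit_variance(self):
        n = 4
        y = np.full(n, 3.0)
        prob = VCProblem(y=y, X=np.ones((n, 1)), V=[np.eye(n)], c=[0.0])
        assert loglikelihood(prob, np.array([3.0]), np.array([1.0])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_scalar_covariance_closed_form(self):
        # V = 2I, n = 2, residual (1,1): L = -ln 2 - 1/2
        y = np.array([1.0, 1.0])
        prob = VCProblem(y=y, X=np.zeros((2, 1)), V=[np.eye(2)], c=[0.0])
        L = loglikelihood(prob, np.array([0.0]), np.array([2.0]))
        assert L == pytest.approx(-np.log(2.0) - 0.5, abs=1e-12)

    def test_matches_dense_oracle(self, rng):
        n, m = 6, 2
        prob = small_problem(rng, n=n, m=m)
        beta = rng.standard_normal(prob.p)
        sigma2 = rng.uniform(0.2, 2.0, m + 1)
        V = sum(s * Vi for s, Vi in zip(sigma2, prob.V))
        r = prob.y - prob.X @ beta
        expected = -0.5 * np.log(np.linalg.det(V)) - 0.5 * r @ np.linalg.inv(V) @ r
        assert loglikelihood(prob, beta, sigma2) == pytest.approx(expected,
                                                                  rel=1e-10)


class TestPenalizedObjective:
    def test_lambda_zero_is_negative_loglik(self, rng):
        prob = small_problem(rng)
        beta = np.zeros(prob.p)
        sigma2 = np.ones(prob.m)
        assert penalized_objective(prob, beta, sigma2, 0.0) == \
            pytest.approx(-loglikelihood(prob, beta, sigma2))

    def test_hand_sum(self, rng):
        # c=(0,1,1), sigma (std dev)=(1,2,3), lambda=1 -> penalty 5
        n = 5
        y = np.arange(n, dtype=float)
        V = [np.eye(n), random_psd(rng, n), random_psd(rng, n)]
        prob = VCProblem(y=y, X=np.ones((n, 1)), V=V, c=[0.0, 1.0, 1.0])
        sigma2 = np.array([1.0, 4.0, 9.0])
        beta = np.array([0.0])
        expected = -loglikelihood(prob, beta, sigma2) + 5.0
        assert penalized_objective(prob, beta, sigma2, 1.0) == \
            pytest.approx(expected)

    def test_negative_sigma_rejected(self, rng):
        prob = small_problem(rng)
        with pytest.raises(ValueError):
            penalized_objective(prob, np.zeros(prob.p),
                                np.array([1.0, -0.1, 1.0]), 1.0)

    def test_penalty_weight_rescaling_invariance(self, rng):
        # doubling lambda while halving all c_i leaves the objective unchanged
        n = 8
        V = [random_psd(rng, n), np.eye(n)]
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        p1 = VCProblem(y=y, X=X, V=V, c=[1.0, 0.0])
        p2 = VCProblem(y=y, X=X, V=V, c=[0.5, 0.0])
        s2 = np.array([0.7, 1.3])
        b = np.array([0.1])
        assert penalized_objective(p1, b, s2, 0.8) == \
            pytest.approx(penalized_objective(p2, b, s2, 1.6))


class TestUpdateBeta:
    def test_identity_covariance_is_ols(self, rng):
        n, p = 20, 3
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        prob = VCProblem(y=y, X=X, V=[np.eye(n)], c=[0.0])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(update_beta(prob, np.array([1.0])), ols,
                                   atol=1e-10)

    def test_intercept_only_gives_mean(self, rng):
        y = rng.standard_normal(15)
        prob = VCProblem(y=y, X=np.ones((15, 1)), V=[np.eye(15)], c=[0.0])
        assert update_beta(prob, np.array([2.5]))[0] == pytest.approx(y.mean())

    def test_matches_explicit_inverse_formula(self, rng):
        n, p = 5, 2
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        V = [random_psd(rng, n) + 0.5 * np.eye(n)]
        prob = VCProblem(y=y, X=X, V=V, c=[0.0])
        s2 = np.array([1.7])
        Vinv = np.linalg.inv(s2[0] * V[0])
        expected = np.linalg.inv(X.T @ Vinv @ X) @ X.T @ Vinv @ y
        np.testing.assert_allclose(update_beta(prob, s2), expected, atol=1e-10)

    def test_collinear_design_raises(self, rng):
        n = 10
        x = rng.standard_normal(n)
        X = np.column_stack([x, 2 * x])
        prob = VCProblem(y=rng.standard_normal(n), X=X, V=[np.eye(n)], c=[0.0])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            update_beta(prob, np.array([1.0]))


class TestQuarticUpdate:
    def test_lambda_zero_closed_form(self):
        # 2 s^4 - 8 = 0 -> s^2 = 2
        assert _positive_quartic_root(2.0, 0.0, 8.0) ** 2 == pytest.approx(2.0)

    def test_known_root(self):
        # s^4 + s^3 - 1 = 0, unique positive root ~ 0.8191725
        s = _positive_quartic_root(1.0, 1.0, 1.0)
        roots = np.roots([1.0, 1.0, 0.0, 0.0, -1.0])
        pos = [r.real for r in roots if abs(r.imag) < 1e-12 and r.real > 0]
        assert len(pos) == 1
        assert s == pytest.approx(pos[0], abs=1e-10)

    @given(tr=st.floats(0.01, 100.0), lam=st.floats(0.0, 50.0),
           k=st.floats(1e-6, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_matches_polynomial_solver(self, tr, lam, k):
        s = _positive_quartic_root(tr, lam, k)
        roots = np.roots([tr, lam, 0.0, 0.0, -k])
        pos = [r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0]
        assert len(pos) == 1  # exactly one sign change in coefficients
        assert s == pytest.approx(pos[0], rel=1e-10, abs=1e-12)

    def test_zero_sigma_is_absorbing(self, rng):
        prob = small_problem(rng, m=2)
        sigma2 = np.array([0.0, 0.5, 1.0])
        beta = update_beta(prob, sigma2)
        out = update_sigma(prob, beta, sigma2, lam=0.1)
        assert out[0] == 0.0
        assert np.all(out[1:] > 0)

    def test_update_sigma_matches_oracle_polynomial(self, rng):
        prob = small_problem(rng, n=10, m=3)
        sigma2 = rng.uniform(0.3, 1.5, 4)
        beta = update_beta(prob, sigma2)
        lam = 0.7
        # oracle: rebuild tr_i and q_i densely, solve with np.roots
        V = sum(s * Vi for s, Vi in zip(sigma2, prob.V))
        Vinv = np.linalg.inv(V)
        r = prob.y - prob.X @ beta
        out = update_sigma(prob, beta, sigma2, lam)
        for i, Vi in enumerate(prob.V):
            tr = np.trace(Vinv @ Vi)
            q = r @ Vinv @ Vi @ Vinv @ r
            k = sigma2[i] ** 2 * q
            roots = np.roots([tr, lam * prob.c[i], 0.0, 0.0, -k])
            pos = [z.real for z in roots if abs(z.imag) < 1e-9 and z.real > 0]
            assert out[i] == pytest.approx(pos[0] ** 2, rel=1e-8)


class TestFit:
    def test_iid_mle_closed_form(self, rng):
        y = rng.normal(2.0, 1.5, 40)
        prob = VCProblem(y=y, X=np.ones((40, 1)), V=[np.eye(40)], c=[0.0])
        res = fit(prob, lam=0.0, tol=1e-12)
        rss = np.sum((y - y.mean()) ** 2)
        assert res.converged
        assert res.sigma2[0] == pytest.approx(rss / 40, abs=1e-8)
        assert res.beta[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_large_lambda_all_sparse_gls(self, rng):
        prob = small_problem(rng, n=15, m=3)
        res = fit(prob, lam=1e3, tol=1e-10)
        assert not res.selected.any()
        np.testing.assert_array_equal(res.sigma2[:3], 0.0)
        # beta equals the fit under unpenalized components only
        null = VCProblem(y=prob.y, X=prob.X, V=[prob.V[-1]], c=[0.0])
        ref = fit(null, lam=0.0, tol=1e-10)
        np.testing.assert_allclose(res.beta, ref.beta, atol=1e-8)

    def test_objective_trace_non_increasing(self, rng):
        for _ in range(10):
            prob = small_problem(rng, n=14, m=3)
            for lam in (0.0, 0.1, 1.0):
                res = fit(prob, lam=lam)
                diffs = np.diff(res.objective_trace)
                scale = 1.0 + np.abs(res.objective_trace[:-1])
                assert np.all(diffs <= 1e-8 * scale)

    def test_default_tolerance_documented(self):
        import inspect
        sig = inspect.signature(fit)
        assert sig.parameters["tol"].default == 1e-4

    def test_nonconvergence_flag_not_exception(self, rng):
        prob = small_problem(rng, n=12, m=2)
        res = fit(prob, lam=0.0, tol=1e-14, max_iter=2)
        assert not res.converged

    def test_sigma_nonnegative(self, rng):
        prob = small_problem(rng, n=12, m=4)
        res = fit(prob, lam=0.5)
        assert np.all(res.sigma2 >= 0)


class TestFitPath:
    def test_single_lambda_max_grid(self, rng):
        prob = small_problem(rng, n=15, m=3)
        lmax = lambda_max(prob)
        path = fit_path(prob, lambdas=np.array([lmax]))
        assert len(path) == 1
        assert not path[0].selected.any()

    def test_warm_cold_lambda_zero_agree(self, rng):
        prob = small_problem(rng, n=15, m=2)
        lmax = lambda_max(prob)
        grid = lmax * np.geomspace(1.0, 1e-12, 8)
        grid[-1] = 0.0
        warm = fit_path(prob, lambdas=grid, tol=1e-8)[-1]
        cold = fit(prob, lam=0.0, tol=1e-8)
        assert warm.objective == pytest.approx(cold.objective, abs=1e-4)
        np.testing.assert_allclose(warm.sigma2, cold.sigma2,
                                   atol=1e-3 * np.var(prob.y))

    def test_true_components_enter_before_null(self, rng):
        # strong planted signal: true kernels get variance 100
        n, m_true, m_null = 60, 2, 4
        Ks = [random_psd(rng, n) for _ in range(m_true + m_null)]
        cov = 1e-2 * np.eye(n)
        for K in Ks[:m_true]:
            cov += 100.0 * K
        y = np.linalg.cholesky(cov) @ rng.standard_normal(n)
        prob = VCProblem(y=y, X=np.ones((n, 1)),
                         V=Ks + [np.eye(n)],
                         c=[1.0] * (m_true + m_null) + [0.0])
        path = fit_path(prob, n_lambda=12, min_ratio=1e-3)
        entry = entry_lambdas(path)[:m_true + m_null]
        assert entry[:m_true].min() > entry[m_true:].max()

    def test_empty_grid_rejected(self, rng):
        prob = small_problem(rng)
        with pytest.raises(ValueError, match="empty"):
            fit_path(prob, lambdas=np.array([]))


class TestOracleEquivalence:
    def test_final_objective_at_least_as_good_as_multistart(self, rng):
        """MM end point vs a generic box-constrained optimizer (10 starts)."""
        from scipy.optimize import minimize

        for trial in range(5):
            prob = small_problem(rng, n=10, m=2)
            lam = (0.0, 0.3, 1.0)[trial % 3]

            def objective(s):
                s2 = s**2
                beta = update_beta(prob, s2)
                return penalized_objective(prob, beta, s2, lam)

            best = np.inf
            for _ in range(10):
                s0 = rng.uniform(0.05, 2.0, prob.m) * prob.y.std()
                r = minimize(objective, s0, method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12,
                                      "maxiter": 4000})
                best = min(best, r.fun)
            res = fit(prob, lam=lam, tol=1e-10)
            assert res.objective <= best + 1e-6


class TestBuildProblem:
    def test_components_and_penalties(self, rng):
        n = 9
        subj = np.repeat(["a", "b", "c"], 3)
        K = {"g1": random_psd(rng, n), "g2": random_psd(rng, n)}
        prob = build_problem(rng.standard_normal(n), np.ones((n, 1)), K,
                             subject_of=subj)
        assert prob.names == ["g1", "g2", "subject", "residual"]
        np.testing.assert_array_equal(prob.c, [1.0, 1.0, 0.0, 0.0])
        # ZZ' block structure: 1 within subject, 0 across
        ZZ = prob.V[2]
        assert ZZ[0, 2] == 1.0 and ZZ[0, 3] == 0.0
        np.testing.assert_array_equal(prob.V[3], np.eye(n))
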