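"""Homotopy path solver: step oracles, path invariants, recovery."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from fmtomo.homotopy import (
    HomotopyLasso,
    active_direction,
    homotopy_solve,
    residual_correlations,
    step_sizes,
    update_support,
)


def random_orthonormal(m, n, rng):
    q, _ = np.linalg.qr(rng.standard_normal((m, m)))
    return q[:, :n]


class TestResidualCorrelations:
    def test_zero_start_gives_gram_projection_of_data(self, rng):
        A = rng.standard_normal((6, 10))
        b = rng.standard_normal(6)
        np.testing.assert_allclose(residual_correlations(A, b, np.zeros(10)), A.T @ b)

    def test_least_squares_solution_zeroes_correlations(self, rng):
        A = rng.standard_normal((8, 8)) + 4 * np.eye(8)
        b = rng.standard_normal(8)
        x = np.linalg.solve(A, b)
        np.testing.assert_allclose(residual_correlations(A, b, x), 0.0, atol=1e-9)

    def test_matches_dense_arithmetic(self, rng):
        A = rng.standard_normal((6, 10))
        b = rng.standard_normal(6)
        x = rng.standard_normal(10)
        expected = np.array([A[:, j] @ (b - A @ x) for j in range(10)])
        np.testing.assert_allclose(residual_correlations(A, b, x), expected, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            residual_correlations(rng.standard_normal((6, 10)), np.zeros(5), np.zeros(10))


class TestUpdateSupport:
    def test_unique_maximizer(self):
        np.testing.assert_array_equal(update_support(np.array([3.0, -1.0, 0.5]), 3.0), [0])

    def test_tied_correlations_both_enter(self):
        np.testing.assert_array_equal(update_support(np.array([2.0, -2.0, 1.0]), 2.0), [0, 1])

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            c = rng.standard_normal(15)
            lam = abs(rng.standard_normal()) + 0.1
            tol = 1e-10
            expected = [i for i in range(15) if abs(c[i]) >= lam - tol]
            if not expected:
                continue
            np.testing.assert_array_equal(update_support(c, lam, tol), expected)


class TestActiveDirection:
    def test_single_column_scalar_normal_equation(self, rng):
        A = rng.standard_normal((8, 5))
        c = rng.standard_normal(5)
        d = active_direction(A, c, [2])
        assert d[2] == pytest.approx(np.sign(c[2]) / (A[:, 2] @ A[:, 2]))
        assert np.count_nonzero(d) == 1

    def test_orthonormal_columns_give_sign_vector(self, rng):
        A = random_orthonormal(10, 6, rng)
        c = rng.standard_normal(6)
        d = active_direction(A, c, [0, 3, 5])
        np.testing.assert_allclose(d[[0, 3, 5]], np.sign(c[[0, 3, 5]]), atol=1e-12)

    def test_matches_explicit_gram_solve(self, rng):
        A = rng.standard_normal((8, 12))
        c = rng.standard_normal(12)
        I = [1, 4, 7]
        d = active_direction(A, c, I)
        gram = A[:, I].T @ A[:, I]
        np.testing.assert_allclose(d[I], np.linalg.solve(gram, np.sign(c[I])), rtol=1e-10)


class TestStepSizes:
    def test_no_removal_when_signs_align(self, rng):
        A = rng.standard_normal((6, 8))
        I = [0, 1]
        x = np.zeros(8)
        x[I] = [1.0, 2.0]
        d = np.zeros(8)
        d[I] = [0.5, 0.5]  # -x/d < 0 on all of I
        c = A.T @ np.ones(6)
        gp, jp, gm, jm = step_sizes(A, c, x, d, I, lam=10.0)
        assert gm == np.inf and jm is None

    def test_single_column_path_terminates_at_least_squares(self, rng):
        a = rng.standard_normal(7).reshape(-1, 1)
        b = rng.standard_normal(7)
        x, state = homotopy_solve(a, b, residual_tol=0.0, lam_min=1e-12)
        ls = (a.ravel() @ b) / (a.ravel() @ a.ravel())
        assert x[0] == pytest.approx(ls, rel=1e-6)

    def test_matches_brute_force_crossing_enumeration(self, rng):
        for _ in range(10):
            m, n = 10, 20
            A = rng.standard_normal((m, n))
            b = rng.standard_normal(m)
            x = np.zeros(n)
            c = residual_correlations(A, b, x)
            lam = np.max(np.abs(c))
            I = list(np.atleast_1d(update_support(c, lam)))
            d = active_direction(A, c, I)
            # take one event so x is nonzero on I, then enumerate from there
            gp, jp, gm, jm = step_sizes(A, c, x, d, I, lam)
            gamma = min(gp, gm)
            x[I] += gamma * d[I]
            lam -= gamma
            if jp is not None and gp < gm:
                I.append(jp)
            c = residual_correlations(A, b, x)
            d = active_direction(A, c, I)
            gp, jp, gm, jm = step_sizes(A, c, x, d, I, lam)
            # brute force over every candidate crossing
            best_plus, best_minus = np.inf, np.inf
            for i in range(n):
                if i in I:
                    if d[i] != 0 and -x[i] / d[i] > 1e-10:
                        best_minus = min(best_minus, -x[i] / d[i])
                else:
                    v = A[:, i] @ (A[:, I] @ d[I])
                    for cand in ((lam - c[i]) / (1 - v), (lam + c[i]) / (1 + v)):
                        if cand > 1e-10:
                            best_plus = min(best_plus, cand)
            assert gp == pytest.approx(best_plus)
            assert gm == pytest.approx(best_minus) or (gm is np.inf and best_minus is np.inf)


class TestHomotopySolve:
    def test_zero_data_returns_zero_without_iterating(self):
        x, state = homotopy_solve(np.eye(4), np.zeros(4))
        assert not x.any()
        assert state.iteration == 0
        assert state.stop_reason == "zero_signal"

    def test_orthonormal_path_is_soft_thresholding(self, rng):
        A = random_orthonormal(40, 25, rng)
        b = rng.standard_normal(40)
        _, state = homotopy_solve(A, b, residual_tol=0.0, lam_min=1e-10,
                                  max_active=25, max_iter=300)
        c0 = A.T @ b
        for lam, x in zip(state.path_lambdas, state.path_coefs):
            soft = np.sign(c0) * np.maximum(np.abs(c0) - lam, 0.0)
            np.testing.assert_allclose(x, soft, atol=1e-10)

    def test_matches_coordinate_descent_lasso_at_visited_lambdas(self, rng):
        A = rng.standard_normal((20, 50))
        x_true = np.zeros(50)
        x_true[[3, 17, 40]] = [2.0, -1.5, 1.0]
        b = A @ x_true
        _, state = homotopy_solve(A, b, residual_tol=0.0,
                                  lam_min=1e-4 * np.max(np.abs(A.T @ b)),
                                  max_active=19, max_iter=300)
        for lam, x in list(zip(state.path_lambdas, state.path_coefs))[1::3]:
            oracle = Lasso(alpha=lam / 20, fit_intercept=False, tol=1e-13,
                           max_iter=200000).fit(A, b)
            np.testing.assert_allclose(x, oracle.coef_, atol=1e-6)

    def test_exact_support_recovery_noiseless(self, rng):
        A = rng.standard_normal((20, 50))
        x_true = np.zeros(50)
        x_true[[3, 17, 40]] = [2.0, -1.5, 1.0]
        b = A @ x_true
        x, state = homotopy_solve(A, b, residual_tol=1e-10, lam_min=0.0,
                                  max_active=15, max_iter=300)
        support = np.flatnonzero(np.abs(x) > 1e-8 * np.abs(x).max())
        np.testing.assert_array_equal(support, [3, 17, 40])
        np.testing.assert_allclose(x, x_true, atol=1e-8)

    def test_kkt_invariants_hold_along_path(self, rng):
        for _ in range(5):
            A = rng.standard_normal((15, 40))
            b = rng.standard_normal(15)
            _, state = homotopy_solve(A, b, residual_tol=0.0,
                                      lam_min=1e-6 * np.max(np.abs(A.T @ b)),
                                      max_active=14, max_iter=300)
            for lam, x in zip(state.path_lambdas, state.path_coefs):
                c = A.T @ (b - A @ x)
                on = np.abs(x) > 0
                if (~on).any():
                    assert np.max(np.abs(c[~on])) <= lam + 1e-7
                if on.any():
                    np.testing.assert_allclose(np.abs(c[on]), lam, atol=1e-7)

    def test_lambda_monotone_decreasing_and_single_events(self, rng):
        A = rng.standard_normal((15, 30))
        b = rng.standard_normal(15)
        _, state = homotopy_solve(A, b, residual_tol=0.0,
                                  lam_min=1e-6 * np.max(np.abs(A.T @ b)),
                                  max_active=14, max_iter=300)
        lams = state.path_lambdas
        assert all(b < a for a, b in zip(lams, lams[1:]))
        sizes = [rec[5] for rec in state.step_history]
        for prev, cur in zip(sizes, sizes[1:]):
            assert abs(cur - prev) <= 1

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            homotopy_solve(np.array([[np.nan, 1.0]]), np.array([1.0]))


class TestHomotopyLassoEstimator:
    def test_fit_predict_roundtrip(self, rng):
        A = rng.standard_normal((30, 10))
        x_true = np.zeros(10)
        x_true[[1, 6]] = [1.5, -2.0]
        y = A @ x_true
        est = HomotopyLasso(residual_tol=1e-10, lam_min=1e-10, max_active=8).fit(A, y)
        np.testing.assert_allclose(est.coef_, x_true, atol=1e-6)
        np.testing.assert_allclose(est.predict(A), y, atol=1e-5)
        assert est.lambda_ >= 0
        assert set(np.flatnonzero(np.abs(est.coef_) > 1e-8)) <= set(est.active_set_)

    def test_get_set_params_roundtrip(self):
        est = HomotopyLasso(residual_tol=0.01)
        params = est.get_params()
        assert params["residual_tol"] == 0.01
        est.set_params(max_active=7)
        assert est.max_active == 7
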