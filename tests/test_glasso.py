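"""Penalized precision estimation: closed forms, independent solvers,
cross-validation, Fisher transform, condition-mean GLM."""

import numpy as np
import pytest

from dynconn.glasso import (
    condition_mean_glm,
    default_lambda_grid,
    fisher_transform_matrix,
    glasso_fit,
    select_lambda_cv,
)
from dynconn.windows import CONDITIONS


# ------------------------------------------------------------- oracles
def p2_closed_form(S, lam):
    """Closed-form covariance for the 2x2 diagonal-penalized problem:
    W_ii = S_ii + lam, W_12 = sign(S_12) * max(|S_12| - lam, 0)."""
    W = np.array(
        [
            [S[0, 0] + lam, np.sign(S[0, 1]) * max(abs(S[0, 1]) - lam, 0.0)],
            [0.0, S[1, 1] + lam],
        ]
    )
    W[1, 0] = W[0, 1]
    return W


def admm_glasso(S, lam, rho=1.0, n_iter=4000, pen_diag=True):
    """Independent reference solver (ADMM with eigendecomposition-based
    proximal step), structurally unrelated to the package's proximal
    gradient scheme."""
    n = S.shape[0]
    Z = np.eye(n)
    U = np.zeros((n, n))
    for _ in range(n_iter):
        theta, Q = np.linalg.eigh(rho * (Z - U) - S)
        x_eig = (theta + np.sqrt(theta**2 + 4 * rho)) / (2 * rho)
        X = (Q * x_eig) @ Q.T
        A = X + U
        Znew = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        if not pen_diag:
            np.fill_diagonal(Znew, np.diag(A))
        U = U + X - Znew
        Z = Znew
    return Z


class TestGlassoFit:
    def test_lambda_zero_is_inverse(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = glasso_fit(S, 0.0)
        np.testing.assert_allclose(fit.precision,
                                   [[4 / 3, -2 / 3], [-2 / 3, 4 / 3]],
                                   atol=1e-6)

    def test_large_lambda_diagonal(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = glasso_fit(S, 0.6, tol=1e-9, max_iter=10000)
        assert fit.precision[0, 1] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(np.diag(fit.covariance), 1.6, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.2, 0.35, 0.49])
    def test_p2_closed_form_grid(self, lam):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = glasso_fit(S, lam, tol=1e-10, max_iter=50000)
        np.testing.assert_allclose(fit.covariance, p2_closed_form(S, lam),
                                   atol=1e-6)

    def test_p3_matches_admm_reference(self, rng):
        X = rng.standard_normal((30, 3))
        S = np.cov(X.T, bias=True)
        for lam in (0.05, 0.15, 0.3):
            fit = glasso_fit(S, lam, tol=1e-10, max_iter=50000)
            ref = admm_glasso(S, lam)
            assert np.max(np.abs(fit.precision - ref)) < 1e-4

    def test_p14_matches_admm_reference(self, rng):
        X = rng.standard_normal((20, 14))
        S = np.cov(X.T, bias=True)
        fit = glasso_fit(S, 0.1, tol=1e-9, max_iter=50000)
        ref = admm_glasso(S, 0.1, n_iter=6000)
        assert np.max(np.abs(fit.precision - ref)) < 5e-4

    def test_offdiag_mode_matches_sklearn(self, rng):
        from sklearn.covariance import graphical_lasso

        X = rng.standard_normal((200, 8))
        S = np.cov(X.T, bias=True)
        for lam in (0.05, 0.2):
            fit = glasso_fit(S, lam, tol=1e-10, max_iter=50000,
                             penalize_diagonal=False)
            _, prec = graphical_lasso(S, alpha=lam, tol=1e-12, max_iter=2000)
            assert np.max(np.abs(fit.precision - prec)) < 1e-3
            # off-diagonal-only penalty keeps the covariance diagonal at S
            np.testing.assert_allclose(np.diag(fit.covariance), np.diag(S),
                                       atol=1e-5)

    def test_invariants(self, rng):
        X = rng.standard_normal((10, 5))
        S = np.cov(X.T, bias=True)  # singular (10 > 5 ok, make singular)
        S = S[:5, :5]
        fit = glasso_fit(S, 0.1, tol=1e-8, max_iter=20000)
        assert fit.converged
        # precision symmetric PD, W * Omega = I
        np.testing.assert_allclose(fit.precision, fit.precision.T)
        assert np.linalg.eigvalsh(fit.precision)[0] > 0
        assert np.max(np.abs(fit.covariance @ fit.precision - np.eye(5))) < 1e-4

    def test_lambda_monotone_sparsity(self, rng):
        X = rng.standard_normal((12, 6))
        S = np.cov(X.T, bias=True)
        nnz = []
        for lam in np.linspace(0.01, 0.6, 12):
            fit = glasso_fit(S, lam, tol=1e-8, max_iter=20000)
            nnz.append(int(np.sum(np.abs(fit.precision) > 1e-7)) )
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((40, 5))
        S = np.cov(X.T, bias=True)
        perm = rng.permutation(5)
        fit = glasso_fit(S, 0.1, tol=1e-10, max_iter=50000)
        fit_p = glasso_fit(S[np.ix_(perm, perm)], 0.1, tol=1e-10,
                           max_iter=50000)
        np.testing.assert_allclose(fit_p.precision,
                                   fit.precision[np.ix_(perm, perm)],
                                   atol=1e-6)

    def test_negative_lambda_errors(self):
        with pytest.raises(ValueError, match="non-negative"):
            glasso_fit(np.eye(2), -0.1)

    def test_nonconvergence_flagged_not_raised(self, rng):
        X = rng.standard_normal((8, 14))
        S = X.T @ X / 8
        fit = glasso_fit(S, 0.01, tol=1e-12, max_iter=3)
        assert not fit.converged
        assert fit.n_iterations == 3


class TestSelectLambdaCV:
    def test_single_grid_value(self, rng):
        covs = [np.cov(rng.standard_normal((9, 4)).T, bias=True)
                for _ in range(5)]
        sel = select_lambda_cv(covs, grid=np.array([0.2]))
        assert sel.lam == 0.2

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            select_lambda_cv([np.eye(3)])

    def test_recovers_interior_lambda_and_sparsity(self, rng):
        """With a sparse 14-node ground-truth precision, the selected
        penalty is interior to the grid and the selected fit is sparser
        than the unpenalized one."""
        n = 14
        omega = np.eye(n)
        for i in range(0, n - 1, 2):
            omega[i, i + 1] = omega[i + 1, i] = 0.4
        sigma = np.linalg.inv(omega)
        L = np.linalg.cholesky(sigma)
        covs = []
        for _ in range(40):
            X = rng.standard_normal((8, n)) @ L.T
            covs.append(np.cov(X.T, bias=True))
        sel = select_lambda_cv(covs)
        grid = sel.grid
        assert grid[0] < sel.lam < grid[-1]
        fit_sel = glasso_fit(np.mean(covs, axis=0), sel.lam)
        fit_zero = glasso_fit(np.mean(covs, axis=0), 0.0)
        nnz = lambda m: int(np.sum(np.abs(m[~np.eye(n, dtype=bool)]) > 1e-7))
        assert nnz(fit_sel.precision) < nnz(fit_zero.precision)

    def test_ties_take_smaller_lambda(self):
        covs = [np.eye(3), np.eye(3), np.eye(3)]
        sel = select_lambda_cv(covs, grid=np.array([0.1, 0.1]))
        assert sel.lam == 0.1

    def test_default_grid_spans_offdiag_scale(self, rng):
        covs = [np.cov(rng.standard_normal((9, 4)).T, bias=True)
                for _ in range(6)]
        grid = default_lambda_grid(covs)
        top = np.max(np.abs(np.mean(covs, axis=0)[~np.eye(4, dtype=bool)]))
        assert len(grid) == 20
        assert grid[-1] == pytest.approx(top)
        assert grid[0] == pytest.approx(1e-3 * top)


class TestFisherTransform:
    def test_values(self):
        W = np.array([[1.0, 0.5, 0.0],
                      [0.5, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
        W = W + 0.0
        Z = fisher_transform_matrix(W + 1e-9 * np.eye(3))
        assert Z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-4)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(np.diag(Z), 0.0)

    def test_near_unit_correlation_clipped(self):
        W = np.array([[1.0, 0.9999999], [0.9999999, 1.0]])
        W = W + 1e-6 * np.eye(2)
        Z = fisher_transform_matrix(W)
        assert np.isfinite(Z).all()

    def test_scale_invariance(self, rng):
        """The transform depends only on the correlation structure."""
        A = rng.standard_normal((30, 4))
        W = np.cov(A.T)
        d = np.diag([2.0, 0.5, 1.5, 3.0])
        np.testing.assert_allclose(fisher_transform_matrix(d @ W @ d),
                                   fisher_transform_matrix(W), atol=1e-10)

    def test_non_pd_errors(self):
        with pytest.raises(ValueError, match="positive definite"):
            fisher_transform_matrix(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestConditionMeanGlm:
    def test_identical_windows_give_that_matrix(self, rng):
        Z = rng.standard_normal((4, 4))
        Z = Z + Z.T
        np.fill_diagonal(Z, 0.0)
        mats = [(c, Z) for c in CONDITIONS for _ in range(3)]
        out = condition_mean_glm(mats)
        for c in CONDITIONS:
            np.testing.assert_allclose(out[c].matrix, Z, atol=1e-12)

    def test_glm_equals_per_condition_mean(self, rng):
        mats = []
        store = {c: [] for c in CONDITIONS}
        for c in CONDITIONS:
            for _ in range(4):
                Z = rng.standard_normal((5, 5))
                Z = Z + Z.T
                np.fill_diagonal(Z, 0.0)
                mats.append((c, Z))
                store[c].append(Z)
        out = condition_mean_glm(mats)
        for c in CONDITIONS:
            np.testing.assert_allclose(out[c].matrix,
                                       np.mean(store[c], axis=0),
                                       atol=1e-10)

    def test_missing_condition_errors(self, rng):
        Z = np.zeros((3, 3))
        mats = [(c, Z) for c in CONDITIONS if c != "after"]
        with pytest.raises(ValueError, match="after"):
            condition_mean_glm(mats)
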