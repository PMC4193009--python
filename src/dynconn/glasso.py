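"""Sparse regularized covariance estimation per window.

Each tapered window yields an empirical covariance S with at most L ranks
for N = 14 regions; the precision matrix Omega is estimated by maximizing
the penalized Gaussian log-likelihood

    log det(Omega) - tr(S Omega) - lambda * ||Omega||_1,

with the l1 penalty over all entries (an off-diagonal-only variant is
available).  The solver is a monotone proximal-gradient scheme (G-ISTA):
gradient step on the smooth part, elementwise soft-threshold, backtracking
line search that enforces both positive definiteness and the majorization
bound.  It is robust on the rank-deficient window covariances this
pipeline produces.  The penalty lambda is selected per subject by
leave-one-window-out cross-validated held-out likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._solver import solve_glasso
from .windows import CONDITIONS, WindowedCov

__all__ = [
    "GlassoFit",
    "ConditionMatrix",
    "LambdaSelection",
    "glasso_fit",
    "default_lambda_grid",
    "select_lambda_cv",
    "fisher_transform_matrix",
    "condition_mean_glm",
]

log = logging.getLogger(__name__)


@dataclass
class GlassoFit:
    """One penalized precision/covariance fit."""

    lam: float
    precision: np.ndarray
    covariance: np.ndarray
    objective: float
    n_iterations: int
    converged: bool


def _chol_logdet(a: np.ndarray) -> float | None:
    """log det via Cholesky; None if not positive definite."""
    try:
        c = np.linalg.cholesky(a)
    except np.linalg.LinAlgError:
        return None
    return 2.0 * float(np.sum(np.log(np.diag(c))))


def _penalty(om: np.ndarray, penalize_diagonal: bool) -> float:
    p = np.abs(om).sum()
    if not penalize_diagonal:
        p -= np.abs(np.diag(om)).sum()
    return float(p)


def glasso_fit(
    S: np.ndarray | WindowedCov,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 500,
    penalize_diagonal: bool = True,
    precision_init: np.ndarray | None = None,
) -> GlassoFit:
    """Penalized maximum-likelihood precision estimate for one window.

    ``S`` must be symmetric positive semidefinite (a diagonal jitter of
    1e-8 is added if it is singular); ``lam >= 0``.  Convergence is
    declared when the duality-gap surrogate
    ``|tr(S Omega) + lam * pen(Omega) - N|`` falls below ``tol``.
    Non-convergence within ``max_iter`` returns a flagged fit rather than
    raising.  ``lam = 0`` is the plain inverse of (jittered) S.
    ``precision_init`` warm-starts the solver (used along the
    cross-validation path and for per-window fits at a shared penalty).
    """
    if isinstance(S, WindowedCov):
        S = S.matrix
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    S = 0.5 * (S + S.T)
    n = S.shape[0]
    if np.linalg.eigvalsh(S)[0] < 1e-10:
        S = S + 1e-8 * np.eye(n)
    if lam == 0:
        om = np.linalg.inv(S)
        om = 0.5 * (om + om.T)
        ld = _chol_logdet(om)
        obj = (ld if ld is not None else -np.inf) - float(np.sum(S * om))
        return GlassoFit(0.0, om, S.copy(), obj, 0, True)

    if precision_init is not None:
        x0 = np.ascontiguousarray(precision_init, dtype=float)
    else:
        x0 = np.diag(1.0 / (np.diag(S) + lam))
    om, it, converged = solve_glasso(
        np.ascontiguousarray(S), float(lam), float(tol), int(max_iter),
        bool(penalize_diagonal), x0,
    )
    W = np.linalg.inv(om)
    W = 0.5 * (W + W.T)
    obj = _chol_logdet(om) - float(np.sum(S * om)) - lam * _penalty(
        om, penalize_diagonal
    )
    if not converged:
        log.warning("glasso did not converge in %d iterations (lam=%.4g)",
                    max_iter, lam)
    return GlassoFit(float(lam), om, W, obj, int(it), bool(converged))


def default_lambda_grid(
    windows: list[WindowedCov | np.ndarray], n_lambdas: int = 20
) -> np.ndarray:
    """Log-spaced grid in [1e-3, 1] x max |off-diagonal| of the mean
    windowed covariance."""
    mats = [w.matrix if isinstance(w, WindowedCov) else np.asarray(w)
            for w in windows]
    sbar = np.mean(mats, axis=0)
    off = sbar[~np.eye(sbar.shape[0], dtype=bool)]
    top = float(np.max(np.abs(off)))
    if top <= 0:
        top = 1.0
    return top * np.logspace(-3, 0, n_lambdas)


@dataclass
class LambdaSelection:
    """Selected penalty plus the cross-validation curve behind it."""

    lam: float
    grid: np.ndarray
    mean_scores: np.ndarray  # NaN where every fit failed to converge

    def __float__(self) -> float:
        return float(self.lam)


def select_lambda_cv(
    windows: list[WindowedCov | np.ndarray],
    grid: np.ndarray | None = None,
    n_lambdas: int = 20,
    tol: float = 1e-5,
    max_iter: int = 500,
    penalize_diagonal: bool = True,
) -> LambdaSelection:
    """Leave-one-window-out cross-validation of the penalty.

    For each lambda and each held-out window, a fit on the average of the
    remaining windows' covariances is scored on the held-out covariance by
    the Gaussian log-likelihood ``log det Omega - tr(S_ho Omega)``; the
    lambda with the highest mean held-out score wins, ties going to the
    smaller lambda.  Lambdas at which any fold fails to converge are
    removed from contention with a warning.  Fits along the grid are
    warm-started from the neighbouring lambda.
    """
    mats = [np.asarray(w.matrix if isinstance(w, WindowedCov) else w, float)
            for w in windows]
    if len(mats) < 2:
        raise ValueError("cross-validation needs at least 2 windows")
    if grid is None:
        grid = default_lambda_grid(windows, n_lambdas)
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    n_w = len(mats)
    total = np.sum(mats, axis=0)
    scores = np.zeros((len(grid), n_w))
    ok = np.ones(len(grid), dtype=bool)
    n = mats[0].shape[0]
    # path over the grid, largest lambda first; every fold at a given
    # lambda warm-starts from the fit on the subject-mean covariance,
    # which the leave-one-out training matrices sit very close to
    mean_om = None
    mean_cov = total / n_w
    for j in range(len(grid) - 1, -1, -1):
        mean_fit = _warm_fit(mean_cov, grid[j], mean_om, tol, max_iter,
                             penalize_diagonal)
        mean_om = mean_fit.precision
        for i, S_ho in enumerate(mats):
            s_train = (total - S_ho) / (n_w - 1)
            fit = _warm_fit(s_train, grid[j], mean_om, tol, max_iter,
                            penalize_diagonal)
            if not fit.converged:
                ok[j] = False
            ld = _chol_logdet(fit.precision)
            scores[j, i] = (ld if ld is not None else -np.inf) - float(
                np.sum(S_ho * fit.precision)
            )
    if not ok.any():
        raise RuntimeError("no lambda on the grid converged in every fold")
    if not ok.all():
        log.warning("dropped %d lambda value(s) with non-converged folds",
                    int(np.sum(~ok)))
    mean_scores = np.where(ok, scores.mean(axis=1), np.nan)
    best = int(np.nanargmax(mean_scores))  # np.nanargmax takes first (smallest) max
    return LambdaSelection(lam=float(grid[best]), grid=grid,
                           mean_scores=mean_scores)


def _warm_fit(S, lam, om0, tol, max_iter, penalize_diagonal) -> GlassoFit:
    """glasso_fit warm-started from a neighbouring lambda's solution."""
    return glasso_fit(S, lam, tol=tol, max_iter=max_iter,
                      penalize_diagonal=penalize_diagonal,
                      precision_init=om0)


def fisher_transform_matrix(W: np.ndarray) -> np.ndarray:
    """Fisher z-transform of the correlation normalization of W.

    W is converted to a correlation matrix R = D^{-1/2} W D^{-1/2}; the
    off-diagonal entries are clipped to +/-(1 - 1e-7) and mapped through
    atanh; the diagonal is set to 0 by convention.  Raises on non-PD W.
    """
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("W must be symmetric")
    if np.linalg.eigvalsh(W)[0] <= 0:
        raise ValueError("W must be positive definite")
    d = np.sqrt(np.diag(W))
    R = W / np.outer(d, d)
    R = np.clip(R, -(1 - 1e-7), 1 - 1e-7)
    Z = np.arctanh(R)
    np.fill_diagonal(Z, 0.0)
    return 0.5 * (Z + Z.T)


@dataclass
class ConditionMatrix:
    """A subject's condition-mean connectivity matrix (Fisher-z units
    off-diagonal, zero diagonal)."""

    subject_id: str
    condition: str
    matrix: np.ndarray


def condition_mean_glm(
    z_matrices: list[tuple[str, np.ndarray]],
    subject_id: str = "sub-01",
    conditions: tuple[str, ...] = CONDITIONS,
) -> dict[str, ConditionMatrix]:
    """Condition-mean matrices via a general linear model.

    The upper triangles of the per-window Fisher-z matrices are stacked and
    regressed on a one-indicator-per-condition design by ordinary least
    squares; with this design the betas are exactly the per-condition
    arithmetic means, which is asserted as a cross-check.  Raises if any
    condition has no window.
    """
    labels = [c for c, _ in z_matrices]
    for cond in conditions:
        if cond not in labels:
            raise ValueError(f"no windows for condition {cond!r}")
    n = z_matrices[0][1].shape[0]
    iu = np.triu_indices(n, k=1)
    Y = np.stack([m[iu] for _, m in z_matrices])
    X = np.stack(
        [[1.0 if c == cond else 0.0 for cond in conditions] for c in labels]
    )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out: dict[str, ConditionMatrix] = {}
    for j, cond in enumerate(conditions):
        direct = Y[[i for i, c in enumerate(labels) if c == cond]].mean(axis=0)
        if not np.allclose(beta[j], direct, atol=1e-10):
            raise AssertionError(
                "GLM betas diverged from per-condition means"
            )
        M = np.zeros((n, n))
        M[iu] = beta[j]
        M = M + M.T
        out[cond] = ConditionMatrix(subject_id=subject_id, condition=cond,
                                    matrix=M)
    return out
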