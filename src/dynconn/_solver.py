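"""Numba-compiled proximal-gradient core for the penalized precision fit.

FISTA with backtracking line search and monotone (function-value) restart.
The line search enforces positive definiteness via an in-house Cholesky
that reports failure instead of raising, and the majorization bound of the
smooth part -log det(Omega) + tr(S Omega).  Convergence is declared on the
duality-gap surrogate |tr(S Omega) + lam * pen(Omega) - n| < tol.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_glasso"]


@njit(cache=True)
def _chol(a):
    """Cholesky factor and a success flag (False: not PD)."""
    n = a.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            s = a[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 1e-300:
                    return L, False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return L, True


@njit(cache=True)
def _logdet_from_chol(L):
    s = 0.0
    for i in range(L.shape[0]):
        s += np.log(L[i, i])
    return 2.0 * s


@njit(cache=True)
def _penalty(om, pen_diag):
    n = om.shape[0]
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j or pen_diag:
                s += abs(om[i, j])
    return s


@njit(cache=True)
def _soft_sym(z, t, pen_diag):
    n = z.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            v = z[i, j]
            if i == j and not pen_diag:
                out[i, j] = v
            else:
                if v > t:
                    out[i, j] = v - t
                elif v < -t:
                    out[i, j] = v + t
                else:
                    out[i, j] = 0.0
    for i in range(n):
        for j in range(i):
            m = 0.5 * (out[i, j] + out[j, i])
            out[i, j] = m
            out[j, i] = m
    return out


@njit(cache=True)
def solve_glasso(S, lam, tol, max_iter, pen_diag, x0):
    """Returns (precision, n_iterations, converged)."""
    n = S.shape[0]
    x = 0.5 * (x0 + x0.T)
    L, ok = _chol(x)
    if not ok:
        x = np.zeros((n, n))
        for i in range(n):
            x[i, i] = 1.0 / (S[i, i] + lam)
        L, ok = _chol(x)
    g_x = -_logdet_from_chol(L) + np.sum(S * x)
    f_x = g_x + lam * _penalty(x, pen_diag)
    y = x.copy()
    g_y = g_x
    t_mom = 1.0
    step = 1.0
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        grad = S - np.linalg.inv(y)
        # backtracking line search from the extrapolated point y
        g_new = 0.0
        x_new = x
        while True:
            z = y - step * grad
            x_new = _soft_sym(z, step * lam, pen_diag)
            Ln, ok = _chol(x_new)
            if ok:
                g_new = -_logdet_from_chol(Ln) + np.sum(S * x_new)
                d = x_new - y
                bound = g_y + np.sum(grad * d) + np.sum(d * d) / (2.0 * step)
                if g_new <= bound + 1e-12:
                    break
            step *= 0.5
            if step < 1e-18:
                break
        f_new = g_new + lam * _penalty(x_new, pen_diag)
        if f_new > f_x + 1e-12:
            # momentum overshot: restart from the best iterate
            t_mom = 1.0
            y = x.copy()
            g_y = g_x
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        y_cand = x_new + ((t_mom - 1.0) / t_next) * (x_new - x)
        y_cand = 0.5 * (y_cand + y_cand.T)
        Lc, ok = _chol(y_cand)
        if ok:
            g_y = -_logdet_from_chol(Lc) + np.sum(S * y_cand)
            y = y_cand
            t_mom = t_next
        else:  # extrapolation left the PD cone
            y = x_new.copy()
            g_y = g_new
            t_mom = 1.0
        x = x_new
        g_x = g_new
        f_x = f_new
        gap = np.sum(S * x) + lam * _penalty(x, pen_diag) - n
        if abs(gap) < tol:
            converged = True
            break
        step *= 1.1
    return x, it, converged
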