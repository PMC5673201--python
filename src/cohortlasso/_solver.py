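"""Numba-compiled coordinate-descent kernels for the L1 path solvers.

The kernels accept an arbitrary design matrix (per-column curvatures are
recomputed for every weighted subproblem), so the same code serves
full-data fits and row-subset fits during cross-validation, where sliced
columns are no longer exactly mean-zero/unit-SD.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=False)
def _cd_solve(X, w, r, v, beta, beta0, lam, tol, max_updates):
    """Cyclic coordinate descent on
    (1/(2n)) sum_i w_i (z_i - beta0 - X beta)_i^2 + lam * sum_j |beta_j|.

    ``r`` holds the residual z - beta0 - X @ beta and is updated in place,
    as is ``beta``. ``v[j]`` is (1/n) sum_i w_i X_ij^2 (columns with zero
    curvature are skipped). The intercept is unpenalized. Convergence when
    the largest single-parameter change in a sweep drops below ``tol``.
    Returns (beta0, updates_used, converged).
    """
    n, p = X.shape
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    updates = 0
    while True:
        max_delta = 0.0
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / wsum
        if d0 != 0.0:
            beta0 += d0
            for i in range(n):
                r[i] -= d0
            if abs(d0) > max_delta:
                max_delta = abs(d0)
        for j in range(p):
            if v[j] <= 0.0:
                continue
            num = 0.0
            for i in range(n):
                num += w[i] * X[i, j] * r[i]
            num = num / n + v[j] * beta[j]
            bj = _soft(num, lam) / v[j]
            d = bj - beta[j]
            if d != 0.0:
                beta[j] = bj
                for i in range(n):
                    r[i] -= d * X[i, j]
                if abs(d) > max_delta:
                    max_delta = abs(d)
            updates += 1
            if updates >= max_updates:
                return beta0, updates, False
        if max_delta < tol:
            return beta0, updates, True


@njit(cache=False)
def gaussian_path(X, y, lambdas, tol, max_updates):
    """Pathwise solver for (1/(2n))||y - beta0 - X beta||^2 + lam ||beta||_1,
    warm-started along a decreasing lambda grid."""
    n, p = X.shape
    nlam = lambdas.shape[0]
    coefs = np.zeros((nlam, p))
    intercepts = np.zeros(nlam)
    converged = np.zeros(nlam, np.bool_)
    w = np.ones(n)
    v = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        v[j] = s / n
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    beta = np.zeros(p)
    beta0 = ybar
    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - beta0
    for l in range(nlam):
        beta0, _, ok = _cd_solve(X, w, r, v, beta, beta0, lambdas[l], tol, max_updates)
        for j in range(p):
            coefs[l, j] = beta[j]
        intercepts[l] = beta0
        converged[l] = ok
    return coefs, intercepts, converged


@njit(cache=False)
def binomial_path(X, y, lambdas, tol, max_updates, max_irls, w_floor, p_sat):
    """Pathwise penalized logistic solver: IRLS outer loop with coordinate
    descent on the weighted working response, warm-started along the grid.

    Working weights are floored at ``w_floor``; a fit is flagged saturated
    when any fitted probability leaves (p_sat, 1 - p_sat), the
    quasi-separation regime.
    """
    n, p = X.shape
    nlam = lambdas.shape[0]
    coefs = np.zeros((nlam, p))
    intercepts = np.zeros(nlam)
    converged = np.zeros(nlam, np.bool_)
    saturated = np.zeros(nlam, np.bool_)
    pbar = 0.0
    for i in range(n):
        pbar += y[i]
    pbar /= n
    beta = np.zeros(p)
    beta0 = np.log(pbar / (1.0 - pbar))
    eta = np.empty(n)
    prob = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    v = np.empty(p)
    beta_old = np.empty(p)
    for l in range(nlam):
        ok = False
        for _ in range(max_irls):
            for i in range(n):
                s = beta0
                for j in range(p):
                    if beta[j] != 0.0:
                        s += X[i, j] * beta[j]
                eta[i] = s
                prob[i] = 1.0 / (1.0 + np.exp(-s))
                wi = prob[i] * (1.0 - prob[i])
                if wi < w_floor:
                    wi = w_floor
                w[i] = wi
                r[i] = (y[i] - prob[i]) / wi
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                v[j] = s / n
            for j in range(p):
                beta_old[j] = beta[j]
            b0_old = beta0
            beta0, _, inner_ok = _cd_solve(
                X, w, r, v, beta, beta0, lambdas[l], tol, max_updates
            )
            max_change = abs(beta0 - b0_old)
            for j in range(p):
                c = abs(beta[j] - beta_old[j])
                if c > max_change:
                    max_change = c
            if inner_ok and max_change < tol:
                ok = True
                break
        is_sat = False
        for i in range(n):
            s = beta0
            for j in range(p):
                if beta[j] != 0.0:
                    s += X[i, j] * beta[j]
            pi = 1.0 / (1.0 + np.exp(-s))
            if pi > 1.0 - p_sat or pi < p_sat:
                is_sat = True
                break
        for j in range(p):
            coefs[l, j] = beta[j]
        intercepts[l] = beta0
        converged[l] = ok
        saturated[l] = is_sat
        if is_sat:
            # Quasi-separation: solutions diverge for smaller lambdas, so the
            # path is truncated here; the remaining grid points keep this
            # solution and carry the saturation flag.
            for l2 in range(l + 1, nlam):
                for j in range(p):
                    coefs[l2, j] = beta[j]
                intercepts[l2] = beta0
                converged[l2] = ok
                saturated[l2] = True
            break
    return coefs, intercepts, converged, saturated
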