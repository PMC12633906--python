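"""Numba-compiled inner loops of the block coordinate descent glasso."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lasso_column(W11, s12, l12, beta, tol, max_iter):
    """Coordinate descent on 0.5 b'W11 b - s12'b + sum l12 |b| in place."""
    m = beta.shape[0]
    for _ in range(max_iter):
        dmax = 0.0
        for k in range(m):
            acc = 0.0
            for j in range(m):
                acc += W11[k, j] * beta[j]
            r = s12[k] - (acc - W11[k, k] * beta[k])
            lam = l12[k]
            if r > lam:
                bnew = (r - lam) / W11[k, k]
            elif r < -lam:
                bnew = (r + lam) / W11[k, k]
            else:
                bnew = 0.0
            d = bnew - beta[k]
            if d < 0.0:
                d = -d
            if d > dmax:
                dmax = d
            beta[k] = bnew
        if dmax <= tol:
            break


@njit(cache=True)
def glasso_sweep(S, Lam, W, B, inner_tol, inner_max):
    """One full pass over all columns; returns mean |change| of W entries."""
    p = S.shape[0]
    total_change = 0.0
    W11 = np.empty((p - 1, p - 1))
    s12 = np.empty(p - 1)
    l12 = np.empty(p - 1)
    for j in range(p):
        # gather the j-th column problem, skipping row/col j
        r = 0
        for a in range(p):
            if a == j:
                continue
            s12[r] = S[a, j]
            l12[r] = Lam[a, j]
            c = 0
            for b in range(p):
                if b == j:
                    continue
                W11[r, c] = W[a, b]
                c += 1
            r += 1
        beta = B[:, j]
        lasso_column(W11, s12, l12, beta, inner_tol, inner_max)
        # w12 <- W11 beta, track change
        r = 0
        for a in range(p):
            if a == j:
                continue
            acc = 0.0
            for c in range(p - 1):
                acc += W11[r, c] * beta[c]
            d = acc - W[a, j]
            if d < 0.0:
                d = -d
            total_change += d
            W[a, j] = acc
            W[j, a] = acc
            r += 1
    return total_change / (p * p)


@njit(cache=True)
def recover_theta(W, B):
    """Precision matrix from the converged covariance estimate and betas."""
    p = W.shape[0]
    theta = np.empty((p, p))
    for j in range(p):
        acc = 0.0
        r = 0
        for a in range(p):
            if a == j:
                continue
            acc += W[a, j] * B[r, j]
            r += 1
        tjj = 1.0 / (W[j, j] - acc)
        theta[j, j] = tjj
        r = 0
        for a in range(p):
            if a == j:
                continue
            theta[a, j] = -B[r, j] * tjj
            r += 1
    # symmetrize
    for a in range(p):
        for b in range(a + 1, p):
            v = 0.5 * (theta[a, b] + theta[b, a])
            theta[a, b] = v
            theta[b, a] = v
    return theta
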