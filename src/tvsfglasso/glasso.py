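"""Penalized log-determinant solver with an elementwise penalty matrix.

Solves

    argmin_{Theta > 0}  tr(Theta S) - log|Theta| + sum_ij lambda_ij |theta_ij|

by block coordinate descent over columns (the glasso family), extended so
every entry carries its own penalty.  The diagonal is penalized, which pins
the estimated covariance diagonal at ``W_ii = S_ii + lambda_ii``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._solver_core import glasso_sweep, recover_theta

__all__ = [
    "EDGE_THRESHOLD",
    "PenaltyMatrix",
    "PrecisionEstimate",
    "edges_from_theta",
    "glasso_objective",
    "kkt_residual",
    "solve_glasso",
]

logger = logging.getLogger(__name__)

#: entries with |theta_ij| below this are exact zeros when forming edge sets
EDGE_THRESHOLD = 1e-8


@dataclass(frozen=True)
class PenaltyMatrix:
    """Symmetric nonnegative elementwise penalties lambda_ij.

    ``alpha`` and ``epsilons`` record how an adaptive penalty was built and
    are absent for plain uniform-lambda use.
    """

    values: np.ndarray
    alpha: float | None = None
    epsilons: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("penalty matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("penalty matrix must be finite")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("penalty matrix must be symmetric")
        if v.min() < 0:
            raise ValueError("penalty entries must be nonnegative")
        object.__setattr__(self, "values", v)

    @classmethod
    def uniform(cls, lam: float, p: int) -> "PenaltyMatrix":
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        return cls(values=np.full((p, p), float(lam)))

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class PrecisionEstimate:
    """Estimated precision matrix with solver diagnostics."""

    theta: np.ndarray
    covariance_hat: np.ndarray
    objective_value: float
    converged: bool
    iterations: int
    kkt_residual: float
    penalty: PenaltyMatrix | None = None
    objective_history: list[float] | None = None

    def edges(self, threshold: float = EDGE_THRESHOLD) -> set[tuple[int, int]]:
        return edges_from_theta(self.theta, threshold)

    @property
    def df(self) -> int:
        return len(self.edges())


def edges_from_theta(theta: np.ndarray, threshold: float = EDGE_THRESHOLD) -> set[tuple[int, int]]:
    """Nonzero off-diagonal upper-triangle pattern as an edge set."""
    p = theta.shape[0]
    return {
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(theta[i, j]) > threshold
    }


def glasso_objective(theta: np.ndarray, S: np.ndarray, penalty: PenaltyMatrix) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    return float(
        np.sum(theta * S) - logdet + np.sum(penalty.values * np.abs(theta))
    )


def _validate_S(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("S must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have a strictly positive diagonal")
    return 0.5 * (S + S.T)


def solve_glasso(
    S: np.ndarray,
    penalty: PenaltyMatrix,
    tol: float = 1e-4,
    max_iter: int = 200,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
    track_objective: bool = False,
) -> PrecisionEstimate:
    """Block coordinate descent for the elementwise-penalized glasso.

    Parameters
    ----------
    S : (p, p) symmetric matrix with positive diagonal
        Smoothed or plain sample covariance.  Rank deficiency is permitted;
        the penalty regularizes the problem.
    penalty : PenaltyMatrix
        Elementwise penalties; a uniform lambda is the special case of a
        constant matrix.
    tol : float
        Convergence is declared when the mean absolute change of the working
        covariance between sweeps drops below ``tol`` times the mean absolute
        off-diagonal of S.
    warm_start : optional ``(W, B)``
        Working covariance and column-regression coefficients from a related
        problem (e.g. the previous grid point).

    Returns
    -------
    PrecisionEstimate
        With ``converged=False`` and a logged warning if ``max_iter`` sweeps
        did not reach ``tol``.
    """
    S = _validate_S(S)
    if tol <= 0:
        raise ValueError("tol must be positive")
    p = S.shape[0]
    Lam = penalty.values
    if Lam.shape != S.shape:
        raise ValueError("penalty and S dimensions differ")

    if warm_start is not None:
        W = warm_start[0].copy()
        B = warm_start[1].copy()
        np.fill_diagonal(W, np.diag(S) + np.diag(Lam))
    else:
        W = S + np.diag(np.diag(Lam))
        B = np.zeros((p - 1, p))

    offdiag = np.abs(S - np.diag(np.diag(S)))
    scale = offdiag.sum() / (p * (p - 1)) if p > 1 else 0.0
    threshold = tol * scale if scale > 0 else tol
    inner_tol = min(threshold, tol) * 1e-2
    inner_max = 1000

    history: list[float] = []
    converged = False
    sweeps = 0
    if p == 1:
        theta = np.array([[1.0 / W[0, 0]]])
        converged = True
    else:
        for sweeps in range(1, max_iter + 1):
            delta = glasso_sweep(S, Lam, W, B, inner_tol, inner_max)
            if track_objective:
                history.append(glasso_objective(recover_theta(W, B), S, penalty))
            if delta <= threshold:
                converged = True
                break
        theta = recover_theta(W, B)
    if not converged:
        logger.warning(
            "glasso did not reach tol=%g within %d sweeps (last change %.3g)",
            tol, max_iter, delta,
        )
        warnings.warn("glasso did not converge; returning last iterate", RuntimeWarning)

    obj = glasso_objective(theta, S, penalty)
    resid = kkt_residual(S, theta, W, penalty)
    return PrecisionEstimate(
        theta=theta,
        covariance_hat=W,
        objective_value=obj,
        converged=converged,
        iterations=sweeps,
        kkt_residual=resid,
        penalty=penalty,
        objective_history=history if track_objective else None,
    )


def kkt_residual(
    S: np.ndarray,
    theta: np.ndarray,
    W: np.ndarray | None,
    penalty: PenaltyMatrix,
    zero_threshold: float = EDGE_THRESHOLD,
) -> float:
    """Max violation of the stationarity conditions of the penalized problem.

    For off-diagonal zero entries the subgradient condition is
    ``|S_ij - W_ij| <= lambda_ij``; for nonzero entries
    ``S_ij - W_ij + lambda_ij sign(theta_ij) = 0``; the diagonal satisfies
    ``W_ii = S_ii + lambda_ii`` since ``theta_ii > 0``.
    """
    theta = np.asarray(theta, dtype=float)
    if W is None:
        sign, _ = np.linalg.slogdet(theta)
        if sign <= 0:
            raise ValueError("theta must be positive definite")
        W = np.linalg.inv(theta)
    Lam = penalty.values
    G = S - W
    active = np.abs(theta) > zero_threshold
    viol_active = np.abs(G + Lam * np.sign(theta))
    viol_zero = np.maximum(np.abs(G) - Lam, 0.0)
    resid = np.where(active, viol_active, viol_zero)
    np.fill_diagonal(resid, np.abs(np.diag(G) + np.diag(Lam)))
    return float(resid.max())
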