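"""Independent oracles used to cross-check the package implementations.

These deliberately take different algorithmic routes than the code under
test: an ADMM solver for the penalized log-determinant problem (vs. block
coordinate descent), exhaustive pair enumeration for the edge metrics, and
normal-equation OLS for degree slopes.
"""

from __future__ import annotations

import numpy as np


def admm_glasso(
    S: np.ndarray,
    Lam: np.ndarray,
    rho: float = 1.0,
    iters: int = 20000,
    tol: float = 1e-11,
) -> np.ndarray:
    """ADMM on min tr(ThetaS) - log|Theta| + sum Lam |Theta| (split Theta=Z)."""
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    for _ in range(iters):
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        theta = Q @ np.diag((d + np.sqrt(d * d + 4 * rho)) / (2 * rho)) @ Q.T
        Z_old = Z
        A = theta + U
        Z = np.sign(A) * np.maximum(np.abs(A) - Lam / rho, 0.0)
        U += theta - Z
        if np.abs(theta - Z).max() < tol and rho * np.abs(Z - Z_old).max() < tol:
            break
    return Z


def brute_force_metrics(
    est_edges: set[tuple[int, int]],
    true_edges: set[tuple[int, int]],
    p: int,
) -> dict[str, float]:
    """All eight metrics by literal enumeration of every unordered pair."""
    tp = fp = tn = fn = 0
    for i in range(p):
        for j in range(i + 1, p):
            in_est = (i, j) in est_edges or (j, i) in est_edges
            in_true = (i, j) in true_edges or (j, i) in true_edges
            if in_est and in_true:
                tp += 1
            elif in_est:
                fp += 1
            elif in_true:
                fn += 1
            else:
                tn += 1
    pre = tp / (tp + fp) if tp + fp else 0.0
    tpr = tp / (tp + fn) if tp + fn else 0.0
    out = {
        "precision": pre,
        "TPR": tpr,
        "FDR": fp / (tp + fp) if tp + fp else 0.0,
        "FPR": fp / (fp + tn) if fp + tn else 0.0,
        "F1": 2 * pre * tpr / (pre + tpr) if pre + tpr else 0.0,
        "jaccard": tp / (tp + fp + fn) if tp + fp + fn else 1.0,
        "edit_distance": float(fp + fn),
    }
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["MCC"] = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return out


def ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    """Slope from the 2x2 normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1])


def random_edge_set(p: int, n_edges: int, rng: np.random.Generator) -> set[tuple[int, int]]:
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    return {pairs[i] for i in idx}
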