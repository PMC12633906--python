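"""Binary-classification metrics for edge recovery and degree analytics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .time_varying import DynamicNetwork

__all__ = [
    "METRIC_NAMES",
    "MetricsReport",
    "confusion_counts",
    "degree_slopes",
    "degree_trajectories",
    "difference_graph",
    "evaluate_network",
    "metrics",
    "neighborhood",
]

METRIC_NAMES = ("F1", "FDR", "FPR", "MCC", "precision", "TPR", "jaccard", "edit_distance")


@dataclass
class MetricsReport:
    """Per-time metric values plus confusion counts and the time averages."""

    per_time: pd.DataFrame  # one row per time point, metric + count columns
    averages: dict[str, float]


def confusion_counts(
    estimated_edges: set[tuple[int, int]],
    true_edges: set[tuple[int, int]],
    p: int,
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over all p(p-1)/2 unordered node pairs."""
    est = {(min(i, j), max(i, j)) for (i, j) in estimated_edges}
    tru = {(min(i, j), max(i, j)) for (i, j) in true_edges}
    for E in (est, tru):
        for (i, j) in E:
            if not (0 <= i < p and 0 <= j < p) or i == j:
                raise ValueError(f"edge ({i},{j}) invalid for p={p}")
    n_pairs = p * (p - 1) // 2
    tp = len(est & tru)
    fp = len(est - tru)
    fn = len(tru - est)
    tn = n_pairs - tp - fp - fn
    return tp, fp, tn, fn


def metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """The eight edge-recovery metrics from one confusion table.

    Zero-denominator conventions: precision and FDR are 0 when no edge is
    predicted; F1 is 0 when precision + TPR is 0; MCC is 0 when any factor of
    its denominator is 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    pre = tp / (tp + fp) if tp + fp > 0 else 0.0
    tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
    fdr = fp / (tp + fp) if tp + fp > 0 else 0.0
    fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
    f1 = 2 * pre * tpr / (pre + tpr) if pre + tpr > 0 else 0.0
    ji = tp / (tp + fp + fn) if tp + fp + fn > 0 else 1.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {
        "F1": f1,
        "FDR": fdr,
        "FPR": fpr,
        "MCC": float(mcc),
        "precision": pre,
        "TPR": tpr,
        "jaccard": ji,
        "edit_distance": float(fp + fn),
    }


def evaluate_network(
    estimated: DynamicNetwork,
    truth: DynamicNetwork,
) -> MetricsReport:
    """Score an estimated dynamic network against the ground truth."""
    if estimated.p != truth.p:
        raise ValueError("node sets differ")
    if estimated.n_times != truth.n_times:
        raise ValueError("time grids differ")
    rows = []
    for k in range(truth.n_times):
        tp, fp, tn, fn = confusion_counts(
            estimated.edge_sets[k], truth.edge_sets[k], truth.p
        )
        row = {"time": truth.time_points[k], "TP": tp, "FP": fp, "TN": tn, "FN": fn}
        row.update(metrics(tp, fp, tn, fn))
        rows.append(row)
    per_time = pd.DataFrame(rows)
    averages = {name: float(per_time[name].mean()) for name in METRIC_NAMES}
    return MetricsReport(per_time=per_time, averages=averages)


def degree_trajectories(network: DynamicNetwork) -> np.ndarray:
    """(p, N) array: degree of each node at each time point."""
    out = np.zeros((network.p, network.n_times), dtype=int)
    for k, E in enumerate(network.edge_sets):
        for (i, j) in E:
            out[i, k] += 1
            out[j, k] += 1
    return out


def degree_slopes(
    trajectories: np.ndarray,
    time_points: np.ndarray,
    top_k: int = 5,
) -> list[tuple[int, float]]:
    """OLS slope of degree against time per node, top_k steepest first."""
    t = np.asarray(time_points, dtype=float)
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    slopes = (
        trajectories @ tc / denom
        if denom > 0
        else np.zeros(trajectories.shape[0])
    )
    order = np.argsort(-slopes, kind="stable")
    return [(int(i), float(slopes[i])) for i in order[:top_k]]


def neighborhood(
    network: DynamicNetwork,
    node: int,
    k: int,
    radius: int = 1,
) -> tuple[set[int], set[tuple[int, int]]]:
    """Induced subgraph around ``node`` in E(t_k) within ``radius`` hops."""
    E = network.edge_sets[k]
    nodes = {node}
    frontier = {node}
    for _ in range(radius):
        nxt = set()
        for (i, j) in E:
            if i in frontier:
                nxt.add(j)
            if j in frontier:
                nxt.add(i)
        frontier = nxt - nodes
        nodes |= nxt
    edges = {(i, j) for (i, j) in E if i in nodes and j in nodes}
    return nodes, edges


def difference_graph(
    network: DynamicNetwork,
    k: int,
) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """(added, removed) edges between consecutive time points k and k+1."""
    if not 0 <= k < network.n_times - 1:
        raise ValueError("k must index a consecutive pair of time points")
    a, b = network.edge_sets[k], network.edge_sets[k + 1]
    return b - a, a - b
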