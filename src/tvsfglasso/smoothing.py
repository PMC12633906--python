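"""Kernel weights and time-smoothed covariance estimation.

Expression time series are grouped into per-time-point blocks of replicate
observations.  A smoothed covariance at query time ``t`` is the kernel-weighted
convex combination of the per-time sample covariances, which borrows strength
from adjacent time points before any precision-matrix estimation happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KERNELS",
    "EmptyKernelSupportError",
    "ExpressionTimeSeries",
    "KernelSpec",
    "SmoothedCovariance",
    "compute_weights",
    "kernel_weight",
    "per_time_covariance",
    "rescale_times",
    "smoothed_covariance",
]

KERNELS = ("epanechnikov", "epanechnikov_printed")


class EmptyKernelSupportError(ValueError):
    """No time point falls within the kernel support at the query time."""


def rescale_times(raw_times: np.ndarray) -> np.ndarray:
    """Affinely map raw time labels onto [0, 1].

    A single time point maps to 0.0.  The map is invariant to affine
    transformations of the raw labels (e.g. hours vs. minutes).
    """
    raw = np.asarray(raw_times, dtype=float)
    if raw.size == 0:
        raise ValueError("at least one time label is required")
    span = raw.max() - raw.min()
    if span == 0:
        return np.zeros_like(raw)
    return (raw - raw.min()) / span


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice and bandwidth for time smoothing.

    ``epanechnikov`` is the standard kernel 0.75 * (1 - a^2) on [0, 1];
    ``epanechnikov_printed`` is the variant 0.75 * (1 - a)^2 on [0, 1].
    """

    kernel_name: str = "epanechnikov"
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel_name not in KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel_name!r}; choose one of {KERNELS}"
            )
        if not self.bandwidth > 0:
            raise ValueError(f"bandwidth must be positive, got {self.bandwidth}")


@dataclass
class ExpressionTimeSeries:
    """Observations grouped by time point with replicate structure.

    Attributes
    ----------
    gene_ids : list of str
        Identifiers for the p variables (columns of every block).
    time_points : ndarray, shape (N,)
        Strictly increasing, rescaled to [0, 1].
    observations : list of ndarray
        One (n_k, p) block per time point, n_k >= 1.
    centered : bool
        Whether each gene has zero mean over all observations.
    raw_time_labels : ndarray or None
        Original labels (e.g. hours) kept for reporting.
    """

    gene_ids: list[str]
    time_points: np.ndarray
    observations: list[np.ndarray]
    centered: bool = False
    raw_time_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.observations = [np.atleast_2d(np.asarray(b, dtype=float)) for b in self.observations]
        if len(self.observations) != self.time_points.size:
            raise ValueError("one observation block per time point is required")
        if self.time_points.size == 0:
            raise ValueError("empty time series")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.time_points.min() < -1e-12 or self.time_points.max() > 1 + 1e-12:
            raise ValueError("time points must be rescaled to [0, 1]")
        p = len(self.gene_ids)
        for k, block in enumerate(self.observations):
            if block.shape[1] != p:
                raise ValueError(
                    f"block {k} has {block.shape[1]} columns, expected p={p}"
                )
            if block.shape[0] < 1:
                raise ValueError(f"block {k} is empty")
        if self.centered:
            stacked = np.vstack(self.observations)
            if np.abs(stacked.mean(axis=0)).max() > 1e-10:
                raise ValueError("centered flag set but gene means are not zero")

    @property
    def p(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return self.time_points.size

    @property
    def n_per_time(self) -> np.ndarray:
        return np.array([b.shape[0] for b in self.observations])

    @property
    def total_observations(self) -> int:
        return int(self.n_per_time.sum())

    def stacked(self) -> np.ndarray:
        """All observations as a single (sum n_k, p) matrix, time order."""
        return np.vstack(self.observations)

    def center(self) -> "ExpressionTimeSeries":
        """Subtract each gene's grand mean over all observations."""
        if self.centered:
            return self
        mu = self.stacked().mean(axis=0)
        blocks = [b - mu for b in self.observations]
        return replace(self, observations=blocks, centered=True)

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        times: np.ndarray,
        gene_ids: list[str] | None = None,
    ) -> "ExpressionTimeSeries":
        """Group rows of a (n_samples, p) matrix by their time label."""
        X = np.asarray(X, dtype=float)
        times = np.asarray(times, dtype=float)
        if X.shape[0] != times.size:
            raise ValueError("one time label per sample row is required")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(X.shape[1])]
        uniq = np.unique(times)
        blocks = [X[times == t] for t in uniq]
        return cls(
            gene_ids=list(gene_ids),
            time_points=rescale_times(uniq),
            observations=blocks,
            raw_time_labels=uniq,
        )


@dataclass
class SmoothedCovariance:
    """A p x p kernel-weighted covariance at one query time."""

    matrix: np.ndarray
    query_time: float
    weights: np.ndarray
    mode: str  # pooled_samples | replicate_blocks

    def __post_init__(self) -> None:
        if np.abs(self.matrix - self.matrix.T).max() > 1e-12:
            raise ValueError("smoothed covariance must be symmetric")
        if not np.any(self.weights > 0):
            raise ValueError("at least one kernel weight must be positive")


def kernel_weight(a: float, spec: KernelSpec) -> float:
    """Evaluate the kernel at a nonnegative scaled distance ``a``."""
    if a < 0:
        raise ValueError(f"kernel argument must be nonnegative, got {a}")
    if a > 1:
        return 0.0
    if spec.kernel_name == "epanechnikov":
        return 0.75 * (1.0 - a * a)
    return 0.75 * (1.0 - a) ** 2


def compute_weights(
    time_points: np.ndarray,
    t: float,
    spec: KernelSpec,
    fallback: str = "error",
) -> np.ndarray:
    """Kernel weights w_j = K(|t_j - t| / h) over the time grid.

    When no time point lies within the bandwidth, the default is a hard
    ``EmptyKernelSupportError``; with ``fallback="nearest"`` the closest
    time point receives weight 1 instead.
    """
    tp = np.asarray(time_points, dtype=float)
    if tp.size == 0:
        raise ValueError("time_points must be nonempty")
    if not 0 - 1e-12 <= t <= 1 + 1e-12:
        raise ValueError(f"query time {t} outside [0, 1]")
    a = np.abs(tp - t) / spec.bandwidth
    w = np.array([kernel_weight(ai, spec) for ai in a])
    if not np.any(w > 0):
        if fallback == "nearest":
            w = np.zeros_like(w)
            w[np.argmin(np.abs(tp - t))] = 1.0
        else:
            raise EmptyKernelSupportError(
                f"no time point within kernel support at t={t} with h={spec.bandwidth}; "
                "increase h or enable the nearest-neighbor fallback"
            )
    return w


def per_time_covariance(block: np.ndarray) -> np.ndarray:
    """Sample covariance of one centered replicate block, divisor n_k."""
    block = np.atleast_2d(np.asarray(block, dtype=float))
    if block.shape[0] < 1:
        raise ValueError("empty observation block")
    return block.T @ block / block.shape[0]


def smoothed_covariance(
    data: ExpressionTimeSeries,
    t: float,
    spec: KernelSpec,
    fallback: str = "error",
) -> SmoothedCovariance:
    """Kernel-weighted covariance at time ``t``.

    With a single observation per time point this is the weighted average of
    per-observation outer products; with replicates it is the same weighted
    average applied to the per-time sample covariances.  Either way the result
    is a convex combination of PSD matrices and hence PSD.
    """
    if not data.centered:
        raise ValueError("data must be centered before smoothing")
    w = compute_weights(data.time_points, t, spec, fallback=fallback)
    S = np.zeros((data.p, data.p))
    for wk, block in zip(w, data.observations):
        if wk > 0:
            S += wk * per_time_covariance(block)
    S /= w.sum()
    S = 0.5 * (S + S.T)
    mode = "pooled_samples" if np.all(data.n_per_time == 1) else "replicate_blocks"
    return SmoothedCovariance(matrix=S, query_time=float(t), weights=w, mode=mode)
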