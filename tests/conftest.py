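import numpy as np
import pytest

from tvsfglasso import ExpressionTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(p: int, rng: np.random.Generator, cond_floor: float = 0.1) -> np.ndarray:
    """Well-conditioned random symmetric positive-definite matrix."""
    A = rng.standard_normal((2 * p, p))
    return A.T @ A / (2 * p) + cond_floor * np.eye(p)


def series_with_covariances(variance_list, times=None) -> ExpressionTimeSeries:
    """Time series whose k-th per-time covariance is diag(variance_list[k])."""
    blocks = []
    for v in variance_list:
        v = np.asarray(v, dtype=float)
        p = v.size
        rows = []
        for g in range(p):
            e = np.zeros(p)
            e[g] = np.sqrt(v[g] * p)  # 2p rows total -> divisor 2p
            rows += [e, -e]
        blocks.append(np.array(rows))
    N = len(blocks)
    if times is None:
        times = np.linspace(0, 1, N) if N > 1 else np.array([0.0])
    return ExpressionTimeSeries(
        gene_ids=[f"g{i}" for i in range(len(variance_list[0]))],
        time_points=np.asarray(times, dtype=float),
        observations=blocks,
        centered=True,
    )
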