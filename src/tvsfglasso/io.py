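"""Reading, writing and preprocessing of expression data and networks.

Expression matrices are delimited text (TSV/CSV) in either orientation with a
sample-to-time mapping; dynamic networks round-trip through one edge-list file
per time point plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .smoothing import ExpressionTimeSeries, rescale_times
from .time_varying import DynamicNetwork

__all__ = [
    "preprocess_counts",
    "read_expression",
    "read_networks",
    "write_expression",
    "write_networks",
]


def _check_numeric(df: pd.DataFrame, path) -> None:
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric or missing value at row {row!r}, column {col!r} in {path}"
            )


def read_expression(
    path,
    time_column: str = "time",
    orientation: str = "samples_by_genes",
    sep: str = "\t",
    times: dict | None = None,
) -> ExpressionTimeSeries:
    """Load a delimited expression matrix into time-grouped blocks.

    ``samples_by_genes``: one row per sample with a ``time_column`` column.
    ``genes_by_samples``: one row per gene; ``times`` maps sample (column)
    names to time labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes_by_samples":
        if times is None:
            raise ValueError("genes_by_samples orientation requires a sample->time mapping")
        missing = [c for c in df.columns if c not in times]
        if missing:
            raise ValueError(f"missing time labels for samples: {missing}")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        gene_ids = [str(g) for g in df.index]
        X = df.to_numpy(dtype=float).T
        _check_numeric(df, path)
        tvals = np.array([float(times[c]) for c in df.columns])
    elif orientation == "samples_by_genes":
        if time_column not in df.columns:
            raise ValueError(f"missing time column {time_column!r} in {path}")
        tvals = df[time_column].to_numpy(dtype=float)
        mat = df.drop(columns=[time_column])
        if mat.columns.duplicated().any():
            dupes = mat.columns[mat.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        mat = mat.apply(pd.to_numeric, errors="coerce")
        _check_numeric(mat, path)
        gene_ids = [str(g) for g in mat.columns]
        X = mat.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionTimeSeries.from_arrays(X, tvals, gene_ids=gene_ids)


def write_expression(data: ExpressionTimeSeries, path, sep: str = "\t") -> None:
    """Write samples-by-genes TSV with a leading time column (read inverse)."""
    path = Path(path)
    labels = (
        data.raw_time_labels
        if data.raw_time_labels is not None
        else data.time_points
    )
    rows = []
    for t, block in zip(labels, data.observations):
        for x in block:
            rows.append([t, *x])
    df = pd.DataFrame(rows, columns=["time", *data.gene_ids])
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def preprocess_counts(
    counts: pd.DataFrame,
    times: np.ndarray,
    min_nonzero_samples: int = 20,
    min_mean_count: float = 10.0,
    top_variance_k: int = 400,
) -> ExpressionTimeSeries:
    """Count-filtering, log2(x+1), standardization, top-variance selection.

    ``counts`` is samples x genes; ``times`` gives one time label per sample
    row.  Genes must be nonzero in at least ``min_nonzero_samples`` samples
    and average more than ``min_mean_count`` counts.  The top
    ``top_variance_k`` genes are ranked by pre-standardization variance of
    the log counts.
    """
    times = np.asarray(times, dtype=float)
    if counts.shape[0] != times.size:
        raise ValueError("one time label per sample row is required")
    X = counts.to_numpy(dtype=float)
    keep = ((X > 0).sum(axis=0) >= min_nonzero_samples) & (X.mean(axis=0) > min_mean_count)
    if not keep.any():
        raise ValueError("all genes removed by the count filters")
    genes = [str(g) for g, k in zip(counts.columns, keep) if k]
    Y = np.log2(X[:, keep] + 1.0)
    variances = Y.var(axis=0, ddof=1)
    sd = Y.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Y - Y.mean(axis=0)) / sd
    if top_variance_k < len(genes):
        top = np.sort(np.argsort(-variances, kind="stable")[:top_variance_k])
        Z = Z[:, top]
        genes = [genes[i] for i in top]
    return ExpressionTimeSeries.from_arrays(Z, times, gene_ids=genes)


def write_networks(network: DynamicNetwork, out_dir, graphml: bool = False) -> None:
    """One edge-list TSV per time point plus a JSON manifest.

    Edge rows are ``node_i  node_j  theta`` with i < j by node index and the
    precision entry when available (0.0 otherwise).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in range(network.n_times):
        lines = ["node_i\tnode_j\ttheta"]
        theta = network.precisions[k] if network.precisions is not None else None
        for (i, j) in sorted(network.edge_sets[k]):
            w = float(theta[i, j]) if theta is not None else 0.0
            lines.append(
                f"{network.node_ids[i]}\t{network.node_ids[j]}\t{w!r}"
            )
        (out / f"edges_t{k:04d}.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "node_ids": list(network.node_ids),
        "time_points": [float(t) for t in network.time_points],
        "params": network.params,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    if graphml:
        import networkx as nx

        for k in range(network.n_times):
            G = nx.Graph()
            G.add_nodes_from(network.node_ids)
            for (i, j) in sorted(network.edge_sets[k]):
                G.add_edge(network.node_ids[i], network.node_ids[j])
            nx.write_graphml(G, out / f"network_t{k:04d}.graphml")


def read_networks(in_dir) -> DynamicNetwork:
    """Inverse of :func:`write_networks` (edge lists + manifest)."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    node_ids = manifest["node_ids"]
    index = {g: i for i, g in enumerate(node_ids)}
    time_points = np.array(manifest["time_points"], dtype=float)
    edge_sets = []
    for k in range(time_points.size):
        lines = (src / f"edges_t{k:04d}.tsv").read_text().strip().splitlines()
        E = set()
        for line in lines[1:]:
            gi, gj, _w = line.split("\t")
            i, j = index[gi], index[gj]
            E.add((min(i, j), max(i, j)))
        edge_sets.append(E)
    return DynamicNetwork(
        node_ids=node_ids,
        time_points=time_points,
        edge_sets=edge_sets,
        params=manifest.get("params", {}),
    )
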