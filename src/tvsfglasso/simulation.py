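"""Dynamic graph and Gaussian time-series simulators.

Six scenario generators share one contract: a sequence of simple graphs over a
fixed node set, a positive-definite precision matrix per time point whose
support equals the graph exactly, and replicate Gaussian draws per time point.
Evolution between steps obeys four rules: few edge changes per step, preserved
degree skew, preserved acyclicity (tree modes), and low-degree-biased change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .smoothing import ExpressionTimeSeries
from .time_varying import DynamicNetwork

__all__ = [
    "DynamicTruth",
    "SimulationSpec",
    "ba_graph",
    "erdos_renyi_graph",
    "evolve_graph",
    "graph_to_precision",
    "sample_timeseries",
    "simulate_dynamic_truth",
    "superhub_graph",
]

GENERATORS = (
    "ba_huge",
    "ba_liu_ihler",
    "ba_smooth",
    "superhub",
    "yang_peng_abrupt",
    "erdos_renyi",
)

DIAG_SLACK = 0.1


@dataclass(frozen=True)
class SimulationSpec:
    """Configuration of one dynamic-network scenario."""

    generator: str = "ba_huge"
    p: int = 100
    N: int = 50
    n_k: int = 10
    change_rate: float = 1.0
    edge_weight: float = 0.3
    seed: int = 0
    n_hubs: int = 2
    edge_prob: float = 0.04
    shock_fraction: float = 0.3
    smooth_segment: int = 5

    def __post_init__(self) -> None:
        if self.generator not in GENERATORS:
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.p < 4:
            raise ValueError("p must be at least 4")
        if self.N < 1 or self.n_k < 1:
            raise ValueError("N and n_k must be at least 1")
        if self.change_rate < 0:
            raise ValueError("change_rate must be nonnegative")


@dataclass
class DynamicTruth:
    """Ground-truth graphs and matching precision matrices."""

    graphs: DynamicNetwork
    precisions: list[np.ndarray]
    provenance: SimulationSpec

    def __post_init__(self) -> None:
        for k, (theta, E) in enumerate(zip(self.precisions, self.graphs.edge_sets)):
            support = {
                (i, j)
                for i in range(theta.shape[0])
                for j in range(i + 1, theta.shape[0])
                if abs(theta[i, j]) > 1e-12
            }
            if support != E:
                raise ValueError(f"precision support differs from edge set at time {k}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def ba_graph(p: int, init_nodes: int = 2, seed=0) -> nx.Graph:
    """Preferential-attachment tree: each new node attaches to one node
    sampled proportionally to current degree (+1 smoothing while any seed
    node still has degree zero).  The initial component is a path, so the
    result has exactly p-1 edges and no cycles."""
    if init_nodes not in (2, 4):
        raise ValueError("init_nodes must be 2 or 4")
    if p < init_nodes:
        raise ValueError("p must be at least init_nodes")
    rng = _rng(seed)
    G = nx.Graph()
    G.add_nodes_from(range(p))
    G.add_edges_from((i, i + 1) for i in range(init_nodes - 1))
    for v in range(init_nodes, p):
        deg = np.array([G.degree(u) for u in range(v)], dtype=float)
        if np.any(deg == 0):
            deg = deg + 1.0
        target = rng.choice(v, p=deg / deg.sum())
        G.add_edge(v, int(target))
    return G


def superhub_graph(p: int, n_hubs: int = 2, seed=0, background_prob: float = 0.0) -> nx.Graph:
    """Union of stars: hub nodes split the remaining nodes disjointly, plus
    optional sparse background edges between non-hub nodes."""
    if not 1 <= n_hubs < p:
        raise ValueError("need 1 <= n_hubs < p")
    rng = _rng(seed)
    G = nx.Graph()
    G.add_nodes_from(range(p))
    hubs = list(range(n_hubs))
    leaves = np.array(range(n_hubs, p))
    assignment = rng.integers(0, n_hubs, size=leaves.size)
    for hub, leaf in zip(assignment, leaves):
        G.add_edge(int(hubs[hub]), int(leaf))
    if background_prob > 0:
        for a in range(n_hubs, p):
            for b in range(a + 1, p):
                if rng.random() < background_prob:
                    G.add_edge(a, b)
    return G


def erdos_renyi_graph(p: int, edge_prob: float, seed=0) -> nx.Graph:
    """Each unordered pair is an edge independently with ``edge_prob``."""
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = _rng(seed)
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < edge_prob:
                G.add_edge(a, b)
    return G


def graph_to_precision(
    graph: nx.Graph,
    edge_weight: float = 0.3,
    jitter_seed=0,
    sign_map: dict[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Diagonally dominant precision matrix supported exactly on the edges.

    Off-diagonal entries are +/- edge_weight (random signs, or taken from
    ``sign_map`` for persisting edges); each diagonal entry is the absolute
    row sum plus a fixed slack, which guarantees positive definiteness.
    """
    rng = _rng(jitter_seed)
    p = graph.number_of_nodes()
    theta = np.zeros((p, p))
    for (a, b) in sorted((min(e), max(e)) for e in graph.edges()):
        if sign_map is not None and (a, b) in sign_map:
            s = sign_map[(a, b)]
        else:
            s = 1.0 if rng.random() < 0.5 else -1.0
            if sign_map is not None:
                sign_map[(a, b)] = s
        theta[a, b] = theta[b, a] = s * edge_weight
    np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + DIAG_SLACK)
    return theta


def _low_degree_biased_edge(G: nx.Graph, rng: np.random.Generator) -> tuple[int, int]:
    edges = list(G.edges())
    w = np.array([1.0 / (G.degree(a) + G.degree(b)) for a, b in edges])
    idx = rng.choice(len(edges), p=w / w.sum())
    return edges[idx]


def evolve_graph(
    graph: nx.Graph,
    change_rate: float,
    acyclic: bool = True,
    seed=0,
    attach: str = "preferential",
) -> nx.Graph:
    """One evolution step: Poisson(change_rate) edge rewires.

    Deleted edges are sampled with probability inversely proportional to the
    endpoint degree sum (low-degree-biased).  In acyclic mode the orphaned
    lower-degree endpoint re-attaches to the other component with probability
    proportional to degree, which preserves both the edge count and
    acyclicity.  In general mode a fresh non-edge is added (preferential or
    uniform endpoint sampling).
    """
    rng = _rng(seed)
    G = graph.copy()
    d = rng.poisson(change_rate)
    for _ in range(d):
        if G.number_of_edges() == 0:
            break
        a, b = _low_degree_biased_edge(G, rng)
        if G.degree(a) > G.degree(b):
            a, b = b, a  # a is the lower-degree (orphaned) endpoint
        G.remove_edge(a, b)
        if acyclic:
            comp_a = nx.node_connected_component(G, a)
            others = np.array([u for u in G.nodes if u not in comp_a])
            deg = np.array([G.degree(u) for u in others], dtype=float) + 1.0
            target = int(others[rng.choice(others.size, p=deg / deg.sum())])
            G.add_edge(a, target)
        else:
            candidates = [
                u for u in G.nodes if u != a and not G.has_edge(a, u)
            ]
            if not candidates:
                G.add_edge(a, b)
                continue
            if attach == "preferential":
                deg = np.array([G.degree(u) for u in candidates], dtype=float) + 1.0
                target = candidates[rng.choice(len(candidates), p=deg / deg.sum())]
            else:
                target = candidates[rng.integers(len(candidates))]
            G.add_edge(a, int(target))
    return G


def _shock(G: nx.Graph, fraction: float, rng: np.random.Generator) -> nx.Graph:
    """Rewire a block of edges at once (abrupt topological shift)."""
    G = G.copy()
    edges = list(G.edges())
    k = max(1, int(round(fraction * len(edges))))
    idx = rng.choice(len(edges), size=min(k, len(edges)), replace=False)
    removed = [edges[i] for i in idx]
    G.remove_edges_from(removed)
    p = G.number_of_nodes()
    added = 0
    while added < len(removed):
        a, b = rng.integers(p), rng.integers(p)
        if a != b and not G.has_edge(int(a), int(b)):
            G.add_edge(int(a), int(b))
            added += 1
    return G


def _graph_sequence(spec: SimulationSpec, rng: np.random.Generator) -> list[nx.Graph]:
    gen = spec.generator
    if gen in ("ba_huge", "ba_liu_ihler"):
        g0 = ba_graph(spec.p, init_nodes=2, seed=rng)
        acyclic = True
    elif gen == "ba_smooth":
        g0 = ba_graph(spec.p, init_nodes=4, seed=rng)
        acyclic = True
    elif gen == "superhub":
        g0 = superhub_graph(spec.p, n_hubs=spec.n_hubs, seed=rng, background_prob=0.01)
        acyclic = False
    elif gen in ("yang_peng_abrupt", "erdos_renyi"):
        g0 = erdos_renyi_graph(spec.p, spec.edge_prob, seed=rng)
        acyclic = False
    attach = "uniform" if gen in ("yang_peng_abrupt", "erdos_renyi") else "preferential"
    graphs = [g0]
    shock_at = rng.integers(1, spec.N - 1) if (gen == "yang_peng_abrupt" and spec.N > 2) else -1
    for k in range(1, spec.N):
        g = evolve_graph(graphs[-1], spec.change_rate, acyclic=acyclic, seed=rng, attach=attach)
        if k == shock_at:
            g = _shock(g, spec.shock_fraction, rng)
        graphs.append(g)
    return graphs


def _edge_set(G: nx.Graph) -> set[tuple[int, int]]:
    return {(min(a, b), max(a, b)) for a, b in G.edges()}


def simulate_dynamic_truth(spec: SimulationSpec) -> DynamicTruth:
    """Ground-truth dynamic network and precision matrices for a scenario.

    Signs of persisting edges are held fixed over time.  The smooth mode
    generates anchor graphs on a coarser grid and linearly interpolates
    precision entries between anchors (a convex combination of PD matrices,
    hence PD); any residual indefiniteness would be repaired by diagonal
    inflation.
    """
    rng = _rng(spec.seed)
    sign_map: dict[tuple[int, int], float] = {}

    if spec.generator == "ba_smooth" and spec.N > 1:
        L = max(1, spec.smooth_segment)
        n_anchors = int(np.ceil((spec.N - 1) / L)) + 1
        # anchor graphs on a coarse grid, evolving L steps' worth per anchor
        g0 = ba_graph(spec.p, init_nodes=4, seed=rng)
        anchor_graphs = [g0]
        for _ in range(1, n_anchors):
            anchor_graphs.append(
                evolve_graph(anchor_graphs[-1], spec.change_rate * L, acyclic=True, seed=rng)
            )
        anchor_precisions = [
            graph_to_precision(g, spec.edge_weight, jitter_seed=rng, sign_map=sign_map)
            for g in anchor_graphs
        ]
        precisions = []
        for k in range(spec.N):
            pos = k / (spec.N - 1) * (n_anchors - 1)
            lo = min(int(np.floor(pos)), n_anchors - 2)
            frac = pos - lo
            theta = (1 - frac) * anchor_precisions[lo] + frac * anchor_precisions[lo + 1]
            w, _ = np.linalg.eigh(theta)
            if w.min() <= 0:
                theta = theta + (abs(w.min()) + DIAG_SLACK) * np.eye(spec.p)
            precisions.append(theta)
        edge_sets = [
            {
                (i, j)
                for i in range(spec.p)
                for j in range(i + 1, spec.p)
                if abs(th[i, j]) > 1e-12
            }
            for th in precisions
        ]
    else:
        graphs = _graph_sequence(spec, rng)
        precisions = []
        edge_sets = []
        for g in graphs:
            E = _edge_set(g)
            # drop signs of edges that no longer exist so re-added ones redraw
            for e in list(sign_map):
                if e not in E:
                    del sign_map[e]
            precisions.append(
                graph_to_precision(g, spec.edge_weight, jitter_seed=rng, sign_map=sign_map)
            )
            edge_sets.append(E)

    network = DynamicNetwork(
        node_ids=[f"g{i}" for i in range(spec.p)],
        time_points=np.linspace(0, 1, spec.N) if spec.N > 1 else np.array([0.0]),
        edge_sets=edge_sets,
        precisions=precisions,
        params={"generator": spec.generator, "seed": spec.seed},
    )
    return DynamicTruth(graphs=network, precisions=precisions, provenance=spec)


def sample_timeseries(truth: DynamicTruth, n_k: int, seed=0) -> ExpressionTimeSeries:
    """Replicate Gaussian draws N(0, Theta(t_k)^-1) at each time point."""
    if n_k < 1:
        raise ValueError("n_k must be at least 1")
    rng = _rng(seed)
    blocks = []
    for theta in truth.precisions:
        L = np.linalg.cholesky(theta)
        z = rng.standard_normal((n_k, theta.shape[0]))
        # x = L^-T z  has covariance (L L^T)^-1 = Theta^-1
        x = np.linalg.solve(L.T, z.T).T
        blocks.append(x)
    return ExpressionTimeSeries(
        gene_ids=list(truth.graphs.node_ids),
        time_points=truth.graphs.time_points.copy(),
        observations=blocks,
    )
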