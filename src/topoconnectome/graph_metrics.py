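"""Node-level graph-theoretical metrics on weighted brain networks.

Five metrics: degree, strength, local efficiency, betweenness centrality
and closeness centrality, all computed on raw-space (strength) weights.
Path-based metrics use the edge length transform ``length = 1/weight``
(stronger connection = shorter path), the dominant convention in
connectomics toolkits; ``1 - weight`` is available as an alternative.
Zero-weight entries are treated as absent edges.

Multilayer counterparts are computed on the 2N-node supra-adjacency
graph, optionally averaging each region's two replica values back to
length N.  This supra-graph convention is a declared stand-in for
layer-aware multilayer centralities and is flagged as such in logs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .netio import ValidationError, WeightedNetwork
from .preprocess import MultilayerNetwork

logger = logging.getLogger(__name__)

METRICS = ("degree", "strength", "local_efficiency", "betweenness", "closeness")


@dataclass
class NodeMetricVector:
    metric: str
    values: np.ndarray
    conventions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError(f"{self.metric}: values must be finite and >= 0")


def _require_raw(network: WeightedNetwork) -> np.ndarray:
    if network.space != "raw":
        raise ValidationError("graph metrics consume raw (non-inverted) weights")
    w = network.weights
    if w.size and w.min() < 0:
        raise ValidationError("signed weights: apply absolute_correlations first")
    return w


def _length_matrix(w: np.ndarray, transform: str = "inverse") -> np.ndarray:
    """Edge lengths for shortest-path metrics; absent edges become inf."""
    with np.errstate(divide="ignore"):
        if transform == "inverse":
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif transform == "one_minus":
            lengths = np.where(w > 0, 1.0 - w, np.inf)
        else:
            raise ValidationError(f"unknown distance transform {transform!r}")
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _as_length_graph(w: np.ndarray, transform: str) -> nx.Graph:
    lengths = _length_matrix(w, transform)
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    n = w.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=float(lengths[i, j]))
    return g


def node_degree(network: WeightedNetwork, edge_threshold: float = 0.0) -> NodeMetricVector:
    """Count of incident edges with weight strictly above the threshold.

    On dense correlation-derived matrices the default threshold 0 makes
    every degree N - 1; the threshold is exposed precisely because degree
    is otherwise degenerate there."""
    w = _require_raw(network)
    if not 0.0 <= edge_threshold < 1.0:
        raise ValidationError("edge_threshold must lie in [0, 1)")
    deg = (w > edge_threshold).sum(axis=1).astype(float)
    return NodeMetricVector("degree", deg, {"edge_threshold": edge_threshold})


def node_strength(network: WeightedNetwork) -> NodeMetricVector:
    """Sum of incident edge weights (row sums)."""
    w = _require_raw(network)
    return NodeMetricVector("strength", w.sum(axis=1))


def local_efficiency(network: WeightedNetwork, transform: str = "inverse") -> NodeMetricVector:
    """Communication efficiency within each node's neighborhood.

    For node v with neighbors Γ(v) (weight > 0): the global efficiency of
    the subgraph induced on Γ(v) — the mean over ordered neighbor pairs of
    one over their shortest-path length inside that subgraph.  Unreachable
    pairs contribute 0; nodes with fewer than two neighbors score 0.
    """
    w = _require_raw(network)
    n = w.shape[0]
    vals = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(w[v] > 0)
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = shortest_path(_length_matrix(sub, transform), method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        m = len(nbrs)
        vals[v] = inv.sum() / (m * (m - 1))
    return NodeMetricVector("local_efficiency", vals, {"distance": transform})


def betweenness(network: WeightedNetwork, transform: str = "inverse") -> NodeMetricVector:
    """Weighted betweenness centrality with exact shortest-path counting,
    normalized by (N-1)(N-2)/2."""
    w = _require_raw(network)
    g = _as_length_graph(w, transform)
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    vals = np.array([bc[i] for i in range(w.shape[0])])
    return NodeMetricVector("betweenness", vals, {"distance": transform, "normalized": True})


def closeness(network: WeightedNetwork, transform: str = "inverse") -> NodeMetricVector:
    """Component-scaled closeness: c(v) = (r/(N-1)) * (r / sum of distances),
    r = number of other reachable nodes; isolated nodes score 0."""
    w = _require_raw(network)
    g = _as_length_graph(w, transform)
    cc = nx.closeness_centrality(g, distance="length", wf_improved=True)
    vals = np.array([cc[i] for i in range(w.shape[0])])
    return NodeMetricVector("closeness", vals, {"distance": transform, "scaling": "component"})


_METRIC_FNS = {
    "degree": node_degree,
    "strength": node_strength,
    "local_efficiency": local_efficiency,
    "betweenness": betweenness,
    "closeness": closeness,
}


def compute_metric(network: WeightedNetwork, metric: str, **kwargs) -> NodeMetricVector:
    if metric not in _METRIC_FNS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    return _METRIC_FNS[metric](network, **kwargs)


def multilayer_metric(
    supra: MultilayerNetwork, metric: str, aggregate: str = "mean", **kwargs
) -> NodeMetricVector:
    """Single-layer metric evaluated on the 2N-node supra graph.

    ``aggregate="mean"`` averages each region's two replica values back to
    length N so multilayer and single-layer feature tables are comparable;
    ``aggregate="none"`` returns the raw length-2N vector.
    """
    logger.info("multilayer %s via supra-graph convention (aggregate=%s)", metric, aggregate)
    vec = compute_metric(supra.as_network(), metric, **kwargs)
    if aggregate == "none":
        return vec
    if aggregate != "mean":
        raise ValidationError("aggregate must be 'none' or 'mean'")
    n = supra.n_regions
    vals = (vec.values[:n] + vec.values[n:]) / 2.0
    conventions = dict(vec.conventions, multilayer="supra-graph", aggregate="mean")
    return NodeMetricVector(vec.metric, vals, conventions)


# ---------------------------------------------------------------------------
# independent oracles (tests/acceptance only)
# ---------------------------------------------------------------------------

def betweenness_bruteforce(w: np.ndarray, transform: str = "inverse") -> np.ndarray:
    """Exhaustive-enumeration betweenness for tiny graphs (N <= 7).

    Enumerates every simple path between every pair, finds the shortest
    total length, and splits credit among ties.  Normalized like
    :func:`betweenness`."""
    n = w.shape[0]
    if n > 7:
        raise ValidationError("brute-force betweenness is limited to N <= 7")
    lengths = _length_matrix(w, transform)
    credit = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        best, best_paths = np.inf, []
        for k in range(n):
            for mid in itertools.permutations([x for x in range(n) if x not in (s, t)], k):
                path = (s, *mid, t)
                tot = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                if np.isinf(tot):
                    continue
                if tot < best - 1e-12:
                    best, best_paths = tot, [path]
                elif abs(tot - best) <= 1e-12:
                    best_paths.append(path)
        if not best_paths:
            continue
        for path in best_paths:
            for v in path[1:-1]:
                credit[v] += 1.0 / len(best_paths)
    norm = (n - 1) * (n - 2) / 2.0
    return credit / norm if norm > 0 else credit


def closeness_bruteforce(w: np.ndarray, transform: str = "inverse") -> np.ndarray:
    """Closeness via exhaustive simple-path shortest distances (N <= 7)."""
    n = w.shape[0]
    if n > 7:
        raise ValidationError("brute-force closeness is limited to N <= 7")
    lengths = _length_matrix(w, transform)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        best = np.inf
        for k in range(n):
            for mid in itertools.permutations([x for x in range(n) if x not in (s, t)], k):
                path = (s, *mid, t)
                tot = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                best = min(best, tot)
        dist[s, t] = dist[t, s] = best
    out = np.zeros(n)
    for v in range(n):
        reach = np.flatnonzero(np.isfinite(dist[v]) & (np.arange(n) != v))
        if len(reach) == 0:
            continue
        r = len(reach)
        tot = dist[v, reach].sum()
        if tot > 0:
            out[v] = (r / (n - 1)) * (r / tot)
    return out
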