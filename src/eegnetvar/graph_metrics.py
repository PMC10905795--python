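"""Weighted complex-network statistics on unthresholded wPLI graphs.

Electrodes are nodes and wPLI values are connection strengths; no
thresholding is applied, so every positive weight is an edge.  For
shortest-path based measures the edge length is the reciprocal weight
(strong coupling = short distance).  Three statistics are computed:

* characteristic path length  L = (1/n) sum_i sum_{j != i} d_ij / (n - 1),
  the network's integration measure;
* clustering coefficient      C = (1/n) sum_i 2 t_i / (k_i (k_i - 1)),
  with t_i generalized to weighted graphs as the geometric mean of triangle
  weights (weights rescaled by the network maximum); C_i = 0 for k_i < 2;
* betweenness centrality      b_i = [1/((n-1)(n-2))] sum_{h != j != i}
  rho_hj(i) / rho_hj, the fraction of shortest paths through node i, with
  ties counted fractionally.

On 0/1 matrices all three reduce exactly to the textbook binary formulas.
Multiplying every weight by c > 0 divides L by c and leaves C and b_i
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import dijkstra


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with derived 1/w edge lengths."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        """Edge lengths 1/w; absent edges (w == 0) are +inf."""
        with np.errstate(divide="ignore"):
            ln = np.where(self.weights > 0, 1.0 / self.weights, np.inf)
        np.fill_diagonal(ln, 0.0)
        return ln

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii, jj):
            w = self.weights[i, j]
            g.add_edge(int(i), int(j), weight=w, length=1.0 / w)
        return g


@dataclass
class NetworkMetrics:
    """Bundle of network statistics for one session pattern."""

    cpl: float
    cc: float
    cc_nodes: np.ndarray
    bc: np.ndarray
    bc_mean: float
    degree: np.ndarray
    channel_names: tuple[str, ...] = ()


def _as_graph(g) -> WeightedGraph:
    if isinstance(g, WeightedGraph):
        return g
    return WeightedGraph(np.asarray(g, dtype=float))


def shortest_paths(g) -> np.ndarray:
    """All-pairs shortest-path distance matrix on 1/w edge lengths."""
    g = _as_graph(g)
    if g.n < 2:
        raise ValueError("need at least 2 nodes")
    lengths = np.where(np.isfinite(g.lengths), g.lengths, 0.0)
    d = dijkstra(lengths, directed=False)
    return d


def characteristic_path_length(g, on_disconnected: str = "exclude") -> float:
    """Mean shortest-path distance over all ordered node pairs.

    Unreachable pairs are excluded from the average with a warning
    (``on_disconnected="exclude"``, default) or propagate as inf
    (``"inf"``).  A graph with no finite off-diagonal distance at all is an
    error.
    """
    g = _as_graph(g)
    d = shortest_paths(g)
    off = ~np.eye(g.n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("graph is fully disconnected; path length undefined")
    if not finite.all():
        if on_disconnected == "inf":
            return float("inf")
        warnings.warn(
            f"{(~finite).sum()} unreachable node pairs excluded from the "
            "characteristic path length", RuntimeWarning, stacklevel=2,
        )
        vals = vals[finite]
    return float(vals.mean())


def clustering_coefficient(g) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering coefficient on the weighted graph.

    t_i = (1/2) sum_{j,h} (w'_ij w'_ih w'_jh)^{1/3} with w' = w / max(w);
    C_i = 2 t_i / (k_i (k_i - 1)) and C_i = 0 for nodes with fewer than two
    neighbors.  Reduces to the triangle-fraction formula on binary graphs.
    """
    g = _as_graph(g)
    w = g.weights
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(g.n)
    cbrt = np.cbrt(w / wmax)
    t = np.diagonal(cbrt @ cbrt @ cbrt) / 2.0
    k = (w > 0).sum(axis=1)
    ci = np.zeros(g.n)
    mask = k >= 2
    ci[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1.0))
    return float(ci.mean()), ci


def betweenness_centrality(g) -> np.ndarray:
    """Fraction of all shortest (1/w-length) paths passing through each node.

    Normalized by (n-1)(n-2) ordered source-target pairs, so values lie in
    [0, 1]; multiple shortest paths are counted fractionally.
    """
    g = _as_graph(g)
    if g.n < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    G = g.to_networkx()
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(g.n)])


def network_metrics(cm, mean_degree: bool = False) -> NetworkMetrics:
    """All statistics for one session-scope connectivity pattern."""
    from .connectivity import ConnectivityMatrix, node_degree

    if isinstance(cm, ConnectivityMatrix):
        if cm.scope != "session":
            raise ValueError("network metrics are computed on session-scope patterns")
        g = WeightedGraph(cm.values)
        names = cm.channel_names
        degree = node_degree(cm, mean=mean_degree)
    else:
        g = _as_graph(cm)
        names = tuple(f"ch{i}" for i in range(g.n))
        degree = g.weights.sum(axis=1)
        if mean_degree:
            degree = degree / (g.n - 1)

    cpl = characteristic_path_length(g)
    cc, cc_nodes = clustering_coefficient(g)
    bc = betweenness_centrality(g)
    return NetworkMetrics(
        cpl=cpl, cc=cc, cc_nodes=cc_nodes, bc=bc, bc_mean=float(bc.mean()),
        degree=degree, channel_names=names,
    )
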