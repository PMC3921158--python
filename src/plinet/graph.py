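"""Weighted graph metrics on PLI networks with surrogate normalization.

Electrodes are nodes and the PLI matrix supplies symmetric edge weights
in [0, 1].  Two metrics summarize the network:

* mean weighted clustering coefficient ``Cw`` — for node i,
  ``C_i = sum_{k != l} w_ik w_il w_kl / sum_{k != l} w_ik w_il``
  (k, l != i; isolated nodes get 0), averaged over nodes;
* mean weighted path length ``Lw`` — shortest paths under the distance
  transform ``d = 1/w`` (Dijkstra), averaged over node pairs.

Raw values depend on the overall weight level and its dispersion, so both
are normalized by their average over surrogate networks obtained by
randomly permuting the original edge weights (50 surrogates by default,
weight multiset preserved exactly).  The small-world index is
``S = (Cw / Cw_surr) / (Lw / Lw_surr)``; values above 1 together with
elevated normalized clustering indicate small-world organization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

DEFAULT_N_SURROGATES = 50


@dataclass
class WeightedGraph:
    """Symmetric weight matrix in [0, 1] with zero diagonal."""

    weights: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not self.node_labels:
            self.node_labels = tuple(str(i) for i in range(w.shape[0]))
        elif len(self.node_labels) != w.shape[0]:
            raise ValueError("node_labels length does not match matrix")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphMetrics:
    """Raw and surrogate-normalized clustering / path length summaries."""

    mean_clustering: float
    mean_path_length: float
    clustering_norm: float
    path_length_norm: float
    small_world: float
    n_surrogates: int


def _clustering_vector(w: np.ndarray) -> np.ndarray:
    # numerator: sum_{k,l} w_ik w_il w_kl = (W^3)_ii  (diag(W)=0 kills k=l,
    # k=i and l=i terms); denominator: (sum_k w_ik)^2 - sum_k w_ik^2
    num = np.einsum("ik,kl,li->i", w, w, w)
    s = w.sum(axis=1)
    denom = s * s - np.square(w).sum(axis=1)
    out = np.zeros(w.shape[0])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def node_clustering(graph: WeightedGraph, node: int | str) -> float:
    """Weighted clustering coefficient of one node (0 for isolated nodes)."""
    if isinstance(node, str):
        try:
            node = graph.node_labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None
    if not 0 <= node < graph.n_nodes:
        raise KeyError(f"node index {node} out of range")
    return float(_clustering_vector(graph.weights)[node])


def mean_clustering(graph: WeightedGraph) -> float:
    """Mean weighted clustering coefficient over all nodes (Cw)."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    return float(np.mean(_clustering_vector(graph.weights)))


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def mean_path_length(graph: WeightedGraph) -> float:
    """Mean weighted shortest path length over node pairs (Lw).

    Edge length is the inverse weight 1/w; a zero weight means the edge
    is absent.  Unreachable pairs raise rather than being silently
    assigned a large distance.
    """
    w = graph.weights
    if w.shape[0] < 2:
        raise ValueError("path length requires at least two nodes")
    d = _distance_matrix(w)
    # dense Dijkstra; 0 entries in `d` are the diagonal only
    dist = shortest_path(d, method="D", directed=False)
    off = ~np.eye(w.shape[0], dtype=bool)
    if np.any(np.isinf(dist[off])):
        i, j = np.argwhere(np.isinf(dist) & off)[0]
        raise ValueError(
            f"graph is disconnected: no path between nodes "
            f"{graph.node_labels[i]!r} and {graph.node_labels[j]!r}"
        )
    return float(np.mean(dist[off]))


def shuffle_surrogate(graph: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """Random network: uniformly permute the upper-triangle edge weights.

    The weight multiset is preserved exactly; symmetry and the zero
    diagonal are restored by mirroring.
    """
    n = graph.n_nodes
    iu = np.triu_indices(n, k=1)
    vals = graph.weights[iu]
    shuffled = vals[rng.permutation(vals.size)]
    w = np.zeros_like(graph.weights)
    w[iu] = shuffled
    w += w.T
    return WeightedGraph(w, graph.node_labels)


def normalize_metrics(graph: WeightedGraph,
                      n_surrogates: int = DEFAULT_N_SURROGATES,
                      rng: np.random.Generator | None = None,
                      max_resamples: int = 1000) -> GraphMetrics:
    """Cw and Lw normalized by their means over edge-shuffled surrogates.

    A surrogate that happens to be disconnected (possible when the weight
    matrix contains exact zeros) is discarded and redrawn; the event is
    logged.
    """
    if rng is None:
        rng = np.random.default_rng()
    cw = mean_clustering(graph)
    lw = mean_path_length(graph)  # raises early if the graph itself is disconnected
    c_surr, l_surr = [], []
    attempts = 0
    while len(c_surr) < n_surrogates:
        if attempts > n_surrogates + max_resamples:
            raise RuntimeError("too many disconnected surrogates; graph too sparse")
        attempts += 1
        surr = shuffle_surrogate(graph, rng)
        try:
            l_surr.append(mean_path_length(surr))
        except ValueError:
            logger.warning("disconnected surrogate discarded (attempt %d)", attempts)
            continue
        c_surr.append(mean_clustering(surr))
    c_surr_mean = float(np.mean(c_surr))
    if c_surr_mean == 0.0:
        # triangle-free sparse graphs: the normalization is undefined
        logger.warning("surrogate clustering averaged zero; clustering_norm NaN")
        c_norm = np.nan
    else:
        c_norm = cw / c_surr_mean
    l_norm = lw / float(np.mean(l_surr))
    return GraphMetrics(
        mean_clustering=cw,
        mean_path_length=lw,
        clustering_norm=c_norm,
        path_length_norm=l_norm,
        small_world=c_norm / l_norm,
        n_surrogates=n_surrogates,
    )
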