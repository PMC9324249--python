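"""Binary graphs from thresholded connectivity and seven nodal metrics.

Edges are defined by a sample-size-aware test on the Fisher-z scale: the
statistic z_stat = atanh(r) * sqrt(T - 3) must exceed the z threshold
(default 2) and its one-sided normal p-value must fall below the p threshold
(default 0.05).  With the defaults and T >= 8 the p condition is implied by
the z condition (p at z_stat = 2 is 0.0228), which the thresholder asserts.

All metrics are computed from scratch on the boolean adjacency matrix:

* degree, cost = degree / (n - 1)
* nodal global efficiency: mean inverse shortest-path distance to all other
  nodes (unreachable pairs contribute 0)
* nodal local efficiency: mean pairwise inverse distance inside the subgraph
  induced by the node's neighbors (0 for degree < 2)
* betweenness centrality: Brandes accumulation over all shortest paths,
  normalized by (n - 1)(n - 2) / 2 so values live in [0, 1]
* average path length: mean shortest distance to *reachable* nodes only
  (0 for isolated nodes); the harmonic treatment of disconnection already
  lives in global efficiency
* clustering coefficient: fraction of neighbor pairs that are connected
  (0 for degree < 2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import _kernels
from .connectivity import ConnectivityMatrix
from .exceptions import InvalidArgumentError
from .parcellation import ParcellationTable

METRICS = (
    "degree",
    "cost",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "path_length",
    "clustering",
)


@dataclass(frozen=True)
class ThresholdSpec:
    """Edge rule parameters for the adjacency threshold z > 2, p < 0.05."""

    z_stat_threshold: float = 2.0
    p_threshold: float = 0.05
    positive_only: bool = True
    two_sided: bool = False

    def __post_init__(self):
        if self.z_stat_threshold <= 0:
            raise InvalidArgumentError("z_stat_threshold must be > 0")
        if not 0 < self.p_threshold < 1:
            raise InvalidArgumentError("p_threshold must be in (0, 1)")


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph over ROI nodes."""

    adjacency: np.ndarray = field(repr=False)
    node_ids: np.ndarray = field(repr=False)

    def __post_init__(self):
        a = self.adjacency
        if a.dtype != bool or a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidArgumentError("adjacency must be a square boolean matrix")
        if not np.array_equal(a, a.T):
            raise InvalidArgumentError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise InvalidArgumentError("self-loops are not allowed")
        if len(self.node_ids) != a.shape[0]:
            raise InvalidArgumentError("node_ids length must match adjacency")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def threshold_graph(conn: ConnectivityMatrix, spec: ThresholdSpec | None = None,
                    node_ids: np.ndarray | None = None) -> BinaryGraph:
    """Binary adjacency from a Fisher-z matrix via the z/p edge rule."""
    spec = spec or ThresholdSpec()
    if conn.t_effective <= 3:
        raise InvalidArgumentError("thresholding requires T_effective > 3")
    scale = np.sqrt(conn.t_effective - 3)
    z_stat = conn.z * scale
    if spec.two_sided:
        stat = np.abs(z_stat)
        p = 2.0 * norm.sf(stat)
    else:
        stat = z_stat
        p = norm.sf(stat)
    adjacency = (stat > spec.z_stat_threshold) & (p < spec.p_threshold)
    if spec.positive_only:
        adjacency &= conn.z > 0
    np.fill_diagonal(adjacency, False)
    adjacency &= adjacency.T
    if node_ids is None:
        node_ids = np.arange(conn.n_roi)
    return BinaryGraph(adjacency=adjacency, node_ids=np.asarray(node_ids))


def shortest_paths(graph: BinaryGraph) -> np.ndarray:
    """All-pairs shortest path lengths by synchronous multi-source BFS.

    Returns a float matrix with d[i, i] = 0 and np.inf for unreachable pairs.
    """
    return _bfs_distances(graph.adjacency)


def _bfs_distances(adjacency: np.ndarray) -> np.ndarray:
    if _kernels.HAVE_NUMBA:
        return _kernels.bfs_all_pairs(adjacency)
    return _bfs_distances_numpy(adjacency)


def _bfs_distances_numpy(adjacency: np.ndarray) -> np.ndarray:
    n = adjacency.shape[0]
    a = adjacency.astype(np.uint8)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    visited = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier.astype(np.uint8) @ a > 0) & ~visited
        dist[frontier] = d
        visited |= frontier
    return dist


def _betweenness(adjacency: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Brandes betweenness, normalized to [0, 1] by (n-1)(n-2)/2."""
    n = adjacency.shape[0]
    if n < 3:
        return np.zeros(n)
    if _kernels.HAVE_NUMBA:
        return _kernels.brandes_betweenness(adjacency) / ((n - 1) * (n - 2) / 2.0)
    a = adjacency.astype(float)
    bc = np.zeros(n)
    for s in range(n):
        level = dist[s]
        finite = np.isfinite(level)
        if finite.sum() <= 1:
            continue
        max_d = int(level[finite].max())
        # sigma[v]: number of shortest s-v paths, filled level by level.
        sigma = np.zeros(n)
        sigma[s] = 1.0
        layers = [level == d for d in range(max_d + 1)]
        for d in range(1, max_d + 1):
            prev, cur = layers[d - 1], layers[d]
            sigma[cur] = a[np.ix_(cur, prev)] @ sigma[prev]
        # Backward dependency accumulation.
        delta = np.zeros(n)
        for d in range(max_d, 0, -1):
            prev, cur = layers[d - 1], layers[d]
            w = (1.0 + delta[cur]) / sigma[cur]
            delta[prev] += sigma[prev] * (a[np.ix_(prev, cur)] @ w)
        delta[s] = 0.0
        bc += delta
    # Each unordered (s, t) pair was accumulated from both endpoints.
    bc /= 2.0
    return bc / ((n - 1) * (n - 2) / 2.0)


def nodal_metrics(graph: BinaryGraph) -> pd.DataFrame:
    """Seven nodal graph metrics, indexed by roi_id."""
    n = graph.n_nodes
    if n < 2:
        raise InvalidArgumentError("metrics require n_nodes >= 2")
    adj = graph.adjacency
    dist = _bfs_distances(adj)

    degree = adj.sum(axis=1).astype(int)
    cost = degree / (n - 1)
    assert np.array_equal(cost, degree / (n - 1)), "cost = degree/(n-1) violated"

    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    global_eff = inv.sum(axis=1) / (n - 1)

    finite = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    reach_count = finite.sum(axis=1)
    path_sum = np.where(finite, dist, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        path_length = np.where(reach_count > 0, path_sum / np.maximum(reach_count, 1), 0.0)

    if _kernels.HAVE_NUMBA:
        local_eff, clustering = _kernels.local_efficiency_clustering(adj)
        betweenness = _betweenness(adj, dist)
        return _metric_frame(graph, degree, cost, global_eff, local_eff,
                             betweenness, path_length, clustering)

    local_eff = np.zeros(n)
    clustering = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        e = sub.sum() / 2
        clustering[i] = 2.0 * e / (k * (k - 1))
        sub_dist = _bfs_distances(sub)
        with np.errstate(divide="ignore"):
            sub_inv = 1.0 / sub_dist
        np.fill_diagonal(sub_inv, 0.0)
        local_eff[i] = sub_inv.sum() / (k * (k - 1))

    betweenness = _betweenness(adj, dist)
    return _metric_frame(graph, degree, cost, global_eff, local_eff,
                         betweenness, path_length, clustering)


def _metric_frame(graph, degree, cost, global_eff, local_eff, betweenness,
                  path_length, clustering) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "degree": degree,
            "cost": cost,
            "global_efficiency": global_eff,
            "local_efficiency": local_eff,
            "betweenness": betweenness,
            "path_length": path_length,
            "clustering": clustering,
        },
        index=pd.Index(graph.node_ids, name="roi_id"),
    )


def network_summary(metrics: pd.DataFrame, node_subset) -> pd.Series:
    """Unweighted mean of each metric over a non-empty subset of nodes."""
    subset = np.asarray(list(node_subset))
    if subset.size == 0:
        raise InvalidArgumentError("node subset must be non-empty")
    missing = set(subset) - set(metrics.index)
    if missing:
        raise InvalidArgumentError(f"nodes not in metric table: {sorted(missing)}")
    out = metrics.loc[subset].mean()
    out["n_nodes"] = float(len(subset))
    return out


SCOPES = ("whole_brain", "L", "R")


def subject_graph_metrics(
    conn: ConnectivityMatrix,
    parcellation: ParcellationTable,
    spec: ThresholdSpec | None = None,
) -> dict[str, pd.DataFrame]:
    """Nodal metric tables for the whole-brain, left and right networks.

    Hemispheric graphs are rebuilt from the hemisphere's z submatrix (not
    cut out of the whole-brain graph), matching the three analysis
    conditions; with a value threshold the two constructions coincide.
    """
    spec = spec or ThresholdSpec()
    out = {"whole_brain": nodal_metrics(threshold_graph(conn, spec))}
    for hemisphere in ("L", "R"):
        ids = parcellation.hemisphere_ids(hemisphere)
        sub = ConnectivityMatrix(
            z=conn.z[np.ix_(ids, ids)],
            t_effective=conn.t_effective,
            subject_id=conn.subject_id,
        )
        out[hemisphere] = nodal_metrics(threshold_graph(sub, spec, node_ids=ids))
    return out
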