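"""Compiled inner loops for the nodal graph metrics.

Same algorithms as the pure-numpy paths in :mod:`gliograph.graph`
(synchronous BFS, Brandes betweenness, neighbor-subgraph efficiency), just
JIT-compiled: cohort analyses evaluate thousands of graphs per run.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def bfs_all_pairs(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on a boolean adjacency matrix."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    queue = np.empty(n, np.int64)
    for s in range(n):
        dist[s, s] = 0.0
        head, tail = 0, 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] and dist[s, v] == np.inf:
                    dist[s, v] = du + 1.0
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def brandes_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized Brandes betweenness (per unordered source-target pair)."""
    n = adj.shape[0]
    bc = np.zeros(n)
    sigma = np.zeros(n)
    dist = np.zeros(n)
    delta = np.zeros(n)
    order = np.empty(n, np.int64)
    for s in range(n):
        for i in range(n):
            sigma[i] = 0.0
            dist[i] = -1.0
            delta[i] = 0.0
        sigma[s] = 1.0
        dist[s] = 0.0
        head, tail = 0, 0
        order[tail] = s
        tail += 1
        while head < tail:
            u = order[head]
            head += 1
            for v in range(n):
                if adj[u, v]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1.0
                        order[tail] = v
                        tail += 1
                    if dist[v] == dist[u] + 1.0:
                        sigma[v] += sigma[u]
        for idx in range(tail - 1, 0, -1):
            w = order[idx]
            for v in range(n):
                if adj[w, v] and dist[v] == dist[w] - 1.0:
                    delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            bc[w] += delta[w]
    return bc / 2.0


@njit(cache=True)
def local_efficiency_clustering(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node local efficiency and clustering coefficient."""
    n = adj.shape[0]
    local_eff = np.zeros(n)
    clustering = np.zeros(n)
    nbrs = np.empty(n, np.int64)
    dist = np.empty(n)
    queue = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        edges = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nbrs[a], nbrs[b]]:
                    edges += 1
        clustering[i] = 2.0 * edges / (k * (k - 1))
        inv_sum = 0.0
        for src in range(k):
            for t in range(k):
                dist[t] = -1.0
            dist[src] = 0.0
            head, tail = 0, 0
            queue[tail] = src
            tail += 1
            while head < tail:
                u = queue[head]
                head += 1
                for v in range(k):
                    if dist[v] < 0 and adj[nbrs[u], nbrs[v]]:
                        dist[v] = dist[u] + 1.0
                        queue[tail] = v
                        tail += 1
            for t in range(k):
                if t != src and dist[t] > 0:
                    inv_sum += 1.0 / dist[t]
        local_eff[i] = inv_sum / (k * (k - 1))
    return local_eff, clustering
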