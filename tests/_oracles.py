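"""Independent brute-force oracles for the nodal graph metrics.

Deliberately naive: Floyd-Warshall for distances, exhaustive shortest-path
enumeration for betweenness, and direct transcription of the metric
definitions.  Shares no code with gliograph.graph.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _all_shortest_paths(adj, dist, s, t):
    """Every shortest s-t path as a list of node lists."""
    if s == t:
        return [[s]]
    paths = []
    for u in range(adj.shape[0]):
        if adj[u, t] and dist[s, u] == dist[s, t] - 1:
            for path in _all_shortest_paths(adj, dist, s, u):
                paths.append(path + [t])
    return paths


def betweenness_exhaustive(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by enumerating every shortest path."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            paths = _all_shortest_paths(adj, dist, s, t)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    if n < 3:
        return bc
    return bc / ((n - 1) * (n - 2) / 2.0)


def oracle_metrics(adj: np.ndarray) -> dict[str, np.ndarray]:
    """All seven nodal metrics straight from their definitions."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    degree = adj.sum(axis=1)
    out = {
        "degree": degree.astype(float),
        "cost": degree / (n - 1),
        "betweenness": betweenness_exhaustive(adj),
    }
    geff = np.zeros(n)
    plen = np.zeros(n)
    leff = np.zeros(n)
    clust = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        geff[i] = sum(
            1.0 / dist[i, j] for j in others if np.isfinite(dist[i, j])
        ) / (n - 1)
        reach = [dist[i, j] for j in others if np.isfinite(dist[i, j])]
        plen[i] = float(np.mean(reach)) if reach else 0.0
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k >= 2:
            sub = adj[np.ix_(nbrs, nbrs)]
            clust[i] = sub.sum() / (k * (k - 1))
            sub_dist = floyd_warshall(sub)
            total = 0.0
            for a in range(k):
                for b in range(k):
                    if a != b and np.isfinite(sub_dist[a, b]):
                        total += 1.0 / sub_dist[a, b]
            leff[i] = total / (k * (k - 1))
    out["global_efficiency"] = geff
    out["path_length"] = plen
    out["local_efficiency"] = leff
    out["clustering"] = clust
    return out


def er_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric Erdos-Renyi boolean adjacency with empty diagonal."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    adj = adj | adj.T
    return adj
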