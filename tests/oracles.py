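"""Independent brute-force oracles for small weighted graphs.

Everything here works by exhaustive enumeration (all simple paths, all
triplets) and is deliberately independent of the package's graph code,
which uses Dijkstra / Brandes-style algorithms.  Only usable for tiny
graphs (n <= 8 or so).
"""

from __future__ import annotations

import itertools

import numpy as np

REL_TOL = 1e-9


def all_simple_paths(adj: np.ndarray, s: int, t: int):
    """Yield every simple path s -> t as a node tuple (DFS)."""
    n = adj.shape[0]
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in range(n):
            if adj[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + (nxt,)))


def path_length(adj: np.ndarray, path) -> float:
    return sum(1.0 / adj[a, b] for a, b in zip(path, path[1:]))


def brute_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances by exhaustive path enumeration."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            best = np.inf
            for p in all_simple_paths(adj, s, t):
                best = min(best, path_length(adj, p))
            d[s, t] = d[t, s] = best
    return d


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Fraction of shortest paths through each node (endpoints excluded),
    normalized by (n-1)(n-2)/2."""
    n = adj.shape[0]
    bw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(all_simple_paths(adj, s, t))
            if not paths:
                continue
            lengths = np.array([path_length(adj, p) for p in paths])
            best = lengths.min()
            shortest = [
                p for p, l in zip(paths, lengths)
                if l <= best * (1 + REL_TOL)
            ]
            sigma = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p[1:-1])
                bw[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2.0
    return bw / norm if norm > 0 else bw


def brute_eccentricity(adj: np.ndarray) -> np.ndarray:
    d = brute_distances(adj)
    finite = np.where(np.isfinite(d), d, -np.inf)
    e = finite.max(axis=1)
    return np.where(np.isfinite(e), e, 0.0)


def brute_global_efficiency(adj: np.ndarray) -> np.ndarray:
    d = brute_distances(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        inv = [
            1.0 / d[v, u]
            for u in range(n)
            if u != v and np.isfinite(d[v, u]) and d[v, u] > 0
        ]
        out[v] = sum(inv) / (n - 1)
    return out


def brute_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u] > 0]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        ds = brute_distances(sub)
        k = len(nbrs)
        acc = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                if np.isfinite(ds[a, b]) and ds[a, b] > 0:
                    acc += 1.0 / ds[a, b]
        out[v] = acc / (k * (k - 1) / 2.0)
    return out


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by exhaustive triplet enumeration."""
    n = adj.shape[0]
    wmax = adj.max()
    if wmax <= 0:
        return np.zeros(n)
    what = adj / wmax
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for u, w in itertools.combinations(nbrs, 2):
            if adj[u, w] > 0:
                acc += (what[v, u] * what[v, w] * what[u, w]) ** (1 / 3)
        out[v] = 2.0 * acc / (k * (k - 1))
    return out


def brute_degree(adj: np.ndarray) -> np.ndarray:
    return (adj > 0).sum(axis=1).astype(float)


BRUTE_METRICS = {
    "degree": brute_degree,
    "betweenness": brute_betweenness,
    "eccentricity": brute_eccentricity,
    "global_efficiency": brute_global_efficiency,
    "local_efficiency": brute_local_efficiency,
    "clustering": brute_clustering,
}


def random_graph_adj(
    rng: np.random.Generator, n_nodes: int, density: float = 0.5
) -> np.ndarray:
    """Random symmetric weighted adjacency with positive weights."""
    a = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, 1)
    present = rng.random(iu[0].size) < density
    w = rng.uniform(0.2, 2.0, iu[0].size) * present
    a[iu] = w
    a[(iu[1], iu[0])] = w
    return a
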