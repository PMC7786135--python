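"""Independent brute-force oracles for graph statistics and regression.

Everything here is deliberately naive — explicit path enumeration, explicit
triangle counting, per-pair regressions — so the fast implementations in the
package are checked against an algorithmically unrelated route.
"""

from itertools import combinations, permutations

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by hand-rolled BFS; inf if unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if np.isinf(dist[s, v]):
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def clustering_by_triangles(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            continue
        tri = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = tri / (k * (k - 1) / 2)
    return out


def betweenness_by_path_enumeration(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by enumerating every simple path per pair."""
    n = adj.shape[0]
    bc = np.zeros(n)
    nodes = list(range(n))
    for s, t in combinations(nodes, 2):
        # all simple paths s -> t, via every ordering of intermediate nodes
        paths = []
        others = [v for v in nodes if v not in (s, t)]
        for r in range(len(others) + 1):
            for mid in permutations(others, r):
                seq = (s, *mid, t)
                if all(adj[a, b] for a, b in zip(seq, seq[1:])):
                    paths.append(seq)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        for p in sps:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(sps)
    return bc


def efficiency_from_bfs(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = bfs_distances(adj)
    total = 0.0
    for i, j in combinations(range(n), 2):
        if np.isfinite(d[i, j]) and d[i, j] > 0:
            total += 1.0 / d[i, j]
    return 2.0 * total / (n * (n - 1))


def local_efficiency_by_subgraph(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        out[i] = efficiency_from_bfs(adj[np.ix_(nbrs, nbrs)])
    return out


def char_path_length_by_bfs(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i, j in combinations(range(n), 2) if np.isfinite(d[i, j]) and d[i, j] > 0]
    return float(np.mean(vals)) if vals else float("nan")


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = a | a.T
    return a.astype(bool)


def residual_partial_correlations(x: np.ndarray) -> np.ndarray:
    """Partial correlations via explicit regress-out of all other columns."""
    n, p = x.shape
    out = np.eye(p)
    for i, j in combinations(range(p), 2):
        others = [k for k in range(p) if k not in (i, j)]
        design = np.column_stack([np.ones(n), x[:, others]])
        ri = x[:, i] - design @ np.linalg.lstsq(design, x[:, i], rcond=None)[0]
        rj = x[:, j] - design @ np.linalg.lstsq(design, x[:, j], rcond=None)[0]
        r = float(np.corrcoef(ri, rj)[0, 1])
        out[i, j] = out[j, i] = r
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Hand-applied Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
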