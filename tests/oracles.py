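"""Independent brute-force oracles used to validate the efficiency engine.

These deliberately avoid the package's shortest-path and efficiency code:
distances come from exhaustive enumeration of simple paths (with safe
dominance pruning), and efficiencies are computed as literal transcriptions
of the defining formulas from those enumerated distances.  Feasible only for
tiny graphs (N <= ~9), which is the point: an unimpeachable reference.
"""

from __future__ import annotations

import numpy as np

from conneff.connectome import Connectome


def shortest_paths_by_enumeration(edge_lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances by DFS over simple paths.

    A partial path whose cost already exceeds the best known distance to its
    endpoint is abandoned: with nonnegative edge lengths any completion of it
    is dominated by completing the cheaper prefix instead, so the pruning
    never discards the optimum (ties are still explored).
    """
    e = np.asarray(edge_lengths, dtype=float)
    n = e.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)
    adj = [
        [(j, e[i, j]) for j in range(n) if j != i and np.isfinite(e[i, j])]
        for i in range(n)
    ]

    def dfs(source: int, u: int, dist: float, visited: list[bool]) -> None:
        for v, w in adj[u]:
            if visited[v]:
                continue
            nd = dist + w
            if nd > best[source, v]:
                continue
            if nd < best[source, v]:
                best[source, v] = nd
            visited[v] = True
            dfs(source, v, nd, visited)
            visited[v] = False

    for s in range(n):
        visited = [False] * n
        visited[s] = True
        dfs(s, s, 0.0, visited)
    return best


def effective_edge_lengths(c: Connectome, weighted: bool) -> np.ndarray:
    w, l = c.weights, c.lengths
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(w > 0, (l / np.where(w > 0, w, 1.0)) if weighted else l, np.inf)
    np.fill_diagonal(e, np.inf)
    return e


def nodal_global_by_formula(c: Connectome, weighted: bool) -> np.ndarray:
    """(1/(N-1)) * sum_j 1/d_ij, distances from enumeration."""
    n = c.n
    d = shortest_paths_by_enumeration(effective_edge_lengths(c, weighted))
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
        out[i] = total / (n - 1)
    return out


def nodal_local_by_formula(c: Connectome, weighted: bool) -> np.ndarray:
    """Neighborhood-subgraph efficiency, distances from enumeration."""
    n = c.n
    e_full = effective_edge_lengths(c, weighted)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if c.weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        d = shortest_paths_by_enumeration(e_full[np.ix_(nbrs, nbrs)])
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a == b or not np.isfinite(d[a, b]) or d[a, b] <= 0:
                    continue
                if weighted:
                    total += (
                        c.weights[i, nbrs[a]] * c.weights[i, nbrs[b]] / d[a, b]
                    ) ** (1.0 / 3.0)
                else:
                    total += 1.0 / d[a, b]
        out[i] = total / (k * (k - 1))
    return out


def random_connectome(
    rng: np.random.Generator,
    n_min: int = 3,
    n_max: int = 8,
    p_edge: float | None = None,
) -> Connectome:
    """A random symmetric weighted graph with positive lengths on edges."""
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(0.3, 0.9)) if p_edge is None else p_edge
    weights = np.zeros((n, n))
    lengths = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(iu[0].size) < p
    weights[iu] = np.where(mask, rng.uniform(0.1, 1.0, iu[0].size), 0.0)
    lengths[iu] = np.where(weights[iu] > 0, rng.uniform(1.0, 10.0, iu[0].size), 0.0)
    weights += weights.T
    lengths += lengths.T
    return Connectome(weights, lengths)
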