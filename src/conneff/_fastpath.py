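"""Compiled kernels for the per-node neighborhood shortest-path loop.

Nodal local efficiency needs an all-pairs shortest-path solve inside every
node's neighborhood subgraph — ~N Floyd–Warshall runs per subject — which
dominates the cost of a cohort.  The kernels here implement exactly the same
computation as the scipy-based path in :mod:`conneff.efficiency` (tested for
equality there) but without per-call Python overhead.  If numba is
unavailable the plain functions are used as-is, only slower.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _floyd_warshall_inplace(d: np.ndarray) -> None:
    n = d.shape[0]
    for k in range(n):
        for i in range(n):
            dik = d[i, k]
            if dik == np.inf:
                continue
            for j in range(n):
                alt = dik + d[k, j]
                if alt < d[i, j]:
                    d[i, j] = alt


@njit(cache=True)
def local_efficiency_kernel(
    weights: np.ndarray, edge_lengths: np.ndarray, weighted: bool
) -> np.ndarray:
    """Raw nodal local efficiency for every node.

    ``edge_lengths`` holds the effective edge lengths (inf where no edge).
    For each node i the subgraph over its neighbors is extracted, solved
    with Floyd-Warshall, and the ordered-pair efficiency sum accumulated:
    weighted terms ``(w_ij * w_ik / d)^(1/3)``, unweighted terms ``1/d``.
    """
    n = weights.shape[0]
    out = np.zeros(n)
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if weights[i, j] > 0.0:
                nbrs[k] = j
                k += 1
        if k < 2:
            continue
        d = np.empty((k, k))
        for a in range(k):
            for b in range(k):
                d[a, b] = edge_lengths[nbrs[a], nbrs[b]]
            d[a, a] = 0.0
        _floyd_warshall_inplace(d)
        total = 0.0
        for a in range(k):
            wa = weights[i, nbrs[a]]
            for b in range(k):
                if a == b:
                    continue
                dist = d[a, b]
                if dist > 0.0 and dist != np.inf:
                    if weighted:
                        total += (wa * weights[i, nbrs[b]] / dist) ** (1.0 / 3.0)
                    else:
                        total += 1.0 / dist
        out[i] = total / (k * (k - 1))
    return out
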