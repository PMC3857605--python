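"""Physical-distance network efficiency: nodal global, nodal local, whole-net.

The communication efficiency between two nodes is the inverse of the
shortest *physical* path length between them — the smallest sum of fiber
lengths over all paths, not the hop count and not the Euclidean distance.
The weighted variant divides each edge's fiber length by its connection
weight, so strong connections shorten effective distance:

    d^w(i, j) = min over paths of sum_e  l_e / w_e

With weights rescaled to a maximum of 1 (:meth:`Connectome.rescaled`):

* nodal global efficiency of node i:
      E_glob(i) = (1 / (N - 1)) * sum_{j != i} 1 / d(i, j)
* nodal local efficiency of node i, over the subgraph G_i of i's neighbors
  (the neighbors of i and the edges among them, excluding i itself):
      unweighted:  E_loc(i) = (1 / (k (k - 1))) * sum_{j != k in G_i} 1 / d(j, k)
      weighted:    E_loc(i) = (1 / (k (k - 1))) *
                       sum_{j != k in G_i} (w_ij * w_ik / d^w(j, k))^(1/3)
  where k = |G_i|, distances are computed within G_i, and E_loc(i) = 0 when
  k < 2.

Unreachable pairs contribute zero (1 / inf := 0), so the measures remain
defined for sparse subjects.  Raw efficiencies are normalized by the ideal,
fully connected network: the complete graph on the same nodes with every
weight equal to 1 and every length equal to the subject's minimum observed
edge length.  This guarantees normalized values in [0, 1] and reduces to the
classical Latora–Marchiori normalization in the unweighted case.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from . import _fastpath
from .atlas import RegionAtlas
from .connectome import Connectome
from .records import EfficiencyTable, SubjectRecord

__all__ = [
    "weighted_edge_lengths",
    "unweighted_edge_lengths",
    "shortest_path_distances",
    "nodal_global_efficiency",
    "nodal_local_efficiency",
    "network_efficiency",
    "normalize_efficiency",
    "compute_nodal_efficiencies",
    "compute_cohort_efficiency",
]


def weighted_edge_lengths(c: Connectome) -> np.ndarray:
    """Effective edge lengths ``l_ij / w_ij`` (inf where no edge exists).

    Expects weights on their analysis scale (rescale first via
    :meth:`Connectome.rescaled` so the strongest edge has weight 1).
    """
    w, l = c.weights, c.lengths
    bad = (w > 0) & (l <= 0)
    if bad.any():
        i, j = np.nonzero(bad)
        raise ValueError(
            f"positive weight with non-positive length at pairs "
            f"{list(zip(i.tolist(), j.tolist()))[:5]}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(w > 0, l / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(e, np.inf)
    return e


def unweighted_edge_lengths(c: Connectome) -> np.ndarray:
    """Plain physical edge lengths ``l_ij`` (inf where no edge exists)."""
    e = np.where(c.weights > 0, c.lengths, np.inf)
    np.fill_diagonal(e, np.inf)
    return e


def shortest_path_distances(edge_lengths: np.ndarray) -> np.ndarray:
    """Exact all-pairs shortest physical path distances.

    ``edge_lengths`` is an N x N matrix with nonnegative finite entries on
    existing edges and ``inf`` on absent ones; nonnegative lengths make both
    backends (dense Floyd-Warshall, sparse Dijkstra) exact.  Returns a
    symmetric matrix with zero diagonal and ``inf`` for unreachable pairs.
    """
    e = np.asarray(edge_lengths, dtype=float)
    if e.ndim != 2 or e.shape[0] != e.shape[1]:
        raise ValueError(f"edge_lengths must be square, got shape {e.shape}")
    n = e.shape[0]
    finite = np.isfinite(e)
    np.fill_diagonal(finite, False)
    if (e[finite] < 0).any():
        raise ValueError("negative edge length")
    if e[finite].min(initial=np.inf) > 0:
        # dense form (0 == no edge) is unambiguous here and much faster on
        # the near-complete graphs tractography produces
        dense = np.ascontiguousarray(np.where(finite, e, 0.0))
        return _csgraph_shortest_path(dense, method="FW", directed=True)
    i, j = np.nonzero(finite)
    graph = csr_matrix((e[i, j], (i, j)), shape=(n, n))
    return _csgraph_shortest_path(graph, method="D", directed=True)


def _inverse_distances(d: np.ndarray) -> np.ndarray:
    """Elementwise 1/d with 1/inf := 0 and a zero diagonal."""
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(d)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def _edge_lengths(c: Connectome, weighted: bool) -> np.ndarray:
    return weighted_edge_lengths(c) if weighted else unweighted_edge_lengths(c)


def nodal_global_efficiency(c: Connectome, weighted: bool = True) -> np.ndarray:
    """Raw (unnormalized) nodal global efficiency of every node.

    ``E_glob(i) = (1/(N-1)) sum_{j != i} 1/d(i, j)`` with weighted or plain
    physical shortest-path distances.  Unreachable partners contribute zero.
    """
    n = c.n
    if n < 2:
        raise ValueError(f"nodal global efficiency requires at least 2 nodes, got {n}")
    d = shortest_path_distances(_edge_lengths(c, weighted))
    return _inverse_distances(d).sum(axis=1) / (n - 1)


def nodal_local_efficiency(c: Connectome, weighted: bool = True) -> np.ndarray:
    """Raw (unnormalized) nodal local efficiency of every node.

    For each node the efficiency of its neighborhood subgraph G_i (neighbors
    of i and edges among them; i itself excluded), with shortest paths
    restricted to G_i.  Nodes with fewer than two neighbors score 0.  In the
    weighted form each ordered pair (j, k) contributes
    ``(w_ij * w_ik / d^w(j, k))^(1/3)``.
    """
    w = c.weights
    e_full = _edge_lengths(c, weighted)
    if _fastpath.HAVE_NUMBA:
        return _fastpath.local_efficiency_kernel(
            np.ascontiguousarray(w), np.ascontiguousarray(e_full), weighted
        )
    return _nodal_local_efficiency_ref(c, weighted)


def _nodal_local_efficiency_ref(c: Connectome, weighted: bool = True) -> np.ndarray:
    """Reference scipy implementation of :func:`nodal_local_efficiency`."""
    w = c.weights
    e_full = _edge_lengths(c, weighted)
    out = np.zeros(c.n)
    for i in range(c.n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        d_sub = shortest_path_distances(e_full[np.ix_(nbrs, nbrs)])
        inv = _inverse_distances(d_sub)
        if weighted:
            v = np.cbrt(w[i, nbrs])
            total = v @ np.cbrt(inv) @ v
        else:
            total = inv.sum()
        out[i] = total / (k * (k - 1))
    return out


def network_efficiency(c: Connectome, weighted: bool = False) -> tuple[float, float]:
    """Whole-network (global, local) efficiency.

    Global efficiency is the mean of ``1/d(i, j)`` over ordered node pairs;
    local efficiency is the mean over nodes of the global efficiency of each
    node's neighborhood subgraph.
    """
    n = c.n
    if n < 2:
        raise ValueError(f"network efficiency requires at least 2 nodes, got {n}")
    e_full = _edge_lengths(c, weighted)
    d = shortest_path_distances(e_full)
    glob = float(_inverse_distances(d).sum() / (n * (n - 1)))
    local_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(c.weights[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        d_sub = shortest_path_distances(e_full[np.ix_(nbrs, nbrs)])
        local_terms[i] = _inverse_distances(d_sub).sum() / (k * (k - 1))
    return glob, float(local_terms.mean())


def _min_edge_length(c: Connectome) -> float | None:
    mask = c.weights > 0
    np.fill_diagonal(mask, False)
    if not mask.any():
        return None
    return float(c.lengths[mask].min())


def normalize_efficiency(
    raw: np.ndarray, c: Connectome, kind: str, weighted: bool = True
) -> np.ndarray:
    """Normalize raw nodal efficiencies by the ideal fully connected network.

    The ideal network keeps the same nodes, connects every pair directly with
    weight 1 (the post-rescaling maximum) and length ``l_min``, the minimum
    observed edge length of this subject.  Its nodal global efficiency is
    ``1/l_min`` everywhere; its weighted nodal local term is
    ``(1/l_min)^(1/3)``.  Raw efficiencies never exceed the ideal, so the
    result lies in [0, 1].  An edgeless graph normalizes to all zeros.
    """
    if kind not in ("global", "local"):
        raise ValueError(f"kind must be 'global' or 'local', got {kind!r}")
    raw = np.asarray(raw, dtype=float)
    l_min = _min_edge_length(c)
    if l_min is None:
        return np.zeros_like(raw)
    if kind == "global":
        ideal = 1.0 / l_min
    else:
        ideal = (1.0 / l_min) ** (1.0 / 3.0) if weighted else 1.0 / l_min
    return raw / ideal


def compute_nodal_efficiencies(
    c: Connectome, weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (nodal_local, nodal_global) efficiency vectors for one subject.

    Rescales weights to max 1, computes raw nodal efficiencies, and
    normalizes each by the ideal fully connected network.
    """
    cr = c.rescaled()
    raw_glob = nodal_global_efficiency(cr, weighted)
    raw_loc = nodal_local_efficiency(cr, weighted)
    return (
        normalize_efficiency(raw_loc, cr, "local", weighted),
        normalize_efficiency(raw_glob, cr, "global", weighted),
    )


def compute_cohort_efficiency(
    atlas: RegionAtlas,
    subjects: list[SubjectRecord],
    connectomes: list[Connectome],
    weighted: bool = True,
) -> EfficiencyTable:
    """Normalized nodal efficiencies for a whole cohort, in atlas order."""
    if len(subjects) != len(connectomes):
        raise ValueError(
            f"{len(subjects)} subjects but {len(connectomes)} connectomes"
        )
    n_sub = len(subjects)
    loc = np.zeros((n_sub, atlas.n))
    glob = np.zeros((n_sub, atlas.n))
    for s, c in enumerate(connectomes):
        if c.n != atlas.n:
            raise ValueError(
                f"subject {subjects[s].subject_id!r}: connectome has {c.n} nodes "
                f"but atlas has {atlas.n} regions"
            )
        loc[s], glob[s] = compute_nodal_efficiencies(c, weighted)
    return EfficiencyTable(
        subject_ids=[s.subject_id for s in subjects],
        region_ids=atlas.region_ids,
        nodal_local=loc,
        nodal_global=glob,
        weighted=weighted,
        region_names=list(atlas.names),
    )
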