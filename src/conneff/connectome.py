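"""Building a clean, symmetric, size-normalized connectome.

A connectome pairs two N x N matrices over the atlas regions: a strength
matrix ``W`` (tract counts divided by the mean size of the two regions an
edge joins, dimensionless) and a mean fiber-length matrix ``L`` (mm).  An
edge exists iff its strength is positive; lengths are meaningful only on
existing edges.  Tractography counts seeded from both ends of a pathway can
come back asymmetric, so raw count matrices are symmetrized (arithmetic mean
of the two directions) before size normalization, and lengths are combined
by a count-weighted mean so that the better-sampled direction dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: absolute tolerance for symmetry checks
SYM_ATOL = 1e-10


@dataclass(frozen=True)
class Connectome:
    """Paired strength and mean fiber-length matrices for one subject.

    Invariants (checked by :func:`validate_connectome`): both matrices are
    symmetric, ``weights`` has a zero diagonal and no negative entries, and
    every existing edge (``w > 0``) carries a positive length.
    """

    weights: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        l = np.asarray(self.lengths, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if l.shape != w.shape:
            raise ValueError(
                f"lengths shape {l.shape} does not match weights shape {w.shape}"
            )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lengths", l)

    @property
    def n(self) -> int:
        """Number of nodes."""
        return int(self.weights.shape[0])

    def rescaled(self) -> "Connectome":
        """Return a copy with weights divided by the maximum weight.

        After rescaling the strongest connection has weight 1, which removes
        the arbitrary overall scale of tract counts and bounds the cube-root
        term of weighted local efficiency.  Idempotent; an empty graph is
        returned unchanged.
        """
        wmax = float(self.weights.max(initial=0.0))
        if wmax <= 0 or wmax == 1.0:
            return self
        return Connectome(self.weights / wmax, self.lengths)


def compile_strength(counts: np.ndarray, region_sizes: np.ndarray) -> np.ndarray:
    """Convert tract counts into the size-normalized strength index.

    ``strength[i, j] = counts[i, j] / ((size_i + size_j) / 2)`` — the total
    number of reconstructed tracts between two regions divided by the mean
    surface extent of the two regions, so that large regions are not favored
    simply for presenting more seed surface.  The diagonal is forced to zero
    (self-connections carry no information for path-based efficiency).
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(region_sizes, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"counts must be square, got shape {counts.shape}")
    if sizes.shape != (counts.shape[0],):
        raise ValueError(
            f"region_sizes must have length {counts.shape[0]}, got {sizes.shape}"
        )
    bad = np.flatnonzero(sizes <= 0)
    if bad.size:
        raise ValueError(f"non-positive region sizes at indices {bad.tolist()}")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    mean_sizes = (sizes[:, None] + sizes[None, :]) / 2.0
    strength = counts / mean_sizes
    np.fill_diagonal(strength, 0.0)
    return strength


def symmetrize(matrix: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Symmetrize a square matrix; ``mean`` averages the two directions."""
    if mode != "mean":
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    return (m + m.T) / 2.0


def symmetrize_lengths(lengths: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Combine directed mean fiber lengths by a count-weighted mean.

    Where both directions were sampled the result is the count-weighted mean
    of the two directed mean lengths; where only one direction has counts,
    that direction's length is used unchanged; where neither has counts the
    entry is zero (no edge).
    """
    l = np.asarray(lengths, dtype=float)
    c = np.asarray(counts, dtype=float)
    if l.shape != c.shape or l.ndim != 2 or l.shape[0] != l.shape[1]:
        raise ValueError("lengths and counts must be square matrices of equal shape")
    num = c * l + (c * l).T
    den = c + c.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def build_connectome(
    counts: np.ndarray, lengths: np.ndarray, region_sizes: np.ndarray
) -> Connectome:
    """Assemble a validated :class:`Connectome` from raw directed matrices.

    Counts are mean-symmetrized, lengths are count-weighted-symmetrized,
    counts are converted to the size-normalized strength index, and lengths
    are dropped wherever the resulting strength is zero.
    """
    counts_sym = symmetrize(counts)
    lengths_sym = symmetrize_lengths(lengths, counts)
    weights = compile_strength(counts_sym, region_sizes)
    lengths_out = np.where(weights > 0, lengths_sym, 0.0)
    np.fill_diagonal(lengths_out, 0.0)
    c = Connectome(weights, lengths_out)
    report = validate_connectome(c)
    if report:
        raise ValueError("built connectome is invalid: " + "; ".join(report))
    return c


def validate_connectome(c: Connectome) -> list[str]:
    """Return a list of invariant violations (empty list == valid).

    Checks: symmetry of both matrices (to ``SYM_ATOL``), nonnegative
    weights, zero diagonal (no self-loops), nonnegative lengths, and a
    positive length on every existing edge.
    """
    report: list[str] = []
    w, l = c.weights, c.lengths
    if not np.allclose(w, w.T, atol=SYM_ATOL, rtol=0):
        report.append(f"weights asymmetric beyond {SYM_ATOL}")
    if not np.allclose(l, l.T, atol=SYM_ATOL, rtol=0):
        report.append(f"lengths asymmetric beyond {SYM_ATOL}")
    if (w < 0).any():
        i, j = np.nonzero(w < 0)
        report.append(f"negative weights at pairs {list(zip(i.tolist(), j.tolist()))[:5]}")
    diag = np.flatnonzero(np.diag(w) != 0)
    if diag.size:
        report.append(f"self-loop (nonzero diagonal) at nodes {diag.tolist()[:5]}")
    if (l < 0).any():
        report.append("negative lengths")
    missing = (w > 0) & (l <= 0)
    if missing.any():
        i, j = np.nonzero(missing)
        pairs = list(zip(i.tolist(), j.tolist()))[:5]
        report.append(f"missing length on existing edges, e.g. pairs {pairs}")
    return report
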