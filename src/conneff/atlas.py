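"""Cortical parcellation atlas: region labels, sizes and (optional) centroids.

The atlas defines the node set of every connectome in an analysis.  The
default parcellation has 78 cortical regions (39 per hemisphere), mirroring
the cortical subset of the AAL anatomical atlas commonly used to compile
tractography connectivity matrices.  Region ``size`` is the surface extent of
the region at the white-matter/cortex boundary (in boundary-voxel counts);
it is the denominator of the connection-strength index, which divides raw
tract counts by the mean size of the two regions an edge joins.

Centroids (in mm) are only required by the synthetic cohort generator, which
uses them to embed the network in space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered set of cortical regions serving as network nodes.

    Regions are kept in ascending ``region_id`` order everywhere: all on-disk
    matrices and statistic maps use this order, so there is never a join
    ambiguity between files.

    Parameters
    ----------
    region_ids
        Unique integer labels, one per region.
    names
        Human-readable region names (e.g. ``"L07"``).
    hemispheres
        ``"left"`` or ``"right"`` per region.
    sizes
        Positive surface extents (boundary-voxel counts, dimensionless).
    centroids
        Optional ``(n, 3)`` array of region centroids in mm; used only for
        spatial embedding by the synthetic generator.
    """

    region_ids: np.ndarray
    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    sizes: np.ndarray
    centroids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        ids = np.asarray(self.region_ids, dtype=int)
        sizes = np.asarray(self.sizes, dtype=float)
        object.__setattr__(self, "region_ids", ids)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "names", tuple(str(x) for x in self.names))
        object.__setattr__(
            self, "hemispheres", tuple(str(x) for x in self.hemispheres)
        )
        n = ids.size
        if len(self.names) != n or len(self.hemispheres) != n or sizes.size != n:
            raise ValueError(
                "atlas fields have inconsistent lengths: "
                f"{n} ids, {len(self.names)} names, "
                f"{len(self.hemispheres)} hemispheres, {sizes.size} sizes"
            )
        uniq, counts = np.unique(ids, return_counts=True)
        if uniq.size != n:
            dup = uniq[counts > 1]
            raise ValueError(f"region ids are not unique (duplicates: {dup.tolist()})")
        if not np.all(np.diff(ids) > 0):
            raise ValueError("regions must be sorted by ascending region_id")
        bad = np.flatnonzero(sizes <= 0)
        if bad.size:
            raise ValueError(
                f"region sizes must be positive; offending region_ids: {ids[bad].tolist()}"
            )
        unknown = {h for h in self.hemispheres} - set(HEMISPHERES)
        if unknown:
            raise ValueError(f"unknown hemisphere labels: {sorted(unknown)}")
        if self.centroids is not None:
            cent = np.asarray(self.centroids, dtype=float)
            if cent.shape != (n, 3):
                raise ValueError(
                    f"centroids must have shape ({n}, 3), got {cent.shape}"
                )
            object.__setattr__(self, "centroids", cent)

    @property
    def n(self) -> int:
        """Number of regions (network nodes)."""
        return int(self.region_ids.size)
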