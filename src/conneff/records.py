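"""Per-subject covariate records and the per-cohort efficiency table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("ASD", "control")


@dataclass(frozen=True)
class SubjectRecord:
    """Covariates for one study participant.

    ``icv`` (intra-cranial volume, mm^3) indexes the maximum brain size
    attained during development; ``tbv`` (total brain volume, mm^3) is the
    subject's adult brain tissue volume.  The two are analyzed jointly: ICV
    carries the developmental-peak signal while TBV absorbs adult size.
    """

    subject_id: str
    group: str
    age: float
    icv: float
    tbv: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}"
            )
        if not self.age > 0:
            raise ValueError(f"subject {self.subject_id!r}: age must be positive")
        if not (self.icv > self.tbv > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: requires icv > tbv > 0 "
                f"(got icv={self.icv}, tbv={self.tbv})"
            )


@dataclass
class EfficiencyTable:
    """Normalized nodal efficiencies for every subject and region.

    ``nodal_local`` and ``nodal_global`` are ``(n_subjects, n_regions)``
    arrays of efficiencies normalized by the ideal (fully connected) network,
    hence in [0, 1].  ``weighted`` records whether weighted physical
    distances (edge length / edge weight) or plain physical distances were
    used.
    """

    subject_ids: list[str]
    region_ids: np.ndarray
    nodal_local: np.ndarray
    nodal_global: np.ndarray
    weighted: bool = True
    region_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        self.nodal_local = np.asarray(self.nodal_local, dtype=float)
        self.nodal_global = np.asarray(self.nodal_global, dtype=float)
        shape = (len(self.subject_ids), self.region_ids.size)
        for name in ("nodal_local", "nodal_global"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if self.region_names is not None and len(self.region_names) != self.region_ids.size:
            raise ValueError("region_names length does not match region_ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    def measure(self, which: str) -> np.ndarray:
        """Return the ``(n_subjects, n_regions)`` matrix for one measure."""
        if which == "local":
            return self.nodal_local
        if which == "global":
            return self.nodal_global
        raise ValueError(f"measure must be 'local' or 'global', got {which!r}")
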