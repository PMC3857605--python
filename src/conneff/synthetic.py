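"""Synthetic cohorts of spatially embedded connectomes with known effects.

No imaging data ship with this package, so validation runs on simulated
cohorts that embody the scientific premises of the analysis: connection
weight falls off with fiber length (distance-dependent wiring cost), larger
brains (indexed by intra-cranial volume, ICV) have proportionally longer
fibers and selectively weakened long-range connections, and an ASD group can
carry an additional long-range weight deficit independent of ICV.  Every
effect parameter is recorded in a ground-truth sidecar so downstream
statistics can be checked against what was actually simulated.

The generative model, per subject:

* region centroids sit on two mirror-symmetric hemispheric shells (an
  ellipsoid with brain-like semi-axes), fixed across subjects;
* fiber length  l_ij = tortuosity * Euclid(i, j) * (ICV / icv_mean)^(1/3)
  + Gaussian noise, floored at a positive minimum — linear dimensions scale
  as the cube root of volume;
* expected log tract count falls linearly with length at scale
  ``wiring_decay`` (mm); counts are drawn log-normal around that mean and
  rounded to integers, as a tract counter would report;
* edges whose Euclidean distance exceeds the ``longrange_percentile`` of all
  pairwise distances are "long-range"; their log counts are further shifted
  by ``icv_longrange_slope * (ICV - icv_mean)`` and, for ASD subjects, by
  ``log(1 - group_weight_deficit)``.

Counts and lengths then pass through the same symmetrize/size-normalize
build as real tractography matrices.  A master seed drives per-subject
substreams, so any single subject is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .atlas import RegionAtlas
from .connectome import Connectome, build_connectome
from .records import SubjectRecord

#: brain-like ellipsoid semi-axes in mm (lateral, anterior-posterior, inferior-superior)
_SHELL_AXES = np.array([65.0, 85.0, 60.0])
#: minimal lateral offset (as a fraction of the unit direction) keeping the
#: two hemispheres separated
_LATERAL_MARGIN = 0.08
#: minimum distance between region centroids within a hemisphere (mm);
#: parcellation units are sizeable patches of cortex, never coincident points
_MIN_SEPARATION = 18.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Defaults describe a 44-subject adult-male cohort (22 ASD, 22 controls)
    on a 78-region cortical parcellation with a modest ASD head-size
    surplus, an inverse ICV effect on long-range connection weight, and an
    ICV-independent ASD long-range weight deficit.
    """

    n_per_group: int = 22
    n_regions: int = 78
    icv_mean: float = 1.55e6  # mm^3, adult male average
    icv_sd: float = 1.2e5  # mm^3
    icv_group_shift: float = 5.0e4  # mm^3 added to ASD ICV (early overgrowth)
    wiring_decay: float = 35.0  # mm, exponential length penalty on log-weight
    tortuosity: float = 1.3  # fiber length / Euclidean distance
    length_noise_sd: float = 0.3  # mm, uncertainty of a mean over many streamlines
    weight_noise_cv: float = 0.1  # coefficient of variation of compiled counts
    icv_longrange_slope: float = -2.0e-6  # per mm^3, on long-range log-weights
    group_weight_deficit: float = 0.2  # proportional ASD long-range reduction
    longrange_percentile: float = 75.0  # Euclidean-distance percentile threshold
    icv_length_exponent: float = 1.0 / 3.0  # volume -> linear dimension
    base_count: float = 2000.0  # expected tract count at zero length
    tbv_ratio: float = 0.85  # TBV as a fraction of ICV
    tbv_noise_sd: float = 2.5e4  # mm^3
    age_range: tuple[float, float] = (19.0, 51.0)  # years
    min_length: float = 1.0  # mm, floor for noisy lengths
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.n_regions < 4 or self.n_regions % 2:
            raise ValueError("n_regions must be even and at least 4")
        for name in (
            "icv_mean",
            "icv_sd",
            "wiring_decay",
            "base_count",
            "tbv_ratio",
            "min_length",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.tortuosity < 1:
            raise ValueError("tortuosity must be >= 1")
        if not 0 <= self.group_weight_deficit < 1:
            raise ValueError("group_weight_deficit must be in [0, 1)")
        if self.length_noise_sd < 0 or self.weight_noise_cv < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0 < self.longrange_percentile < 100:
            raise ValueError("longrange_percentile must be in (0, 100)")
        if not 0 < self.tbv_ratio < 1:
            raise ValueError("tbv_ratio must be in (0, 1)")

    def null(self) -> "GeneratorConfig":
        """A copy with every ICV and group effect switched off.

        Used for false-discovery calibration: connectomes become
        statistically independent of every covariate.
        """
        return dataclasses.replace(
            self,
            icv_group_shift=0.0,
            icv_longrange_slope=0.0,
            group_weight_deficit=0.0,
            icv_length_exponent=0.0,
        )


@dataclass
class Cohort:
    """One generated cohort plus the ground truth that produced it."""

    atlas: RegionAtlas
    subjects: list[SubjectRecord]
    connectomes: list[Connectome]
    ground_truth: dict[str, Any] = field(default_factory=dict)


def _sample_shell_points(rng: np.random.Generator, count: int) -> np.ndarray:
    """Seeded left-hemisphere shell positions with a minimum separation.

    Draws directions uniformly, pushes them left of the midline with a
    lateral margin, and rejects candidates closer than ``_MIN_SEPARATION``
    to an accepted point.  If the shell cannot host ``count`` points at the
    current separation the requirement is relaxed by 5% and sampling
    restarts, so the procedure always terminates (deterministically for a
    given generator state).
    """
    separation = _MIN_SEPARATION
    while True:
        points: list[np.ndarray] = []
        attempts = 0
        while len(points) < count and attempts < 200 * count:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            u[0] = -(abs(u[0]) + _LATERAL_MARGIN)
            u /= np.linalg.norm(u)
            candidate = u * _SHELL_AXES
            attempts += 1
            if all(np.linalg.norm(candidate - p) >= separation for p in points):
                points.append(candidate)
        if len(points) == count:
            return np.array(points)
        separation *= 0.95


def generate_atlas_geometry(
    config: GeneratorConfig, seed: int | np.random.SeedSequence
) -> RegionAtlas:
    """Place regions on two mirror-symmetric hemispheric shells.

    Half the regions get seeded positions on a left-hemisphere ellipsoidal
    shell; the right hemisphere mirrors them through the midsagittal plane.
    Sizes are log-normal and mirrored, so homologous regions match.
    """
    n = config.n_regions
    if n < 4 or n % 2:
        raise ValueError("n_regions must be even and at least 4")
    rng = np.random.default_rng(seed)
    half = n // 2
    left = _sample_shell_points(rng, half)
    right = left * np.array([-1.0, 1.0, 1.0])
    sizes_half = rng.lognormal(mean=np.log(1000.0), sigma=0.4, size=half)
    width = len(str(half))
    return RegionAtlas(
        region_ids=np.arange(1, n + 1),
        names=tuple(
            [f"L{i + 1:0{width}d}" for i in range(half)]
            + [f"R{i + 1:0{width}d}" for i in range(half)]
        ),
        hemispheres=tuple(["left"] * half + ["right"] * half),
        sizes=np.concatenate([sizes_half, sizes_half]),
        centroids=np.vstack([left, right]),
    )


def generate_subject_connectome(
    atlas: RegionAtlas,
    subject: SubjectRecord,
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence,
) -> Connectome:
    """Simulate one subject's tract-count/length matrices and build them.

    See the module docstring for the generative model.  The output always
    satisfies the connectome invariants (symmetric, zero diagonal, positive
    lengths on existing edges).
    """
    if atlas.centroids is None:
        raise ValueError("atlas has no centroids; generate one with geometry")
    rng = np.random.default_rng(seed)
    n = atlas.n
    euclid = squareform(pdist(atlas.centroids))
    iu = np.triu_indices(n, k=1)
    scale = (subject.icv / config.icv_mean) ** config.icv_length_exponent
    lengths_u = config.tortuosity * euclid[iu] * scale
    if config.length_noise_sd > 0:
        lengths_u = lengths_u + rng.normal(0.0, config.length_noise_sd, lengths_u.size)
    lengths_u = np.maximum(lengths_u, config.min_length)

    threshold = np.percentile(euclid[iu], config.longrange_percentile)
    longrange = euclid[iu] > threshold
    mu = np.log(config.base_count) - lengths_u / config.wiring_decay
    shift = config.icv_longrange_slope * (subject.icv - config.icv_mean)
    if subject.group == "ASD":
        shift += np.log1p(-config.group_weight_deficit)
    mu = mu + longrange * shift
    if config.weight_noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.weight_noise_cv**2))
        log_counts = mu + rng.normal(0.0, sigma, mu.size)
    else:
        log_counts = mu
    counts_u = np.round(np.exp(log_counts))

    counts = np.zeros((n, n))
    counts[iu] = counts_u
    counts += counts.T
    lengths = np.zeros((n, n))
    lengths[iu] = lengths_u
    lengths += lengths.T
    lengths = np.where(counts > 0, lengths, 0.0)
    return build_connectome(counts, lengths, atlas.sizes)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate atlas, subjects and connectomes for one full cohort.

    ICV is Normal(icv_mean [+ icv_group_shift for ASD], icv_sd), age is
    uniform over ``age_range``, and TBV is ``tbv_ratio * ICV`` plus noise,
    clipped so that ICV > TBV > 0 always holds.  Randomness flows from the
    master seed through spawned per-subject substreams (atlas first, then
    covariates, then one stream per subject in id order).
    """
    master = np.random.SeedSequence(config.seed)
    n_subjects = 2 * config.n_per_group
    streams = master.spawn(2 + n_subjects)
    atlas = generate_atlas_geometry(config, streams[0])
    rng = np.random.default_rng(streams[1])

    width = len(str(config.n_per_group))
    subjects: list[SubjectRecord] = []
    for k in range(n_subjects):
        is_asd = k >= config.n_per_group
        sid = (
            f"asd{k - config.n_per_group + 1:0{width}d}"
            if is_asd
            else f"ctl{k + 1:0{width}d}"
        )
        icv_mu = config.icv_mean + (config.icv_group_shift if is_asd else 0.0)
        icv = float(rng.normal(icv_mu, config.icv_sd))
        icv = max(icv, 0.25 * config.icv_mean)
        age = float(rng.uniform(*config.age_range))
        tbv = float(config.tbv_ratio * icv + rng.normal(0.0, config.tbv_noise_sd))
        tbv = float(np.clip(tbv, 0.05 * icv, 0.97 * icv))
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group="ASD" if is_asd else "control",
                age=age,
                icv=icv,
                tbv=tbv,
            )
        )

    connectomes = [
        generate_subject_connectome(atlas, s, config, streams[2 + k])
        for k, s in enumerate(subjects)
    ]
    ground_truth = {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "n_regions": config.n_regions,
        "icv_group_shift": config.icv_group_shift,
        "icv_longrange_slope": config.icv_longrange_slope,
        "group_weight_deficit": config.group_weight_deficit,
        "icv_length_exponent": config.icv_length_exponent,
        "longrange_percentile": config.longrange_percentile,
        "wiring_decay": config.wiring_decay,
    }
    return Cohort(atlas=atlas, subjects=subjects, connectomes=connectomes, ground_truth=ground_truth)
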