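"""End-to-end orchestration: cohort -> efficiencies -> maps -> similarity.

A run loads or generates a cohort, computes normalized nodal local and
global efficiency for every subject, fits the three regional contrasts
(``icv``, ``group``, ``icv_x_group``) for each efficiency measure with FDR
correction across regions, writes one CSV map per measure/contrast plus a
t-map cosine-similarity report, and records everything in a deterministic
JSON manifest.  Identical configuration and seed yield byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .efficiency import compute_cohort_efficiency
from .io import (
    read_atlas,
    read_connectome_pair,
    read_subject_table,
    write_atlas,
    write_connectome_pair,
    write_efficiency_table,
    write_region_stats,
    write_subject_table,
)
from .records import EfficiencyTable, SubjectRecord
from .stats import CONTRASTS, cosine_similarity, fit_region_models
from .synthetic import Cohort, GeneratorConfig, generate_cohort

logger = logging.getLogger("conneff")

MEASURES = ("local", "global")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``mode`` is ``"synthetic"`` (generate a cohort from ``generator``) or
    ``"real-data"`` (read the files named in ``paths``: keys ``atlas``,
    ``subjects``, and ``matrix_dir`` containing
    ``<subject_id>_strength.tsv`` / ``<subject_id>_length.tsv`` pairs).
    """

    mode: str = "synthetic"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    paths: dict[str, str] | None = None
    weighted: bool = True
    q_level: float = 0.05
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real-data"):
            raise ValueError(f"mode must be 'synthetic' or 'real-data', got {self.mode!r}")
        if not 0 < self.q_level < 1:
            raise ValueError(f"q_level must be in (0, 1), got {self.q_level}")
        if self.mode == "real-data":
            needed = {"atlas", "subjects", "matrix_dir"}
            have = set(self.paths or {})
            if not needed <= have:
                raise ValueError(f"real-data mode requires paths {sorted(needed - have)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**data.pop("generator", {}))
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(generator=gen, **data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["generator"]["age_range"] = list(d["generator"]["age_range"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_real_cohort(paths: dict[str, str]) -> Cohort:
    atlas = read_atlas(paths["atlas"])
    subjects = read_subject_table(paths["subjects"])
    matrix_dir = Path(paths["matrix_dir"])
    connectomes = []
    for s in subjects:
        strength = matrix_dir / f"{s.subject_id}_strength.tsv"
        length = matrix_dir / f"{s.subject_id}_length.tsv"
        if not strength.exists() or not length.exists():
            raise FileNotFoundError(
                f"stage load-cohort: missing matrix pair for subject {s.subject_id!r}"
            )
        connectomes.append(read_connectome_pair(strength, length, atlas))
    return Cohort(atlas=atlas, subjects=subjects, connectomes=connectomes)


def fit_all_maps(
    eff: EfficiencyTable,
    subjects: list[SubjectRecord],
    q_level: float = 0.05,
) -> dict[str, dict[str, list]]:
    """Fit every (measure, contrast) map; returns maps[measure][contrast]."""
    return {
        measure: {
            contrast: fit_region_models(eff, subjects, contrast, measure, q_level)
            for contrast in CONTRASTS
        }
        for measure in MEASURES
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and return the run manifest.

    Outputs in ``config.output_dir``: the subject table, atlas, efficiency
    table, six regional maps (two measures x three contrasts), a similarity
    report ``similarity.csv`` and ``manifest.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage load-cohort: mode=%s", config.mode)
    if config.mode == "synthetic":
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen)
    else:
        cohort = _load_real_cohort(config.paths or {})
    atlas, subjects = cohort.atlas, cohort.subjects
    logger.info(
        "stage load-cohort: %d subjects, %d regions", len(subjects), atlas.n
    )

    logger.info("stage efficiency: weighted=%s", config.weighted)
    eff = compute_cohort_efficiency(
        atlas, subjects, cohort.connectomes, weighted=config.weighted
    )

    logger.info("stage fit: contrasts=%s", ",".join(CONTRASTS))
    maps = fit_all_maps(eff, subjects, config.q_level)

    files: dict[str, str] = {}
    write_subject_table(subjects, out / "subjects.csv")
    files["subjects"] = "subjects.csv"
    write_atlas(atlas, out / "atlas.csv")
    files["atlas"] = "atlas.csv"
    write_efficiency_table(eff, out / "efficiency.csv")
    files["efficiency"] = "efficiency.csv"
    if config.mode == "synthetic":
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(cohort.ground_truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        files["ground_truth"] = "ground_truth.json"

    summary: dict[str, Any] = {"maps": {}, "cosine_icv_group": {}}
    for measure in MEASURES:
        for contrast in CONTRASTS:
            results = maps[measure][contrast]
            fname = f"stats_{measure}_{contrast}.csv"
            write_region_stats(results, out / fname)
            files[f"stats_{measure}_{contrast}"] = fname
            summary["maps"][f"{measure}/{contrast}"] = {
                "n_regions": len(results),
                "n_significant_negative": sum(
                    1 for r in results if r.significant and r.t < 0
                ),
                "n_significant_positive": sum(
                    1 for r in results if r.significant and r.t > 0
                ),
            }
        t_icv = np.array([r.t for r in maps[measure]["icv"]])
        t_group = np.array([r.t for r in maps[measure]["group"]])
        summary["cosine_icv_group"][measure] = cosine_similarity(t_icv, t_group)

    with open(out / "similarity.csv", "w") as fh:
        fh.write("measure,contrast_a,contrast_b,cosine\n")
        for measure in MEASURES:
            fh.write(
                f"{measure},icv,group,%.12g\n" % summary["cosine_icv_group"][measure]
            )
    files["similarity"] = "similarity.csv"

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_subjects": len(subjects),
        "n_regions": atlas.n,
        "files": files,
        "hashes": {k: _sha256(out / v) for k, v in files.items()},
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage write: %d files in %s", len(files) + 1, out)
    return manifest


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort to disk in the real-data layout (for `generate`)."""
    out = Path(out_dir)
    matrix_dir = out / "matrices"
    matrix_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.csv")
    write_subject_table(cohort.subjects, out / "subjects.csv")
    for s, c in zip(cohort.subjects, cohort.connectomes):
        write_connectome_pair(
            c,
            cohort.atlas,
            matrix_dir / f"{s.subject_id}_strength.tsv",
            matrix_dir / f"{s.subject_id}_length.tsv",
        )
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def summarize_run(manifest: dict[str, Any]) -> str:
    """Human-readable per-contrast counts of significant regions and cosines."""
    for key in ("summary", "n_subjects", "n_regions", "seed"):
        if key not in manifest:
            raise ValueError(f"incomplete manifest: missing {key!r}")
    summary = manifest["summary"]
    lines = [
        f"conneff run (seed {manifest['seed']}): "
        f"{manifest['n_subjects']} subjects, {manifest['n_regions']} regions",
    ]
    for key in sorted(summary["maps"]):
        m = summary["maps"][key]
        lines.append(
            f"  {key}: {m['n_significant_negative']}/{m['n_regions']} significant negative, "
            f"{m['n_significant_positive']}/{m['n_regions']} significant positive"
        )
    for measure in sorted(summary["cosine_icv_group"]):
        lines.append(
            f"  cosine(t_icv, t_group) [{measure}]: "
            f"{summary['cosine_icv_group'][measure]:.4f}"
        )
    return "\n".join(lines)


def calibrate(
    generator: GeneratorConfig,
    n_replicates: int,
    seed: int = 0,
    q_level: float = 0.05,
    weighted: bool = True,
) -> dict[str, Any]:
    """Monte-Carlo calibration of the region-wise testing procedure.

    Repeats the full cohort -> efficiency -> fit chain ``n_replicates``
    times with independent seeds under the supplied generator, and records
    per map family: the realized false discovery proportion (meaningful when
    ``generator`` is a null configuration, where every discovery is false),
    and the fraction of replicates in which the ICV x group interaction map
    has no FDR-significant region.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates) % (2**31)
    fdp: dict[str, list[float]] = {
        f"{m}/{c}": [] for m in MEASURES for c in CONTRASTS
    }
    interaction_clean = {m: 0 for m in MEASURES}
    for rep, rep_seed in enumerate(rep_seeds):
        gen = dataclasses.replace(generator, seed=int(rep_seed))
        cohort = generate_cohort(gen)
        eff = compute_cohort_efficiency(
            cohort.atlas, cohort.subjects, cohort.connectomes, weighted=weighted
        )
        maps = fit_all_maps(eff, cohort.subjects, q_level)
        for m in MEASURES:
            for c in CONTRASTS:
                n_sig = sum(1 for r in maps[m][c] if r.significant)
                fdp[f"{m}/{c}"].append(1.0 if n_sig > 0 else 0.0)
            if not any(r.significant for r in maps[m]["icv_x_group"]):
                interaction_clean[m] += 1
        if (rep + 1) % 25 == 0:
            logger.info("stage calibrate: %d/%d replicates", rep + 1, n_replicates)
    out: dict[str, Any] = {
        "n_replicates": n_replicates,
        "q_level": q_level,
        "fdp_mean": {k: float(np.mean(v)) for k, v in fdp.items()},
        "fdp_se": {
            k: float(np.std(v, ddof=1) / np.sqrt(len(v))) for k, v in fdp.items()
        },
        "interaction_nonsignificant_frac": {
            m: interaction_clean[m] / n_replicates for m in MEASURES
        },
    }
    return out
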