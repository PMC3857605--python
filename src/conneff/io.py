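"""Reading and writing every tabular artifact of the pipeline.

Conventions (fixed so files diff cleanly and round-trip exactly):

* connectome matrices — TSV, one header row of region ids, N numeric columns;
  strengths dimensionless, lengths in mm;
* region atlas — CSV ``region_id,name,hemisphere,size,cx,cy,cz``
  (centroid columns may be empty);
* subject covariates — CSV ``subject_id,group,age,icv,tbv``;
* regional statistic maps — CSV
  ``region_id,name,beta,t,p,q,significant``;
* efficiency tables — CSV ``subject_id,region_id,nodal_local,nodal_global``.

All numeric output uses 12 significant digits, so write → read reproduces
values to better than 1e-10 relative error.  Region order in every file is
atlas order (ascending region_id); reading validates and never reorders.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .connectome import Connectome, validate_connectome
from .records import EfficiencyTable, SubjectRecord
from .stats import RegionStatResult

FLOAT_FMT = "%.12g"

_GROUP_ALIASES = {"asd": "ASD", "control": "control", "ctl": "control", "ctrl": "control"}


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# connectome matrix pairs (TSV)


def write_matrix(matrix: np.ndarray, path: str | Path, region_ids: np.ndarray) -> None:
    """Write an N x N matrix as TSV with a header row of region ids."""
    m = np.asarray(matrix, dtype=float)
    ids = np.asarray(region_ids, dtype=int)
    if m.shape != (ids.size, ids.size):
        raise ValueError(f"matrix shape {m.shape} does not match {ids.size} region ids")
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(str(i) for i in ids) + "\n")
        for row in m:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TSV matrix; returns (region_ids, matrix)."""
    df = pd.read_csv(path, sep="\t", header=0)
    try:
        ids = np.array([int(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: header must contain integer region ids") from exc
    return ids, np.ascontiguousarray(df.to_numpy(dtype=float))


def read_connectome_pair(
    strength_path: str | Path, length_path: str | Path, atlas: RegionAtlas
) -> Connectome:
    """Read a strength/length TSV pair and validate it against the atlas.

    Lengths are retained only where strength is positive.  Raises on
    dimension mismatch with the atlas, header/atlas id mismatch, negative
    entries, or any connectome-invariant violation.
    """
    ids_s, strength = read_matrix(strength_path)
    ids_l, length = read_matrix(length_path)
    for label, ids, mat in (
        ("strength", ids_s, strength),
        ("length", ids_l, length),
    ):
        if mat.shape != (atlas.n, atlas.n):
            raise ValueError(
                f"{label} matrix is {mat.shape[0]}x{mat.shape[1]} "
                f"but the atlas has {atlas.n} regions"
            )
        if not np.array_equal(ids, atlas.region_ids):
            offending = sorted(
                set(ids.tolist()).symmetric_difference(atlas.region_ids.tolist())
            )
            raise ValueError(
                f"{label} matrix header ids do not match the atlas; "
                f"offending ids: {offending[:10]}"
            )
        if (mat < 0).any():
            raise ValueError(f"{label} matrix contains negative entries")
    length = np.where(strength > 0, length, 0.0)
    c = Connectome(strength, length)
    report = validate_connectome(c)
    if report:
        raise ValueError(f"invalid connectome in {strength_path}: " + "; ".join(report))
    return c


def write_connectome_pair(
    c: Connectome,
    atlas: RegionAtlas,
    strength_path: str | Path,
    length_path: str | Path,
) -> None:
    """Write a connectome as a strength/length TSV pair in atlas order."""
    if c.n != atlas.n:
        raise ValueError(f"connectome has {c.n} nodes but atlas has {atlas.n} regions")
    write_matrix(c.weights, strength_path, atlas.region_ids)
    write_matrix(c.lengths, length_path, atlas.region_ids)


# ---------------------------------------------------------------------------
# region atlas (CSV)

_ATLAS_COLS = ["region_id", "name", "hemisphere", "size", "cx", "cy", "cz"]


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ATLAS_COLS)
        for i in range(atlas.n):
            cent = (
                [_fmt(v) for v in atlas.centroids[i]]
                if atlas.centroids is not None
                else ["", "", ""]
            )
            w.writerow(
                [
                    atlas.region_ids[i],
                    atlas.names[i],
                    atlas.hemispheres[i],
                    _fmt(atlas.sizes[i]),
                    *cent,
                ]
            )


def read_atlas(path: str | Path) -> RegionAtlas:
    df = pd.read_csv(path)
    missing = [c for c in _ATLAS_COLS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing atlas columns {missing}")
    centroids = None
    if {"cx", "cy", "cz"} <= set(df.columns) and not df[["cx", "cy", "cz"]].isna().any().any():
        centroids = df[["cx", "cy", "cz"]].to_numpy(dtype=float)
    return RegionAtlas(
        region_ids=df["region_id"].to_numpy(dtype=int),
        names=tuple(df["name"].astype(str)),
        hemispheres=tuple(df["hemisphere"].astype(str)),
        sizes=df["size"].to_numpy(dtype=float),
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# subject covariate table (CSV)

_SUBJECT_COLS = ["subject_id", "group", "age", "icv", "tbv"]


def write_subject_table(subjects: list[SubjectRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SUBJECT_COLS)
        for s in subjects:
            w.writerow([s.subject_id, s.group, _fmt(s.age), _fmt(s.icv), _fmt(s.tbv)])


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read a subject covariate CSV into validated records.

    Group labels are mapped case-insensitively onto {ASD, control}.  Raises
    naming the column on a missing column and naming the subject on invalid
    covariates (e.g. non-positive ICV).
    """
    df = pd.read_csv(path)
    missing = [c for c in _SUBJECT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        raw_group = str(row["group"]).strip().lower()
        if raw_group not in _GROUP_ALIASES:
            raise ValueError(
                f"subject {row['subject_id']!r}: unknown group label {row['group']!r}"
            )
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=_GROUP_ALIASES[raw_group],
                age=float(row["age"]),
                icv=float(row["icv"]),
                tbv=float(row["tbv"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# regional statistic maps (CSV)

_STATS_COLS = ["region_id", "name", "beta", "t", "p", "q", "significant"]


def write_region_stats(results: list[RegionStatResult], path: str | Path) -> None:
    """Write one contrast's regional map, one row per region in id order."""
    if not results:
        raise ValueError("no results to write")
    contrasts = {r.contrast for r in results}
    if len(contrasts) > 1:
        raise ValueError(
            f"results mix contrasts {sorted(contrasts)}; write one contrast per file"
        )
    ordered = sorted(results, key=lambda r: r.region_id)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_STATS_COLS)
        for r in ordered:
            w.writerow(
                [
                    r.region_id,
                    r.name,
                    _fmt(r.beta),
                    _fmt(r.t),
                    _fmt(r.p),
                    _fmt(r.q),
                    r.significant,
                ]
            )


def read_region_stats(path: str | Path, contrast: str) -> list[RegionStatResult]:
    df = pd.read_csv(path)
    missing = [c for c in _STATS_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        RegionStatResult(
            region_id=int(row["region_id"]),
            contrast=contrast,
            beta=float(row["beta"]),
            t=float(row["t"]),
            p=float(row["p"]),
            q=float(row["q"]),
            significant=bool(row["significant"]),
            name="" if pd.isna(row["name"]) else str(row["name"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# efficiency tables (CSV, long format)


def write_efficiency_table(eff: EfficiencyTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "region_id", "nodal_local", "nodal_global"])
        for s, sid in enumerate(eff.subject_ids):
            for r, rid in enumerate(eff.region_ids):
                w.writerow(
                    [sid, rid, _fmt(eff.nodal_local[s, r]), _fmt(eff.nodal_global[s, r])]
                )


def read_efficiency_table(path: str | Path, weighted: bool = True) -> EfficiencyTable:
    df = pd.read_csv(path)
    needed = ["subject_id", "region_id", "nodal_local", "nodal_global"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    subject_ids = list(dict.fromkeys(df["subject_id"].astype(str)))
    region_ids = np.array(sorted(df["region_id"].unique()), dtype=int)
    wide_l = df.pivot(index="subject_id", columns="region_id", values="nodal_local")
    wide_g = df.pivot(index="subject_id", columns="region_id", values="nodal_global")
    wide_l = wide_l.loc[subject_ids, region_ids]
    wide_g = wide_g.loc[subject_ids, region_ids]
    return EfficiencyTable(
        subject_ids=subject_ids,
        region_ids=region_ids,
        nodal_local=wide_l.to_numpy(dtype=float),
        nodal_global=wide_g.to_numpy(dtype=float),
        weighted=weighted,
    )
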