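"""Region-wise linear models, FDR correction, and t-map similarity.

Each cortical region's normalized efficiency is regressed on subject-level
covariates with ordinary least squares, one model per region (the standard
mass-univariate approach).  Three contrasts are supported:

* ``icv``          — efficiency ~ ICV + age + TBV; inference on the ICV slope.
* ``group``        — efficiency ~ group + age; group coded control = 0,
                     ASD = 1, so a negative t means lower efficiency in ASD.
* ``icv_x_group``  — efficiency ~ ICV + group + ICV:group + age + TBV;
                     inference on the interaction.

Two-sided p-values come from the t distribution with residual degrees of
freedom.  Multiplicity across the regions of one map is handled by the
Benjamini–Hochberg false-discovery-rate step-up, applied separately per
contrast and per efficiency measure; ``significant`` means q <= q_level.
Spatial agreement between two regional t-maps is measured by cosine
similarity of the t vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .records import EfficiencyTable, SubjectRecord

CONTRASTS = ("icv", "group", "icv_x_group")


@dataclass(frozen=True)
class RegionStatResult:
    """OLS inference for one region under one contrast."""

    region_id: int
    contrast: str
    beta: float
    t: float
    p: float
    q: float
    significant: bool
    name: str = ""


def _design(subjects: list[SubjectRecord], contrast: str):
    """Build the design matrix, its column names and the index of interest."""
    icv = np.array([s.icv for s in subjects], dtype=float)
    age = np.array([s.age for s in subjects], dtype=float)
    tbv = np.array([s.tbv for s in subjects], dtype=float)
    grp = np.array([1.0 if s.group == "ASD" else 0.0 for s in subjects])
    ones = np.ones_like(icv)
    if contrast == "icv":
        cols = [ones, icv, age, tbv]
        names = ["intercept", "icv", "age", "tbv"]
        idx = 1
    elif contrast == "group":
        cols = [ones, grp, age]
        names = ["intercept", "group", "age"]
        idx = 1
    elif contrast == "icv_x_group":
        cols = [ones, icv, grp, icv * grp, age, tbv]
        names = ["intercept", "icv", "group", "icv_x_group", "age", "tbv"]
        idx = 3
    else:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    return np.column_stack(cols), names, idx


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        collinear = [names[piv[k]] for k in range(len(names)) if diag[k] <= tol]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {collinear}"
        )


def fit_region_models(
    eff: EfficiencyTable,
    subjects: list[SubjectRecord],
    contrast: str,
    measure: str = "local",
    q_level: float = 0.05,
) -> list[RegionStatResult]:
    """Fit one OLS model per region and FDR-correct across regions.

    All regions share the same design matrix, so the fits are vectorized:
    one least-squares solve yields every region's coefficients, and per-region
    residual variances give the t-statistics on the contrast of interest.
    """
    y = eff.measure(measure)
    by_id = {s.subject_id: s for s in subjects}
    missing = [sid for sid in eff.subject_ids if sid not in by_id]
    if missing:
        raise ValueError(f"no covariates for subjects: {missing[:5]}")
    ordered = [by_id[sid] for sid in eff.subject_ids]
    x, names, idx = _design(ordered, contrast)
    n, p_cols = x.shape
    if n < p_cols + 2:
        raise ValueError(
            f"need at least {p_cols + 2} subjects for a {p_cols}-term model, got {n}"
        )
    _check_rank(x, names)

    beta_all, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_all
    df = n - p_cols
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[idx, idx])
    beta = beta_all[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    q, sig = fdr_adjust(p, q_level)

    region_names = eff.region_names or [""] * eff.n_regions
    return [
        RegionStatResult(
            region_id=int(rid),
            contrast=contrast,
            beta=float(beta[r]),
            t=float(t[r]),
            p=float(p[r]),
            q=float(q[r]),
            significant=bool(sig[r]),
            name=region_names[r],
        )
        for r, rid in enumerate(eff.region_ids)
    ]


def fdr_adjust(
    p_values: np.ndarray, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns the adjusted values (monotone, in [0, 1]) and the significance
    mask ``q <= q_level``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q_level < 1:
        raise ValueError(f"q_level must be in (0, 1), got {q_level}")
    _, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def cosine_similarity(t1: np.ndarray, t2: np.ndarray) -> float:
    """Cosine of the angle between two regional statistic vectors."""
    a = np.asarray(t1, dtype=float)
    b = np.asarray(t2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {a.shape} and {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))
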