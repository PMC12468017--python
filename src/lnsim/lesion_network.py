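"""Lesion-network (LN) template derivation.

Seeding each patient's lesion mask in every matched control's cleaned
resting-state run yields one Fisher-Z seed-connectivity map per
(patient lesion, control) pair.  The stack of maps is merged by
per-voxel ordinary least squares on mean-centred age and motion,
sum-to-zero-coded gender, site, and lesion (patient) factors; the model
intercept — the covariate-adjusted grand mean — is the group LN
template.  Residual maps are retained for spatial-smoothness estimation
and the intercept t/p maps support thresholded LN region extraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .grid import GridSpec
from .qc import CleanRun

__all__ = ["FCMap", "LNTemplate", "seed_fc_map", "build_fc_stack",
           "derive_ln_template", "threshold_ln", "MAX_ABS_R"]

log = logging.getLogger(__name__)

#: Correlations are clipped to +/- this value before the Fisher-Z transform
#: so that Z stays finite at |r| = 1.
MAX_ABS_R = 0.999
MAX_ABS_Z = float(np.arctanh(MAX_ABS_R))


@dataclass
class FCMap:
    """3D Fisher-Z seed-connectivity map with its provenance covariates."""

    values: np.ndarray  # 3D; NaN outside the brain mask
    mask: np.ndarray  # bool 3D
    grid: GridSpec
    provenance: dict = field(default_factory=dict)
    flagged_voxels: np.ndarray | None = None  # (n, 3) zero-variance voxels

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class LNTemplate:
    """Covariate-adjusted group lesion-network map (the voxel-wise intercept)."""

    intercept: np.ndarray  # 3D
    t_map: np.ndarray  # 3D, intercept != 0 test
    p_map: np.ndarray  # 3D
    residuals: np.ndarray  # (n_maps, V) for smoothness estimation
    mask: np.ndarray
    grid: GridSpec
    n_maps: int
    df_resid: int

    def in_mask(self) -> np.ndarray:
        return self.intercept[self.mask]


def _standardize_rows(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled so that dot products give Pearson r; returns (scaled, sd)."""
    y = y - y.mean(axis=1, keepdims=True)
    sd = np.sqrt((y ** 2).sum(axis=1))
    good = sd > 0
    y[good] /= sd[good, None]
    return y, sd


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -MAX_ABS_R, MAX_ABS_R))


def seed_fc_map(clean: CleanRun, lesion_mask: np.ndarray,
                provenance: dict | None = None) -> FCMap:
    """Correlate the mean lesion-mask signal with every brain voxel.

    Pearson r on the kept timepoints, clipped to ±0.999, Fisher-Z
    transformed.  Zero-variance seed or voxels yield Z = 0 and are
    flagged (and logged) rather than NaN.
    """
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    t = clean.data.shape[-1]
    if t < 10:
        raise ValueError(f"need >= 10 kept timepoints, got {t}")
    mask = clean.brain_mask
    seed = clean.data[lesion_mask].mean(axis=0)
    seed = seed - seed.mean()
    seed_sd = np.sqrt((seed ** 2).sum())

    y = clean.data[mask].astype(float)
    ys, sd = _standardize_rows(y)
    flagged_idx = np.flatnonzero(sd == 0)

    if seed_sd == 0:
        log.warning("%s visit %s: zero-variance lesion seed; map set to 0",
                    clean.subject_id, clean.visit)
        r = np.zeros(ys.shape[0])
        flagged_idx = np.arange(ys.shape[0])
    else:
        r = ys @ (seed / seed_sd)
        r[sd == 0] = 0.0
        if flagged_idx.size:
            log.warning("%s visit %s: %d zero-variance voxel(s) set to Z=0",
                        clean.subject_id, clean.visit, flagged_idx.size)

    values = np.full(clean.grid.shape, np.nan)
    values[mask] = fisher_z(r)
    coords = np.argwhere(mask)
    return FCMap(values=values, mask=mask, grid=clean.grid,
                 provenance=provenance or {},
                 flagged_voxels=coords[flagged_idx] if flagged_idx.size else None)


def build_fc_stack(
    control_cleans: dict[str, CleanRun],
    control_records: dict[str, "SubjectRecord"],
    patients: list["SubjectRecord"],
    lesion_masks: dict[str, np.ndarray],
) -> list[FCMap]:
    """One FC map per (patient lesion, matched control) pair.

    Each map carries the five provenance covariates: the control's age,
    gender, max motion and imaging site, plus the patient identifying the
    lesion region.
    """
    stack: list[FCMap] = []
    for pat in sorted(patients, key=lambda r: r.subject_id):
        mask = lesion_masks[pat.subject_id]
        for cid in sorted(control_cleans):
            rec = control_records[cid]
            prov = {
                "patient_id": pat.subject_id,
                "control_id": cid,
                "age": rec.age,
                "gender": rec.gender,
                "max_motion": rec.mean_max_motion,
                "site": rec.site,
            }
            stack.append(seed_fc_map(control_cleans[cid], mask, provenance=prov))
    return stack


def _sum_code(levels: list) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns."""
    uniq = sorted(set(levels))
    cols = np.zeros((len(levels), max(len(uniq) - 1, 0)))
    for i, lev in enumerate(levels):
        j = uniq.index(lev)
        if j < len(uniq) - 1:
            cols[i, j] = 1.0
        else:
            cols[i, :] = -1.0
    return cols, uniq


def _template_design(stack: list[FCMap]) -> np.ndarray:
    age = np.asarray([m.provenance["age"] for m in stack], dtype=float)
    motion = np.asarray([m.provenance["max_motion"] for m in stack], dtype=float)
    gender, _ = _sum_code([m.provenance["gender"] for m in stack])
    site, _ = _sum_code([m.provenance["site"] for m in stack])
    lesion, _ = _sum_code([m.provenance["patient_id"] for m in stack])
    parts = [np.ones(len(stack)), age - age.mean(), motion - motion.mean(),
             gender, site, lesion]
    return np.column_stack([p if np.ndim(p) == 2 else p[:, None] for p in parts])


def derive_ln_template(stack: list[FCMap]) -> LNTemplate:
    """Per-voxel OLS of Fisher-Z on the provenance covariates; intercept = LN.

    With mean-centred continuous covariates and sum-to-zero factors the
    intercept is the covariate-adjusted grand mean.  Aliased design
    columns are dropped with a warning.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 FC maps")
    mask = stack[0].mask
    grid = stack[0].grid
    y = np.stack([m.values[mask] for m in stack])  # (n, V)

    x = _template_design(stack)
    q, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * diag[0]).sum())
    if rank < x.shape[1]:
        warnings.warn(f"LN design rank deficient: dropping {x.shape[1] - rank} "
                      "aliased column(s)", stacklevel=2)
        x = x[:, np.sort(piv[:rank])]

    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / max(df, 1)
    xtx_inv = np.linalg.inv(x.T @ x)
    se0 = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(se0 > 0, beta[0] / np.where(se0 > 0, se0, 1.0), 0.0)
    p0 = 2.0 * stats.t.sf(np.abs(t0), df=max(df, 1))

    def to3d(v):
        out = np.full(grid.shape, np.nan)
        out[mask] = v
        return out

    return LNTemplate(
        intercept=to3d(beta[0]),
        t_map=to3d(t0),
        p_map=to3d(p0),
        residuals=resid,
        mask=mask,
        grid=grid,
        n_maps=n,
        df_resid=df,
    )


def threshold_ln(template: LNTemplate, p_voxel: float, min_cluster_mm3: float):
    """Suprathreshold LN clusters: p < p_voxel, face-adjacent, >= min_cluster_mm3."""
    from .clusters import extract_clusters

    min_vox = int(np.ceil(min_cluster_mm3 / template.grid.voxel_volume_mm3))
    return extract_clusters(
        stat_map=template.t_map,
        p_map=template.p_map,
        p_voxel=p_voxel,
        min_cluster_voxels=max(min_vox, 1),
        grid=template.grid,
        mask=template.mask,
    )
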