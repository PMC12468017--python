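"""Lesion-network similarity (LNS) mapping.

For each brain voxel of a cleaned run, its whole-brain connectivity
profile (Fisher-Z correlation with every other brain voxel, the seed
itself excluded) is correlated with the lesion-network template over the
same seed-excluded support; the Pearson r is clipped to ±0.999 and
Fisher-Z transformed.  A high value marks a voxel whose connectivity
fingerprint resembles the lesion network — the operational definition of
a compensation candidate.  The statistic is applied identically to
patient and control runs, so control runs provide the healthy reference
level.

Profiles are computed by blocked matrix products over standardised time
series; results are identical to voxel-at-a-time evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTemplateError
from .grid import GridSpec
from .lesion_network import LNTemplate, MAX_ABS_R, fisher_z
from .qc import CleanRun

__all__ = ["SimilarityMap", "voxel_fc_profile", "similarity_map"]


@dataclass
class SimilarityMap:
    """Per subject-visit 3D map of LNS values (Fisher-Z)."""

    values: np.ndarray  # 3D Fisher-Z; NaN outside mask / at degenerate voxels
    mask: np.ndarray
    grid: GridSpec
    subject_id: str
    visit: int
    covariates: dict = field(default_factory=dict)  # ADL, age, gender, motion at visit
    degenerate_voxels: np.ndarray | None = None

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def r_values(self) -> np.ndarray:
        """The similarity map on the correlation (r) scale."""
        return np.tanh(self.values)


def _standardized_series(clean: CleanRun, brain_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = clean.data[brain_mask].astype(float)
    y = y - y.mean(axis=1, keepdims=True)
    sd = np.sqrt((y ** 2).sum(axis=1))
    good = sd > 0
    y[good] /= sd[good, None]
    y[~good] = 0.0
    return y, good


def voxel_fc_profile(clean: CleanRun, voxel: tuple[int, int, int],
                     brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Fisher-Z connectivity profile of one voxel with every *other* brain voxel.

    Returned in brain-mask enumeration order with the seed voxel removed,
    so the profile has (mask size − 1) entries.  A zero-variance seed
    raises a degenerate-profile error.
    """
    if brain_mask is None:
        brain_mask = clean.brain_mask
    if not brain_mask[voxel]:
        raise ValueError(f"voxel {voxel} is outside the brain mask")
    ys, good = _standardized_series(clean, brain_mask)
    coords = np.argwhere(brain_mask)
    (seed_idx,) = np.flatnonzero((coords == np.asarray(voxel)).all(axis=1))
    if not good[seed_idx]:
        raise DegenerateTemplateError(f"zero-variance seed voxel {voxel}")
    r = ys @ ys[seed_idx]
    r[~good] = 0.0
    return fisher_z(np.delete(r, seed_idx))


def similarity_map(
    clean: CleanRun,
    template: LNTemplate,
    brain_mask: np.ndarray | None = None,
    *,
    voxels: np.ndarray | None = None,
    covariates: dict | None = None,
    block_size: int = 256,
) -> SimilarityMap:
    """Voxel-wise correlation of connectivity profiles with the LN template.

    Parameters
    ----------
    voxels
        Optional (n, 3) voxel coordinates restricting the computation to a
        subset of seeds (the rest of the map stays NaN); the full map is
        the default.

    Raises
    ------
    DegenerateTemplateError
        If the template is constant over the profile support.
    """
    if brain_mask is None:
        brain_mask = clean.brain_mask
    if template.intercept.shape != clean.grid.shape:
        raise ValueError("template and run are on different grids")

    tvec = template.intercept[brain_mask].astype(float)
    v = tvec.size
    if np.ptp(tvec) == 0 or not np.all(np.isfinite(tvec)):
        raise DegenerateTemplateError("LN template is constant or undefined over the mask")

    ys, good = _standardized_series(clean, brain_mask)
    coords = np.argwhere(brain_mask)

    if voxels is None:
        rows = np.arange(v)
    else:
        lut = -np.ones(clean.grid.shape, dtype=int)
        lut[tuple(coords.T)] = np.arange(v)
        rows = lut[tuple(np.asarray(voxels, dtype=int).T)]
        if np.any(rows < 0):
            raise ValueError("requested seed voxels fall outside the brain mask")

    # template sufficient statistics over the full support
    st = tvec.sum()
    stt = (tvec ** 2).sum()

    out = np.full(v, np.nan)
    degenerate = ~good
    for start in range(0, rows.size, block_size):
        idx = rows[start:start + block_size]
        r_block = ys[idx] @ ys.T  # (b, V) Pearson r (0 rows for degenerate voxels)
        p_block = fisher_z(r_block)
        # self-correlation appears as the clipped maximum; remove it algebraically
        self_vals = p_block[np.arange(idx.size), idx]
        n_eff = v - 1
        sp = p_block.sum(axis=1) - self_vals
        spp = (p_block ** 2).sum(axis=1) - self_vals ** 2
        spt = p_block @ tvec - self_vals * tvec[idx]
        st_i = st - tvec[idx]
        stt_i = stt - tvec[idx] ** 2
        cov = spt - sp * st_i / n_eff
        var_p = spp - sp ** 2 / n_eff
        var_t = stt_i - st_i ** 2 / n_eff
        denom = np.sqrt(np.maximum(var_p, 0.0) * np.maximum(var_t, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
        z = fisher_z(r)
        z[degenerate[idx]] = np.nan
        out[idx] = z

    values = np.full(clean.grid.shape, np.nan)
    values[brain_mask] = out
    deg_coords = coords[degenerate & np.isin(np.arange(v), rows)]
    return SimilarityMap(
        values=values,
        mask=brain_mask,
        grid=clean.grid,
        subject_id=clean.subject_id,
        visit=clean.visit,
        covariates=covariates or {},
        degenerate_voxels=deg_coords if deg_coords.size else None,
    )
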