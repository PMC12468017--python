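"""Censoring, run screening, and time-series cleaning.

Screening applies three run-level inclusion criteria, each a strict
inequality: (1) more than 4.7 minutes of data must survive censoring,
(2) maximum pairwise head motion must stay below 2 mm, and (3) fewer than
20% of timepoints may be censored.

Cleaning projects out nuisance structure (motion parameters and their
first differences, optional tissue regressors, polynomial trends) and the
out-of-band frequencies in a single regression on the kept timepoints
only — the censoring-compatible equivalent of separate nuisance
regression and bandpass filtering.  Spatial smoothing is a
mask-renormalised Gaussian that preserves the in-mask mean of every
volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, ndimage

from .cohort import BoldRun
from .errors import UndefinedMotionError
from .grid import GridSpec

__all__ = [
    "ROTATION_RADIUS_MM",
    "CensorVector",
    "QCReport",
    "CleanRun",
    "motion_trace_to_mm",
    "max_pairwise_motion",
    "build_censor",
    "screen_run",
    "clean_run",
    "smooth_in_mask",
]

#: Head radius used to convert rotations (degrees) to mm of arc length.
ROTATION_RADIUS_MM = 50.0

#: Run-level inclusion thresholds (strict inequalities).
MIN_REMAINING_MINUTES = 4.7
MAX_PAIRWISE_MOTION_MM = 2.0
MAX_CENSORED_FRACTION = 0.20


@dataclass
class CensorVector:
    """Per-timepoint keep/censor flags with the reason for each censoring."""

    keep: np.ndarray  # (T,) bool
    reasons: list[set[str]]  # per timepoint, subset of {"motion", "outlier"}

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if len(self.reasons) != self.keep.size:
            raise ValueError("reasons must have one entry per timepoint")

    @property
    def censored_fraction(self) -> float:
        return float(1.0 - self.keep.mean())

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.keep.astype(int)[:, None], fmt="%d",
                   delimiter="\t", header="keep", comments="")


@dataclass
class QCReport:
    subject_id: str
    visit: int
    remaining_minutes: float
    max_pairwise_motion_mm: float
    censored_fraction: float
    pass_1: bool
    pass_2: bool
    pass_3: bool

    @property
    def included(self) -> bool:
        return self.pass_1 and self.pass_2 and self.pass_3


@dataclass
class CleanRun:
    """A cleaned run restricted to its kept timepoints."""

    data: np.ndarray  # (X, Y, Z, T_kept)
    kept_index: np.ndarray  # (T_kept,) indices into the original run
    band: tuple[float, float]
    smoothing_fwhm_mm: float | None
    tr_seconds: float
    grid: GridSpec
    brain_mask: np.ndarray
    subject_id: str
    visit: int


def motion_trace_to_mm(trace: np.ndarray) -> np.ndarray:
    """Convert a (T, 6) motion trace to all-mm units.

    Translations pass through; rotations in degrees become arc length on a
    sphere of radius :data:`ROTATION_RADIUS_MM`.
    """
    trace = np.asarray(trace, dtype=float)
    mm = trace.copy()
    mm[:, 3:] = np.radians(trace[:, 3:]) * ROTATION_RADIUS_MM
    return mm


def max_pairwise_motion(motion_trace: np.ndarray) -> float:
    """Maximum over all timepoint pairs of the 6D Euclidean parameter distance (mm)."""
    trace = np.asarray(motion_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if trace.shape[0] < 2:
        raise UndefinedMotionError("max pairwise motion needs at least 2 timepoints")
    mm = motion_trace_to_mm(trace)
    # pairwise via the Gram trick; exact and O(T^2) memory at T ~ 130
    diff = mm[:, None, :] - mm[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def build_censor(
    motion_trace: np.ndarray,
    outlier_fraction: np.ndarray,
    motion_step_limit_mm: float = 0.5,
    outlier_limit: float = 0.10,
) -> CensorVector:
    """Flag timepoints with excessive frame-to-frame motion or signal outliers.

    A frame-to-frame displacement above ``motion_step_limit_mm`` censors
    both frames straddling the motion; an outlier fraction above
    ``outlier_limit`` censors that frame.
    """
    if motion_step_limit_mm <= 0 or outlier_limit <= 0:
        raise ValueError("censor thresholds must be positive")
    mm = motion_trace_to_mm(np.asarray(motion_trace, dtype=float))
    out = np.asarray(outlier_fraction, dtype=float)
    t = mm.shape[0]
    if out.shape != (t,):
        raise ValueError("outlier fraction length must match the motion trace")

    keep = np.ones(t, dtype=bool)
    reasons: list[set[str]] = [set() for _ in range(t)]
    step = np.sqrt((np.diff(mm, axis=0) ** 2).sum(1))  # step[i] between i and i+1
    for i in np.flatnonzero(step > motion_step_limit_mm):
        for j in (i, i + 1):
            keep[j] = False
            reasons[j].add("motion")
    for j in np.flatnonzero(out > outlier_limit):
        keep[j] = False
        reasons[j].add("outlier")
    return CensorVector(keep=keep, reasons=reasons)


def screen_run(run: BoldRun, censor: CensorVector) -> QCReport:
    """Apply the three inclusion criteria (all strict inequalities)."""
    if censor.keep.size != run.n_timepoints:
        raise ValueError("censor length does not match run length")
    # round away float fuzz so printed thresholds act as exact boundaries
    # (26/130 censored must compare equal to 20%, not 0.19999999999999996)
    remaining_min = round(censor.n_kept * run.tr_seconds / 60.0, 9)
    mpm = round(max_pairwise_motion(run.motion_trace), 9)
    frac = round(censor.censored_fraction, 9)
    return QCReport(
        subject_id=run.subject_id,
        visit=run.visit,
        remaining_minutes=remaining_min,
        max_pairwise_motion_mm=mpm,
        censored_fraction=frac,
        pass_1=remaining_min > MIN_REMAINING_MINUTES,
        pass_2=mpm < MAX_PAIRWISE_MOTION_MM,
        pass_3=frac < MAX_CENSORED_FRACTION,
    )


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------


def bandstop_regressors(t_total: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Sine/cosine pairs for every DFT frequency outside ``band`` (excluding DC)."""
    freqs = np.fft.rfftfreq(t_total, d=tr)
    times = np.arange(t_total) * tr
    cols = []
    for k, f in enumerate(freqs):
        if k == 0 or band[0] <= f <= band[1]:
            continue
        cols.append(np.cos(2 * np.pi * f * times))
        if k < (t_total + 1) // 2 or t_total % 2 == 1:  # Nyquist has no sine term
            cols.append(np.sin(2 * np.pi * f * times))
    if not cols:
        return np.empty((t_total, 0))
    return np.column_stack(cols)


def _design_matrix(run_t: int, tr: float, motion: np.ndarray | None,
                   nuisance: np.ndarray | None, band: tuple[float, float]) -> np.ndarray:
    cols = [np.ones(run_t), np.linspace(-1.0, 1.0, run_t)]
    if motion is not None:
        dmot = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
        cols.extend([motion, dmot])
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        cols.append(nuis)
    cols.append(bandstop_regressors(run_t, tr, band))
    return np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])


def _prune_collinear(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Drop collinear columns (pivoted QR), warning when any are removed."""
    if x.shape[1] == 0:
        return x
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    keep_n = int((diag > tol * max(diag[0], 1e-300)).sum())
    if keep_n < x.shape[1]:
        warnings.warn(
            f"design is rank deficient: dropping {x.shape[1] - keep_n} collinear column(s)",
            stacklevel=3,
        )
        keep_cols = np.sort(piv[:keep_n])
        return x[:, keep_cols]
    return x


def smooth_in_mask(volume: np.ndarray, mask: np.ndarray, fwhm_mm: float,
                   voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Mask-renormalised Gaussian smoothing preserving the in-mask mean.

    Values outside the mask never leak in; after kernel renormalisation a
    scalar offset restores the original in-mask mean exactly.
    """
    sigma_vox = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in voxel_size]
    m = mask.astype(float)
    num = ndimage.gaussian_filter(volume * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = np.zeros_like(volume, dtype=float)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    out[inside] += volume[mask].mean() - out[inside].mean()
    return out


def clean_run(
    run: BoldRun,
    censor: CensorVector,
    nuisance: np.ndarray | None = None,
    band: tuple[float, float] = (0.009, 0.08),
    brain_mask: np.ndarray | None = None,
    fwhm_mm: float | None = 5.0,
) -> CleanRun:
    """Project out nuisance + out-of-band structure on kept timepoints, then smooth.

    The regression design spans a constant, a linear trend, the six motion
    parameters and their first differences, any supplied ``nuisance``
    columns, and sine/cosine pairs for every frequency outside ``band``.
    Residuals are orthogonal to every retained design column.  Collinear
    columns are dropped with a warning, never silently.
    """
    if censor.keep.size != run.n_timepoints:
        raise ValueError("censor length does not match run length")
    if brain_mask is None:
        brain_mask = run.grid.brain_mask()
    kept = np.flatnonzero(censor.keep)

    x_full = _design_matrix(run.n_timepoints, run.tr_seconds, run.motion_trace, nuisance, band)
    x = _prune_collinear(x_full[kept])
    if x.shape[1] >= kept.size:
        raise ValueError(
            f"design has {x.shape[1]} columns for only {kept.size} kept timepoints"
        )
    q, _ = np.linalg.qr(x)

    y = run.data[..., kept]
    flat = y.reshape(-1, kept.size)
    resid = flat - (flat @ q) @ q.T
    resid = resid.reshape(y.shape)

    if fwhm_mm is not None and fwhm_mm > 0:
        for k in range(resid.shape[-1]):
            resid[..., k] = smooth_in_mask(resid[..., k], brain_mask, fwhm_mm,
                                           run.grid.voxel_size)

    return CleanRun(
        data=resid,
        kept_index=kept,
        band=band,
        smoothing_fwhm_mm=fwhm_mm,
        tr_seconds=run.tr_seconds,
        grid=run.grid,
        brain_mask=brain_mask,
        subject_id=run.subject_id,
        visit=run.visit,
    )
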