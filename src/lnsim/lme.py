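"""Voxel-wise linear mixed-effects modelling of similarity and connectivity.

The model at every voxel is

    response = b0 + b_ADL*ADL + b_age*age + b_gender*gender + b_motion*motion
               + u_subject + e,     u_subject ~ N(0, tau^2),  e ~ N(0, sigma^2)

with a random intercept per subject, fitted by REML.  All voxels share
one fixed-effects design and one grouping structure, which permits a
fast profiled-REML fit: for a candidate variance ratio lambda =
tau^2/sigma^2 the GLS transform is a per-subject partial demeaning, the
log-determinant terms are voxel-independent, and only the residual sum
of squares varies by voxel.  The ratio is optimised on a log-spaced grid
with parabolic refinement, then exact per-voxel GLS statistics are
computed at the optimum.  Wald t-tests use the between-within degrees of
freedom df = n_obs − n_fixed − n_subjects + 1; voxels whose variance
ratio hits the lambda = 0 boundary fall back to plain OLS (df = n_obs −
n_fixed) and are flagged.

The public surface follows the Model/Results idiom: ``VoxelLME`` is
built from data and ``fit()`` returns a ``VoxelLMEResults`` carrying the
per-voxel estimates, their uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import SimilarityMap

__all__ = ["VoxelLME", "VoxelLMEResults", "fit_voxel_lme", "effect_size_eta2",
           "predicted_connectivity_at_adl", "direct_fc_longitudinal",
           "simulate_lme_responses"]

DEFAULT_COVARIATES = ("adl", "age", "gender", "motion")
GENDER_CODE = {"male": 0.0, "female": 1.0}


def _group_index(groups) -> tuple[np.ndarray, int, np.ndarray]:
    uniq, inv = np.unique(np.asarray(groups), return_inverse=True)
    sizes = np.bincount(inv)
    return inv, len(uniq), sizes


class VoxelLME:
    """Random-intercept LME fitted independently at each voxel.

    Parameters
    ----------
    endog
        (n_obs, V) response matrix; one column per voxel (or region).
    exog
        (n_obs, p) fixed-effects design including the intercept column.
    groups
        (n_obs,) subject labels defining the random intercepts.
    exog_names
        Names of the design columns, ``exog_names[0]`` being the intercept.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray, groups,
                 exog_names: list[str] | None = None):
        endog = np.asarray(endog, dtype=float)
        if endog.ndim == 1:
            endog = endog[:, None]
        exog = np.asarray(exog, dtype=float)
        n, p = exog.shape
        if endog.shape[0] != n or len(groups) != n:
            raise ValueError("endog, exog and groups must agree on n_obs")
        inv, g, sizes = _group_index(groups)
        if g < 2 or n < p + 2:
            raise ValueError("need >= 2 subjects and more observations than parameters")
        self.valid_voxels = np.all(np.isfinite(endog), axis=0)
        self.endog = np.where(self.valid_voxels[None, :], np.nan_to_num(endog), 0.0)
        self.exog = exog
        self.group_index = inv
        self.n_groups = g
        self.group_sizes = sizes
        self.exog_names = list(exog_names) if exog_names else (
            ["const"] + [f"x{j}" for j in range(1, p)])

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_maps(cls, maps: list[SimilarityMap], mask: np.ndarray | None = None,
                  covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                  center: bool = True) -> "VoxelLME":
        """Assemble the voxel-wise model from per subject-visit maps.

        Each map must carry the per-visit covariates (``adl``, ``age``,
        ``gender``, ``motion``) in its ``covariates`` dict.  Age and
        motion are mean-centred (and gender coded 0/1) so the intercept is
        directly interpretable for prediction maps.
        """
        import warnings

        if mask is None:
            mask = maps[0].mask
        endog = np.stack([m.values[mask] for m in maps])
        cols = [np.ones(len(maps))]
        names = ["const"]
        for name in covariates:
            vals = []
            for m in maps:
                v = m.covariates[name]
                vals.append(GENDER_CODE.get(v, v) if isinstance(v, str) else float(v))
            vals = np.asarray(vals, dtype=float)
            if np.ptp(vals) == 0:
                warnings.warn(f"covariate {name!r} is constant; dropped from the "
                              "voxel-wise design", stacklevel=2)
                continue
            if center and name in ("age", "motion"):
                vals = vals - vals.mean()
            cols.append(vals)
            names.append(name)
        exog = np.column_stack(cols)
        groups = [m.subject_id for m in maps]
        model = cls(endog, exog, groups, exog_names=names)
        model._maps_meta = {"mask": mask, "grid": maps[0].grid}
        return model

    # -- REML machinery ------------------------------------------------------

    def _transform(self, lam: float | np.ndarray):
        """Partial per-group demeaning implementing the GLS whitening.

        For V0 = I + lam * J_group, V0^{-1/2} y = y − c_g * mean_g(y) with
        c_g = 1 − 1/sqrt(1 + lam*n_g).
        """
        inv = self.group_index
        n_g = self.group_sizes.astype(float)
        lam = np.asarray(lam, dtype=float)
        c = 1.0 - 1.0 / np.sqrt(1.0 + lam * n_g if lam.ndim == 0 else
                                1.0 + lam[..., None] * n_g)
        return c, inv, n_g

    def _rss_at(self, lam: float) -> tuple[np.ndarray, float]:
        """Per-voxel RSS at a shared lambda, plus the shared log-det penalty."""
        c, inv, n_g = self._transform(lam)
        counts = self.group_sizes
        ym = _group_means(self.endog, inv, counts)
        xm = _group_means(self.exog, inv, counts)
        yt = self.endog - (np.asarray(c)[inv, None] * ym[inv])
        xt = self.exog - (np.asarray(c)[inv, None] * xm[inv])
        q, r = np.linalg.qr(xt)
        resid = yt - q @ (q.T @ yt)
        rss = (resid ** 2).sum(axis=0)
        logdet_v = float(np.sum(np.log1p(lam * n_g)))
        sign, logdet_xvx = np.linalg.slogdet(r.T @ r)
        return rss, logdet_v + logdet_xvx

    def _reml_crit(self, lam: float) -> np.ndarray:
        n, p = self.exog.shape
        rss, pen = self._rss_at(lam)
        return (n - p) * np.log(np.maximum(rss, 1e-300)) + pen

    def fit(self, lam_grid: np.ndarray | None = None) -> "VoxelLMEResults":
        """Profiled-REML fit; returns the per-voxel results object."""
        n, p = self.exog.shape
        v = self.endog.shape[1]
        if lam_grid is None:
            lam_grid = np.r_[0.0, np.logspace(-3, 3, 49)]
        crit = np.empty((lam_grid.size, v))
        for i, lam in enumerate(lam_grid):
            crit[i] = self._reml_crit(float(lam))
        crit = np.where(np.isfinite(crit), crit, np.inf)
        best = crit.argmin(axis=0)

        # parabolic refinement in log-lambda where the optimum is interior
        lam_opt = lam_grid[best].astype(float)
        interior = (best > 0) & (best < lam_grid.size - 1)
        if interior.any():
            idx = np.flatnonzero(interior)
            b = best[idx]
            # grid point 0 is lambda=0; log-parabola needs three positive points
            ok = b > 1
            idx, b = idx[ok], b[ok]
            if idx.size:
                x0, x1, x2 = (np.log(lam_grid[b - 1]), np.log(lam_grid[b]),
                              np.log(lam_grid[b + 1]))
                y0 = crit[b - 1, idx]
                y1 = crit[b, idx]
                y2 = crit[b + 1, idx]
                denom = (y0 - 2 * y1 + y2)
                shift = np.where(np.abs(denom) > 1e-12,
                                 0.5 * (y0 - y2) / np.where(np.abs(denom) > 1e-12, denom, 1.0),
                                 0.0)
                shift = np.clip(shift, -1.0, 1.0)
                lam_opt[idx] = np.exp(x1 + shift * (x1 - x0))

        return self._finalize(lam_opt)

    def _finalize(self, lam_opt: np.ndarray) -> "VoxelLMEResults":
        n, p = self.exog.shape
        v = self.endog.shape[1]
        g = self.n_groups
        boundary = lam_opt <= 0.0

        params = np.empty((p, v))
        bse = np.empty((p, v))
        sigma2 = np.empty(v)
        cov_diag = np.empty((p, v))

        counts = self.group_sizes
        ym = _group_means(self.endog, self.group_index, counts)
        xm = _group_means(self.exog, self.group_index, counts)

        # batch voxels by unique lambda to reuse the design transform
        order = np.argsort(lam_opt, kind="stable")
        uniq, starts = np.unique(lam_opt[order], return_index=True)
        bounds = np.r_[starts, order.size]
        for u, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
            cols = order[lo:hi]
            c_g = 1.0 - 1.0 / np.sqrt(1.0 + u * counts.astype(float))
            xt = self.exog - c_g[self.group_index, None] * xm[self.group_index]
            yt = self.endog[:, cols] - c_g[self.group_index, None] * ym[self.group_index][:, cols]
            xtx = xt.T @ xt
            xtx_inv = np.linalg.inv(xtx)
            beta = xtx_inv @ (xt.T @ yt)
            resid = yt - xt @ beta
            rss = (resid ** 2).sum(axis=0)
            s2 = rss / max(n - p, 1)
            params[:, cols] = beta
            sigma2[cols] = s2
            cov_diag[:, cols] = np.diag(xtx_inv)[:, None] * s2[None, :]

        bse = np.sqrt(np.maximum(cov_diag, 0.0))
        df_mixed = n - p - g + 1
        df = np.where(boundary, n - p, df_mixed).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, params / np.where(bse > 0, bse, 1.0),
                             np.sign(params) * np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df[None, :])
        tau2 = lam_opt * sigma2
        bad = ~self.valid_voxels
        if bad.any():  # voxels with non-finite responses report NaN throughout
            for arr in (params, bse, tvals):
                arr[:, bad] = np.nan
            pvals[:, bad] = np.nan
            sigma2[bad] = np.nan
            tau2[bad] = np.nan

        fitted = self.exog @ params
        resid_raw = self.endog - fitted  # marginal residuals, for smoothness maps

        return VoxelLMEResults(
            model=self,
            params=params, bse=bse, tvalues=tvals, pvalues=pvals,
            sigma2=sigma2, tau2=tau2, lam=lam_opt,
            df=df, boundary=boundary,
            n_obs=n, n_subjects=g, n_fixed=p,
            resid=resid_raw,
        )


def _group_means(a: np.ndarray, inv: np.ndarray, counts: np.ndarray) -> np.ndarray:
    g = counts.size
    sums = np.zeros((g,) + a.shape[1:])
    np.add.at(sums, inv, a)
    return sums / counts.reshape((g,) + (1,) * (a.ndim - 1))


@dataclass
class VoxelLMEResults:
    """Per-voxel mixed-effects estimates, uncertainties and diagnostics."""

    model: VoxelLME
    params: np.ndarray  # (p, V)
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2: np.ndarray  # (V,) residual variance
    tau2: np.ndarray  # (V,) random-intercept variance
    lam: np.ndarray
    df: np.ndarray  # (V,)
    boundary: np.ndarray  # (V,) bool: lambda hit 0, OLS fallback
    n_obs: int
    n_subjects: int
    n_fixed: int
    resid: np.ndarray  # (n_obs, V) marginal residuals

    def _term(self, name: str) -> int:
        try:
            return self.model.exog_names.index(name)
        except ValueError:
            raise KeyError(f"no term named {name!r}; have {self.model.exog_names}")

    def coef(self, name: str) -> np.ndarray:
        return self.params[self._term(name)]

    def tvalue(self, name: str) -> np.ndarray:
        return self.tvalues[self._term(name)]

    def pvalue(self, name: str) -> np.ndarray:
        return self.pvalues[self._term(name)]

    def eta_squared(self, name: str = "adl") -> np.ndarray:
        """Partial eta-squared of one fixed effect: t^2 / (t^2 + df)."""
        if np.any(self.df <= 0):
            raise ValueError("non-positive degrees of freedom")
        t = self.tvalue(name)
        t2 = t ** 2
        return np.where(np.isinf(t2), 1.0, t2 / (t2 + self.df))

    def conf_int(self, name: str, alpha: float = 0.05) -> np.ndarray:
        j = self._term(name)
        q = stats.t.ppf(1 - alpha / 2, df=self.df)
        return np.stack([self.params[j] - q * self.bse[j],
                         self.params[j] + q * self.bse[j]])

    def predict_at(self, name: str, levels, covariate_means: dict | None = None) -> np.ndarray:
        """Predicted response at given levels of one term, others at their means.

        Returns an array of shape (len(levels), V); with a centred design
        this is b0 + b_gender*mean_gender + b_term*level per level.
        """
        xbar = self.model.exog.mean(axis=0)
        j = self._term(name)
        out = []
        for lev in levels:
            row = xbar.copy()
            row[j] = lev
            out.append(row @ self.params)
        return np.stack(out)

    def to_map(self, values: np.ndarray) -> np.ndarray:
        """Scatter a (V,) vector back to the 3D grid (NaN elsewhere)."""
        meta = getattr(self.model, "_maps_meta", None)
        if meta is None:
            raise ValueError("model was not built from maps; no grid to scatter onto")
        out = np.full(meta["grid"].shape, np.nan)
        out[meta["mask"]] = values
        return out

    def summary(self, name: str = "adl") -> pd.DataFrame:
        """Across-voxel summary of one fixed effect."""
        j = self._term(name)
        eta = self.eta_squared(name)
        rows = {
            "coef_mean": np.nanmean(self.params[j]),
            "coef_min": np.nanmin(self.params[j]),
            "coef_max": np.nanmax(self.params[j]),
            "t_min": np.nanmin(self.tvalues[j]),
            "t_max": np.nanmax(self.tvalues[j]),
            "frac_p_lt_0.05": float(np.nanmean(self.pvalues[j] < 0.05)),
            "eta2_max": float(np.nanmax(eta)),
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_voxels": self.params.shape[1],
            "n_boundary": int(self.boundary.sum()),
        }
        return pd.DataFrame([rows], index=[name])


# ---------------------------------------------------------------------------
# spec-level operations
# ---------------------------------------------------------------------------


def fit_voxel_lme(maps: list[SimilarityMap], mask: np.ndarray | None = None,
                  covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> VoxelLMEResults:
    """Fit response ~ ADL + age + gender + motion with a subject random intercept."""
    subjects = {m.subject_id for m in maps}
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    visits = {}
    for m in maps:
        visits.setdefault(m.subject_id, set()).add(m.visit)
    if sum(len(v) >= 2 for v in visits.values()) < 2:
        raise ValueError("need >= 2 visits for >= 2 subjects")
    return VoxelLME.from_maps(maps, mask=mask, covariates=covariates).fit()


def effect_size_eta2(result: VoxelLMEResults, name: str = "adl") -> np.ndarray:
    """Partial eta-squared map of one fixed effect."""
    return result.eta_squared(name)


def predicted_connectivity_at_adl(result: VoxelLMEResults,
                                  levels=(47.0, 65.0, 83.0)) -> dict[float, np.ndarray]:
    """Predicted connectivity at the requested ADL levels.

    Other covariates sit at their sample means, so each map is the
    model's adjusted connectivity at that recovery level.  Levels outside
    the observed ADL range are linearly extrapolated with a warning.
    """
    import warnings

    j = result._term("adl")
    observed = result.model.exog[:, j]
    for lev in levels:
        if not (observed.min() <= lev <= observed.max()):
            warnings.warn(f"ADL level {lev} outside the observed range "
                          f"[{observed.min():.1f}, {observed.max():.1f}]; extrapolating",
                          stacklevel=2)
    pred = result.predict_at("adl", levels)
    return {float(lev): pred[i] for i, lev in enumerate(levels)}


def direct_fc_longitudinal(
    patient_cleans: list,
    lesion_masks: dict[str, np.ndarray],
    core_regions,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Direct lesion-to-region FC across visits, with a visit-effect test.

    For each core region (a row of a cluster table carrying a ``voxels``
    entry) and each patient visit, the Fisher-Z correlation between the
    lesion-mask mean signal and the region mean signal is computed; the
    longitudinal change is then tested per region with the same
    random-intercept machinery, visit index as the predictor.

    Returns ``(summary, tests)``: per-region-and-visit mean FC, and
    per-region visit-effect estimates with p-values.
    """
    from .lesion_network import fisher_z

    regions = list(core_regions.itertuples()) if isinstance(core_regions, pd.DataFrame) \
        else list(core_regions)
    if not regions:
        raise ValueError("no core regions supplied; relax the LN threshold")

    rows = []
    for clean in patient_cleans:
        lm = lesion_masks[clean.subject_id]
        seed = clean.data[lm].mean(axis=0)
        seed = seed - seed.mean()
        ssd = np.sqrt((seed ** 2).sum())
        for reg in regions:
            vox = np.asarray(reg.voxels)
            series = clean.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
            series = series - series.mean()
            rsd = np.sqrt((series ** 2).sum())
            r = float(seed @ series / (ssd * rsd)) if ssd > 0 and rsd > 0 else 0.0
            rows.append({"region_id": reg.cluster_id, "subject_id": clean.subject_id,
                         "visit": clean.visit, "fc_z": float(fisher_z(np.asarray(r)))})
    long = pd.DataFrame(rows)

    summary = (long.groupby(["region_id", "visit"])["fc_z"]
               .agg(["mean", "std", "count"]).reset_index()
               .rename(columns={"mean": "mean_fc_z", "std": "sd_fc_z", "count": "n"}))

    tests = []
    for rid, sub in long.groupby("region_id"):
        endog = sub["fc_z"].to_numpy()[:, None]
        exog = np.column_stack([np.ones(len(sub)), sub["visit"].to_numpy(dtype=float)])
        res = VoxelLME(endog, exog, sub["subject_id"].tolist(),
                       exog_names=["const", "visit"]).fit()
        tests.append({"region_id": rid,
                      "visit_coef": float(res.coef("visit")[0]),
                      "visit_t": float(res.tvalue("visit")[0]),
                      "visit_p": float(res.pvalue("visit")[0])})
    return summary, pd.DataFrame(tests)


def simulate_lme_responses(
    exog: np.ndarray,
    groups,
    beta: np.ndarray,
    re_sd: float,
    resid_sd: float,
    n_voxels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (n_obs, n_voxels) responses from the random-intercept model.

    Used for calibration studies: the same planted fixed effects at every
    voxel, independent subject intercepts and residuals per voxel.
    """
    inv, g, _ = _group_index(groups)
    mean = (np.asarray(exog, dtype=float) @ np.asarray(beta, dtype=float))[:, None]
    u = re_sd * rng.standard_normal((g, n_voxels))
    e = resid_sd * rng.standard_normal((exog.shape[0], n_voxels))
    return mean + u[inv] + e
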