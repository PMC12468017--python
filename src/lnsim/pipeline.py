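"""End-to-end orchestration: simulate → QC → match → LN → similarity → LME → clusters.

A single JSON config drives every stage; all randomness flows from one
master seed, so two runs with the same (config, seed) produce identical
report tables.  Each stage writes its artifacts under the output
directory together with a manifest entry (config-hash checked), so a
pipeline can be resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as cl
from . import lme as lme_mod
from .cohort import CohortConfig, SyntheticCohort, simulate_cohort
from .errors import StageError
from .grid import GridSpec, save_nifti
from .lesion_network import build_fc_stack, derive_ln_template, threshold_ln
from .matching import fit_propensity, match_controls
from .qc import QCReport, build_censor, clean_run, screen_run
from .similarity import similarity_map

__all__ = ["PipelineConfig", "run_pipeline", "subject_usability_filter"]

log = logging.getLogger("lnsim.pipeline")

STAGES = ("simulate", "qc", "match", "ln", "similarity", "lme", "clusters", "report")


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    version: int = 1
    cohort: CohortConfig = field(default_factory=CohortConfig)
    motion_step_limit_mm: float = 0.5
    outlier_limit: float = 0.10
    band: tuple[float, float] = (0.009, 0.08)
    fwhm_mm: float = 5.0
    matching_k: int = 3
    p_voxel: float = 0.001
    alpha: float = 0.05
    n_iter: int = 1000
    ln_p_voxel: float = 0.001
    ln_min_cluster_mm3: float = 216.0
    core_region_p: float = 1e-5
    adl_levels: tuple[float, float, float] = (47.0, 65.0, 83.0)
    write_maps: bool = True

    def validate(self) -> None:
        for name in ("motion_step_limit_mm", "outlier_limit", "fwhm_mm",
                     "p_voxel", "alpha", "ln_p_voxel", "ln_min_cluster_mm3",
                     "core_region_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_iter < 1 or self.matching_k < 1:
            raise ValueError("n_iter and matching_k must be >= 1")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")
        self.cohort.validate()

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid"] = {"shape": list(self.cohort.grid.shape),
                               "voxel_size": list(self.cohort.grid.voxel_size)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        coh = dict(d.pop("cohort", {}))
        if "grid" in coh:
            g = coh.pop("grid")
            coh["grid"] = GridSpec(tuple(g["shape"]), tuple(g["voxel_size"]))
        for key in ("adl_means", "adl_sds", "days_means", "days_sds",
                    "similarity_anchors", "lesion_activity_by_visit",
                    "lesion_overlap_range"):
            if key in coh and isinstance(coh[key], list):
                coh[key] = tuple(coh[key])
        d["cohort"] = CohortConfig(**coh)
        for key in ("band", "adl_levels"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def subject_usability_filter(qc_reports: list[QCReport]) -> dict[str, list[int]]:
    """Patients keep only usable visits, and only if >= 2 visits are usable."""
    by_subject: dict[str, list[int]] = {}
    for rep in qc_reports:
        if rep.included:
            by_subject.setdefault(rep.subject_id, []).append(rep.visit)
    return {sid: sorted(vs) for sid, vs in by_subject.items() if len(vs) >= 2}


@dataclass
class PipelineReport:
    """Machine-readable result bundle of one pipeline run.

    Fields belonging to stages after ``stop_after`` are None/empty."""

    config_hash: str
    seed: int
    qc: pd.DataFrame | None = None
    usable_patients: dict | None = None
    matches: pd.DataFrame | None = None
    n_fc_maps: int = 0
    ln_cluster_table: pd.DataFrame | None = None
    adl_cluster_table: pd.DataFrame | None = None
    similarity_by_visit: pd.DataFrame | None = None
    direct_fc_summary: pd.DataFrame | None = None
    direct_fc_tests: pd.DataFrame | None = None
    min_cluster_voxels: int = 0
    acf: cl.AcfModel | None = None
    adl_level_maps: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)
    paths: dict = field(default_factory=dict)


def _write_manifest(out: Path, chash: str, seed: int, stage_log: list[dict]) -> None:
    manifest = {"config_hash": chash, "seed": int(seed),
                "completed_stages": [e["stage"] for e in stage_log]}
    (out / "stages.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(config: PipelineConfig, seed: int, outdir,
                 stop_after: str = "report") -> PipelineReport:
    """Run the pipeline stages in order from one config and master seed.

    ``stop_after`` names the last stage to execute (one of
    ``simulate, qc, match, ln, similarity, lme, clusters, report``); the
    whole run is deterministic per (config, seed), so later invocations
    with a later ``stop_after`` reproduce earlier artifacts bit-identically
    (the ``stages.json`` manifest records the config hash for checking).
    Any stage failure raises :class:`StageError` naming the stage;
    artifacts written by earlier stages are retained.
    """
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    chash = config.content_hash()
    stage_log: list[dict] = []
    paths: dict[str, str] = {}

    report = PipelineReport(config_hash=chash, seed=int(seed),
                            stage_log=stage_log, paths=paths)

    def done(stage: str) -> bool:
        _write_manifest(out, chash, seed, stage_log)
        return stop_after == stage

    def log_stage(stage: str, **info):
        entry = {"stage": stage, **info}
        stage_log.append(entry)
        log.info("stage %s: %s", stage, info)

    grid = config.cohort.grid
    brain_mask = grid.brain_mask()

    # -- simulate -----------------------------------------------------------
    try:
        cohort = simulate_cohort(config.cohort, seed)
        cohort.write(out / "cohort")
        paths["cohort"] = str(out / "cohort")
        log_stage("simulate", n_patients=len(cohort.patients),
                  n_pool=len(cohort.controls))
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    if done("simulate"):
        return report

    # -- qc ------------------------------------------------------------------
    try:
        reports: list[QCReport] = []
        censors: dict[tuple[str, int], object] = {}
        for rec in cohort.records:
            for v in rec.visits:
                run = cohort.run(rec.subject_id, v.visit)
                cen = build_censor(run.motion_trace, run.outlier_fraction,
                                   config.motion_step_limit_mm, config.outlier_limit)
                censors[(rec.subject_id, v.visit)] = cen
                reports.append(screen_run(run, cen))
        qc_df = pd.DataFrame([dataclasses.asdict(r) | {"included": r.included}
                              for r in reports])
        qc_df.to_csv(out / "qc.tsv", sep="\t", index=False)
        paths["qc"] = str(out / "qc.tsv")
        censor_dir = out / "censors"
        censor_dir.mkdir(exist_ok=True)
        for (sid, visit), cen in censors.items():
            cen.to_tsv(censor_dir / f"{sid}_visit{visit}_censor.tsv")

        usable = subject_usability_filter(
            [r for r in reports if r.subject_id.startswith("P")])
        usable_controls = [r.subject_id for r in reports
                           if r.subject_id.startswith("C") and r.included]
        if not usable:
            raise ValueError("no usable runs: every patient failed screening")
        log_stage("qc", n_runs=len(reports),
                  n_usable_patients=len(usable), n_usable_controls=len(usable_controls))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", str(e)) from e
    report.qc = qc_df
    report.usable_patients = usable
    if done("qc"):
        return report

    # -- match ---------------------------------------------------------------
    try:
        patients = [p for p in cohort.patients if p.subject_id in usable]
        pool = [c for c in cohort.controls if c.subject_id in usable_controls]
        model = fit_propensity(patients, pool)
        matches = match_controls(model, patients, pool, k=config.matching_k)
        matches.to_csv(out / "matches.tsv", sep="\t", index=False)
        paths["matches"] = str(out / "matches.tsv")
        selected_controls = sorted(matches["control_id"].unique())
        log_stage("match", n_patients=len(patients),
                  n_selected_controls=len(selected_controls),
                  propensity_method=model.method)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("match", str(e)) from e
    report.matches = matches
    if done("match"):
        return report

    # -- ln -------------------------------------------------------------------
    try:
        control_cleans = {}
        for cid in selected_controls:
            run = cohort.run(cid, 1)
            control_cleans[cid] = clean_run(run, censors[(cid, 1)], band=config.band,
                                            brain_mask=brain_mask, fwhm_mm=config.fwhm_mm)
        lesion_masks = {p.subject_id: cohort.lesion_mask(p.subject_id) for p in patients}
        control_records = {c.subject_id: c for c in pool if c.subject_id in selected_controls}
        stack = build_fc_stack(control_cleans, control_records, patients, lesion_masks)
        template = derive_ln_template(stack)
        ln_clusters = threshold_ln(template, config.ln_p_voxel, config.ln_min_cluster_mm3)
        if config.write_maps:
            save_nifti(np.nan_to_num(template.intercept), grid, out / "ln_template.nii.gz")
            save_nifti(np.nan_to_num(template.t_map), grid, out / "ln_t.nii.gz")
            save_nifti(np.nan_to_num(template.p_map, nan=1.0), grid, out / "ln_p.nii.gz")
        ln_clusters.drop(columns="voxels").to_csv(out / "ln_clusters.tsv", sep="\t", index=False)
        paths["ln_template"] = str(out / "ln_template.nii.gz")
        log_stage("ln", n_fc_maps=len(stack), n_ln_clusters=len(ln_clusters))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("ln", str(e)) from e
    report.n_fc_maps = len(stack)
    report.ln_cluster_table = ln_clusters.drop(columns="voxels")
    if done("ln"):
        return report

    # -- similarity -----------------------------------------------------------
    try:
        sim_maps = []
        for pat in patients:
            for v in pat.visits:
                if v.visit not in usable[pat.subject_id]:
                    continue
                run = cohort.run(pat.subject_id, v.visit)
                clean = clean_run(run, censors[(pat.subject_id, v.visit)], band=config.band,
                                  brain_mask=brain_mask, fwhm_mm=config.fwhm_mm)
                cov = {"adl": v.adl, "age": pat.age, "gender": pat.gender,
                       "motion": v.max_head_motion}
                sim_maps.append(similarity_map(clean, template, brain_mask,
                                               covariates=cov))
        if config.write_maps:
            sim_dir = out / "similarity"
            sim_dir.mkdir(exist_ok=True)
            for m in sim_maps:
                stem = f"{m.subject_id}_visit{m.visit}_lns"
                save_nifti(np.nan_to_num(m.values), grid, sim_dir / f"{stem}.nii.gz")
                (sim_dir / f"{stem}.json").write_text(json.dumps(m.covariates))
        log_stage("similarity", n_maps=len(sim_maps))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("similarity", str(e)) from e
    if done("similarity"):
        return report

    # -- lme -------------------------------------------------------------------
    try:
        result = lme_mod.fit_voxel_lme(sim_maps, mask=brain_mask)
        eta2 = result.eta_squared("adl")
        if config.write_maps:
            save_nifti(result.to_map(result.coef("adl")), grid, out / "adl_beta.nii.gz")
            save_nifti(result.to_map(result.tvalue("adl")), grid, out / "adl_t.nii.gz")
            save_nifti(np.nan_to_num(result.to_map(result.pvalue("adl")), nan=1.0),
                       grid, out / "adl_p.nii.gz")
            save_nifti(result.to_map(eta2), grid, out / "adl_eta2.nii.gz")
        log_stage("lme", n_obs=result.n_obs, n_subjects=result.n_subjects,
                  n_boundary=int(result.boundary.sum()))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("lme", str(e)) from e
    if done("lme"):
        return report

    # -- clusters ---------------------------------------------------------------
    try:
        acf = cl.estimate_acf(result.resid, brain_mask, grid)
        min_vox = cl.cluster_threshold_mc(brain_mask, acf, config.p_voxel, config.alpha,
                                          config.n_iter, seed=(seed ^ 0x5EED) & 0x7FFFFFFF,
                                          voxel_size=grid.voxel_size)
        cl.threshold_to_json(out / "cluster_threshold.json", p_voxel=config.p_voxel,
                             alpha=config.alpha, n_iter=config.n_iter,
                             min_cluster_voxels=min_vox, acf=acf)
        p3d = np.nan_to_num(result.to_map(result.pvalue("adl")), nan=1.0)
        t3d = np.nan_to_num(result.to_map(result.tvalue("adl")))
        adl_clusters = cl.extract_clusters(t3d, p3d, config.p_voxel, min_vox, grid,
                                           mask=brain_mask)
        log_stage("clusters", min_cluster_voxels=min_vox,
                  n_adl_clusters=len(adl_clusters),
                  acf_fwhm_mm=acf.equivalent_fwhm(float(np.mean(grid.voxel_size))))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("clusters", str(e)) from e
    report.min_cluster_voxels = min_vox
    report.acf = acf
    if done("clusters"):
        return report

    # -- report -----------------------------------------------------------------
    try:
        eta2_3d = result.to_map(eta2)
        sim_rows = []
        cluster_voxels_all = []
        for row in adl_clusters.itertuples():
            vox = np.asarray(row.voxels)
            cluster_voxels_all.append(vox)
            per_visit: dict[int, list[float]] = {}
            for m in sim_maps:
                vals = m.values[vox[:, 0], vox[:, 1], vox[:, 2]]
                per_visit.setdefault(m.visit, []).append(float(np.nanmean(vals)))
            entry = {
                "cluster_id": row.cluster_id,
                "x_rai_mm": row.x_rai_mm, "y_rai_mm": row.y_rai_mm,
                "z_rai_mm": row.z_rai_mm, "volume_mm3": row.volume_mm3,
                "eta2": float(np.nanmean(eta2_3d[vox[:, 0], vox[:, 1], vox[:, 2]])),
                "overlaps_lesion": bool(cohort.truth.lesion_mask[vox[:, 0], vox[:, 1],
                                                                 vox[:, 2]].any()),
                "voxels": row.voxels,
            }
            for ci, cmask in enumerate(cohort.truth.compensation_masks):
                entry[f"overlaps_compensation_{ci + 1}"] = bool(
                    cmask[vox[:, 0], vox[:, 1], vox[:, 2]].any())
            for visit in sorted(per_visit):
                z = float(np.mean(per_visit[visit]))
                entry[f"similarity_z_visit{visit}"] = z
                entry[f"similarity_r_visit{visit}"] = float(np.tanh(z))
            sim_rows.append(entry)
        table2 = pd.DataFrame(sim_rows)
        (table2.drop(columns="voxels") if "voxels" in table2 else table2).to_csv(
            out / "adl_clusters.tsv", sep="\t", index=False)
        paths["adl_clusters"] = str(out / "adl_clusters.tsv")

        # Fig-9-style bars: per-visit patient similarity in each cluster plus the
        # control reference (same statistic on matched-control runs, cluster seeds)
        bar_rows = []
        for row, vox in zip(adl_clusters.itertuples(), cluster_voxels_all):
            for m in sim_maps:
                vals = m.values[vox[:, 0], vox[:, 1], vox[:, 2]]
                bar_rows.append({"cluster_id": row.cluster_id, "condition": f"patient-{m.visit}",
                                 "subject_id": m.subject_id,
                                 "similarity_z": float(np.nanmean(vals))})
        n_ref = min(len(selected_controls), 10)  # control reference subsample
        for row, vox in zip(adl_clusters.itertuples(), cluster_voxels_all):
            for cid in selected_controls[:n_ref]:
                ctrl_map = similarity_map(control_cleans[cid], template, brain_mask,
                                          voxels=vox)
                vals = ctrl_map.values[vox[:, 0], vox[:, 1], vox[:, 2]]
                bar_rows.append({"cluster_id": row.cluster_id, "condition": "control",
                                 "subject_id": cid,
                                 "similarity_z": float(np.nanmean(vals))})
        bars = pd.DataFrame(bar_rows)
        if len(bars):
            bars = (bars.groupby(["cluster_id", "condition"])["similarity_z"]
                    .agg(["mean", "std", "count"]).reset_index())
        bars.to_csv(out / "similarity_by_visit.tsv", sep="\t", index=False)

        # adjusted group connectivity of each identified region at the
        # requested ADL levels (seed = cluster voxels; same LME machinery
        # with connectivity as the response)
        patient_clean_cache: list = []
        for pat in patients:
            for v in pat.visits:
                if v.visit in usable[pat.subject_id]:
                    run = cohort.run(pat.subject_id, v.visit)
                    patient_clean_cache.append(
                        (pat, v, clean_run(run, censors[(pat.subject_id, v.visit)],
                                           band=config.band, brain_mask=brain_mask,
                                           fwhm_mm=config.fwhm_mm)))
        from .lesion_network import seed_fc_map
        from .similarity import SimilarityMap

        adl_level_maps: dict[int, dict[float, np.ndarray]] = {}
        for row, vox in zip(adl_clusters.itertuples(), cluster_voxels_all):
            seed_mask = np.zeros(grid.shape, bool)
            seed_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            fc_maps = []
            for pat, v, pc in patient_clean_cache:
                fc = seed_fc_map(pc, seed_mask)
                fc_maps.append(SimilarityMap(
                    values=fc.values, mask=brain_mask, grid=grid,
                    subject_id=pat.subject_id, visit=v.visit,
                    covariates={"adl": v.adl, "age": pat.age,
                                "gender": pat.gender,
                                "motion": v.max_head_motion}))
            fc_fit = lme_mod.fit_voxel_lme(fc_maps, mask=brain_mask)
            pred = lme_mod.predicted_connectivity_at_adl(fc_fit,
                                                         levels=config.adl_levels)
            adl_level_maps[int(row.cluster_id)] = pred
            if config.write_maps:
                for lev, vals in pred.items():
                    vol = np.full(grid.shape, np.nan)
                    vol[brain_mask] = vals
                    save_nifti(np.nan_to_num(vol), grid,
                               out / f"cluster{row.cluster_id}_fc_adl{int(lev)}.nii.gz")
        report.adl_level_maps = adl_level_maps

        # §3.4-style control analysis: direct lesion FC with stringent LN cores
        core = threshold_ln(template, config.core_region_p, config.ln_min_cluster_mm3)
        if len(core):
            fc_summary, fc_tests = lme_mod.direct_fc_longitudinal(
                [pc for _, _, pc in patient_clean_cache], lesion_masks, core)
        else:
            fc_summary = pd.DataFrame(columns=["region_id", "visit", "mean_fc_z",
                                               "sd_fc_z", "n"])
            fc_tests = pd.DataFrame(columns=["region_id", "visit_coef", "visit_t", "visit_p"])
        fc_summary.to_csv(out / "direct_fc_by_visit.tsv", sep="\t", index=False)
        fc_tests.to_csv(out / "direct_fc_tests.tsv", sep="\t", index=False)

        report.adl_cluster_table = table2
        report.similarity_by_visit = bars
        report.direct_fc_summary = fc_summary
        report.direct_fc_tests = fc_tests
        summary = {
            "config_hash": chash, "seed": int(seed),
            "n_patients_usable": len(usable),
            "n_selected_controls": len(selected_controls),
            "n_fc_maps": len(stack),
            "min_cluster_voxels": min_vox,
            "n_adl_clusters": len(table2),
            "acf": {"a": acf.a, "b": acf.b, "c": acf.c},
            "stages": stage_log,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=1))
        paths["report"] = str(out / "report.json")
        log_stage("report", n_adl_clusters=len(table2))
        _write_manifest(out, chash, seed, stage_log)
        return report
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("report", str(e)) from e
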