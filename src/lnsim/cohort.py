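"""Synthetic stroke-rehabilitation cohort generator.

Emulates the study design the rest of the package analyses: a small group
of stroke patients scanned at three rehabilitation visits plus a pool of
healthy controls, all on a common low-resolution grid.  The simulated
brain carries a latent network of disjoint node regions sharing
band-limited latent time courses.  One node is the lesion: in patients it
emits pure noise ("not functioning"), in controls it functions normally.
One or more nodes are compensation regions whose latent mixing weights are
blended with the lesion node's weights by a per-visit similarity level
``s``; by construction the correlation between a compensation node's
noiseless signal and the lesion node's noiseless signal equals ``s``.
``s`` is tied linearly to the subject's ADL (activities of daily living)
score at each visit so that recovery (rising ADL) lowers the planted
network resemblance — the effect the downstream mixed-effects analysis is
meant to detect.

Every random quantity derives from one master seed; per-run seeds are
obtained by stable hashing of (subject_id, visit) so any single BOLD run
can be regenerated in isolation, bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MatchingInfeasibleError, PlacementError
from .grid import GridSpec, save_nifti

__all__ = [
    "NetworkSpec",
    "VisitRecord",
    "SubjectRecord",
    "BoldRun",
    "TruthTable",
    "CohortConfig",
    "SyntheticCohort",
    "generate_network_spec",
    "simulate_bold_run",
    "simulate_cohort",
    "simulate_motion_trace",
]

BAND_HZ = (0.01, 0.08)  # latent signal band; inside the analysis passband


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Latent network: disjoint node regions plus latent mixing weights."""

    grid: GridSpec
    node_regions: list[np.ndarray]  # each (n_i, 3) int voxel coordinates
    weights: np.ndarray  # (n_nodes, n_latent), unit-norm rows
    lesion_node: int
    compensation_nodes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.lesion_node in self.compensation_nodes:
            raise ValueError("lesion node cannot also be a compensation node")
        seen: set[tuple[int, int, int]] = set()
        for reg in self.node_regions:
            vox = {tuple(v) for v in np.asarray(reg)}
            if seen & vox:
                raise ValueError("node regions must be pairwise disjoint")
            seen |= vox

    @property
    def n_nodes(self) -> int:
        return len(self.node_regions)

    def node_mask(self, i: int) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        reg = np.asarray(self.node_regions[i])
        mask[reg[:, 0], reg[:, 1], reg[:, 2]] = True
        return mask


@dataclass
class VisitRecord:
    visit: int
    days_from_onset: float | None
    adl: float | None
    max_head_motion: float


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    age: float
    gender: str  # "male" | "female"
    site: str  # "local" | "remote"
    visits: list[VisitRecord]

    def __post_init__(self) -> None:
        n = len(self.visits)
        if self.group == "patient" and n != 3:
            raise ValueError(f"patients have exactly 3 visits, got {n}")
        if self.group == "control" and n != 1:
            raise ValueError(f"controls have exactly 1 visit, got {n}")
        for v in self.visits:
            if v.adl is not None and not (0.0 <= v.adl <= 100.0):
                raise ValueError(f"ADL outside [0, 100]: {v.adl}")

    @property
    def mean_max_motion(self) -> float:
        return float(np.mean([v.max_head_motion for v in self.visits]))


@dataclass
class BoldRun:
    """One subject-visit 4D time series with acquisition metadata."""

    data: np.ndarray  # (X, Y, Z, T)
    tr_seconds: float
    motion_trace: np.ndarray  # (T, 6): dx,dy,dz mm; rx,ry,rz deg
    outlier_fraction: np.ndarray  # (T,)
    subject_id: str
    visit: int
    grid: GridSpec

    def __post_init__(self) -> None:
        t = self.data.shape[-1]
        if t < 2:
            raise ValueError("a BOLD run needs at least 2 timepoints")
        if self.motion_trace.shape != (t, 6):
            raise ValueError("motion trace must be (T, 6)")
        if self.outlier_fraction.shape != (t,):
            raise ValueError("outlier fraction must be (T,)")
        for name, arr in (("data", self.data), ("motion", self.motion_trace),
                          ("outliers", self.outlier_fraction)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[-1])


@dataclass
class TruthTable:
    """Ground truth planted by the generator, for validating the analysis."""

    lesion_mask: np.ndarray  # bool 3D (union over patients)
    compensation_masks: list[np.ndarray]  # bool 3D per compensation node
    similarity: dict[tuple[str, int], float]  # (subject_id, visit) -> s
    adl: dict[tuple[str, int], float]
    similarity_adl_slope: float  # d s / d ADL (0 when schedule is constant)
    similarity_anchors: tuple[float, float]
    control_similarity: float
    lesion_activity_by_visit: tuple[float, float, float]

    @property
    def planted_adl_effect_is_zero(self) -> bool:
        return self.similarity_adl_slope == 0.0

    def to_json(self, path) -> None:
        def mask_to_list(m: np.ndarray) -> list[list[int]]:
            return np.argwhere(m).tolist()

        payload = {
            "lesion_mask_voxels": mask_to_list(self.lesion_mask),
            "compensation_mask_voxels": [mask_to_list(m) for m in self.compensation_masks],
            "similarity": {f"{sid}|{v}": s for (sid, v), s in self.similarity.items()},
            "adl": {f"{sid}|{v}": a for (sid, v), a in self.adl.items()},
            "similarity_adl_slope": self.similarity_adl_slope,
            "similarity_anchors": list(self.similarity_anchors),
            "control_similarity": self.control_similarity,
            "lesion_activity_by_visit": list(self.lesion_activity_by_visit),
            "shape": list(self.lesion_mask.shape),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study-design parameters.

    Defaults reproduce the emulated study conditions: 17 patients scanned
    three times (TR = 3 s, 130 volumes) with ADL rising on average
    32.2 → 75.3 → 88.4 across visits, a control pool large enough for
    3:1 matching, and planted compensation-to-lesion similarity decaying
    from 0.75 (at the visit-1 mean ADL) to 0.40 (at the visit-3 mean ADL).
    """

    n_patients: int = 17
    pool_local: int = 24
    pool_remote: int = 96
    grid: GridSpec = field(default_factory=GridSpec)
    n_nodes: int = 10
    n_latent: int = 16
    node_radius_mm: float = 6.0
    lesion_radius_mm: float = 4.0
    compensation_radius_mm: float | None = None
    n_compensation: int = 2
    lesion_overlap_range: tuple[float, float] = (0.35, 0.8)
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    adl_means: tuple[float, float, float] = (32.2, 75.3, 88.4)
    adl_sds: tuple[float, float, float] = (6.3, 18.2, 16.8)
    days_means: tuple[float, float, float] = (2.0, 104.6, 210.3)
    days_sds: tuple[float, float, float] = (0.9, 11.7, 14.2)
    patient_age_mean: float = 63.2
    patient_age_sd: float = 9.1
    control_age_mean: float = 61.0
    control_age_sd: float = 14.3
    patient_female_frac: float = 4.0 / 17.0
    control_female_frac: float = 19.0 / 51.0
    patient_motion_mean: float = 0.79
    patient_motion_sd: float = 0.64
    control_motion_mean: float = 0.59
    control_motion_sd: float = 0.39
    similarity_anchors: tuple[float, float] = (0.75, 0.40)
    constant_similarity: bool = False
    control_similarity: float = 0.0
    lesion_activity_by_visit: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 1.0
    signal_sd: float = 2.0
    qc_violation_fraction: float = 0.0
    outlier_spike_prob: float = 0.01
    matching_k: int = 3

    @property
    def pool_size(self) -> int:
        return self.pool_local + self.pool_remote

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.pool_size < self.matching_k * self.n_patients:
            raise MatchingInfeasibleError(
                f"pool of {self.pool_size} controls cannot supply "
                f"{self.matching_k} distinct matches for {self.n_patients} patients"
            )
        if self.n_nodes < 3:
            raise ValueError("need at least 3 network nodes (lesion + compensation + other)")
        if not (0 <= self.n_compensation <= self.n_nodes - 1):
            raise ValueError("invalid number of compensation nodes")

    def similarity_at_adl(self, adl: float) -> float:
        """Planted similarity level as a linear function of ADL, clipped to [0, 1]."""
        s1, s3 = self.similarity_anchors
        if self.constant_similarity:
            return float(np.clip(s1, 0.0, 1.0))
        a1, _, a3 = self.adl_means
        slope = (s3 - s1) / (a3 - a1)
        return float(np.clip(s1 + slope * (adl - a1), 0.0, 1.0))

    @property
    def similarity_adl_slope(self) -> float:
        if self.constant_similarity:
            return 0.0
        s1, s3 = self.similarity_anchors
        a1, _, a3 = self.adl_means
        return (s3 - s1) / (a3 - a1)


# ---------------------------------------------------------------------------
# seeding helpers
# ---------------------------------------------------------------------------


def _stable_id(subject_id: str) -> int:
    """Deterministic, platform-independent 31-bit hash of a subject id."""
    return zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF


def run_seed_sequence(master_seed: int, subject_id: str, visit: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, _stable_id(subject_id), int(visit)])


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def generate_network_spec(
    grid: GridSpec,
    n_nodes: int,
    seed: int,
    *,
    n_latent: int = 12,
    node_radius_mm: float = 6.0,
    lesion_radius_mm: float | None = 4.0,
    compensation_radius_mm: float | None = None,
    n_compensation: int = 2,
    lesion_overlap_range: tuple[float, float] = (0.35, 0.8),
    brain_mask: np.ndarray | None = None,
) -> NetworkSpec:
    """Place ``n_nodes`` disjoint spherical node regions inside the brain mask.

    Node 0 is the lesion node; nodes 1..n_compensation are compensation
    nodes whose latent weights are orthogonalised against the lesion
    node's so the planted similarity level maps exactly onto noiseless
    signal correlation.  Deterministic for a fixed seed.

    Raises
    ------
    PlacementError
        If the grid cannot host the requested number of disjoint regions.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA11CE]))
    if brain_mask is None:
        brain_mask = grid.brain_mask()
    if lesion_radius_mm is None:
        lesion_radius_mm = node_radius_mm
    if compensation_radius_mm is None:
        compensation_radius_mm = node_radius_mm

    def sphere_offsets(radius_mm: float) -> np.ndarray:
        r_vox = np.asarray([radius_mm / v for v in grid.voxel_size])
        rad_int = np.floor(r_vox).astype(int)
        offs = np.argwhere(np.ones(2 * rad_int + 1, dtype=bool)) - rad_int
        inside = np.sum((offs / np.maximum(r_vox, 1e-12)) ** 2, axis=1) <= 1.0
        return offs[inside]

    def radius_for(i: int) -> float:
        if i == 0:
            return lesion_radius_mm
        if i <= n_compensation:
            return compensation_radius_mm
        return node_radius_mm

    offsets = [sphere_offsets(radius_for(i)) for i in range(n_nodes)]

    # candidate centres: sphere fully inside the brain mask, regions disjoint
    candidates = np.argwhere(brain_mask)
    rng.shuffle(candidates)
    shape = np.asarray(grid.shape)
    r_sep = np.asarray([node_radius_mm / v for v in grid.voxel_size])
    min_sep2 = float(np.sum((2 * r_sep + 1) ** 2)) / 3.0  # mean-axis separation
    centres: list[np.ndarray] = []
    for c in candidates:
        offs = offsets[len(centres)]
        vox = c + offs
        if np.any(vox < 0) or np.any(vox >= shape):
            continue
        if not brain_mask[vox[:, 0], vox[:, 1], vox[:, 2]].all():
            continue
        if any(float(np.sum((c - p) ** 2)) < min_sep2 for p in centres):
            continue
        centres.append(c)
        if len(centres) == n_nodes:
            break
    if len(centres) < n_nodes:
        raise PlacementError(
            f"could only place {len(centres)} of {n_nodes} disjoint node regions "
            f"of radius {node_radius_mm} mm on grid {grid.shape}"
        )

    regions = [np.asarray(c + offsets[i], dtype=int) for i, c in enumerate(centres)]

    weights = rng.standard_normal((n_nodes, n_latent))
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)
    w_lesion = weights[0]

    def perp_unit(w: np.ndarray) -> np.ndarray:
        w = w - np.dot(w, w_lesion) * w_lesion
        nrm = np.linalg.norm(w)
        while nrm < 1e-8:  # pathologically parallel draw; replace
            w = rng.standard_normal(n_latent)
            w -= np.dot(w, w_lesion) * w_lesion
            nrm = np.linalg.norm(w)
        return w / nrm

    # compensation nodes: own weights orthogonal to the lesion's, so the
    # per-visit blend s*w_lesion + sqrt(1-s^2)*w_own has signal correlation
    # exactly s with the lesion node
    for i in range(1, 1 + n_compensation):
        weights[i] = perp_unit(weights[i])
    # remaining nodes are the lesion's network: genuinely connected to the
    # lesion node with overlap rho, so the group lesion-seed map carries an
    # extended spatial pattern for the similarity statistic to recover
    for i in range(1 + n_compensation, n_nodes):
        rho = rng.uniform(*lesion_overlap_range)
        weights[i] = rho * w_lesion + np.sqrt(1.0 - rho ** 2) * perp_unit(weights[i])

    return NetworkSpec(
        grid=grid,
        node_regions=regions,
        weights=weights,
        lesion_node=0,
        compensation_nodes=tuple(range(1, 1 + n_compensation)),
    )


# ---------------------------------------------------------------------------
# time-series simulation
# ---------------------------------------------------------------------------


def _band_limited_signals(rng: np.random.Generator, n: int, t: int, tr: float,
                          band: tuple[float, float] = BAND_HZ) -> np.ndarray:
    """n unit-variance Gaussian time courses with power confined to ``band``."""
    freqs = np.fft.rfftfreq(t, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # very short runs: keep the lowest nonzero frequency
        keep = np.zeros_like(freqs, dtype=bool)
        keep[min(1, len(freqs) - 1)] = True
    coef = np.zeros((n, freqs.size), dtype=complex)
    k = int(keep.sum())
    coef[:, keep] = rng.standard_normal((n, k)) + 1j * rng.standard_normal((n, k))
    sig = np.fft.irfft(coef, n=t, axis=1)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def simulate_motion_trace(rng: np.random.Generator, t: int, target_mm: float) -> np.ndarray:
    """Random-walk 6-parameter trace scaled to an exact max pairwise displacement.

    Columns are dx, dy, dz in mm and rx, ry, rz in degrees.  The scaling
    target is the maximum pairwise Euclidean norm of parameter differences
    after converting rotations to mm of arc on a 50 mm sphere.
    """
    from .qc import ROTATION_RADIUS_MM, motion_trace_to_mm

    steps = rng.standard_normal((t, 6))
    steps[0] = 0.0
    # rotations drawn so their mm-equivalent step size matches translations
    deg_per_mm = np.degrees(1.0 / ROTATION_RADIUS_MM)
    steps[:, 3:] *= deg_per_mm
    trace = np.cumsum(steps, axis=0)
    mm = motion_trace_to_mm(trace)
    span = _max_pairwise_norm(mm)
    if span > 0:
        trace *= target_mm / span
    return trace


def _max_pairwise_norm(points: np.ndarray) -> float:
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def simulate_bold_run(
    spec: NetworkSpec,
    subject: SubjectRecord,
    visit: int,
    seed: int,
    *,
    n_timepoints: int = 130,
    tr_seconds: float = 3.0,
    similarity: float = 0.0,
    lesion_activity: float | None = None,
    noise_sd: float = 1.0,
    signal_sd: float = 1.0,
    motion_target_mm: float | None = None,
    outlier_spike_prob: float = 0.01,
) -> BoldRun:
    """Simulate one subject-visit BOLD run on the network ``spec``.

    Node voxels carry the node's latent mixture plus white noise.
    Compensation nodes blend the lesion node's weights with their own
    (orthogonal) weights as ``s*w_lesion + sqrt(1-s^2)*w_own`` so the
    noiseless compensation/lesion signal correlation equals ``s`` exactly.
    Patients' lesion-node voxels emit pure noise unless a nonzero
    ``lesion_activity`` re-injects a scaled lesion signal (used for
    longitudinal direct-connectivity experiments).
    """
    visits = [v.visit for v in subject.visits]
    if visit not in visits:
        raise ValueError(f"visit {visit} not valid for {subject.group} {subject.subject_id}")
    vrec = subject.visits[visits.index(visit)]

    rng = np.random.default_rng(run_seed_sequence(seed, subject.subject_id, visit))
    t = int(n_timepoints)
    latents = _band_limited_signals(rng, spec.weights.shape[1], t, tr_seconds)

    data = noise_sd * rng.standard_normal(spec.grid.shape + (t,))
    s = float(np.clip(similarity, 0.0, 1.0))
    if lesion_activity is None:
        lesion_activity = 0.0 if subject.group == "patient" else 1.0

    for i, region in enumerate(spec.node_regions):
        if i == spec.lesion_node:
            w = lesion_activity * spec.weights[spec.lesion_node]
            if lesion_activity == 0.0:
                continue  # lesion not functioning: pure noise
        elif i in spec.compensation_nodes:
            w = s * spec.weights[spec.lesion_node] + np.sqrt(1.0 - s ** 2) * spec.weights[i]
        else:
            w = spec.weights[i]
        sig = w @ latents
        reg = np.asarray(region)
        data[reg[:, 0], reg[:, 1], reg[:, 2], :] += signal_sd * sig

    target = motion_target_mm if motion_target_mm is not None else vrec.max_head_motion
    motion = simulate_motion_trace(rng, t, float(target))
    outliers = rng.beta(1.0, 400.0, size=t)
    spikes = rng.random(t) < outlier_spike_prob
    outliers[spikes] = rng.uniform(0.12, 0.35, size=int(spikes.sum()))

    return BoldRun(
        data=data,
        tr_seconds=tr_seconds,
        motion_trace=motion,
        outlier_fraction=outliers,
        subject_id=subject.subject_id,
        visit=visit,
        grid=spec.grid,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


class SyntheticCohort:
    """A simulated cohort: subject records, ground truth, and lazy BOLD runs.

    BOLD runs are generated on demand from per-run seeds; the same
    (master seed, subject, visit) always yields a bit-identical run.
    """

    def __init__(self, config: CohortConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = int(seed) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC0117]))

        self.network = generate_network_spec(
            config.grid,
            config.n_nodes,
            self.seed,
            n_latent=config.n_latent,
            node_radius_mm=config.node_radius_mm,
            lesion_radius_mm=config.lesion_radius_mm,
            compensation_radius_mm=config.compensation_radius_mm,
            n_compensation=config.n_compensation,
            lesion_overlap_range=config.lesion_overlap_range,
        )

        self.records: list[SubjectRecord] = []
        similarity: dict[tuple[str, int], float] = {}
        adl_truth: dict[tuple[str, int], float] = {}

        for p in range(config.n_patients):
            sid = f"P{p + 1:03d}"
            age = float(_truncated_normal(rng, config.patient_age_mean, config.patient_age_sd, 30, 95))
            gender = "female" if rng.random() < config.patient_female_frac else "male"
            adls = np.sort(np.clip(rng.normal(config.adl_means, config.adl_sds), 0.0, 100.0))
            days = np.sort(_truncated_normal(rng, np.asarray(config.days_means),
                                             np.asarray(config.days_sds), 0.5, 400))
            visits = []
            for v in range(3):
                motion = self._draw_motion_target(rng, config.patient_motion_mean,
                                                 config.patient_motion_sd,
                                                 config.qc_violation_fraction)
                visits.append(VisitRecord(visit=v + 1, days_from_onset=float(days[v]),
                                          adl=float(adls[v]), max_head_motion=motion))
                similarity[(sid, v + 1)] = config.similarity_at_adl(float(adls[v]))
                adl_truth[(sid, v + 1)] = float(adls[v])
            self.records.append(SubjectRecord(sid, "patient", age, gender, "local", visits))

        for c in range(config.pool_size):
            sid = f"C{c + 1:04d}"
            site = "local" if c < config.pool_local else "remote"
            age = float(_truncated_normal(rng, config.control_age_mean, config.control_age_sd, 20, 95))
            gender = "female" if rng.random() < config.control_female_frac else "male"
            motion = self._draw_motion_target(rng, config.control_motion_mean,
                                              config.control_motion_sd,
                                              config.qc_violation_fraction)
            visits = [VisitRecord(visit=1, days_from_onset=None, adl=None, max_head_motion=motion)]
            self.records.append(SubjectRecord(sid, "control", age, gender, site, visits))
            similarity[(sid, 1)] = config.control_similarity

        comp_masks = [self.network.node_mask(i) for i in self.network.compensation_nodes]
        self.truth = TruthTable(
            lesion_mask=self.network.node_mask(self.network.lesion_node),
            compensation_masks=comp_masks,
            similarity=similarity,
            adl=adl_truth,
            similarity_adl_slope=config.similarity_adl_slope,
            similarity_anchors=config.similarity_anchors,
            control_similarity=config.control_similarity,
            lesion_activity_by_visit=config.lesion_activity_by_visit,
        )

    @staticmethod
    def _draw_motion_target(rng, mean, sd, violation_frac) -> float:
        if rng.random() < violation_frac:
            return float(rng.uniform(2.1, 3.5))
        return float(np.clip(abs(rng.normal(mean, sd)), 0.05, 1.9))

    # -- access -------------------------------------------------------------

    @property
    def patients(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == "patient"]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == "control"]

    def record(self, subject_id: str) -> SubjectRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    def lesion_mask(self, patient_id: str) -> np.ndarray:
        """Lesion mask for one patient (the shared contiguous lesion region)."""
        self.record(patient_id)  # existence check
        return self.truth.lesion_mask

    @property
    def lesion_masks(self) -> dict[str, np.ndarray]:
        return {p.subject_id: self.lesion_mask(p.subject_id) for p in self.patients}

    def run(self, subject_id: str, visit: int = 1) -> BoldRun:
        """Generate (deterministically) the BOLD run for one subject-visit."""
        rec = self.record(subject_id)
        cfg = self.config
        vidx = visit - 1
        lesion_activity = None
        if rec.group == "patient":
            lesion_activity = cfg.lesion_activity_by_visit[vidx]
        return simulate_bold_run(
            self.network,
            rec,
            visit,
            self.seed,
            n_timepoints=cfg.n_timepoints,
            tr_seconds=cfg.tr_seconds,
            similarity=self.truth.similarity[(subject_id, visit)],
            lesion_activity=lesion_activity,
            noise_sd=cfg.noise_sd,
            signal_sd=cfg.signal_sd,
            outlier_spike_prob=cfg.outlier_spike_prob,
        )

    def iter_runs(self, group: str | None = None):
        for rec in self.records:
            if group is not None and rec.group != group:
                continue
            for v in rec.visits:
                yield self.run(rec.subject_id, v.visit)

    # -- export -------------------------------------------------------------

    def covariate_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for v in r.visits:
                rows.append({
                    "subject_id": r.subject_id, "group": r.group, "age": r.age,
                    "gender": r.gender, "site": r.site, "visit": v.visit,
                    "days_from_onset": v.days_from_onset, "ADL": v.adl,
                    "max_head_motion": v.max_head_motion,
                })
        return pd.DataFrame(rows)

    def write(self, outdir, *, runs: bool = False, subjects: list[str] | None = None) -> None:
        """Write covariates (TSV), masks + optionally BOLD runs (NIfTI-1), truth (JSON)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariate_table().to_csv(out / "covariates.tsv", sep="\t", index=False)
        save_nifti(self.truth.lesion_mask.astype(float), self.config.grid, out / "lesion_mask.nii.gz")
        for i, m in enumerate(self.truth.compensation_masks):
            save_nifti(m.astype(float), self.config.grid, out / f"compensation_mask_{i + 1}.nii.gz")
        save_nifti(self.config.grid.brain_mask().astype(float), self.config.grid,
                   out / "brain_mask.nii.gz")
        self.truth.to_json(out / "truth.json")
        if runs:
            wanted = set(subjects) if subjects is not None else None
            for rec in self.records:
                if wanted is not None and rec.subject_id not in wanted:
                    continue
                for v in rec.visits:
                    run = self.run(rec.subject_id, v.visit)
                    stem = f"{rec.subject_id}_visit{v.visit}"
                    save_nifti(run.data, self.config.grid, out / f"{stem}_bold.nii.gz")
                    np.savetxt(out / f"{stem}_motion.tsv", run.motion_trace, delimiter="\t",
                               header="dx\tdy\tdz\trx\try\trz", comments="")
                    np.savetxt(out / f"{stem}_outliers.tsv", run.outlier_fraction[:, None],
                               delimiter="\t", header="outlier_fraction", comments="")


def simulate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Build the synthetic cohort (records + truth; runs generated lazily)."""
    return SyntheticCohort(config, seed)
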