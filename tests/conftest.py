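"""Shared fixtures: a small synthetic cohort and derived analysis objects.

Everything is generated at test time from fixed seeds; session scope keeps
the expensive objects (cleaned runs, LN template) shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from lnsim.cohort import CohortConfig, simulate_cohort
from lnsim.grid import GridSpec
from lnsim.lesion_network import build_fc_stack, derive_ln_template
from lnsim.qc import build_censor, clean_run


SMALL_GRID = GridSpec((14, 16, 14))


def small_cohort_config(**overrides) -> CohortConfig:
    base = dict(
        grid=SMALL_GRID,
        n_patients=6,
        pool_local=6,
        pool_remote=18,
        n_nodes=9,
        node_radius_mm=5.0,
        lesion_radius_mm=3.5,
        n_compensation=2,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return SMALL_GRID


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_cohort_config(), seed=11)


def clean(cohort, subject_id: str, visit: int, fwhm: float | None = 5.0):
    run = cohort.run(subject_id, visit)
    cen = build_censor(run.motion_trace, run.outlier_fraction)
    return clean_run(run, cen, brain_mask=cohort.config.grid.brain_mask(), fwhm_mm=fwhm)


@pytest.fixture(scope="session")
def small_template(small_cohort):
    """LN template from the first 12 pool controls of the small cohort."""
    cleans = {c.subject_id: clean(small_cohort, c.subject_id, 1)
              for c in small_cohort.controls[:12]}
    records = {c.subject_id: c for c in small_cohort.controls}
    stack = build_fc_stack(cleans, records, small_cohort.patients,
                           small_cohort.lesion_masks)
    return derive_ln_template(stack)


def lme_design(rng: np.random.Generator, n_subjects: int = 17):
    """A study-shaped fixed-effects design: 3 visits, rising ADL, covariates."""
    groups = np.repeat([f"S{i:02d}" for i in range(n_subjects)], 3)
    adl = np.concatenate([
        np.sort(np.clip(rng.normal([32.2, 75.3, 88.4], [6.3, 18.2, 16.8]), 0, 100))
        for _ in range(n_subjects)
    ])
    age = np.repeat(rng.normal(63.2, 9.1, n_subjects), 3)
    gender = np.repeat(rng.integers(0, 2, n_subjects), 3).astype(float)
    motion = rng.uniform(0.1, 1.5, n_subjects * 3)
    exog = np.column_stack([np.ones(n_subjects * 3), adl, age - age.mean(),
                            gender, motion - motion.mean()])
    return exog, groups


LME_NAMES = ["const", "adl", "age", "gender", "motion"]
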