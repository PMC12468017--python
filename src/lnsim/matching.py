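"""Propensity-score matching of healthy controls to patients.

Each patient is matched to k controls (default 3) by a logistic
propensity model of group membership on age, gender, and maximum head
motion (patients contribute their motion averaged across the three
scans).  Matching is greedy nearest-neighbour on the absolute propensity
score difference, without replacement, processing patients in ascending
subject id and breaking ties by ascending control id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import MatchingInfeasibleError

__all__ = ["PropensityModel", "fit_propensity", "match_controls"]

GENDER_CODE = {"male": 0.0, "female": 1.0}
_COVARIATES = ("age", "gender", "max_head_motion")


@dataclass
class PropensityModel:
    """Fitted logistic propensity model and per-subject scores."""

    coefficients: dict[str, float]  # intercept + covariate coefficients
    scores: dict[str, float]  # subject_id -> fitted probability of being a patient
    method: str  # "mle" or "ridge"

    def score(self, subject_id: str) -> float:
        return self.scores[subject_id]


def _covariate_row(rec: SubjectRecord) -> list[float]:
    return [rec.age, GENDER_CODE[rec.gender], rec.mean_max_motion]


def _ridge_logit(x: np.ndarray, y: np.ndarray, alpha: float = 1.0,
                 max_iter: int = 200) -> np.ndarray:
    """Newton solver for L2-penalised logistic regression (intercept unpenalised)."""
    n, p = x.shape
    beta = np.zeros(p)
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu) - pen @ beta
        hess = (x * w[:, None]).T @ x + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def fit_propensity(patients: list[SubjectRecord], pool: list[SubjectRecord]) -> PropensityModel:
    """Fit the logistic propensity model of patient membership.

    Constant covariate columns are dropped (their coefficient reported as
    0).  Perfect separation triggers a ridge-penalised refit with a
    warning rather than a failure.
    """
    if not pool:
        raise ValueError("control pool is empty")
    subjects = list(patients) + list(pool)
    x_raw = np.asarray([_covariate_row(r) for r in subjects], dtype=float)
    y = np.asarray([1.0 if r.group == "patient" else 0.0 for r in subjects])

    variable = [j for j in range(x_raw.shape[1]) if np.ptp(x_raw[:, j]) > 0]
    x = np.column_stack([np.ones(len(subjects)), x_raw[:, variable]])

    import statsmodels.api as sm

    method = "mle"
    beta = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=200, method="newton")
            beta = np.asarray(res.params)
            probs = 1.0 / (1.0 + np.exp(-(x @ beta)))
            separated = probs[y == 1].min() > 1 - 1e-6 and probs[y == 0].max() < 1e-6
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e3 or separated:
                beta = None
        except Exception:
            beta = None
    if beta is None:
        warnings.warn("propensity model separated or failed to converge; "
                      "falling back to ridge-penalised fit", stacklevel=2)
        method = "ridge"
        beta = _ridge_logit(x, y)

    names = ["intercept"] + [_COVARIATES[j] for j in variable]
    coefficients = {name: 0.0 for name in ("intercept",) + _COVARIATES}
    for name, b in zip(names, beta):
        coefficients[name] = float(b)

    scores = 1.0 / (1.0 + np.exp(-(x @ beta)))
    score_map = {r.subject_id: float(s) for r, s in zip(subjects, scores)}
    return PropensityModel(coefficients=coefficients, scores=score_map, method=method)


def match_controls(
    model: PropensityModel,
    patients: list[SubjectRecord],
    pool: list[SubjectRecord],
    k: int = 3,
) -> pd.DataFrame:
    """Greedy 1:k nearest-neighbour matching without replacement.

    Returns a DataFrame with columns patient_id, control_id,
    score_distance — one row per selected control.
    """
    if len(pool) < k * len(patients):
        raise MatchingInfeasibleError(
            f"pool of {len(pool)} cannot supply {k} distinct controls "
            f"for {len(patients)} patients"
        )
    remaining = sorted((c.subject_id for c in pool))
    rows = []
    for pat in sorted(patients, key=lambda r: r.subject_id):
        ps = model.score(pat.subject_id)
        ranked = sorted(remaining, key=lambda cid: (abs(model.score(cid) - ps), cid))
        chosen = ranked[:k]
        for cid in chosen:
            rows.append({
                "patient_id": pat.subject_id,
                "control_id": cid,
                "score_distance": abs(model.score(cid) - ps),
            })
            remaining.remove(cid)
    return pd.DataFrame(rows)
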