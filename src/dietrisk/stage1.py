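"""Stage 1: confounder-adjusted Cox proportional-hazards fits per nutrient.

One Cox model is fitted per (nutrient, patient group): the scaled nutrient
intake plus the 19 adjustment covariates (serum chemistry, vitals, diabetes,
BMI). The model reports the hazard ratio per scaled unit with its Wald 95%
CI and P value, and yields per-patient dietary risk scores

    s_i = exp(eta_i - mean(eta)),

the exponentiated mean-centered full linear predictor, so the geometric
mean of s is 1 and s_i < 1 reads "below the group's average predicted
risk". The (intake, score) pairs per patient are the input of stage 2.

Ties in event times are handled with the Efron correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cohort import CONFOUNDERS
from .errors import CovariateError, FittingError
from .stratify import SubtypeAssignment

__all__ = ["UNIT_SCALES", "CoxFit", "CoxResult", "RiskPairSet",
           "fit_cox", "nutrient_hr", "risk_scores", "build_risk_pairs"]

#: intake rescaling used for reporting hazard ratios (raw units / scale)
UNIT_SCALES: dict[str, float] = {
    "Water": 100.0, "Fat": 10.0, "Calories": 10.0, "K": 10.0, "Na": 100.0,
    "Mg": 10.0, "Ca": 100.0, "P": 10.0, "Retinol": 10.0, "Vitamin A": 100.0,
    "Carotene": 100.0, "DPI": 0.1,
}


@dataclass
class CoxFit:
    params: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    columns: tuple[str, ...]


@dataclass
class CoxResult:
    nutrient: str
    group: str
    unit_scale: float
    hr: float
    ci95: tuple[float, float]
    p_wald: float
    fit: CoxFit


@dataclass
class RiskPairSet:
    nutrient: str
    group: str
    pairs: pd.DataFrame  # columns: intake, score


def fit_cox(T, event, covariates: pd.DataFrame) -> CoxFit:
    """Maximize the Efron-corrected Cox partial likelihood.

    Returns the MLE, the inverse observed information as covariance, and
    the maximized partial log-likelihood.
    """
    T = np.asarray(T, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise FittingError("no events: Cox model is degenerate")
    X = covariates.astype(float)
    bad = [c for c in X.columns if not np.isfinite(X[c]).all()]
    if bad:
        raise FittingError(f"non-finite covariate values in {bad}")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise FittingError(f"constant covariate column {const}")
    df = X.copy()
    df["_T"] = T
    df["_E"] = event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # tight step tolerance so small-sample MLEs agree with a direct
            # partial-likelihood search to ~1e-6
            cph.fit(df, duration_col="_T", event_col="_E",
                    fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise FittingError(f"Cox fit did not converge: {exc}") from exc
    return CoxFit(
        params=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        log_likelihood=float(cph.log_likelihood_),
        columns=tuple(X.columns),
    )


def _design(profiles: pd.DataFrame, nutrient: str, confounders, unit_scale: float):
    missing = [c for c in [nutrient, *confounders] if c not in profiles.columns]
    if missing:
        raise CovariateError(f"profiles lack required columns {missing}")
    X = profiles[[nutrient, *confounders]].copy()
    X[nutrient] = X[nutrient] / unit_scale
    return X


def nutrient_hr(
    profiles: pd.DataFrame,
    nutrient: str,
    group: str = "all",
    assignment: SubtypeAssignment | None = None,
    confounders=CONFOUNDERS,
    unit_scale: float | None = None,
) -> CoxResult:
    """Scaled hazard ratio of one nutrient in one albumin group (or 'all')."""
    if unit_scale is None:
        unit_scale = UNIT_SCALES.get(nutrient, 1.0)
    sub = profiles
    if group != "all":
        if assignment is None:
            raise CovariateError("group-specific fit needs a SubtypeAssignment")
        sub = profiles[profiles["patient_id"].isin(assignment.ids_for(group))]
    X = _design(sub, nutrient, confounders, unit_scale)
    if len(sub) <= len(X.columns) + 2:
        raise FittingError(
            f"group {group!r} has {len(sub)} patients for {len(X.columns)} covariates; "
            "reduce the confounder set"
        )
    fit = fit_cox(sub["T"], sub["event"], X)
    beta = float(fit.params[nutrient])
    se = float(np.sqrt(fit.covariance.loc[nutrient, nutrient]))
    from scipy import stats as sps

    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    p = float(2 * sps.norm.sf(abs(beta) / se))
    return CoxResult(nutrient, group, unit_scale, hr, ci, p, fit)


def risk_scores(fit: CoxFit, profiles: pd.DataFrame, nutrient: str,
                confounders=CONFOUNDERS, unit_scale: float = 1.0) -> pd.Series:
    """Per-patient dietary evaluation score s = exp(eta - mean(eta))."""
    X = _design(profiles, nutrient, confounders, unit_scale)
    if tuple(X.columns) != fit.columns:
        raise CovariateError(
            f"covariate schema mismatch: model {fit.columns}, data {tuple(X.columns)}"
        )
    eta = X.to_numpy() @ fit.params.to_numpy()
    s = np.exp(eta - eta.mean())
    return pd.Series(s, index=profiles.index, name="score")


def build_risk_pairs(
    profiles: pd.DataFrame, scores: pd.Series, nutrient: str, group: str = "all"
) -> RiskPairSet:
    """(intake, score) pairs, one per patient, consumed by stage 2."""
    if len(profiles) == 0:
        raise FittingError(f"empty group {group!r}: no risk pairs")
    if not profiles.index.equals(scores.index):
        raise CovariateError("scores are not aligned with profiles")
    pairs = pd.DataFrame({
        "intake": profiles[nutrient].to_numpy(dtype=float),
        "score": scores.to_numpy(dtype=float),
    })
    return RiskPairSet(nutrient, group, pairs)
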