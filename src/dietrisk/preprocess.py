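"""Time-averaged exposure profiles from raw longitudinal tables.

Each patient's follow-up is segmented into fixed-length windows anchored at
their own entry ([0,w), [w,2w), ...). Records inside a window are averaged,
empty windows are discarded rather than zero-filled, and the window means
are then averaged again. This two-level mean deliberately differs from the
pooled mean of all raw records: it weights sparse late follow-up equally
with dense early follow-up.

Lab values are imputed by last observation carried forward (LOCF) before
windowing; dietary records are never imputed — a missing dietary follow-up
simply contributes nothing to its window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import LongitudinalCohort, LAB_FEATURES, NUTRIENTS
from .errors import DietriskError

logger = logging.getLogger(__name__)

__all__ = [
    "locf_impute",
    "window_average",
    "patient_time_average",
    "ideal_body_weight",
    "derive_dpi_dei",
    "build_profiles",
]


def locf_impute(records: pd.DataFrame, time_col: str = "month") -> pd.DataFrame:
    """Fill missing values from the most recent earlier observation.

    ``records`` must be one patient's visits, sorted by ``time_col``.
    Values before the first observation of a feature stay missing; observed
    values are never altered.
    """
    t = records[time_col].to_numpy()
    if np.any(np.diff(t) < 0):
        raise DietriskError("locf_impute requires records sorted by time")
    out = records.copy()
    value_cols = [c for c in records.columns if c not in (time_col, "patient_id")]
    out[value_cols] = out[value_cols].ffill()
    return out


def window_average(
    records: pd.DataFrame, window_length: float, time_col: str = "month"
) -> pd.DataFrame:
    """Per-window means over half-open windows [k*w, (k+1)*w).

    Windows containing no records are omitted. Missing values are excluded
    feature-wise from each window's mean. Returns a frame indexed by window
    ordinal with one column per feature; empty input gives an empty frame.
    """
    if not window_length > 0:
        raise DietriskError("window_length must be positive")
    value_cols = [c for c in records.columns if c not in (time_col, "patient_id")]
    if len(records) == 0:
        return pd.DataFrame(columns=value_cols)
    win = np.floor(records[time_col].to_numpy() / window_length).astype(int)
    return records[value_cols].groupby(win).mean()


def patient_time_average(window_means: pd.DataFrame | pd.Series) -> pd.Series:
    """Unweighted mean of the window means (the second averaging level)."""
    if isinstance(window_means, pd.Series):
        return pd.Series({"value": window_means.mean()})
    return window_means.mean()


def ideal_body_weight(height_cm: float) -> float:
    """Modified Broca ideal body weight: height in cm minus 105."""
    if not height_cm > 105:
        raise DietriskError(f"ideal body weight undefined for height {height_cm} cm (<= 105)")
    return height_cm - 105.0


def derive_dpi_dei(
    avg_protein: float, avg_calories: float, ibw: float
) -> tuple[float, float]:
    """Protein (g/kg/d) and energy (kcal/kg/d) intake normalized by ideal body weight."""
    if not ibw > 0:
        raise DietriskError(f"ideal body weight must be positive, got {ibw}")
    return avg_protein / ibw, avg_calories / ibw


def build_profiles(
    cohort: LongitudinalCohort, window_length: float = 6.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One time-averaged profile per eligible patient.

    Labs go through LOCF -> window means -> overall mean; nutrients skip
    LOCF. DPI/DEI are appended from the averaged protein and calories and
    the ideal body weight. Returns (profiles, exclusions); every excluded
    patient appears in ``exclusions`` with a reason.
    """
    lab_cols = [c for c in cohort.visits.columns if c in LAB_FEATURES]
    nut_cols = [c for c in cohort.diets.columns if c not in ("patient_id", "month")]

    visits = cohort.visits.sort_values(["patient_id", "month"], kind="mergesort")
    diets = cohort.diets.sort_values(["patient_id", "month"], kind="mergesort")
    base = cohort.baseline.set_index("patient_id")
    outcomes = cohort.outcomes.set_index("patient_id")

    def two_level(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        # LOCF handled by the caller; window means, then the mean of window
        # means per patient (NaN-skipping at both levels, empty windows
        # never materialize as groups)
        win = np.floor(df["month"].to_numpy() / window_length).astype(int)
        wmeans = df.groupby([df["patient_id"].to_numpy(), win])[cols].mean()
        out = wmeans.groupby(level=0).mean()
        out.index.name = "patient_id"
        return out

    filled = visits.copy()
    filled[lab_cols] = filled.groupby("patient_id")[lab_cols].ffill()
    lab_avg = two_level(filled, lab_cols)
    nut_avg = two_level(diets, nut_cols)

    excluded = []
    for pid in sorted(set(base.index) - set(visits["patient_id"])):
        excluded.append({"patient_id": pid, "reason": "no visits"})
    for pid in sorted(set(visits["patient_id"]) - set(diets["patient_id"])):
        excluded.append({"patient_id": pid, "reason": "no diet records"})
    short = base.index[base["height"] <= 105]
    for pid in short:
        excluded.append({"patient_id": pid, "reason": "height <= 105 cm"})
    bad_ids = {rec["patient_id"] for rec in excluded}
    for rec in excluded:
        logger.warning("excluding patient %s: %s", rec["patient_id"], rec["reason"])

    keep = [pid for pid in base.index
            if pid not in bad_ids and pid in nut_avg.index and pid in lab_avg.index]
    profiles = lab_avg.loc[keep].join(nut_avg.loc[keep])
    height = base.loc[keep, "height"].astype(float)
    profiles["bmi"] = profiles["weight"] / (height / 100.0) ** 2
    if {"Protein", "Calories"} <= set(nut_cols):
        ibw = height.map(ideal_body_weight)
        profiles["DPI"] = profiles["Protein"] / ibw
        profiles["DEI"] = profiles["Calories"] / ibw
    profiles["age"] = base.loc[keep, "age"].astype(float)
    profiles["gender"] = base.loc[keep, "gender"].astype(int)
    profiles["diabetes"] = base.loc[keep, "diabetes"].astype(int)
    profiles["baseline_albumin"] = base.loc[keep, "albumin"].astype(float)
    profiles["T"] = (outcomes.loc[keep, "tend"] - outcomes.loc[keep, "t0"]).astype(float)
    profiles["event"] = outcomes.loc[keep, "event"].astype(int)
    profiles = profiles.reset_index()

    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return profiles, exclusions
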