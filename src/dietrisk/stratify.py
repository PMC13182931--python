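"""Albumin-tertile subtyping and the descriptive statistics battery.

Patients are partitioned at the empirical 1/3 and 2/3 quantiles of baseline
serum albumin into low / medium / high groups. Continuous variables are
compared across groups by one-way ANOVA with Tukey HSD pairwise tests,
categorical variables by the chi-square test, and survival by Kaplan-Meier
curves with the k-sample log-rank test. All tests are two-tailed; no
multiple-testing correction is applied across descriptive variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import StratificationError

GROUPS = ("low", "medium", "high")

__all__ = ["GROUPS", "SubtypeAssignment", "GroupComparison",
           "tertile_split", "compare_groups", "km_logrank"]


@dataclass
class SubtypeAssignment:
    assignment: pd.DataFrame  # patient_id, group
    cutpoints: tuple[float, float]

    def ids_for(self, group: str) -> np.ndarray:
        return self.assignment.loc[self.assignment["group"] == group, "patient_id"].to_numpy()


@dataclass
class GroupComparison:
    variable: str
    kind: str                       # 'continuous' | 'categorical'
    per_group: dict                 # group -> (mean, sd) or counts
    p_overall: float
    pairwise: dict = field(default_factory=dict)  # (g1, g2) -> Tukey p


def tertile_split(values: pd.Series, patient_ids=None) -> SubtypeAssignment:
    """Split patients at the empirical 1/3 and 2/3 quantiles.

    Boundary convention: value < q1/3 -> low; value <= q2/3 -> medium;
    else high. Ties therefore fall deterministically on the lower side.
    """
    v = pd.Series(values).astype(float)
    if patient_ids is None:
        patient_ids = v.index
    finite = np.isfinite(v.to_numpy())
    if finite.sum() < 3:
        raise StratificationError("tertile split needs at least 3 finite values")
    q1, q2 = np.quantile(v.to_numpy()[finite], [1 / 3, 2 / 3])
    if q1 == q2:
        warnings.warn("degenerate albumin distribution: all patients assigned 'medium'")
        group = np.where(v < q1, "low", np.where(v <= q2, "medium", "high"))
    else:
        group = np.where(v < q1, "low", np.where(v <= q2, "medium", "high"))
    out = pd.DataFrame({"patient_id": np.asarray(patient_ids), "group": group})
    return SubtypeAssignment(out, (float(q1), float(q2)))


def compare_groups(
    profiles: pd.DataFrame,
    assignment: SubtypeAssignment,
    variable: str,
    categorical: bool = False,
) -> GroupComparison:
    """ANOVA + Tukey HSD for continuous variables, chi-square for categorical."""
    merged = profiles.merge(assignment.assignment, on="patient_id")
    groups = [g for g in GROUPS if (merged["group"] == g).any()]
    if len(groups) < 2:
        raise StratificationError(f"compare_groups needs >= 2 nonempty groups for {variable}")

    if categorical:
        table = pd.crosstab(merged["group"], merged[variable])
        chi2, p, _, _ = stats.chi2_contingency(table)
        if table.shape[1] < 2:
            p = 1.0
        return GroupComparison(variable, "categorical",
                               {g: table.loc[g].to_dict() for g in table.index}, float(p))

    samples = [merged.loc[merged["group"] == g, variable].dropna().to_numpy() for g in groups]
    per_group = {g: (float(np.mean(s)), float(np.std(s, ddof=1)) if len(s) > 1 else 0.0)
                 for g, s in zip(groups, samples)}
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples if len(s)}) <= 1:
        warnings.warn(f"{variable}: zero variance in every group; reporting P = 1")
        return GroupComparison(variable, "continuous", per_group, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*samples)
    if not np.isfinite(p):
        p = 1.0
    pairwise = {}
    if len(groups) > 1 and all(len(s) > 1 for s in samples):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(samples)
        labels = np.concatenate([[g] * len(s) for g, s in zip(groups, samples)])
        if np.ptp(values) > 0:
            tk = pairwise_tukeyhsd(values, labels)
            for row in tk.summary().data[1:]:  # group1, group2, meandiff, p-adj, ...
                pairwise[(str(row[0]), str(row[1]))] = float(row[3])
    return GroupComparison(variable, "continuous", per_group, float(p), pairwise)


def km_logrank(
    T: pd.Series, event: pd.Series, assignment: SubtypeAssignment, patient_ids=None
) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier curves per albumin group plus the k-sample log-rank P.

    Returns (curves, p) where ``curves`` has columns (group, time, survival).
    Groups with zero subjects are dropped with a warning.
    """
    df = pd.DataFrame({
        "patient_id": np.asarray(patient_ids) if patient_ids is not None else np.asarray(T.index),
        "T": np.asarray(T, dtype=float),
        "event": np.asarray(event, dtype=int),
    }).merge(assignment.assignment, on="patient_id")
    if not (df["T"] > 0).all():
        raise StratificationError("follow-up times must be positive")

    curves = []
    for g in GROUPS:
        sub = df[df["group"] == g]
        if len(sub) == 0:
            warnings.warn(f"group {g!r} has no subjects; excluded from KM/log-rank")
            continue
        km = KaplanMeierFitter().fit(sub["T"], sub["event"], label=g)
        sf = km.survival_function_
        curves.append(pd.DataFrame({
            "group": g,
            "time": sf.index.to_numpy(),
            "survival": sf[g].to_numpy(),
        }))
    present = df[df["group"].isin({c["group"].iloc[0] for c in curves})]
    if present["group"].nunique() >= 2:
        res = multivariate_logrank_test(present["T"], present["group"], present["event"])
        p = float(res.p_value)
    else:
        p = 1.0
    return pd.concat(curves, ignore_index=True), p
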