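"""Stage 2: restricted cubic splines over the stage-1 risk pairs.

log s is regressed on a restricted cubic spline (RCS) basis of the nutrient
intake. The RCS basis is Harrell's truncated-power construction: piecewise
cubic, twice continuously differentiable, and exactly linear beyond the
boundary knots. Two nested F-tests accompany each fit:

* P (overall)  : spline model vs. intercept-only model,
* P-NL         : spline model vs. linear-only model (the nonlinearity test).

The fitted log-HR curve is centered to mean zero over the group's observed
intake distribution — the same reference as the stage-1 score centering —
so HR(x) < 1 means "below the group's average predicted risk". The
protective set {x : HR(x) < 1} is decomposed into at most two intervals
reported as points A, B, C: [A, B] and optionally [C, domain max).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SplineError
from .stage1 import RiskPairSet, nutrient_hr, risk_scores, build_risk_pairs, CONFOUNDERS
from .stratify import SubtypeAssignment

__all__ = ["SplineModel", "RangeReport", "choose_knots", "rcs_basis",
           "fit_spline", "anova_nonlinearity", "extract_ranges", "range_report"]

_KNOT_PERCENTILES = {
    3: (10, 50, 90),
    4: (5, 35, 65, 95),
    5: (5, 27.5, 50, 72.5, 95),
}


@dataclass
class SplineModel:
    nutrient: str
    group: str
    knots: np.ndarray
    coefficients: np.ndarray      # intercept, linear, k-2 restricted cubic terms
    domain: tuple[float, float]
    center_value: float           # mean fitted value over the training intakes
    ols_result: object = None

    def predict(self, x) -> np.ndarray:
        """Fitted (uncentered) log risk-score curve."""
        X = sm.add_constant(rcs_basis(np.asarray(x, dtype=float), self.knots),
                            has_constant="add")
        return X @ self.coefficients

    def log_hr(self, x) -> np.ndarray:
        """Fitted log-HR curve, centered to mean 0 over the intake distribution."""
        return self.predict(x) - self.center_value


@dataclass
class RangeReport:
    nutrient: str
    group: str
    A: float | None
    B: float | None
    C: float | None
    p_overall: float
    p_nonlinear: float
    flags: tuple[str, ...] = ()


def choose_knots(x, k: int = 4) -> np.ndarray:
    """Knots at Harrell's percentile convention (e.g. 5/35/65/95 for k=4)."""
    if k not in _KNOT_PERCENTILES:
        raise SplineError(f"knot count must be one of {sorted(_KNOT_PERCENTILES)}, got {k}")
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < 10:
        raise SplineError("need >= 10 distinct intake values to place knots")
    knots = np.percentile(x, _KNOT_PERCENTILES[k])
    if not np.all(np.diff(knots) > 0):
        knots = np.percentile(x, np.linspace(5, 95, k))
    if not np.all(np.diff(knots) > 0):
        raise SplineError("cannot place strictly increasing knots")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Design columns [x, C_1(x), ..., C_{k-2}(x)] of the restricted cubic basis.

    Each C_j is the standard truncated-power restricted term, normalized by
    (t_k - t_1)^2 so the columns share the scale of x.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise SplineError("non-finite intake values")
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    norm = (tk - t1) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        cj = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(cj)
    return np.column_stack(cols)


def fit_spline(pairs: RiskPairSet, knots) -> SplineModel:
    """OLS of log score on the RCS basis of intake."""
    x = pairs.pairs["intake"].to_numpy(dtype=float)
    y = np.log(pairs.pairs["score"].to_numpy(dtype=float))
    knots = np.asarray(knots, dtype=float)
    if len(x) < knots.size + 2:
        raise SplineError(f"need at least {knots.size + 2} pairs, got {len(x)}")
    X = sm.add_constant(rcs_basis(x, knots), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SplineError("rank-deficient spline design")
    res = sm.OLS(y, X).fit()
    model = SplineModel(
        nutrient=pairs.nutrient,
        group=pairs.group,
        knots=knots,
        coefficients=np.asarray(res.params),
        domain=(float(x.min()), float(x.max())),
        center_value=0.0,
        ols_result=res,
    )
    model.center_value = float(model.predict(x).mean())
    return model


def anova_nonlinearity(pairs: RiskPairSet, knots) -> tuple[float, float]:
    """(p_overall, p_nonlinear) from nested F-tests of the spline fit."""
    x = pairs.pairs["intake"].to_numpy(dtype=float)
    y = np.log(pairs.pairs["score"].to_numpy(dtype=float))
    knots = np.asarray(knots, dtype=float)
    X_full = sm.add_constant(rcs_basis(x, knots), has_constant="add")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise SplineError("rank-deficient spline design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.OLS(y, X_full).fit()
        linear = sm.OLS(y, sm.add_constant(x)).fit()
        p_overall = float(full.f_pvalue)
        scale = max(float(np.var(y)) * len(y), 1.0)
        if linear.ssr - full.ssr <= 1e-12 * scale:
            # the linear model already fits (numerically) perfectly: F = 0
            p_nonlinear = 1.0
        else:
            _, p_nonlinear, _ = full.compare_f_test(linear)
    if not np.isfinite(p_overall):
        p_overall = 1.0
    if not np.isfinite(p_nonlinear):
        p_nonlinear = 1.0
    return p_overall, float(p_nonlinear)


def extract_ranges(model: SplineModel, grid_size: int = 200,
                   min_component_frac: float = 0.02):
    """Protective intake intervals {x : exp(g(x)) < 1} on the observed domain.

    The centered curve is evaluated on a uniform grid; crossings are located
    by linear interpolation between grid nodes; components narrower than
    ``min_component_frac`` of the domain are suppressed as grid noise and at
    most the two widest components are kept (with a warning flag).

    Returns (intervals, flags): a list of (lo, hi) plus diagnostic flags.
    """
    lo, hi = model.domain
    if not hi > lo:
        raise SplineError("degenerate intake domain")
    grid = np.linspace(lo, hi, grid_size)
    g = model.log_hr(grid)

    intervals = []
    below = g < 0
    i = 0
    while i < grid_size:
        if below[i]:
            j = i
            while j + 1 < grid_size and below[j + 1]:
                j += 1
            a = grid[i]
            if i > 0:  # interpolate the downward crossing
                a = grid[i - 1] + (grid[i] - grid[i - 1]) * g[i - 1] / (g[i - 1] - g[i])
            b = grid[j]
            if j + 1 < grid_size:
                b = grid[j] + (grid[j + 1] - grid[j]) * g[j] / (g[j] - g[j + 1])
            intervals.append((a, b))
            i = j + 1
        else:
            i += 1

    flags = []
    width = hi - lo
    kept = [iv for iv in intervals if iv[1] - iv[0] >= min_component_frac * width]
    if len(kept) < len(intervals):
        flags.append("narrow components suppressed")
    if len(kept) > 2:
        kept = sorted(sorted(kept, key=lambda iv: iv[0] - iv[1])[:2])
        flags.append("more than two protective components; kept the two widest")
    return kept, tuple(flags)


def _points_from_intervals(intervals, domain, flags):
    lo, hi = domain
    eps = 1e-9 * max(1.0, abs(hi - lo))
    A = B = C = None
    if len(intervals) >= 1:
        a, b = intervals[0]
        A = a
        if b < hi - eps:
            B = b
    if len(intervals) == 2:
        c, d = intervals[1]
        C = c
        if d < hi - eps:
            flags = flags + ("upper protective component closes before the domain max",)
    return A, B, C, flags


def range_report(
    profiles: pd.DataFrame,
    nutrient: str,
    group: str = "all",
    assignment: SubtypeAssignment | None = None,
    confounders=CONFOUNDERS,
    knots: int = 4,
    grid_size: int = 200,
) -> RangeReport:
    """End-to-end two-stage analysis of one (nutrient, group).

    Composes the stage-1 Cox fit, risk scoring, pair sampling, knot
    placement, the RCS fit, the nonlinearity ANOVA, and range extraction
    into one row of the protective-range table.
    """
    cox = nutrient_hr(profiles, nutrient, group, assignment, confounders)
    sub = profiles
    if group != "all":
        sub = profiles[profiles["patient_id"].isin(assignment.ids_for(group))]
    scores = risk_scores(cox.fit, sub, nutrient, confounders, cox.unit_scale)
    pairs = build_risk_pairs(sub, scores, nutrient, group)
    kn = choose_knots(pairs.pairs["intake"], knots)
    model = fit_spline(pairs, kn)
    p_overall, p_nonlinear = anova_nonlinearity(pairs, kn)
    intervals, flags = extract_ranges(model, grid_size)
    A, B, C, flags = _points_from_intervals(intervals, model.domain, flags)
    if not intervals:
        flags = flags + ("protective set empty",)
    return RangeReport(nutrient, group, A, B, C, p_overall, p_nonlinear, flags)
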