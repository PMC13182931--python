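"""Synthetic longitudinal dialysis cohorts with known diet-mortality effects.

The generator emulates the structure of a peritoneal-dialysis registry:
a baseline table (demographics + entry labs), irregular quarterly-ish visits
with per-feature lab missingness, 3-day-dietary-record style nutrient intakes
with whole-record missingness, and a survival outcome (all-cause death,
everything else collapsed to censoring).

Ground truth is injected through :class:`EffectSpec` terms on the log hazard
(linear or U-shaped quadratic per nutrient), so every downstream stage of the
two-stage pipeline can be tested against an analytic protective interval.

A deliberate feature of the data-generating process: a few labs (albumin
foremost) *respond* to the total dietary hazard contribution. Serum albumin
is the canonical marker of nutritional adequacy in dialysis patients, and it
is this biomarker channel that lets a linear risk-score stage expose a
nonlinear diet effect downstream (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SpecificationError

__all__ = [
    "EffectSpec",
    "BaselineHazard",
    "CohortConfig",
    "LongitudinalCohort",
    "generate_cohort",
    "log_hazard",
    "sample_event_time",
    "true_protective_interval",
    "default_nutrient_marginals",
    "NUTRIENTS",
    "LAB_FEATURES",
    "CONFOUNDERS",
]


def default_nutrient_marginals() -> dict[str, tuple[float, float]]:
    """Mean/SD of each raw nutrient intake, taken from the packaged
    time-averaged dietary profile table (units as printed there)."""
    path = resources.files("dietrisk.data").joinpath("table3.csv")
    with path.open() as fh:
        t3 = pd.read_csv(fh)
    t3 = t3[~t3["variable"].isin(["DPI", "DEI"])]
    return {r.variable: (float(r.mean_all), float(r.sd_all)) for r in t3.itertuples()}


#: the 24 raw nutrient intakes recorded at each dietary follow-up
NUTRIENTS: tuple[str, ...] = tuple(default_nutrient_marginals())

# lab feature -> (mean, sd, missing rate, health loading, diet-factor loading,
#                 diet-response loading)
# Means/SDs follow the cohort-wide baseline lab distribution; missing rates
# follow the per-feature record missingness of the registry (6-29%).
_LAB_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "cl":       (101.48,   6.33, 0.06, 0.30, 0.10, 0.0),
    "co2cp":    (25.87,    4.44, 0.07, 0.30, 0.10, 0.0),
    "wbc":      (6.88,     2.28, 0.09, 0.20, 0.10, 0.0),
    "hb":       (108.11,  21.78, 0.09, 0.45, 0.10, 0.2),
    "urea":     (21.26,    6.54, 0.10, 0.30, 0.10, 0.0),
    "serum_ca": (2.24,     0.40, 0.11, 0.30, 0.10, 0.0),
    "serum_k":  (4.33,     0.78, 0.11, 0.20, 0.10, 0.0),
    "serum_na": (139.17,   4.87, 0.12, 0.20, 0.10, 0.0),
    "scr":      (720.38, 254.87, 0.10, 0.40, 0.10, 0.0),
    "serum_p":  (1.61,     0.49, 0.12, 0.30, 0.10, 0.0),
    "albumin":  (37.15,    4.90, 0.22, 0.45, 0.10, 0.6),
    "hscrp":    (5.66,    13.29, 0.29, -0.35, 0.00, 0.0),
    "glucose":  (6.19,     2.94, 0.28, -0.25, 0.00, 0.0),
    "weight":   (61.17,   11.95, 0.05, 0.30, 0.15, 0.2),
    "sbp":      (135.65,  21.38, 0.05, -0.20, 0.00, 0.0),
    "dbp":      (78.97,   14.20, 0.05, 0.10, 0.00, 0.0),
    "gfr":      (0.06,     0.06, 0.05, 0.10, 0.00, 0.0),
}

LAB_FEATURES: tuple[str, ...] = tuple(_LAB_TABLE)

#: the 19 adjustment covariates used by stage 1 (serum labs, vitals,
#: diabetes status and BMI; dietary K/Na/Ca/P are distinct measurements)
CONFOUNDERS: tuple[str, ...] = LAB_FEATURES + ("diabetes", "bmi")

# log-hazard slopes of the confounders (per raw unit, covariate centered)
DEFAULT_CONFOUNDER_BETAS: dict[str, float] = {
    "albumin": -0.05,
    "hb": -0.005,
    "weight": -0.005,
    "hscrp": 0.01,
    "glucose": 0.03,
    "diabetes": 0.4,
}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth contribution of one nutrient to the log hazard.

    kind='null'      : no effect.
    kind='linear'    : beta * x.
    kind='quadratic' : curvature * (x - center)^2, a U-shape for curvature>0.
    """

    nutrient: str
    kind: str = "null"
    beta: float | None = None
    center: float | None = None
    curvature: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("null", "linear", "quadratic"):
            raise SpecificationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "linear":
            if self.beta is None or not np.isfinite(self.beta):
                raise SpecificationError(f"{self.nutrient}: linear effect needs finite beta")
            if self.center is not None or self.curvature is not None:
                raise SpecificationError(f"{self.nutrient}: linear effect takes only beta")
        elif self.kind == "quadratic":
            if self.center is None or self.curvature is None:
                raise SpecificationError(
                    f"{self.nutrient}: quadratic effect needs center and curvature"
                )
            if not self.curvature > 0:
                raise SpecificationError(f"{self.nutrient}: curvature must be > 0")
            if self.beta is not None:
                raise SpecificationError(f"{self.nutrient}: quadratic effect takes no beta")
        elif self.beta is not None or self.center is not None or self.curvature is not None:
            raise SpecificationError(f"{self.nutrient}: null effect takes no parameters")

    def contribution(self, x):
        """Log-hazard contribution at intake ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.beta * x
        if self.kind == "quadratic":
            return self.curvature * (x - self.center) ** 2
        return np.zeros_like(x)


@dataclass(frozen=True)
class BaselineHazard:
    """Weibull baseline hazard, parameterized per month.

    shape=1 reduces to an exponential with rate 1/scale; the cumulative
    hazard is H0(t) = (t/scale)**shape, inverted in closed form when
    sampling event times.
    """

    shape: float = 1.0
    scale: float = 140.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ConfigurationError("baseline_hazard.shape must be positive")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ConfigurationError("baseline_hazard.scale must be positive")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the registry's published topline: n=656 patients,
    ~3-month visits over up to 120 months, 6-month averaging windows,
    20% whole-record diet missingness, per-lab missingness of 5-29%, and
    an outcome mix of ~44% deaths.
    """

    n_patients: int = 656
    nutrients: dict[str, tuple[float, float]] | None = None  # name -> (mean, sd)
    follow_up_horizon: float = 120.0  # months
    visit_interval_mean: float = 3.0  # months
    visit_interval_sd: float = 1.0
    window_length: float = 6.0  # months
    diet_missing_rate: float = 0.20
    lab_missing_rates: dict[str, float] | None = None
    diet_factor_loading: float = 0.5   # nutrient loading on the shared diet factor
    lab_visit_noise: float = 0.3       # within-patient visit noise, lab-SD units
    diet_visit_noise: float = 0.25     # within-patient record noise, intake-SD units
    confounder_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_BETAS)
    )
    effect_specs: list[EffectSpec] = field(default_factory=list)
    baseline_hazard: BaselineHazard = field(default_factory=BaselineHazard)
    censor_rate: float = 0.40  # P(random censoring before the horizon)
    seed: int = 0

    def resolved_nutrients(self) -> dict[str, tuple[float, float]]:
        return dict(self.nutrients) if self.nutrients else default_nutrient_marginals()

    def validate(self) -> None:
        if self.n_patients < 3:
            raise ConfigurationError("n_patients must be >= 3 (tertiles must be nonempty)")
        for name in ("diet_missing_rate", "censor_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or (name == "censor_rate" and v == 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1)"
                                         if name == "censor_rate"
                                         else f"{name} must lie in [0, 1]")
        if not self.follow_up_horizon > self.window_length:
            raise ConfigurationError("follow_up_horizon must exceed window_length")
        if not self.visit_interval_mean > 0:
            raise ConfigurationError("visit_interval_mean must be positive")
        nutrients = self.resolved_nutrients()
        for k, (m, s) in nutrients.items():
            if not (m > 0 and s > 0):
                raise ConfigurationError(f"nutrients[{k!r}] needs positive mean and sd")
        if self.lab_missing_rates is not None:
            for k, v in self.lab_missing_rates.items():
                if k not in _LAB_TABLE:
                    raise ConfigurationError(f"lab_missing_rates: unknown lab {k!r}")
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"lab_missing_rates[{k!r}] must lie in [0, 1]")
        for spec in self.effect_specs:
            if spec.nutrient not in nutrients:
                raise SpecificationError(f"effect spec names unknown nutrient {spec.nutrient!r}")
        for k in self.confounder_betas:
            if k not in CONFOUNDERS:
                raise ConfigurationError(f"confounder_betas: unknown covariate {k!r}")


@dataclass
class LongitudinalCohort:
    """Raw cohort tables plus (synthetic-only) ground-truth metadata."""

    baseline: pd.DataFrame
    visits: pd.DataFrame
    diets: pd.DataFrame
    outcomes: pd.DataFrame
    truth: dict | None = None

    def validate(self) -> None:
        ids = set(self.baseline["patient_id"])
        for name in ("visits", "diets", "outcomes"):
            tab = getattr(self, name)
            orphans = set(tab["patient_id"]) - ids
            if orphans:
                raise ConfigurationError(f"{name} contains unknown patient ids {sorted(orphans)[:5]}")
        if not (self.outcomes["tend"] > self.outcomes["t0"]).all():
            raise ConfigurationError("outcomes: tend must exceed t0 for every patient")
        if not self.outcomes["event"].isin([0, 1]).all():
            raise ConfigurationError("outcomes: event must be binary after collapsing to death/censored")

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(outdir / "baseline.csv", index=False)
        self.visits.to_csv(outdir / "visits.csv", index=False)
        self.diets.to_csv(outdir / "diets.csv", index=False)
        self.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        if self.truth is not None:
            (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))

    @classmethod
    def from_csv(cls, indir) -> "LongitudinalCohort":
        from pathlib import Path

        indir = Path(indir)
        truth = None
        tpath = indir / "truth.json"
        if tpath.exists():
            truth = json.loads(tpath.read_text())
        return cls(
            baseline=pd.read_csv(indir / "baseline.csv"),
            visits=pd.read_csv(indir / "visits.csv"),
            diets=pd.read_csv(indir / "diets.csv"),
            outcomes=pd.read_csv(indir / "outcomes.csv"),
            truth=truth,
        )


def log_hazard(
    baseline_covariates: Mapping[str, float],
    nutrient_intakes: Mapping[str, float],
    effect_specs: Sequence[EffectSpec],
    confounder_betas: Mapping[str, float],
) -> float:
    """Deterministic log relative hazard: sum(gamma_j * z_j) + nutrient effects."""
    for spec in effect_specs:
        if spec.nutrient not in nutrient_intakes:
            raise SpecificationError(f"effect spec names unknown nutrient {spec.nutrient!r}")
    total = 0.0
    for name, gamma in confounder_betas.items():
        total += gamma * float(baseline_covariates[name])
    for spec in effect_specs:
        total += float(spec.contribution(nutrient_intakes[spec.nutrient]))
    return total


def sample_event_time(
    log_hr: float,
    baseline_hazard: BaselineHazard,
    horizon: float,
    rng: np.random.Generator,
    censor_rate: float = 0.0,
) -> tuple[float, int]:
    """Draw one (time, event) pair by inverse-CDF from the Weibull hazard
    h0(t)*exp(log_hr), with independent exponential censoring calibrated so
    P(censor < horizon) = censor_rate, plus administrative censoring."""
    if not np.isfinite(log_hr):
        raise ValueError("log_hr must be finite")
    t, event = _sample_event_times(
        np.array([log_hr]), baseline_hazard, horizon, rng, censor_rate
    )
    return float(t[0]), int(event[0])


def _sample_event_times(log_hr, baseline_hazard, horizon, rng, censor_rate):
    log_hr = np.asarray(log_hr, dtype=float)
    n = log_hr.size
    e = rng.exponential(size=n)
    t_event = baseline_hazard.scale * (e / np.exp(log_hr)) ** (1.0 / baseline_hazard.shape)
    if censor_rate > 0 and np.isfinite(horizon):
        lam_c = -np.log1p(-censor_rate) / horizon
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    elif censor_rate > 0:
        raise ConfigurationError("censor_rate > 0 requires a finite horizon")
    else:
        t_cens = np.full(n, np.inf)
    t_admin = np.minimum(t_cens, horizon)
    event = (t_event <= t_admin).astype(int)
    t_obs = np.maximum(np.minimum(t_event, t_admin), 1e-6)
    return t_obs, event


def true_protective_interval(
    spec: EffectSpec,
    intake_mean: float,
    intake_sd: float,
    lower: float = 0.0,
    upper: float = np.inf,
) -> tuple[float, float] | None:
    """Analytic protective interval {x : f(x) < E[f(X)]} for one effect spec,
    the expectation taken over the truncated-normal intake distribution.

    Quadratic effects give a finite interval around the center; linear
    effects give a half-line bounded by the mean intake; null effects have
    no protective range.
    """
    if spec.kind == "null":
        return None
    a = (lower - intake_mean) / intake_sd
    b = (upper - intake_mean) / intake_sd if np.isfinite(upper) else np.inf
    dist = stats.truncnorm(a, b, loc=intake_mean, scale=intake_sd)
    mu = float(dist.mean())
    if spec.kind == "linear":
        return (lower, mu) if spec.beta > 0 else (mu, upper)
    # quadratic: c*(x-center)^2 < c*E[(X-center)^2]
    second_moment = float(dist.var()) + (mu - spec.center) ** 2
    r = np.sqrt(second_moment)
    return (max(lower, spec.center - r), min(upper, spec.center + r))


def _truncated_shifted_normal(rng, base, sd_units, lower=0.0, max_iter=100):
    """base + draws, redrawing the idiosyncratic part until above ``lower``.

    ``base`` carries the correlated (factor) structure; redrawing only the
    residual keeps the copula intact except in the far lower tail.
    """
    base = np.asarray(base, dtype=float)
    sd = np.broadcast_to(np.asarray(sd_units, dtype=float), base.shape)
    x = base + sd * rng.standard_normal(base.shape)
    for _ in range(max_iter):
        bad = x < lower
        if not bad.any():
            break
        x = x.copy()
        x[bad] = base[bad] + sd[bad] * rng.standard_normal(int(bad.sum()))
    return np.maximum(x, lower + 1e-9)


def generate_cohort(config: CohortConfig) -> LongitudinalCohort:
    """Generate one reproducible longitudinal cohort.

    Identical config (including seed) yields byte-identical CSV output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    nutrients = config.resolved_nutrients()
    nut_names = list(nutrients)
    mu_x = np.array([nutrients[k][0] for k in nut_names])
    sd_x = np.array([nutrients[k][1] for k in nut_names])

    # --- patient-level latents -------------------------------------------
    diet_factor = rng.standard_normal(n)
    health_factor = rng.standard_normal(n)
    lam = config.diet_factor_loading
    resid = np.sqrt(1.0 - lam**2)
    base = mu_x[None, :] + sd_x[None, :] * (lam * diet_factor[:, None])
    intakes = _truncated_shifted_normal(rng, base, resid * sd_x[None, :])

    # total nutrient log-hazard contribution and its cohort-standardized form
    q = np.zeros(n)
    for spec in config.effect_specs:
        q += spec.contribution(intakes[:, nut_names.index(spec.nutrient)])
    q_sd = q.std()
    q_tilde = (q - q.mean()) / q_sd if q_sd > 0 else np.zeros(n)

    # --- labs: factor model with a diet-responsive channel ---------------
    lab_latent = {}
    for name, (m, s, _miss, l_health, l_diet, l_resp) in _LAB_TABLE.items():
        c = np.sqrt(max(1.0 - l_health**2 - l_diet**2 - l_resp**2, 0.05))
        z = (
            l_health * health_factor
            + l_diet * diet_factor
            - l_resp * q_tilde
            + c * rng.standard_normal(n)
        )
        lab_latent[name] = np.maximum(m + s * z, 1e-9)

    # --- demographics -----------------------------------------------------
    age = np.clip(rng.normal(59.1, 15.8, n), 16, 97)
    gender = rng.integers(0, 2, n)  # 1 = female
    height = np.clip(rng.normal(162.6, 9.46, n), 130, 200)
    diabetes = (rng.random(n) < 0.37).astype(int)
    bmi = lab_latent["weight"] / (height / 100.0) ** 2

    # --- event times ------------------------------------------------------
    betas = config.confounder_betas
    lhr = q.copy()
    for name, gamma in betas.items():
        if name == "diabetes":
            lhr += gamma * (diabetes - diabetes.mean())
        elif name == "bmi":
            lhr += gamma * (bmi - bmi.mean())
        else:
            m = _LAB_TABLE[name][0]
            lhr += gamma * (lab_latent[name] - m)
    t_obs, event = _sample_event_times(
        lhr, config.baseline_hazard, config.follow_up_horizon, rng, config.censor_rate
    )

    # --- visit schedule (per-patient renewal process) ---------------------
    miss_rates = dict(config.lab_missing_rates or {})
    pid = np.arange(1, n + 1)
    visit_rows, diet_rows = [], []
    for i in range(n):
        months = [0]
        t = 0.0
        while True:
            t += max(0.5, rng.normal(config.visit_interval_mean, config.visit_interval_sd))
            if t >= t_obs[i]:
                break
            m = int(round(t))
            if m > months[-1]:
                months.append(m)
        for m in months:
            row = {"patient_id": pid[i], "month": m}
            for name, (mu, s, miss_default, *_rest) in _LAB_TABLE.items():
                val = lab_latent[name][i] + s * config.lab_visit_noise * rng.standard_normal()
                val = max(val, 0.0)
                miss = miss_rates.get(name, miss_default)
                if m > 0 and rng.random() < miss:
                    val = np.nan
                row[name] = round(val, 4)
            visit_rows.append(row)
            if rng.random() >= config.diet_missing_rate:
                drow = {"patient_id": pid[i], "month": m}
                for k, name in enumerate(nut_names):
                    v = intakes[i, k] + sd_x[k] * config.diet_visit_noise * rng.standard_normal()
                    drow[name] = round(max(v, 0.0), 4)
                diet_rows.append(drow)

    visits = pd.DataFrame(visit_rows)
    diets = pd.DataFrame(diet_rows, columns=["patient_id", "month"] + nut_names)

    baseline = pd.DataFrame({
        "patient_id": pid,
        "age": np.round(age, 2),
        "gender": gender,
        "height": np.round(height, 2),
        "diabetes": diabetes,
    })
    entry = visits[visits["month"] == 0].drop(columns="month").set_index("patient_id")
    # baseline labs are the entry-visit measurements, kept complete
    baseline = baseline.join(entry, on="patient_id")

    outcomes = pd.DataFrame({
        "patient_id": pid,
        "t0": 0.0,
        "tend": np.round(t_obs, 4),
        "event": event,
    })

    truth = {
        "effects": [asdict(s) for s in config.effect_specs],
        "protective_intervals": {
            s.nutrient: true_protective_interval(s, *nutrients[s.nutrient])
            for s in config.effect_specs
        },
        "confounder_betas": dict(betas),
        "baseline_hazard": asdict(config.baseline_hazard),
        "seed": config.seed,
    }

    cohort = LongitudinalCohort(baseline, visits, diets, outcomes, truth)
    cohort.validate()
    return cohort
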