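"""Generator contracts: determinism, hazard arithmetic, event-time law,
missingness rates, and the analytic protective intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from dietrisk.cohort import (
    BaselineHazard,
    CohortConfig,
    EffectSpec,
    generate_cohort,
    log_hazard,
    sample_event_time,
    true_protective_interval,
    _sample_event_times,
)
from dietrisk.errors import ConfigurationError, SpecificationError


class TestEffectSpec:
    def test_exactly_one_parameterization(self):
        with pytest.raises(SpecificationError):
            EffectSpec("x", "linear")  # no beta
        with pytest.raises(SpecificationError):
            EffectSpec("x", "quadratic", center=1.0, curvature=-0.1)
        with pytest.raises(SpecificationError):
            EffectSpec("x", "null", beta=0.5)
        with pytest.raises(SpecificationError):
            EffectSpec("x", "linear", beta=np.inf)

    def test_contributions(self):
        assert EffectSpec("x", "null").contribution(3.0) == 0.0
        assert EffectSpec("x", "linear", beta=0.1).contribution(10.0) == pytest.approx(1.0)
        spec = EffectSpec("x", "quadratic", center=5.0, curvature=0.2)
        assert spec.contribution(3.0) == pytest.approx(0.8)


class TestLogHazard:
    def test_empty_sum_is_zero(self):
        assert log_hazard({}, {"x": 3.0}, [EffectSpec("x")], {}) == 0.0

    def test_linear_and_quadratic_arithmetic(self):
        specs = [EffectSpec("x", "linear", beta=0.1)]
        assert log_hazard({}, {"x": 10.0}, specs, {}) == pytest.approx(1.0)
        specs = [EffectSpec("x", "quadratic", center=5.0, curvature=0.2)]
        assert log_hazard({}, {"x": 3.0}, specs, {}) == pytest.approx(0.8)

    def test_unknown_nutrient_rejected(self):
        with pytest.raises(SpecificationError):
            log_hazard({}, {"y": 1.0}, [EffectSpec("x", "linear", beta=1.0)], {})

    def test_confounders_additive(self):
        val = log_hazard({"albumin": 2.0, "glucose": 1.0}, {}, [],
                         {"albumin": -0.05, "glucose": 0.03})
        assert val == pytest.approx(-0.07)


class TestEventTimes:
    def test_nonfinite_log_hr_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_event_time(np.inf, BaselineHazard(), 120.0, rng)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ConfigurationError):
            BaselineHazard(scale=0.0)

    def test_exponential_mean_and_ph_scaling(self):
        """Mean event time matches 1/rate, and halves under log HR = log 2."""
        rng = np.random.default_rng(42)
        scale = 50.0  # exponential with rate 1/50 per month
        n = 100_000
        t0, e0 = _sample_event_times(np.zeros(n), BaselineHazard(1.0, scale),
                                     np.inf, rng, 0.0)
        assert e0.all()
        se = scale / np.sqrt(n)
        assert abs(t0.mean() - scale) < 2 * se
        t2, _ = _sample_event_times(np.full(n, np.log(2.0)), BaselineHazard(1.0, scale),
                                    np.inf, rng, 0.0)
        assert abs(t2.mean() - scale / 2) < 2 * se / 2

    def test_death_fraction_matches_numeric_integration(self):
        """Observed deaths under a null cohort match P(T < horizon) from the
        numerically integrated Weibull density."""
        cfg = CohortConfig(
            n_patients=2000, seed=3, nutrients={"NutX": (5.0, 1.0)},
            effect_specs=[], confounder_betas={},
            baseline_hazard=BaselineHazard(1.0, 600.0), censor_rate=0.0,
        )
        cohort = generate_cohort(cfg)
        horizon, scale = cfg.follow_up_horizon, 600.0
        p, _ = integrate.quad(lambda t: np.exp(-t / scale) / scale, 0, horizon)
        observed = cohort.outcomes["event"].mean()
        se = np.sqrt(p * (1 - p) / cfg.n_patients)
        assert abs(observed - p) < 2 * se


class TestGenerateCohort:
    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            generate_cohort(CohortConfig(n_patients=2))
        with pytest.raises(ConfigurationError, match="diet_missing_rate"):
            CohortConfig(diet_missing_rate=1.5).validate()
        with pytest.raises(SpecificationError, match="unknown nutrient"):
            CohortConfig(effect_specs=[EffectSpec("Unobtainium", "linear", beta=1.0)]).validate()

    def test_deterministic_output(self, tmp_path):
        for d in ("a", "b"):
            generate_cohort(CohortConfig(n_patients=100, seed=7)).to_csv(tmp_path / d)
        for name in ("baseline.csv", "visits.csv", "diets.csv", "outcomes.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_baseline_row_count(self):
        cohort = generate_cohort(CohortConfig(n_patients=100, seed=7))
        assert len(cohort.baseline) == 100

    def test_table_referential_integrity(self, small_cohort):
        ids = set(small_cohort.baseline["patient_id"])
        for tab in (small_cohort.visits, small_cohort.diets, small_cohort.outcomes):
            assert set(tab["patient_id"]) <= ids
        assert (small_cohort.outcomes["tend"] > small_cohort.outcomes["t0"]).all()
        assert small_cohort.outcomes["event"].isin([0, 1]).all()

    def test_missingness_rates(self):
        """Realized diet-record and per-lab missingness sit near the
        configured rates (binomial 3 SE band at n=1000)."""
        cfg = CohortConfig(n_patients=1000, seed=5)
        cohort = generate_cohort(cfg)
        n_visits = len(cohort.visits)
        diet_rate = 1.0 - len(cohort.diets) / n_visits
        se = np.sqrt(0.2 * 0.8 / n_visits)
        assert abs(diet_rate - cfg.diet_missing_rate) < 3 * se

        followup = cohort.visits[cohort.visits["month"] > 0]
        for lab, expected in [("albumin", 0.22), ("hscrp", 0.29), ("cl", 0.06)]:
            rate = followup[lab].isna().mean()
            se = np.sqrt(expected * (1 - expected) / len(followup))
            assert abs(rate - expected) < 3 * se, lab


class TestTrueProtectiveInterval:
    def test_null_has_no_interval(self):
        assert true_protective_interval(EffectSpec("x"), 5.0, 1.0) is None

    def test_quadratic_normal_unit_variance(self):
        """center 5, X ~ N(5,1): E[c(X-5)^2] = c, so the interval is (4, 6)."""
        spec = EffectSpec("x", "quadratic", center=5.0, curvature=0.3)
        lo, hi = true_protective_interval(spec, 5.0, 1.0)
        assert lo == pytest.approx(4.0, abs=1e-3)
        assert hi == pytest.approx(6.0, abs=1e-3)

    def test_linear_half_line_at_mean(self):
        spec = EffectSpec("x", "linear", beta=0.2)
        lo, hi = true_protective_interval(spec, 5.0, 1.0)
        assert lo == 0.0
        assert hi == pytest.approx(5.0, abs=1e-3)
        spec = EffectSpec("x", "linear", beta=-0.2)
        lo, hi = true_protective_interval(spec, 5.0, 1.0)
        assert hi == np.inf

    def test_matches_monte_carlo_under_truncation(self):
        """With heavy truncation at 0 the analytic endpoints agree with a
        Monte-Carlo estimate of {x: f(x) < E f(X)} to grid resolution."""
        spec = EffectSpec("x", "quadratic", center=2.0, curvature=0.5)
        mean, sd = 2.0, 1.5
        lo, hi = true_protective_interval(spec, mean, sd)
        rng = np.random.default_rng(1)
        a = (0 - mean) / sd
        draws = stats.truncnorm(a, np.inf, loc=mean, scale=sd).rvs(200_000, random_state=rng)
        target = spec.contribution(draws).mean()
        grid = np.linspace(0, 8, 2001)
        below = spec.contribution(grid) < target
        assert lo == pytest.approx(grid[below].min(), abs=0.01)
        assert hi == pytest.approx(grid[below].max(), abs=0.01)
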