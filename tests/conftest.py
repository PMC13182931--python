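"""Shared fixtures: small synthetic cohorts and the heavier replicate sets
used by both the recovery and the cross-check acceptance tests."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from dietrisk.cohort import CohortConfig, EffectSpec, generate_cohort
from dietrisk.preprocess import build_profiles

logging.getLogger("dietrisk").setLevel(logging.ERROR)

#: study conditions of the quadratic-recovery experiment: one nutrient with a
#: U-shaped effect centered at 5 (intake ~ N(5, 1) truncated at 0), whose
#: analytic protective interval is (4, 6)
QUAD_NUTRIENT = {"NutX": (5.0, 1.0)}
QUAD_EFFECT = EffectSpec("NutX", "quadratic", center=5.0, curvature=0.3)


def quadratic_config(seed: int, n: int = 600) -> CohortConfig:
    return CohortConfig(
        n_patients=n,
        seed=seed,
        nutrients=dict(QUAD_NUTRIENT),
        effect_specs=[QUAD_EFFECT],
    )


@pytest.fixture(scope="session")
def quadratic_profiles():
    """Profiles of a single medium-sized quadratic-truth cohort."""
    profiles, _ = build_profiles(generate_cohort(quadratic_config(seed=7)))
    return profiles


@pytest.fixture(scope="session")
def quadratic_replicates():
    """Profiles of 50 seeded quadratic-truth cohorts (n=600 each).

    Shared between the endpoint-recovery test and the single-stage
    cross-check so the cohorts are only generated once.
    """
    out = []
    for seed in range(50):
        profiles, _ = build_profiles(generate_cohort(quadratic_config(seed=1000 + seed)))
        out.append(profiles)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at reduced size for smoke-level checks."""
    cfg = CohortConfig(n_patients=150, seed=11)
    return generate_cohort(cfg)


def simulate_survival_frame(
    n: int,
    rng: np.random.Generator,
    beta_x: float = 0.0,
    gamma: tuple[float, float] = (0.5, -0.5),
    scale: float = 100.0,
    horizon: float = 60.0,
    censor_rate: float = 0.3,
) -> pd.DataFrame:
    """Light-weight proportional-hazards draw used by calibration tests.

    One nutrient-like exposure x ~ N(5,1) plus two independent standard
    normal confounders with known log-hazard slopes; exponential baseline.
    """
    from dietrisk.cohort import BaselineHazard, _sample_event_times

    x = rng.normal(5.0, 1.0, n)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    lhr = beta_x * (x - 5.0) + gamma[0] * z1 + gamma[1] * z2
    t, event = _sample_event_times(lhr, BaselineHazard(1.0, scale), horizon, rng, censor_rate)
    return pd.DataFrame({
        "patient_id": np.arange(n), "x": x, "z1": z1, "z2": z2,
        "T": t, "event": event,
    })
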