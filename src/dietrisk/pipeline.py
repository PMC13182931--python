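"""End-to-end orchestration: simulate -> preprocess -> stratify -> stage 1 -> stage 2.

Every stage writes headered CSV; a JSON manifest records inputs, seed and
per-stage row counts. Identical configuration (including seed) reproduces
identical output files.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortConfig, LongitudinalCohort, generate_cohort, NUTRIENTS, CONFOUNDERS
from .errors import DietriskError, FittingError, SplineError, StratificationError
from .preprocess import build_profiles
from .stage1 import nutrient_hr, UNIT_SCALES
from .stage2 import range_report
from .stratify import GROUPS, tertile_split, km_logrank
from .tables import pearson_matrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage1_table", "stage2_table"]

#: the 26 reported dietary variables (24 raw nutrients + DPI + DEI)
REPORT_NUTRIENTS = tuple(NUTRIENTS) + ("DPI", "DEI")


@dataclass
class RunConfig:
    outdir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None  # read an existing cohort instead of simulating
    window_length: float = 6.0
    knots: int = 4
    nutrients: tuple[str, ...] = REPORT_NUTRIENTS
    groups: tuple[str, ...] = ("all",) + GROUPS
    confounders: tuple[str, ...] = CONFOUNDERS

    def validate(self) -> None:
        if not self.confounders:
            raise DietriskError("confounder list must be nonempty")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise DietriskError(f"input_dir {self.input_dir} does not exist")


def stage1_table(profiles, assignment, nutrients, groups, confounders) -> pd.DataFrame:
    """Hazard-ratio table: one row per (nutrient x group)."""
    rows = []
    for nut in nutrients:
        for grp in groups:
            try:
                res = nutrient_hr(profiles, nut, grp, assignment, confounders)
            except (FittingError, StratificationError) as exc:
                logger.warning("stage1 %s/%s failed: %s", nut, grp, exc)
                continue
            rows.append({
                "nutrient": nut, "group": grp, "unit_scale": res.unit_scale,
                "hr": round(res.hr, 4), "ci_lo": round(res.ci95[0], 4),
                "ci_hi": round(res.ci95[1], 4), "p": res.p_wald,
            })
    return pd.DataFrame(rows)


def stage2_table(profiles, assignment, nutrients, groups, confounders, knots=4) -> pd.DataFrame:
    """Protective-range table: A/B/C points and P / P-NL per (nutrient x group)."""
    rows = []
    for nut in nutrients:
        for grp in groups:
            try:
                rep = range_report(profiles, nut, grp, assignment, confounders, knots)
            except (FittingError, SplineError, StratificationError) as exc:
                logger.warning("stage2 %s/%s failed: %s", nut, grp, exc)
                continue
            fmt = lambda v: round(v, 2) if v is not None else None
            rows.append({
                "nutrient": nut, "group": grp,
                "A": fmt(rep.A), "B": fmt(rep.B), "C": fmt(rep.C),
                "p": rep.p_overall, "p_nonlinear": rep.p_nonlinear,
                "flags": "; ".join(rep.flags),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Writes cohort tables, profiles.csv, groups.csv, comparison/KM output,
    stage1.csv, stage2.csv, the nutrient correlation matrix, a manifest and
    a log. The manifest records the first failed stage on error.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "python": platform.python_version(),
                      "seed": config.cohort.seed, "stages": {}}
    stage = "simulate"
    try:
        if config.input_dir is not None:
            cohort = LongitudinalCohort.from_csv(config.input_dir)
            manifest["input_dir"] = str(config.input_dir)
        else:
            cohort = generate_cohort(config.cohort)
            cohort.to_csv(out / "cohort")
        manifest["stages"]["simulate"] = {"patients": int(len(cohort.baseline))}

        stage = "preprocess"
        profiles, exclusions = build_profiles(cohort, config.window_length)
        profiles.to_csv(out / "profiles.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"]["preprocess"] = {
            "profiles": int(len(profiles)), "excluded": int(len(exclusions)),
        }

        stage = "stratify"
        assignment = tertile_split(
            profiles["baseline_albumin"], profiles["patient_id"]
        )
        assignment.assignment.to_csv(out / "groups.csv", index=False)
        curves, logrank_p = km_logrank(
            profiles["T"], profiles["event"], assignment, profiles["patient_id"]
        )
        curves.to_csv(out / "km_curves.csv", index=False)
        manifest["stages"]["stratify"] = {
            "cutpoints": list(assignment.cutpoints), "logrank_p": logrank_p,
        }

        stage = "stage1"
        nutrients = [n for n in config.nutrients if n in profiles.columns]
        t4 = stage1_table(profiles, assignment, nutrients, config.groups, config.confounders)
        t4.to_csv(out / "stage1.csv", index=False)
        manifest["stages"]["stage1"] = {"rows": int(len(t4))}

        stage = "stage2"
        t5 = stage2_table(profiles, assignment, nutrients, config.groups,
                          config.confounders, config.knots)
        t5.to_csv(out / "stage2.csv", index=False)
        manifest["stages"]["stage2"] = {"rows": int(len(t5))}

        stage = "reports"
        corr = pearson_matrix(profiles, nutrients)
        corr.to_csv(out / "nutrient_correlation.csv")
        manifest["stages"]["reports"] = {"correlation_dim": int(corr.shape[0])}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
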