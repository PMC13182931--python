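"""Stage 1: one confounder-adjusted Cox model per (nutrient, albumin group),
reporting the scaled hazard ratio, 95% CI and Wald P — the hazard-ratio
table of the analysis.

Writes results/stage1.csv.
"""

from pathlib import Path

import pandas as pd

from dietrisk.cohort import CONFOUNDERS
from dietrisk.pipeline import REPORT_NUTRIENTS, stage1_table
from dietrisk.stratify import SubtypeAssignment

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    profiles = pd.read_csv(ROOT / "profiles.csv")
    groups = pd.read_csv(ROOT / "groups.csv")
    assignment = SubtypeAssignment(groups, (float("nan"), float("nan")))
    nutrients = [n for n in REPORT_NUTRIENTS if n in profiles.columns]
    table = stage1_table(profiles, assignment, nutrients,
                         ("all", "low", "medium", "high"), CONFOUNDERS)
    table.to_csv(ROOT / "stage1.csv", index=False)
    allrows = table[table["group"] == "all"]
    n_sig = (allrows["p"] < 0.05).sum()
    print(f"{len(table)} hazard-ratio rows written")
    print(f"whole-cohort column: {n_sig}/{len(allrows)} nutrients associated "
          f"with mortality (P < 0.05)")
    for _, r in allrows[allrows["nutrient"].isin(["Protein", "Fat", "Na", "Df"])].iterrows():
        print(f"  {r['nutrient']:>8}: HR {r['hr']:.2f} "
              f"({r['ci_lo']:.2f}-{r['ci_hi']:.2f}) per {r['unit_scale']:g} unit(s), "
              f"P = {r['p']:.2e}")


if __name__ == "__main__":
    main()
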