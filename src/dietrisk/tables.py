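"""Packaged printed-table fixtures and the count checks derived from them.

The four report tables (baseline characteristics, time-averaged dietary
profiles, per-nutrient hazard ratios, and protective intake ranges) ship as
versioned CSV fixtures. P-value cells use the printed dialect: an exact
numeral ("0.56"), an upper bound ("<0.001"), or "-" for absent.

Two threshold conventions coexist in the source tables and both are
first-class here: the hazard-ratio table's significance counts require
treating a printed "0.05" as significant (inclusive), while the joint
P/P-NL count of the range table requires the strict comparison.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import FixtureError

__all__ = ["load_fixture", "parse_p_cell", "count_significant",
           "count_joint_significant", "count_guideline_gaps", "pearson_matrix",
           "percent"]

_FILES = {"T1": "table1.csv", "T3": "table3.csv", "T4": "table4.csv", "T5": "table5.csv"}
_P_RE = re.compile(r"^(<)?\s*(\d*\.?\d+)$")


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one printed-table fixture (T1, T3, T4 or T5)."""
    if table_id not in _FILES:
        raise FixtureError(f"unknown table id {table_id!r}")
    path = resources.files("dietrisk.data").joinpath(_FILES[table_id])
    with path.open() as fh:
        return pd.read_csv(fh, dtype=str)


@dataclass(frozen=True)
class PCell:
    value: float | None
    is_bound: bool  # True when printed as "<value"


def parse_p_cell(text: str) -> PCell:
    """Parse one printed P cell: "<0.001" -> bound, "0.56" -> value, "-" -> absent."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        raise FixtureError("empty P cell")
    s = str(text).strip()
    if not s:
        raise FixtureError("empty P cell")
    if s == "-":
        return PCell(None, False)
    m = _P_RE.match(s)
    if not m:
        raise FixtureError(f"unparseable P cell {text!r}")
    return PCell(float(m.group(2)), m.group(1) == "<")


def _significant(cell: PCell, threshold: float, inclusive: bool) -> bool:
    if cell.value is None:
        return False
    if cell.is_bound:  # "<x" is below any threshold >= x
        return cell.value <= threshold
    return cell.value <= threshold if inclusive else cell.value < threshold


def percent(count: int, total: int) -> int:
    """Whole-percent share, rounded half-up (the prose convention)."""
    return int(math.floor(100.0 * count / total + 0.5))


def count_significant(
    fixture: pd.DataFrame, column: str, threshold: float = 0.05, inclusive: bool = True
) -> tuple[int, int]:
    """(count, whole-percent) of rows whose P column is significant.

    Cells printed "-" are excluded from both numerator and denominator.
    """
    if column not in fixture.columns:
        raise FixtureError(f"fixture has no column {column!r}")
    cells = [parse_p_cell(v) for v in fixture[column]]
    usable = [c for c in cells if c.value is not None]
    n_sig = sum(_significant(c, threshold, inclusive) for c in usable)
    return n_sig, percent(n_sig, len(usable))


def count_joint_significant(
    fixture: pd.DataFrame, group: str, threshold: float = 0.05, strict: bool = True
) -> tuple[int, int]:
    """Rows of the range table where both P and P-NL clear the threshold.

    The joint criterion uses the strict comparison by default, matching the
    footnote "only when both P and P for nonlinear are significant".
    """
    pcol, nlcol = f"p_{group}", f"pnl_{group}"
    for c in (pcol, nlcol):
        if c not in fixture.columns:
            raise FixtureError(f"fixture has no column {c!r}")
    inclusive = not strict
    n = 0
    for pv, nl in zip(fixture[pcol], fixture[nlcol]):
        if _significant(parse_p_cell(pv), threshold, inclusive) and _significant(
            parse_p_cell(nl), threshold, inclusive
        ):
            n += 1
    return n, percent(n, len(fixture))


def count_guideline_gaps(fixture: pd.DataFrame) -> int:
    """Nutrients whose recommended intake is absent ("-") or carries only a
    general-population value (a "Normal"-prefixed recommendation)."""
    if "recommended" not in fixture.columns:
        raise FixtureError("fixture has no 'recommended' column")
    n = 0
    for cell in fixture["recommended"]:
        s = str(cell).strip()
        if s == "-" or s.lower().startswith("normal"):
            n += 1
    return n


def pearson_matrix(profiles: pd.DataFrame, columns) -> pd.DataFrame:
    """Pearson correlation matrix of the nutrient intake columns."""
    if len(profiles) < 3:
        raise FixtureError("need at least 3 profiles for a correlation matrix")
    sub = profiles[list(columns)].astype(float)
    zero_var = [c for c in sub.columns if sub[c].nunique() <= 1]
    if zero_var:
        import warnings

        warnings.warn(f"zero-variance columns excluded from correlation: {zero_var}")
        sub = sub.drop(columns=zero_var)
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr
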