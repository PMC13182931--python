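"""Time-averaging exactness: LOCF, half-open windows, the two-level mean,
ideal body weight and DPI/DEI arithmetic, and profile assembly."""

import numpy as np
import pandas as pd
import pytest

from dietrisk.cohort import LongitudinalCohort
from dietrisk.errors import DietriskError
from dietrisk.preprocess import (
    build_profiles,
    derive_dpi_dei,
    ideal_body_weight,
    locf_impute,
    patient_time_average,
    window_average,
)


def frame(months, values, col="albumin"):
    return pd.DataFrame({"month": months, col: values})


class TestLocf:
    def test_carry_forward(self):
        out = locf_impute(frame([0, 1, 2], [5.0, np.nan, np.nan]))
        assert out["albumin"].tolist() == [5.0, 5.0, 5.0]

    def test_no_backward_fill(self):
        out = locf_impute(frame([0, 1], [np.nan, 7.0]))
        assert np.isnan(out["albumin"].iloc[0]) and out["albumin"].iloc[1] == 7.0

    def test_reset_at_new_observation(self):
        out = locf_impute(frame([0, 1, 2, 3], [1.0, np.nan, 3.0, np.nan]))
        assert out["albumin"].tolist() == [1.0, 1.0, 3.0, 3.0]

    def test_unsorted_rejected(self):
        with pytest.raises(DietriskError, match="sorted"):
            locf_impute(frame([2, 1], [1.0, 2.0]))


class TestWindowAverage:
    def test_fig3_scheme(self):
        out = window_average(frame([1, 2, 8], [10.0, 20.0, 30.0]), 6)
        assert out["albumin"].tolist() == [15.0, 30.0]

    def test_empty_windows_dropped(self):
        out = window_average(frame([13, 14, 17], [1.0, 2.0, 3.0]), 6)
        assert len(out) == 1
        assert out["albumin"].iloc[0] == pytest.approx(2.0)

    def test_permutation_within_window(self):
        a = window_average(frame([1, 2, 3], [10.0, 20.0, 30.0]), 6)
        b = window_average(frame([3, 1, 2], [30.0, 10.0, 20.0]), 6)
        assert a["albumin"].tolist() == b["albumin"].tolist()

    def test_no_records_gives_empty(self):
        out = window_average(frame([], []), 6)
        assert len(out) == 0


class TestTwoLevelAverage:
    def test_mean_of_window_means(self):
        assert patient_time_average(pd.Series([15.0, 30.0]))["value"] == 22.5
        assert patient_time_average(pd.Series([30.0]))["value"] == 30.0

    def test_two_level_differs_from_pooled(self):
        """Records {10,20 | 30}: pooled mean is 20, the two-level mean 22.5."""
        records = frame([1, 2, 8], [10.0, 20.0, 30.0])
        pooled = records["albumin"].mean()
        two_level = patient_time_average(window_average(records, 6))["albumin"]
        assert pooled == 20.0
        assert two_level == 22.5

    def test_reduces_to_pooled_with_balanced_windows(self):
        records = frame([1, 2, 7, 8], [10.0, 20.0, 30.0, 40.0])
        two_level = patient_time_average(window_average(records, 6))["albumin"]
        assert two_level == records["albumin"].mean()


class TestBodyWeightArithmetic:
    def test_modified_broca(self):
        assert ideal_body_weight(160.0) == 55.0
        assert ideal_body_weight(105.5) == pytest.approx(0.5)
        with pytest.raises(DietriskError):
            ideal_body_weight(100.0)

    def test_dpi_dei(self):
        assert derive_dpi_dei(55.0, 1650.0, 55.0) == (1.0, 30.0)
        assert derive_dpi_dei(0.0, 1650.0, 55.0)[0] == 0.0
        with pytest.raises(DietriskError):
            derive_dpi_dei(55.0, 1650.0, 0.0)

    def test_cohort_scale_coherence(self):
        """Mean protein 52.52 g/d at the implied mean ideal body weight
        (~57.6 kg) lands near the printed mean DPI of 0.92."""
        dpi, _ = derive_dpi_dei(52.52, 1582.3, 57.6)
        assert dpi == pytest.approx(0.912, abs=0.001)


def toy_cohort():
    """Three patients with hand-computable averages.

    p1: albumin windows [0,6)={30,34} -> 32, [6,12)={38} -> 38; avg 35.
        weight constant 60. Protein windows {50,60}->55, {70}->70; avg 62.5.
        Calories {1500},{1700} -> 1600. Height 160 -> ibw 55.
        DPI = 62.5/55, DEI = 1600/55.
    p2: albumin observed only at month 12 (LOCF cannot backfill):
        windows [0,6) empty for albumin, [12,18)={40} -> 40.
        single diet record month 0.
    p3: no diet records -> excluded.
    """
    baseline = pd.DataFrame({
        "patient_id": [1, 2, 3],
        "age": [60.0, 50.0, 55.0],
        "gender": [1, 0, 1],
        "height": [160.0, 170.0, 165.0],
        "diabetes": [0, 1, 0],
        "albumin": [30.0, 36.0, 33.0],
        "weight": [60.0, 70.0, 65.0],
    })
    visits = pd.DataFrame({
        "patient_id": [1, 1, 1, 2, 2, 2, 3],
        "month": [0, 3, 8, 0, 3, 12, 0],
        "albumin": [30.0, 34.0, 38.0, np.nan, np.nan, 40.0, 33.0],
        "weight": [60.0, 60.0, 60.0, 70.0, 70.0, 70.0, 65.0],
    })
    diets = pd.DataFrame({
        "patient_id": [1, 1, 1, 2],
        "month": [0, 3, 8, 0],
        "Protein": [50.0, 60.0, 70.0, 40.0],
        "Calories": [1500.0, 1500.0, 1700.0, 1200.0],
    })
    outcomes = pd.DataFrame({
        "patient_id": [1, 2, 3],
        "t0": [0.0, 0.0, 0.0],
        "tend": [14.0, 15.0, 6.0],
        "event": [1, 0, 0],
    })
    return LongitudinalCohort(baseline, visits, diets, outcomes)


class TestBuildProfiles:
    def test_hand_computed_toy_cohort(self):
        profiles, exclusions = build_profiles(toy_cohort(), 6)
        assert profiles["patient_id"].tolist() == [1, 2]
        p1 = profiles.set_index("patient_id").loc[1]
        assert p1["albumin"] == pytest.approx((32 + 38) / 2)
        assert p1["Protein"] == pytest.approx((55 + 70) / 2)
        assert p1["Calories"] == pytest.approx((1500 + 1700) / 2)
        assert p1["DPI"] == pytest.approx(62.5 / 55)
        assert p1["DEI"] == pytest.approx(1600 / 55)
        assert p1["T"] == 14.0 and p1["event"] == 1

    def test_no_future_imputation(self):
        """A lab observed only late never leaks into earlier windows: the
        profile value equals that late value, from the single populated
        window, and LOCF leaves the early windows empty."""
        profiles, _ = build_profiles(toy_cohort(), 6)
        p2 = profiles.set_index("patient_id").loc[2]
        assert p2["albumin"] == pytest.approx(40.0)

    def test_dietless_patient_excluded_with_reason(self):
        profiles, exclusions = build_profiles(toy_cohort(), 6)
        assert 3 not in set(profiles["patient_id"])
        row = exclusions.set_index("patient_id").loc[3]
        assert "diet" in row["reason"]

    def test_single_window_degeneracy(self):
        """With every record inside one window, profiles are plain means."""
        cohort = toy_cohort()
        cohort.visits = cohort.visits[cohort.visits["month"] < 6].reset_index(drop=True)
        cohort.diets = cohort.diets[cohort.diets["month"] < 6].reset_index(drop=True)
        profiles, _ = build_profiles(cohort, 6)
        p1 = profiles.set_index("patient_id").loc[1]
        assert p1["albumin"] == pytest.approx(32.0)
        assert p1["Protein"] == pytest.approx(55.0)

    def test_matches_per_patient_composition(self, small_cohort):
        """The vectorized profile builder equals the documented per-patient
        locf -> window_average -> patient_time_average composition."""
        profiles, _ = build_profiles(small_cohort, 6)
        prof = profiles.set_index("patient_id")
        visits = small_cohort.visits.sort_values(["patient_id", "month"])
        for pid in prof.index[:20]:
            pv = visits[visits["patient_id"] == pid][["month", "albumin", "weight"]]
            manual = patient_time_average(window_average(locf_impute(pv), 6))
            assert prof.at[pid, "albumin"] == pytest.approx(manual["albumin"], nan_ok=True)
            assert prof.at[pid, "weight"] == pytest.approx(manual["weight"])

    def test_profile_count_bounded_and_reasons_logged(self, small_cohort):
        profiles, exclusions = build_profiles(small_cohort, 6)
        assert len(profiles) + len(exclusions) >= len(small_cohort.baseline)
        assert len(profiles) <= len(small_cohort.baseline)
        assert exclusions["reason"].notna().all()
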