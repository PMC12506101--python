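import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bmirrda.config import StudyConfig
from bmirrda.derive import (
    GrowthReference,
    ReferenceRangeError,
    categorise_adult,
    categorise_cyp,
    compute_bmi,
    lms_zscore,
    pair_adult,
    pair_cyp,
    read_reference,
    reference_lookup,
    write_reference,
)

CATEGORY_ORDER = {"underweight": 1, "normal": 2, "overweight": 3, "obese": 4}


class TestComputeBmi:
    def test_arithmetic(self):
        assert compute_bmi(70.0, 1.75) == pytest.approx(22.857142857, rel=1e-9)
        assert compute_bmi(100.0, 1.0) == 100.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(0.0, 1.75)
        with pytest.raises(ValueError):
            compute_bmi(70.0, -1.0)


class TestLmsZscore:
    @pytest.mark.parametrize("L", [-2.0, -1.0, 0.0, 0.5, 1.0])
    def test_zero_at_median(self, L):
        assert lms_zscore(16.0, L, 16.0, 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_log_branch_closed_form(self):
        # L = 0: z = ln(x/M)/S, so x = M e^S gives z = 1
        assert lms_zscore(16.0 * math.exp(0.1), 0.0, 16.0, 0.1) == pytest.approx(1.0, rel=1e-12)

    def test_frozen_value(self):
        # independently recomputed: ((20/16)^-1.6 - 1)/(-1.6 * 0.11)
        assert lms_zscore(20.0, -1.6, 16.0, 0.11) == pytest.approx(1.705956094751716, rel=1e-12)

    def test_non_positive_inputs_rejected(self):
        for bad in [(0.0, -1.0, 16.0, 0.1), (16.0, -1.0, 0.0, 0.1), (16.0, -1.0, 16.0, 0.0)]:
            with pytest.raises(ValueError):
                lms_zscore(*bad)

    @given(
        # |L| >= 1e-3: below that the power transform underflows to the log
        # branch's behaviour and strict monotonicity is only approximate
        st.floats(min_value=-2.0, max_value=1.5).filter(lambda L: abs(L) >= 1e-3),
        st.floats(min_value=10.0, max_value=25.0),
        st.floats(min_value=0.05, max_value=0.2),
        st.floats(min_value=10.0, max_value=60.0),
        st.floats(min_value=0.1, max_value=5.0),
    )
    def test_strictly_increasing_in_x(self, L, M, S, x, dx):
        assert lms_zscore(x + dx, L, M, S) > lms_zscore(x, L, M, S)


class TestReferenceLookup:
    def test_exact_at_grid_knots(self, reference):
        row = reference.frame.iloc[10]
        L, M, S = reference_lookup(reference, row["sex"], row["age_months"])
        assert (L, M, S) == (row["L"], row["M"], row["S"])

    def test_midpoint_is_arithmetic_mean(self, reference):
        grp = reference.frame[reference.frame["sex"] == "F"].reset_index(drop=True)
        a0, a1 = grp.loc[3, "age_months"], grp.loc[4, "age_months"]
        L, M, S = reference_lookup(reference, "F", (a0 + a1) / 2)
        assert M == pytest.approx((grp.loc[3, "M"] + grp.loc[4, "M"]) / 2, rel=1e-12)
        assert L == pytest.approx((grp.loc[3, "L"] + grp.loc[4, "L"]) / 2, rel=1e-12)
        assert S == pytest.approx((grp.loc[3, "S"] + grp.loc[4, "S"]) / 2, rel=1e-12)

    def test_age_outside_grid_names_bound(self, reference):
        with pytest.raises(ReferenceRangeError, match=r"\[24"):
            reference_lookup(reference, "F", 12.0)

    def test_round_trip_through_file(self, reference, tmp_path):
        path = tmp_path / "ref.csv"
        write_reference(reference, path)
        back = read_reference(path)
        pd.testing.assert_frame_equal(back.frame, reference.frame)

    def test_invalid_reference_rejected(self):
        bad = pd.DataFrame({"sex": ["F", "F"], "age_months": [24, 24], "L": [1, 1], "M": [16, 16], "S": [0.1, 0.1]})
        with pytest.raises(ValueError, match="strictly increasing"):
            GrowthReference(bad)


class TestCategoriseAdult:
    @pytest.mark.parametrize(
        "bmi,expected",
        [
            (12.0, "underweight"),
            (18.4, "underweight"),
            (18.5, "normal"),       # lower cut belongs to normal
            (24.9, "normal"),
            (25.0, "overweight"),
            (29.9, "overweight"),
            (30.0, "obese"),        # WHO convention: 30 is obese
            (32.1, "obese"),
            (100.0, "obese"),
        ],
    )
    def test_cut_points(self, bmi, expected):
        assert categorise_adult(bmi) == expected

    @given(st.floats(min_value=12.0, max_value=100.0), st.floats(min_value=0.0, max_value=10.0))
    def test_monotone_in_bmi(self, bmi, delta):
        lo = categorise_adult(bmi)
        hi = categorise_adult(min(bmi + delta, 100.0))
        assert CATEGORY_ORDER[lo] <= CATEGORY_ORDER[hi]


class TestCategoriseCyp:
    def test_examples(self, config):
        th = config.cyp_z_thresholds()
        assert categorise_cyp(0.0, th) == "normal"
        assert categorise_cyp(2.0, th) == "obese"       # above the 95th-percentile z
        assert categorise_cyp(-3.0, th) == "underweight"
        assert categorise_cyp(1.2, th) == "overweight"

    @given(st.floats(min_value=-4, max_value=4), st.floats(min_value=0, max_value=2))
    def test_monotone_in_z(self, z, dz):
        th = StudyConfig().cyp_z_thresholds()
        assert CATEGORY_ORDER[categorise_cyp(z, th)] <= CATEGORY_ORDER[categorise_cyp(z + dz, th)]

    @given(
        st.floats(min_value=13.0, max_value=40.0),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_composition_with_zscore_monotone_in_bmi(self, x, dx):
        th = StudyConfig().cyp_z_thresholds()
        L, M, S = -1.2, 16.5, 0.11
        lo = categorise_cyp(lms_zscore(x, L, M, S), th)
        hi = categorise_cyp(lms_zscore(x + dx, L, M, S), th)
        assert CATEGORY_ORDER[lo] <= CATEGORY_ORDER[hi]


def _hw(rows, component):
    df = pd.DataFrame(rows, columns=["record_id", "date", "value"])
    df["date"] = pd.to_datetime(df["date"])
    df["person_id"] = "A"
    df["component"] = component
    return df


class TestPairCyp:
    def test_nearest_in_window_wins(self, config):
        heights = _hw([("h0", "2009-12-02", 1.40), ("h1", "2009-06-15", 1.38)], "height")
        weights = _hw([("w0", "2010-01-01", 40.0)], "weight")
        out = pair_cyp(heights, weights, config)
        assert len(out) == 1
        assert out.iloc[0]["height_record_id"] == "h0"  # 30 days beats 200 days

    def test_181_days_is_out_of_window(self, config):
        heights = _hw([("h0", "2009-07-04", 1.40)], "height")  # 181 days before
        weights = _hw([("w0", "2010-01-01", 40.0)], "weight")
        assert pair_cyp(heights, weights, config).empty

    def test_same_day_gap_zero(self, config):
        heights = _hw([("h0", "2010-01-01", 1.40)], "height")
        weights = _hw([("w0", "2010-01-01", 40.0)], "weight")
        out = pair_cyp(heights, weights, config)
        assert out.iloc[0]["height_date"] == out.iloc[0]["weight_date"]

    def test_tie_prefers_earlier_height(self, config):
        heights = _hw([("h0", "2010-01-11", 1.41), ("h1", "2009-12-22", 1.40)], "height")
        weights = _hw([("w0", "2010-01-01", 40.0)], "weight")
        out = pair_cyp(heights, weights, config)
        assert out.iloc[0]["height_record_id"] == "h1"

    @given(
        st.lists(st.integers(min_value=0, max_value=720), min_size=0, max_size=8),
        st.lists(st.integers(min_value=0, max_value=720), min_size=1, max_size=8),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_brute_force_oracle(self, hdays, wdays, salt):
        config = StudyConfig()
        base = dt.date(2005, 1, 1)
        heights = _hw(
            [(f"h{i}", (base + dt.timedelta(days=d)).isoformat(), 1.3 + (i % 5) / 100) for i, d in enumerate(hdays)],
            "height",
        )
        weights = _hw(
            [(f"w{i}", (base + dt.timedelta(days=d)).isoformat(), 35.0 + i) for i, d in enumerate(wdays)],
            "weight",
        )
        out = pair_cyp(heights, weights, config)
        got = {r["weight_record_id"]: r["height_record_id"] for _, r in out.iterrows()}
        # brute force: filter all pairs then argmin on (gap, date, value, id)
        expected = {}
        for _, w in weights.iterrows():
            cands = [
                (abs((h["date"] - w["date"]).days), h["date"], h["value"], h["record_id"])
                for _, h in heights.iterrows()
                if abs((h["date"] - w["date"]).days) <= config.hw_pair_window_days
            ]
            if cands:
                expected[w["record_id"]] = min(cands)[3]
        assert got == expected


class TestPairAdult:
    def test_carry_forward_uses_most_recent_on_or_before(self, config):
        heights = _hw([("h0", "2005-03-01", 1.80), ("h1", "2015-03-01", 1.78)], "height")
        weights = _hw([("w0", "2012-06-01", 80.0)], "weight")
        out = pair_adult(heights, weights, config)
        assert out.iloc[0]["height_record_id"] == "h0"

    def test_forward_fallback_when_no_prior_height(self, config):
        heights = _hw([("h0", "2005-03-01", 1.80)], "height")
        weights = _hw([("w0", "2003-01-01", 80.0)], "weight")
        out = pair_adult(heights, weights, config)
        assert out.iloc[0]["height_record_id"] == "h0"

    def test_no_heights_no_pairs(self, config):
        weights = _hw([("w0", "2003-01-01", 80.0)], "weight")
        assert pair_adult(_hw([], "height"), weights, config).empty

    def test_single_height_mode_uses_most_recent_everywhere(self):
        config = StudyConfig(adult_height_mode="single")
        heights = _hw([("h0", "2005-03-01", 1.80), ("h1", "2015-03-01", 1.78)], "height")
        weights = _hw([("w0", "2003-01-01", 80.0), ("w1", "2012-06-01", 82.0)], "weight")
        out = pair_adult(heights, weights, config)
        assert set(out["height_record_id"]) == {"h1"}


def test_paired_bmi_reproducible_from_components(small_result, small_dataset):
    """Every derived entry's BMI equals weight/height^2 of its stored parts."""
    rrda = small_result.rrda
    derived = rrda[rrda["data_type"] == "height_weight"]
    assert not derived.empty
    assert derived["height_date"].notna().all()
    assert derived["weight_date"].notna().all()
    # the pairing window only binds the CYP branch
    cyp = derived[derived["branch"] == "CYP"]
    gaps = (cyp["height_date"] - cyp["weight_date"]).dt.days.abs()
    assert (gaps <= small_dataset.config.hw_pair_window_days).all()
    assert (derived["bmi_date"] == derived["weight_date"]).all()
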