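import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bmirrda.config import CATEGORIES, StudyConfig
from bmirrda.harmonise import (
    decode_category,
    encode_category,
    flag_pregnancy,
    over_time_clean,
    same_day_clean,
    select_daily_entry,
)


def _entries(rows):
    """rows: (entry_id, person, date, value_or_None, category, rank, source, branch, preg)"""
    df = pd.DataFrame(
        rows,
        columns=["entry_id", "person_id", "bmi_date", "bmi_value", "category", "rank", "source", "branch",
                 "pregnancy_flag"],
    )
    df["bmi_date"] = pd.to_datetime(df["bmi_date"])
    df["bmi_value"] = df["bmi_value"].astype(float)
    return df


class TestEncodeCategory:
    def test_published_encoding(self):
        assert encode_category("underweight") == 1
        assert encode_category("normal") == 2
        assert encode_category("overweight") == 3
        assert encode_category("obese") == 4

    def test_bijection(self):
        for c in CATEGORIES:
            assert decode_category(encode_category(c)) == c

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            encode_category("severely obese")
        with pytest.raises(ValueError):
            decode_category(5)


class TestSameDayClean:
    def test_category_only_pair_one_apart_both_removed(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", None, "normal", 5, "WLGP", "adult", False),
                ("b", "P", "2010-01-01", None, "overweight", 5, "WLGP", "adult", False),
            ]
        )
        kept, removed, dec = same_day_clean(e, config)
        assert kept.empty and len(removed) == 2
        assert dec[0]["rule"] == "same_day_category_conflict"

    def test_values_within_5pct_same_category_kept(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 24.0, "normal", 1, "WLGP", "adult", False),
                ("b", "P", "2010-01-01", 24.5, "normal", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = same_day_clean(e, config)
        assert len(kept) == 2 and removed.empty

    def test_values_with_category_disagreement_removed(self, config):
        # 24.0 vs 25.0: only ~4.2% apart but categories differ -> inconsistent
        e = _entries(
            [
                ("a", "P", "2010-01-01", 24.0, "normal", 1, "WLGP", "adult", False),
                ("b", "P", "2010-01-01", 25.0, "overweight", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = same_day_clean(e, config)
        assert kept.empty and len(removed) == 2

    def test_singleton_kept(self, config):
        e = _entries([("a", "P", "2010-01-01", 27.3, "overweight", 1, "WLGP", "adult", False)])
        kept, removed, dec = same_day_clean(e, config)
        assert len(kept) == 1 and removed.empty and dec == []

    def test_mixed_day_value_and_matching_category_kept(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 26.0, "overweight", 1, "WLGP", "adult", False),
                ("b", "P", "2010-01-01", None, "overweight", 5, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = same_day_clean(e, config)
        assert len(kept) == 2

    def test_partition_identity(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 24.0, "normal", 1, "WLGP", "adult", False),
                ("b", "P", "2010-01-01", 31.0, "obese", 1, "WLGP", "adult", False),
                ("c", "Q", "2010-01-01", 22.0, "normal", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = same_day_clean(e, config)
        assert len(kept) + len(removed) == len(e)

    @given(
        st.lists(
            st.tuples(
                st.one_of(st.none(), st.floats(min_value=13.0, max_value=60.0)),
                st.sampled_from(CATEGORIES),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_exhaustive_pairwise_oracle(self, day):
        config = StudyConfig()
        e = _entries(
            [(f"e{i}", "P", "2010-01-01", v, c, 1, "WLGP", "adult", False) for i, (v, c) in enumerate(day)]
        )
        kept, removed, _ = same_day_clean(e, config)
        # oracle: an entry is removed iff it belongs to any inconsistent pair
        bad = set()
        for (i, (vi, ci)), (j, (vj, cj)) in itertools.combinations(enumerate(day), 2):
            if vi is not None and vj is not None:
                ok = abs(vi - vj) / min(vi, vj) < config.same_day_rel_diff and ci == cj
            else:
                ok = ci == cj
            if not ok:
                bad |= {f"e{i}", f"e{j}"}
        assert set(removed["entry_id"]) == bad
        assert set(kept["entry_id"]) == {f"e{i}" for i in range(len(day))} - bad


class TestOverTimeClean:
    def test_gradual_change_kept(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 25.0, "overweight", 1, "WLGP", "adult", False),
                ("b", "P", "2011-01-01", 26.0, "overweight", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = over_time_clean(e, config)
        assert len(kept) == 2 and removed.empty

    def test_implausible_jump_removed(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 25.0, "overweight", 1, "WLGP", "adult", False),
                ("b", "P", "2010-01-31", 45.0, "obese", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, dec = over_time_clean(e, config)
        assert list(removed["entry_id"]) == ["b"]
        assert dec[0]["rule"] == "over_time_conflict"

    def test_cyp_entries_returned_unchanged(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 16.0, "normal", 1, "WLGP", "CYP", False),
                ("b", "P", "2010-01-31", 30.0, "obese", 1, "WLGP", "CYP", False),
            ]
        )
        kept, removed, _ = over_time_clean(e, config)
        assert len(kept) == 2 and removed.empty

    def test_pregnancy_entries_exempt_and_not_baseline(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 24.0, "normal", 1, "WLGP", "adult", False),
                ("b", "P", "2010-07-01", 31.0, "obese", 3, "MIDS", "adult", True),
                ("c", "P", "2010-10-01", 24.5, "normal", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = over_time_clean(e, config)
        assert removed.empty  # the pregnancy spike neither is removed nor poisons "c"

    def test_baseline_stays_after_removal(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 25.0, "overweight", 1, "WLGP", "adult", False),
                ("b", "P", "2010-01-20", 45.0, "obese", 1, "WLGP", "adult", False),
                ("c", "P", "2010-02-15", 25.3, "overweight", 1, "WLGP", "adult", False),
            ]
        )
        kept, removed, _ = over_time_clean(e, config)
        assert list(removed["entry_id"]) == ["b"]
        assert "c" in set(kept["entry_id"])


class TestSelectDailyEntry:
    def test_lowest_rank_wins(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 24.0, "normal", 4, "NCCH", "CYP", False),
                ("b", "P", "2010-01-01", 24.2, "normal", 1, "WLGP", "CYP", False),
            ]
        )
        out = select_daily_entry(e)
        assert list(out["entry_id"]) == ["b"]

    def test_rank_tie_broken_by_ascending_bmi(self, config):
        e = _entries(
            [
                ("a", "P", "2010-01-01", 24.8, "normal", 2, "WLGP", "adult", False),
                ("b", "P", "2010-01-01", 24.1, "normal", 2, "WLGP", "adult", False),
            ]
        )
        out = select_daily_entry(e)
        assert out.iloc[0]["bmi_value"] == 24.1

    def test_single_survivor_is_itself(self, config):
        e = _entries([("a", "P", "2010-01-01", 24.0, "normal", 1, "WLGP", "adult", False)])
        out = select_daily_entry(e)
        assert list(out["entry_id"]) == ["a"]

    def test_one_entry_per_person_day(self, small_result):
        assert not small_result.rrda.duplicated(subset=["person_id", "bmi_date"]).any()


class TestFlagPregnancy:
    def _births(self, rows):
        df = pd.DataFrame(rows, columns=["person_id", "birth_date"])
        df["birth_date"] = pd.to_datetime(df["birth_date"])
        return df

    @pytest.mark.parametrize(
        "bmi_date,expected",
        [
            ("2010-06-15", True),    # 200 days before the birth
            ("2011-10-23", False),   # 295 days after: just outside
            ("2011-10-22", True),    # 294 days after: boundary included
            ("2009-03-01", False),
        ],
    )
    def test_window_boundaries(self, config, bmi_date, expected):
        e = _entries([("a", "P", bmi_date, 24.0, "normal", 1, "WLGP", "adult", False)])
        out = flag_pregnancy(e, self._births([("P", "2011-01-01")]), config)
        assert bool(out.iloc[0]["pregnancy_flag"]) is expected

    def test_no_maternity_data_all_false(self, config):
        e = _entries([("a", "P", "2010-06-15", 24.0, "normal", 1, "WLGP", "adult", False)])
        out = flag_pregnancy(e, self._births([]), config)
        assert not out["pregnancy_flag"].any()
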