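import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bmirrda.audit import AuditLog
from bmirrda.codelists import default_codelists
from bmirrda.config import StudyConfig
from bmirrda.extract import (
    RankError,
    assign_rank,
    collate,
    filter_extremes,
    match_events,
    standardise_units,
)


def _wlgp(rows):
    df = pd.DataFrame(rows, columns=["person_id", "event_date", "code", "numeric_value", "unit"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


def _pedw(rows):
    df = pd.DataFrame(rows, columns=["person_id", "admission_date", "code"])
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    return df


def _components(rows):
    df = pd.DataFrame(
        rows,
        columns=["record_id", "person_id", "date", "component", "value", "category", "source", "data_type", "rank"],
    )
    df["date"] = pd.to_datetime(df["date"])
    return df


class TestMatchEvents:
    def test_obesity_diagnosis_becomes_obese_rank_6(self, config):
        out = match_events(_wlgp([]), _pedw([("A", "2010-01-01", "E66")]), default_codelists(), config)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["component"] == "obesity_dx"
        assert row["category"] == "obese"
        assert row["rank"] == 6

    def test_unlisted_code_dropped_and_audited(self, config):
        audit = AuditLog()
        out = match_events(
            _wlgp([("A", "2010-01-01", "ZZZ..", 20.0, "")]), _pedw([]), default_codelists(), config, audit
        )
        assert out.empty
        assert audit.count("extract", "unmatched_code") == 1

    def test_height_event_gets_rank_2(self, config):
        out = match_events(
            _wlgp([("A", "2010-01-01", "229..", 1.75, "")]), _pedw([]), default_codelists(), config
        )
        assert out.iloc[0]["component"] == "height"
        assert out.iloc[0]["rank"] == 2
        assert out.iloc[0]["value"] == 1.75

    def test_valueless_measurement_audited(self, config):
        audit = AuditLog()
        out = match_events(
            _wlgp([("A", "2010-01-01", "22K..", np.nan, "")]), _pedw([]), default_codelists(), config, audit
        )
        assert out.empty
        assert audit.count("extract", "missing_value") == 1


class TestStandardiseUnits:
    @pytest.mark.parametrize(
        "component,value,unit,expected",
        [
            ("height", 175.0, "cm", 1.75),
            ("height", 1750.0, "mm", 1.75),
            ("height", 1.75, "m", 1.75),
            ("height", 1.75, None, 1.75),   # unit-less, <= 3 -> metres
            ("height", 175.0, None, 1.75),  # unit-less, > 3 -> centimetre heuristic
            ("weight", 70.0, "kg", 70.0),
            ("weight", 70000.0, "g", 70.0),
            ("weight", 11.0, "stone", 11.0 * 6.35029318),
            ("weight", 154.0, "lb", 154.0 * 0.45359237),
            ("weight", 70.0, None, 70.0),
        ],
    )
    def test_conversions(self, component, value, unit, expected):
        df = _components([("r0", "A", "2010-01-01", component, value, None, "WLGP", "height_weight", 2)])
        df["unit"] = unit
        out = standardise_units(df)
        assert out.iloc[0]["value"] == pytest.approx(expected, rel=1e-12)

    def test_non_positive_rejected(self):
        df = _components([("r0", "A", "2010-01-01", "weight", -5.0, None, "WLGP", "height_weight", 2)])
        audit = AuditLog()
        out = standardise_units(df, audit)
        assert out.empty
        assert audit.count("standardise", "non_positive_value") == 1

    def test_unknown_unit_rejected(self):
        df = _components([("r0", "A", "2010-01-01", "height", 5.7, None, "WLGP", "height_weight", 2)])
        df["unit"] = "ft"
        out = standardise_units(df)
        assert out.empty


class TestFilterExtremes:
    @pytest.mark.parametrize(
        "component,value,kept",
        [
            ("bmi_value", 11.9, False),
            ("bmi_value", 100.5, False),
            ("bmi_value", 12.0, True),    # boundary values are kept
            ("bmi_value", 100.0, True),
            ("bmi_value", 22.5, True),
            ("height", 0.4, False),
            ("height", 2.6, False),
            ("height", 1.75, True),
            ("weight", 4.0, False),
            ("weight", 360.0, False),
            ("weight", 80.0, True),
        ],
    )
    def test_boundaries(self, config, component, value, kept):
        dtp = "bmi_value" if component == "bmi_value" else "height_weight"
        rank = 1 if component == "bmi_value" else 2
        df = _components([("r0", "A", "2010-01-01", component, value, None, "WLGP", dtp, rank)])
        k, r = filter_extremes(df, config)
        assert (len(k), len(r)) == ((1, 0) if kept else (0, 1))

    @given(st.lists(st.floats(min_value=0.1, max_value=200.0, allow_nan=False), max_size=30))
    def test_partition_property(self, values):
        config = StudyConfig()
        rows = [
            (f"r{i}", "A", "2010-01-01", "bmi_value", v, None, "WLGP", "bmi_value", 1)
            for i, v in enumerate(values)
        ]
        k, r = filter_extremes(_components(rows), config)
        assert len(k) + len(r) == len(values)
        assert set(k["record_id"]) | set(r["record_id"]) == {f"r{i}" for i in range(len(values))}
        assert set(k["record_id"]) & set(r["record_id"]) == set()


class TestAssignRank:
    @pytest.mark.parametrize(
        "source,data_type,rank",
        [
            ("WLGP", "bmi_value", 1),
            ("WLGP", "height_weight", 2),
            ("MIDS", "height_weight", 3),
            ("NCCH", "height_weight", 4),
            ("WLGP", "bmi_category", 5),
            ("PEDW", "obese_category", 6),
        ],
    )
    def test_hierarchy_table(self, config, source, data_type, rank):
        assert assign_rank(source, data_type, config) == rank

    def test_unknown_pair_named_in_error(self, config):
        with pytest.raises(RankError, match="PEDW.*bmi_value"):
            assign_rank("PEDW", "bmi_value", config)

    def test_rank_function_injective_onto_1_to_6(self, config):
        ranks = [assign_rank(s, d, config) for s, d, _ in config.hierarchy]
        assert sorted(ranks) == [1, 2, 3, 4, 5, 6]


class TestCollate:
    def test_exact_duplicate_collapsed_with_multiplicity(self):
        row = ("r0", "A", "2010-01-01", "bmi_value", 24.0, None, "WLGP", "bmi_value", 1)
        dup = ("r1", "A", "2010-01-01", "bmi_value", 24.0, None, "WLGP", "bmi_value", 1)
        audit = AuditLog()
        out = collate(_components([row, dup]), audit)
        assert len(out) == 1
        assert out.iloc[0]["record_id"] == "r0"  # first occurrence wins
        assert audit.count("collate", "exact_duplicate") == 2

    def test_same_day_records_from_different_sources_retained(self):
        rows = [
            ("r0", "A", "2010-01-01", "weight", 40.0, None, "WLGP", "height_weight", 2),
            ("r1", "A", "2010-01-01", "weight", 40.0, None, "NCCH", "height_weight", 4),
        ]
        out = collate(_components(rows))
        assert len(out) == 2

    def test_idempotent(self):
        rows = [
            ("r0", "B", "2010-02-01", "bmi_value", 30.0, None, "WLGP", "bmi_value", 1),
            ("r1", "A", "2010-01-01", "weight", 40.0, None, "NCCH", "height_weight", 4),
            ("r1b", "A", "2010-01-01", "weight", 40.0, None, "NCCH", "height_weight", 4),
        ]
        once = collate(_components(rows))
        twice = collate(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        out = collate(_components([]))
        assert out.empty
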