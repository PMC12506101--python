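"""Readers and writers for the six input table schemas and the RRDA output.

All files are header-bearing delimited text (CSV) with ISO-8601 calendar
dates.  Dates are held in memory as ``datetime64[ns]`` columns (NaT for
missing), numeric values as float64 (NaN for missing).  Unparseable rows are
reported with their row numbers rather than silently dropped; writing then
re-reading an RRDA is the identity on every field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A structural problem: missing column, unknown schema, duplicate key."""


@dataclass(frozen=True)
class RowError:
    """One unparseable input row (0-based data row number)."""

    row: int
    column: str
    message: str


class TableData(NamedTuple):
    frame: pd.DataFrame
    errors: list[RowError]


# column -> kind; kinds: str, opt_str, date, opt_date, float, opt_float, int, bool
SCHEMAS: dict[str, dict[str, str]] = {
    "demographics": {
        "person_id": "str",
        "sex": "opt_str",
        "week_of_birth": "opt_date",
        "date_of_death": "opt_date",
        "linkage_status": "int",
    },
    "residency": {
        "person_id": "str",
        "start_date": "opt_date",
        "end_date": "opt_date",
    },
    "wlgp_events": {
        "person_id": "str",
        "event_date": "date",
        "code": "str",
        "numeric_value": "opt_float",
        "unit": "opt_str",
    },
    "pedw_episodes": {
        "person_id": "str",
        "admission_date": "date",
        "code": "str",
    },
    "mids_records": {
        "person_id": "str",
        "record_date": "date",
        "height_value": "opt_float",
        "height_unit": "opt_str",
        "weight_value": "opt_float",
        "weight_unit": "opt_str",
        "baby_birth_date": "opt_date",
    },
    "ncch_records": {
        "person_id": "str",
        "record_date": "date",
        "height_value": "opt_float",
        "height_unit": "opt_str",
        "weight_value": "opt_float",
        "weight_unit": "opt_str",
    },
    "rrda": {
        "person_id": "str",
        "bmi_date": "date",
        "bmi_value": "opt_float",
        "category": "str",
        "category_code": "int",
        "source": "str",
        "data_type": "str",
        "rank": "int",
        "branch": "str",
        "age_at_record": "int",
        "pregnancy_flag": "bool",
        "height_date": "opt_date",
        "weight_date": "opt_date",
        "in_window": "bool",
    },
}

#: Short name per input table used to build stable record identifiers.
TABLE_PREFIX = {
    "wlgp_events": "wlgp",
    "pedw_episodes": "pedw",
    "mids_records": "mids",
    "ncch_records": "ncch",
}


def _parse_column(raw: pd.Series, kind: str, column: str, errors: list[RowError]):
    """Convert a string column per its declared kind, recording bad rows."""
    stripped = raw.str.strip()
    empty = stripped == ""
    if kind in ("str", "opt_str"):
        if kind == "str":
            for i in np.flatnonzero(empty.to_numpy()):
                errors.append(RowError(int(i), column, "required value missing"))
        return stripped
    if kind in ("date", "opt_date"):
        parsed = pd.to_datetime(stripped.where(~empty), format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & ~empty
        if kind == "date":
            bad |= empty
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(RowError(int(i), column, f"invalid date {stripped.iat[i]!r}"))
        return parsed
    if kind in ("float", "opt_float"):
        parsed = pd.to_numeric(stripped.where(~empty), errors="coerce")
        bad = parsed.isna() & ~empty
        if kind == "float":
            bad |= empty
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(RowError(int(i), column, f"invalid number {stripped.iat[i]!r}"))
        nonfinite = np.isfinite(parsed.fillna(0.0).to_numpy()) == False  # noqa: E712
        for i in np.flatnonzero(nonfinite):
            errors.append(RowError(int(i), column, "non-finite number"))
        return parsed.astype(float)
    if kind == "int":
        parsed = pd.to_numeric(stripped.where(~empty), errors="coerce")
        bad = parsed.isna() | empty | (parsed % 1 != 0)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(RowError(int(i), column, f"invalid integer {stripped.iat[i]!r}"))
        return parsed
    if kind == "bool":
        ok = stripped.isin(["true", "false"])
        for i in np.flatnonzero((~ok).to_numpy()):
            errors.append(RowError(int(i), column, f"invalid boolean {stripped.iat[i]!r}"))
        return stripped == "true"
    raise AssertionError(f"unknown kind {kind}")


def read_table(path, schema_name: str) -> TableData:
    """Read a delimited file against one of the declared schemas.

    Returns the typed frame plus a list of :class:`RowError` for every row
    that failed to parse (those rows are excluded from the frame).
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(schema) - set(raw.columns)
    if missing:
        raise SchemaError(f"{schema_name}: missing required columns {sorted(missing)}")
    raw = raw.reset_index(drop=True)
    errors: list[RowError] = []
    out = {}
    for column, kind in schema.items():
        out[column] = _parse_column(raw[column], kind, column, errors)
    frame = pd.DataFrame(out, columns=list(schema))
    if errors:
        bad_rows = sorted({e.row for e in errors})
        frame = frame.drop(index=bad_rows).reset_index(drop=True)
    for column, kind in schema.items():
        if kind == "int":
            frame[column] = frame[column].astype("int64")
    if schema_name == "demographics" and frame["person_id"].duplicated().any():
        dupes = frame.loc[frame["person_id"].duplicated(), "person_id"].unique()
        raise SchemaError(f"demographics: duplicate person_id {list(dupes[:5])}")
    return TableData(frame, errors)


def _format_column(series: pd.Series, kind: str) -> pd.Series:
    if kind in ("date", "opt_date"):
        s = pd.to_datetime(series)
        return s.dt.strftime("%Y-%m-%d").fillna("")
    if kind in ("float", "opt_float"):
        return series.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    if kind == "int":
        return series.map(lambda v: str(int(v)))
    if kind == "bool":
        return series.map(lambda v: "true" if bool(v) else "false")
    return series.fillna("").astype(str)


def write_table(frame: pd.DataFrame, path, schema_name: str) -> None:
    """Write a typed frame to delimited text with the schema's column order."""
    schema = SCHEMAS[schema_name]
    missing = set(schema) - set(frame.columns)
    if missing:
        raise SchemaError(f"{schema_name}: frame missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {c: _format_column(frame[c], k) for c, k in schema.items()},
        columns=list(schema),
    )
    out.to_csv(path, index=False)


def write_rrda(entries: pd.DataFrame, path) -> None:
    """Write the research-ready data asset.

    Refuses frames violating the one-entry-per-person-per-day contract.
    """
    if len(entries):
        dup = entries.duplicated(subset=["person_id", "bmi_date"])
        if dup.any():
            offender = entries.loc[dup, ["person_id", "bmi_date"]].iloc[0]
            raise SchemaError(
                "rrda must have a single entry per (person_id, bmi_date); "
                f"duplicate at {offender.person_id!r} {offender.bmi_date}"
            )
        bad_code = ~entries["category_code"].isin([1, 2, 3, 4])
        if bad_code.any():
            raise SchemaError("rrda category_code must be in 1..4")
    write_table(entries, path, "rrda")


def read_rrda(path) -> TableData:
    return read_table(path, "rrda")
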