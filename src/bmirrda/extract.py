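"""Stage 1: turn raw coded events from the four linked sources into
standardised, rank-annotated BMI component records.

Components are ``bmi_value`` (kg/m²), ``height`` (m), ``weight`` (kg),
``bmi_category`` and ``obesity_dx``.  Heights and weights are standardised to
SI units (with a magnitude heuristic when the unit string is absent),
implausible values are removed, exact extraction duplicates are collapsed,
and every record is annotated with its source-hierarchy rank.  Same-day
records from *different* sources are deliberately retained — resolving them
is the job of the cleaning stages.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .audit import AuditLog
from .codelists import CodeListCollection
from .config import StudyConfig

COMPONENT_COLUMNS = [
    "record_id",
    "person_id",
    "date",
    "component",
    "value",
    "category",
    "source",
    "data_type",
    "rank",
]

_COMPONENT_TO_DATA_TYPE = {
    "bmi_value": "bmi_value",
    "height": "height_weight",
    "weight": "height_weight",
    "bmi_category": "bmi_category",
    "obesity_dx": "obese_category",
}

HEIGHT_UNITS_TO_M = {"m": 1.0, "cm": 0.01, "mm": 0.001}
WEIGHT_UNITS_TO_KG = {"kg": 1.0, "g": 0.001, "stone": 6.35029318, "st": 6.35029318, "lb": 0.45359237}
#: height magnitude above which a unit-less value is assumed to be centimetres
HEIGHT_CM_HEURISTIC_THRESHOLD = 3.0


class RankError(KeyError):
    pass


def assign_rank(source: str, data_type: str, config: StudyConfig) -> int:
    """Rank of a (source, data_type) pair in the configured hierarchy."""
    try:
        return config.rank_table()[(source, data_type)]
    except KeyError:
        raise RankError(f"({source!r}, {data_type!r}) is not in the source hierarchy") from None


def _empty_components() -> pd.DataFrame:
    df = pd.DataFrame(columns=COMPONENT_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    df["value"] = df["value"].astype(float)
    df["rank"] = df["rank"].astype("int64")
    return df


def match_events(
    wlgp: pd.DataFrame,
    pedw: pd.DataFrame,
    codelists: CodeListCollection,
    config: StudyConfig,
    audit: Optional[AuditLog] = None,
) -> pd.DataFrame:
    """Match coded WLGP (Read v2) and PEDW (ICD-10) events against the code
    lists.  Unmatched codes are not errors; they are counted in the audit."""
    audit = audit if audit is not None else AuditLog()
    rows: list[dict] = []
    unmatched: dict[str, int] = {}
    for i, ev in enumerate(wlgp.itertuples()):
        entry = codelists.lookup(ev.code, "ReadV2")
        if entry is None:
            unmatched["WLGP"] = unmatched.get("WLGP", 0) + 1
            continue
        if entry.component in ("bmi_value", "height", "weight") and pd.isna(ev.numeric_value):
            audit.add("extract", "missing_value", ev.person_id, ev.event_date, "WLGP", f"wlgp:{i}")
            continue
        value = ev.numeric_value if entry.component in ("bmi_value", "height", "weight") else np.nan
        category = entry.category_map if entry.component == "bmi_category" else None
        rows.append(
            {
                "record_id": f"wlgp:{i}",
                "person_id": ev.person_id,
                "date": ev.event_date,
                "component": entry.component,
                "value": value,
                "category": category,
                "source": "WLGP",
                "data_type": _COMPONENT_TO_DATA_TYPE[entry.component],
            }
        )
    for i, ev in enumerate(pedw.itertuples()):
        entry = codelists.lookup(ev.code, "ICD10")
        if entry is None or entry.component != "obesity_dx":
            unmatched["PEDW"] = unmatched.get("PEDW", 0) + 1
            continue
        rows.append(
            {
                "record_id": f"pedw:{i}",
                "person_id": ev.person_id,
                "date": ev.admission_date,
                "component": "obesity_dx",
                "value": np.nan,
                "category": entry.category_map,
                "source": "PEDW",
                "data_type": "obese_category",
            }
        )
    for source, n in sorted(unmatched.items()):
        audit.add("extract", "unmatched_code", source=source, count=n)
    if not rows:
        return _empty_components()
    df = pd.DataFrame(rows)
    df["rank"] = [assign_rank(s, d, config) for s, d in zip(df["source"], df["data_type"])]
    return df[COMPONENT_COLUMNS]


def _measurement_components(frame: pd.DataFrame, source: str, prefix: str, config: StudyConfig) -> pd.DataFrame:
    """Split maternity/child-measurement rows into height and weight components."""
    rows = []
    rank = assign_rank(source, "height_weight", config)
    for i, r in enumerate(frame.itertuples()):
        for comp, suffix, val, unit in (
            ("height", "h", r.height_value, r.height_unit),
            ("weight", "w", r.weight_value, r.weight_unit),
        ):
            if pd.isna(val):
                continue
            rows.append(
                {
                    "record_id": f"{prefix}:{i}:{suffix}",
                    "person_id": r.person_id,
                    "date": r.record_date,
                    "component": comp,
                    "value": float(val),
                    "category": None,
                    "source": source,
                    "data_type": "height_weight",
                    "rank": rank,
                    "unit": unit,
                }
            )
    if not rows:
        out = _empty_components()
        out["unit"] = pd.Series(dtype=object)
        return out
    return pd.DataFrame(rows)


def components_from_mids(mids: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    return _measurement_components(mids, "MIDS", "mids", config)


def components_from_ncch(ncch: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    return _measurement_components(ncch, "NCCH", "ncch", config)


def standardise_units(
    components: pd.DataFrame, audit: Optional[AuditLog] = None
) -> pd.DataFrame:
    """Convert height/weight components to SI (m, kg).

    Explicit unit strings are converted; when absent, a magnitude heuristic
    applies (a unit-less height above 3 is read as centimetres; weights pass
    through as kg).  Non-positive values and unknown units are rejected to
    the audit log.
    """
    audit = audit if audit is not None else AuditLog()
    df = components.copy()
    if "unit" not in df.columns:
        df["unit"] = None
    keep = np.ones(len(df), dtype=bool)
    values = df["value"].to_numpy(dtype=float, copy=True)
    comps = df["component"].to_numpy()
    units = df["unit"].to_numpy(dtype=object)

    for i in range(len(df)):
        comp = comps[i]
        if comp not in ("height", "weight"):
            continue
        v = values[i]
        unit = units[i]
        unit = None if (unit is None or (isinstance(unit, float) and np.isnan(unit)) or unit == "") else str(unit)
        if not np.isfinite(v) or v <= 0:
            keep[i] = False
            row = df.iloc[i]
            audit.add("standardise", "non_positive_value", row.person_id, row.date, row.source, row.record_id)
            continue
        table = HEIGHT_UNITS_TO_M if comp == "height" else WEIGHT_UNITS_TO_KG
        if unit is not None:
            factor = table.get(unit.lower())
            if factor is None:
                keep[i] = False
                row = df.iloc[i]
                audit.add("standardise", f"unknown_unit:{unit}", row.person_id, row.date, row.source, row.record_id)
                continue
            values[i] = v * factor
        elif comp == "height" and v > HEIGHT_CM_HEURISTIC_THRESHOLD:
            values[i] = v * 0.01
            audit.add("standardise", "heuristic_cm_to_m", df.iloc[i].person_id, df.iloc[i].date,
                      df.iloc[i].source, df.iloc[i].record_id)
        # unit-less heights <= threshold are metres; unit-less weights are kg
    df["value"] = values
    out = df[keep].drop(columns=["unit"]).reset_index(drop=True)
    return out[COMPONENT_COLUMNS]


def filter_extremes(
    components: pd.DataFrame, config: StudyConfig, audit: Optional[AuditLog] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove extreme values: BMI strictly below ``bmi_min`` or strictly above
    ``bmi_max`` (boundary values are kept), and heights/weights outside the
    configured plausibility bounds.  Returns (kept, removed); the two
    partition the input."""
    audit = audit if audit is not None else AuditLog()
    v = components["value"].to_numpy(dtype=float)
    comp = components["component"].to_numpy()
    bad = np.zeros(len(components), dtype=bool)
    reasons = np.empty(len(components), dtype=object)

    is_bmi = comp == "bmi_value"
    mask = is_bmi & ((v < config.bmi_min) | (v > config.bmi_max))
    bad |= mask
    reasons[mask] = "extreme_bmi"
    is_h = comp == "height"
    mask = is_h & ((v < config.height_min_m) | (v > config.height_max_m))
    bad |= mask
    reasons[mask] = "implausible_height"
    is_w = comp == "weight"
    mask = is_w & ((v < config.weight_min_kg) | (v > config.weight_max_kg))
    bad |= mask
    reasons[mask] = "implausible_weight"

    removed = components[bad].copy()
    removed["reason"] = reasons[bad]
    for row in removed.itertuples():
        audit.add("filter_extremes", row.reason, row.person_id, row.date, row.source, row.record_id)
    return components[~bad].reset_index(drop=True), removed.reset_index(drop=True)


def filter_study_period(
    components: pd.DataFrame, config: StudyConfig, audit: Optional[AuditLog] = None
) -> pd.DataFrame:
    audit = audit if audit is not None else AuditLog()
    dates = pd.to_datetime(components["date"])
    ok = (dates >= pd.Timestamp(config.study_start)) & (dates <= pd.Timestamp(config.study_end))
    audit.add_frame("extract", "outside_study_period", components[~ok])
    return components[ok].reset_index(drop=True)


def collate(components: pd.DataFrame, audit: Optional[AuditLog] = None) -> pd.DataFrame:
    """Union of all sources' component records, sorted by (person, date, rank),
    with exact duplicates (all domain fields equal) collapsed to the first
    occurrence; multiplicities go to the audit log.  Idempotent."""
    audit = audit if audit is not None else AuditLog()
    if components.empty:
        return components.reset_index(drop=True)
    domain = ["person_id", "date", "component", "value", "category", "source", "data_type", "rank"]
    dup = components.duplicated(subset=domain, keep="first")
    if dup.any():
        sizes = components.groupby(domain, dropna=False).size()
        for key, n in sizes[sizes > 1].items():
            rec = dict(zip(domain, key))
            audit.add("collate", "exact_duplicate", rec["person_id"], rec["date"], rec["source"], count=int(n))
    out = components[~dup]
    out = out.sort_values(["person_id", "date", "rank", "record_id"], kind="mergesort")
    return out.reset_index(drop=True)


def extract_components(
    tables: Mapping[str, pd.DataFrame],
    codelists: CodeListCollection,
    config: StudyConfig,
    audit: Optional[AuditLog] = None,
) -> pd.DataFrame:
    """Full Stage 1: match, standardise, filter and collate all four sources."""
    audit = audit if audit is not None else AuditLog()
    coded = match_events(tables["wlgp_events"], tables["pedw_episodes"], codelists, config, audit)
    # coded WLGP height/weight may carry units from the source table
    if "unit" in tables["wlgp_events"].columns and not coded.empty:
        units = tables["wlgp_events"]["unit"].reset_index(drop=True)
        idx = coded["record_id"].str.startswith("wlgp:")
        coded = coded.copy()
        coded["unit"] = None
        rownum = coded.loc[idx, "record_id"].str.split(":").str[1].astype(int)
        coded.loc[idx, "unit"] = units.iloc[rownum].to_numpy(dtype=object)
    mids = components_from_mids(tables["mids_records"], config)
    ncch = components_from_ncch(tables["ncch_records"], config)
    parts = [p for p in (coded, mids, ncch) if not p.empty]
    if not parts:
        return _empty_components()
    combined = pd.concat(parts, ignore_index=True)
    combined = filter_study_period(combined, config, audit)
    combined = standardise_units(combined, audit)
    kept, _removed = filter_extremes(combined, config, audit)
    return collate(kept, audit)
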