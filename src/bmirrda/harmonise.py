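"""Stages 4–5: inconsistency cleaning, daily resolution and pregnancy flags.

Categories are encoded 1–4 (underweight=1, normal=2, overweight=3, obese=4).
Cleaning is two-stage and deterministic:

* same-day — entries sharing a person and date are compared pairwise.  Two
  value-bearing entries are consistent only if their relative difference
  (against the smaller value) is below the configured tolerance *and* their
  categories agree; any pair involving a category-only entry is consistent
  only if the categories agree.  Every entry in a violating pair is removed.
* over-time (adult branch only) — scanning a person's record chronologically,
  a value-bearing entry whose change against the last kept value exceeds the
  configured annual rate (with a short-gap floor) is removed.  Entries inside
  a pregnancy window are exempt and never serve as the comparison baseline.

Stage 5 keeps the lowest-rank (most trusted) entry per person-day, flags
records within ±``pregnancy_window_days`` of a recorded birth, and emits the
research-ready data asset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .audit import AuditLog
from .codelists import CodeListCollection
from .cohort import ExclusionFlow, apply_exclusions, contribution_windows, impute_residency
from .config import CATEGORIES, StudyConfig
from .derive import GrowthReference, derive_entries
from .extract import extract_components

_ENCODE = {c: i + 1 for i, c in enumerate(CATEGORIES)}
_DECODE = {i + 1: c for i, c in enumerate(CATEGORIES)}

DECISION_COLUMNS = ["person_id", "date", "rule", "records_removed", "detail"]


def encode_category(category: str) -> int:
    """underweight→1, normal→2, overweight→3, obese→4."""
    try:
        return _ENCODE[category]
    except KeyError:
        raise ValueError(f"unknown BMI category {category!r}") from None


def decode_category(code: int) -> str:
    try:
        return _DECODE[code]
    except KeyError:
        raise ValueError(f"unknown BMI category code {code!r}") from None


def _pair_consistent(v1, c1, v2, c2, rel_tol: float) -> bool:
    """Same-day pairwise consistency rule (values may be None)."""
    if v1 is not None and v2 is not None:
        lo = min(v1, v2)
        rel = abs(v1 - v2) / lo
        return rel < rel_tol and c1 == c2
    return c1 == c2


def same_day_clean(
    entries: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Remove mutually inconsistent same-day entries.

    Returns (kept, removed, decisions); kept and removed partition the input.
    """
    decisions: list[dict] = []
    if entries.empty:
        return entries.copy(), entries.iloc[0:0].copy(), decisions
    df = entries.sort_values(
        ["person_id", "bmi_date", "bmi_value", "category", "entry_id"],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    sizes = df.groupby(["person_id", "bmi_date"], sort=False)["entry_id"].transform("size")
    removed_mask = np.zeros(len(df), dtype=bool)
    multi = df[sizes > 1]
    for (pid, date), grp in multi.groupby(["person_id", "bmi_date"], sort=False):
        idx = grp.index.to_numpy()
        vals = [None if pd.isna(v) else float(v) for v in grp["bmi_value"]]
        cats = grp["category"].tolist()
        bad = np.zeros(len(idx), dtype=bool)
        value_conflict = False
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                if not _pair_consistent(vals[i], cats[i], vals[j], cats[j], config.same_day_rel_diff):
                    bad[i] = bad[j] = True
                    if vals[i] is not None and vals[j] is not None:
                        value_conflict = True
        if bad.any():
            removed_mask[idx[bad]] = True
            rule = "same_day_value_conflict" if value_conflict else "same_day_category_conflict"
            decisions.append(
                {
                    "person_id": pid,
                    "date": date,
                    "rule": rule,
                    "records_removed": ";".join(df.loc[idx[bad], "entry_id"]),
                    "detail": f"{int(bad.sum())} of {len(idx)} same-day entries mutually inconsistent",
                }
            )
    kept = df[~removed_mask].reset_index(drop=True)
    removed = df[removed_mask].reset_index(drop=True)
    return kept, removed, decisions


def over_time_clean(
    entries: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Remove longitudinally implausible adult entries.

    An adult value-bearing entry is removed when |ΔBMI| against the last kept
    value-bearing, non-pregnancy entry on an earlier date exceeds
    ``overtime_max_annual_delta`` × max(Δdays, ``overtime_min_gap_days``)/365.
    CYP entries pass through unchanged (only same-day cleaning applies to
    children); pregnancy-window entries are exempt.
    """
    decisions: list[dict] = []
    if entries.empty:
        return entries.copy(), entries.iloc[0:0].copy(), decisions
    df = entries.sort_values(
        ["person_id", "bmi_date", "rank", "entry_id"], kind="mergesort"
    ).reset_index(drop=True)
    removed_mask = np.zeros(len(df), dtype=bool)
    adults = df[df["branch"] == "adult"]
    for pid, grp in adults.groupby("person_id", sort=False):
        base_v: Optional[float] = None
        base_d = None
        for row in grp.itertuples():
            if pd.isna(row.bmi_value):
                continue
            if bool(row.pregnancy_flag):
                continue
            v = float(row.bmi_value)
            d = pd.Timestamp(row.bmi_date)
            if base_v is None:
                base_v, base_d = v, d
                continue
            if d == base_d:
                continue  # same-day consistency already enforced
            gap = (d - base_d).days
            allowed = config.overtime_max_annual_delta * max(gap, config.overtime_min_gap_days) / 365.0
            if abs(v - base_v) > allowed:
                removed_mask[row.Index] = True
                decisions.append(
                    {
                        "person_id": pid,
                        "date": d,
                        "rule": "over_time_conflict",
                        "records_removed": row.entry_id,
                        "detail": f"delta {abs(v - base_v):.2f} kg/m2 over {gap} d exceeds allowance {allowed:.2f}",
                    }
                )
            else:
                base_v, base_d = v, d
    kept = df[~removed_mask].reset_index(drop=True)
    removed = df[removed_mask].reset_index(drop=True)
    return kept, removed, decisions


def select_daily_entry(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep the lowest-rank entry per person-day; ties break by ascending BMI
    value (missing values last), then source name, then entry id."""
    if entries.empty:
        return entries.copy()
    df = entries.sort_values(
        ["person_id", "bmi_date", "rank", "bmi_value", "source", "entry_id"],
        kind="mergesort",
        na_position="last",
    )
    return df.drop_duplicates(subset=["person_id", "bmi_date"], keep="first").reset_index(drop=True)


def flag_pregnancy(entries: pd.DataFrame, births: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Set ``pregnancy_flag`` where |bmi_date − any birth date| ≤ the window.

    *births* has columns person_id, birth_date (from maternity records)."""
    out = entries.copy()
    out["pregnancy_flag"] = False
    if entries.empty or births.empty:
        return out
    b = births.dropna(subset=["birth_date"]).drop_duplicates()
    merged = out.reset_index()[["index", "person_id", "bmi_date"]].merge(b, on="person_id", how="inner")
    if merged.empty:
        return out
    gap = (pd.to_datetime(merged["bmi_date"]) - pd.to_datetime(merged["birth_date"])).abs()
    hit = merged.loc[gap <= pd.Timedelta(days=config.pregnancy_window_days), "index"].unique()
    out.loc[hit, "pregnancy_flag"] = True
    return out


# ---------------------------------------------------------------------------
# full orchestration


@dataclass
class RRDAResult:
    """Everything a pipeline run produces besides the RRDA itself."""

    rrda: pd.DataFrame
    exclusion_flow: ExclusionFlow
    windows: pd.DataFrame
    audit: AuditLog
    decisions: pd.DataFrame
    accounting: dict = field(default_factory=dict)


def _in_window_flags(selected: pd.DataFrame, windows: pd.DataFrame, episodes: pd.DataFrame,
                     config: StudyConfig) -> np.ndarray:
    win = {(w.person_id, w.branch): (w.entry_date, w.exit_date) for w in windows.itertuples()}
    eps: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    imputed, _ = impute_residency(episodes, config)
    for e in imputed.itertuples():
        eps.setdefault(e.person_id, []).append((e.start_date, e.end_date))
    flags = np.zeros(len(selected), dtype=bool)
    for k, row in enumerate(selected.itertuples()):
        w = win.get((row.person_id, row.branch))
        if w is None:
            continue
        d = pd.Timestamp(row.bmi_date)
        if not (w[0] <= d <= w[1]):
            continue
        person_eps = eps.get(row.person_id)
        if person_eps is None:
            flags[k] = True  # no residency table rows: fully imputed episode
        else:
            flags[k] = any(s <= d <= e for s, e in person_eps)
    return flags


def build_rrda(
    tables: Mapping[str, pd.DataFrame],
    codelists: CodeListCollection,
    reference: GrowthReference,
    config: StudyConfig,
) -> RRDAResult:
    """Run the full Stage 1→5 pipeline on the six input tables.

    Every input record is accounted for: it either survives into the RRDA or
    appears in the audit log / cleaning decisions with a reason.
    """
    audit = AuditLog()
    components = extract_components(tables, codelists, config, audit)

    demographics = tables["demographics"]
    with_records = set(components["person_id"])
    known = demographics[demographics["person_id"].isin(with_records)].reset_index(drop=True)
    missing_demo = with_records - set(known["person_id"])
    if missing_demo:
        n = int(components["person_id"].isin(missing_demo).sum())
        audit.add("cohort", "no_demographics", count=n)
        components = components[~components["person_id"].isin(missing_demo)].reset_index(drop=True)

    eligible, flow = apply_exclusions(known, config)
    excluded_ids = with_records - set(eligible["person_id"]) - missing_demo
    if excluded_ids:
        mask = components["person_id"].isin(excluded_ids)
        audit.add("cohort", "excluded_person", count=int(mask.sum()))
        components = components[~mask].reset_index(drop=True)

    windows = contribution_windows(eligible, tables["residency"], config)
    entries = derive_entries(components, eligible, reference, config, audit)

    births = tables["mids_records"][["person_id", "baby_birth_date"]].rename(
        columns={"baby_birth_date": "birth_date"}
    )
    entries = flag_pregnancy(entries, births, config)

    kept_sd, removed_sd, dec_sd = same_day_clean(entries, config)
    kept_ot, removed_ot, dec_ot = over_time_clean(kept_sd, config)
    selected = select_daily_entry(kept_ot)

    n_dedup = len(kept_ot) - len(selected)
    decisions = pd.DataFrame(dec_sd + dec_ot, columns=DECISION_COLUMNS)

    flags = _in_window_flags(selected, windows, tables["residency"], config)
    rrda = selected.copy()
    rrda["category_code"] = [encode_category(c) for c in rrda["category"]]
    rrda["age_at_record"] = np.where(
        rrda["branch"] == "CYP", rrda["age_months"], rrda["age_years"]
    ).astype(int) if len(rrda) else pd.Series(dtype="int64")
    rrda["in_window"] = flags
    rrda = rrda[
        [
            "person_id",
            "bmi_date",
            "bmi_value",
            "category",
            "category_code",
            "source",
            "data_type",
            "rank",
            "branch",
            "age_at_record",
            "pregnancy_flag",
            "height_date",
            "weight_date",
            "in_window",
        ]
    ].sort_values(["person_id", "bmi_date"], kind="mergesort").reset_index(drop=True)

    accounting = {
        "entry_candidates": len(entries)
        + audit.count("derive", "under_2")
        + audit.count("derive", "out_of_branch")
        + audit.count("derive", "derived_bmi_out_of_range")
        + audit.count("derive", "unpaired_weight"),
        "entries": len(entries),
        "removed_same_day": len(removed_sd),
        "removed_over_time": len(removed_ot),
        "deduplicated_same_day": n_dedup,
        "rrda": len(rrda),
    }
    return RRDAResult(
        rrda=rrda,
        exclusion_flow=flow,
        windows=windows,
        audit=audit,
        decisions=decisions,
        accounting=accounting,
    )
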