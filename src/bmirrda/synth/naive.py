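"""Naive reference implementation of the full methodology.

A deliberately plain, loop-over-dicts re-implementation of Stages 1–5, kept
free of the production modules (no pandas vectorisation, its own date and
interpolation arithmetic, ``statistics.NormalDist`` instead of scipy for the
paediatric thresholds).  It exists purely as a differential-testing oracle:
the production pipeline must reproduce its RRDA record for record on any
generated dataset.
"""

from __future__ import annotations

import calendar
import datetime as dt
from statistics import NormalDist

import pandas as pd

from ..codelists import CodeListCollection
from ..config import StudyConfig
from ..derive import GrowthReference

_CAT_CODE = {"underweight": 1, "normal": 2, "overweight": 3, "obese": 4}
_HEIGHT_UNITS = {"m": 1.0, "cm": 0.01, "mm": 0.001}
_WEIGHT_UNITS = {"kg": 1.0, "g": 0.001, "stone": 6.35029318, "st": 6.35029318, "lb": 0.45359237}


def _date(v):
    if v is None or (isinstance(v, float) and v != v) or v is pd.NaT:
        return None
    if isinstance(v, pd.Timestamp):
        return v.date()
    return v


def _monday(d: dt.date) -> dt.date:
    return d - dt.timedelta(days=d.weekday())


def _add_months(anchor: dt.date, months: int) -> dt.date:
    y, m = divmod(anchor.month - 1 + months, 12)
    year, month = anchor.year + y, m + 1
    day = min(anchor.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def _months_between(anchor: dt.date, date: dt.date) -> int:
    m = (date.year - anchor.year) * 12 + (date.month - anchor.month)
    if date.day < min(anchor.day, calendar.monthrange(date.year, date.month)[1]):
        m -= 1
    return m


def _branch(age_months: int, cfg: StudyConfig):
    years = age_months // 12
    if cfg.cyp_age_months_min <= age_months and years < cfg.adult_age_years_min:
        return "CYP"
    if cfg.adult_age_years_min <= years <= cfg.adult_age_years_max:
        return "adult"
    return None


def _interp_lms(ref_rows, sex, age_months):
    rows = ref_rows[sex]
    ages = [r[0] for r in rows]
    if age_months < ages[0] or age_months > ages[-1]:
        raise ValueError("age outside reference grid")
    i = 0
    while i + 2 < len(ages) and ages[i + 1] <= age_months:
        i += 1
    a0, a1 = ages[i], ages[i + 1]
    frac = (age_months - a0) / (a1 - a0)
    out = []
    for k in (1, 2, 3):
        y0, y1 = rows[i][k], rows[i + 1][k]
        out.append(y0 + frac * (y1 - y0))
    return tuple(out)  # L, M, S


def _lms_z(x, L, M, S):
    import math

    if abs(L) < 1e-7:  # Box–Cox power is numerically the log transform
        return math.log(x / M) / S
    return ((x / M) ** L - 1.0) / (L * S)


def _adult_category(bmi, cuts):
    if bmi < cuts[0]:
        return "underweight"
    if bmi < cuts[1]:
        return "normal"
    if bmi < cuts[2]:
        return "overweight"
    return "obese"


def _cyp_category(z, thresholds):
    z_under, z_over, z_obese = thresholds
    if z < z_under:
        return "underweight"
    if z >= z_obese:
        return "obese"
    if z >= z_over:
        return "overweight"
    return "normal"


# ---------------------------------------------------------------------------


def _stage1_components(tables, codelists: CodeListCollection, cfg: StudyConfig) -> list[dict]:
    """Match, standardise, filter extremes and deduplicate; returns component dicts."""
    ranks = cfg.rank_table()
    comps: list[dict] = []

    def push(rid, pid, date, component, value, category, source, data_type, unit=None):
        comps.append(
            {
                "id": rid,
                "pid": pid,
                "date": date,
                "component": component,
                "value": value,
                "category": category,
                "source": source,
                "data_type": data_type,
                "rank": ranks[(source, data_type)],
                "unit": unit,
            }
        )

    for i, row in enumerate(tables["wlgp_events"].to_dict("records")):
        entry = codelists.lookup(row["code"], "ReadV2")
        if entry is None:
            continue
        value = row["numeric_value"]
        value = None if value is None or value != value else float(value)
        comp = entry.component
        if comp in ("bmi_value", "height", "weight") and value is None:
            continue
        unit = row.get("unit") or None
        if comp == "bmi_value":
            push(f"wlgp:{i}", row["person_id"], _date(row["event_date"]), comp, value, None, "WLGP", "bmi_value")
        elif comp in ("height", "weight"):
            push(f"wlgp:{i}", row["person_id"], _date(row["event_date"]), comp, value, None, "WLGP",
                 "height_weight", unit)
        elif comp == "bmi_category":
            push(f"wlgp:{i}", row["person_id"], _date(row["event_date"]), comp, None, entry.category_map,
                 "WLGP", "bmi_category")
    for i, row in enumerate(tables["pedw_episodes"].to_dict("records")):
        entry = codelists.lookup(row["code"], "ICD10")
        if entry is None or entry.component != "obesity_dx":
            continue
        push(f"pedw:{i}", row["person_id"], _date(row["admission_date"]), "obesity_dx", None,
             entry.category_map, "PEDW", "obese_category")
    for prefix, table, source in (("mids", "mids_records", "MIDS"), ("ncch", "ncch_records", "NCCH")):
        for i, row in enumerate(tables[table].to_dict("records")):
            for comp, suffix, vk, uk in (("height", "h", "height_value", "height_unit"),
                                         ("weight", "w", "weight_value", "weight_unit")):
                v = row[vk]
                if v is None or v != v:
                    continue
                push(f"{prefix}:{i}:{suffix}", row["person_id"], _date(row["record_date"]), comp,
                     float(v), None, source, "height_weight", row.get(uk) or None)

    # study-period filter
    comps = [c for c in comps if cfg.study_start <= c["date"] <= cfg.study_end]

    # unit standardisation
    out = []
    for c in comps:
        if c["component"] not in ("height", "weight"):
            out.append(c)
            continue
        v, unit = c["value"], c["unit"]
        if v is None or v <= 0:
            continue
        table = _HEIGHT_UNITS if c["component"] == "height" else _WEIGHT_UNITS
        if unit is not None:
            factor = table.get(str(unit).lower())
            if factor is None:
                continue
            v = v * factor
        elif c["component"] == "height" and v > 3.0:
            v = v * 0.01
        c = dict(c, value=v)
        out.append(c)
    comps = out

    # extreme / implausible values
    out = []
    for c in comps:
        v = c["value"]
        if c["component"] == "bmi_value" and (v < cfg.bmi_min or v > cfg.bmi_max):
            continue
        if c["component"] == "height" and (v < cfg.height_min_m or v > cfg.height_max_m):
            continue
        if c["component"] == "weight" and (v < cfg.weight_min_kg or v > cfg.weight_max_kg):
            continue
        out.append(c)
    comps = out

    # exact-duplicate collapse, first occurrence wins
    seen = set()
    out = []
    for c in comps:
        key = (c["pid"], c["date"], c["component"], c["value"], c["category"], c["source"],
               c["data_type"], c["rank"])
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


def _eligible_persons(tables, comps, cfg: StudyConfig):
    """Fixed-order exclusions; returns (person dict, flow rows)."""
    with_records = {c["pid"] for c in comps}
    demo = {
        r["person_id"]: r
        for r in tables["demographics"].to_dict("records")
        if r["person_id"] in with_records
    }
    flow = []
    current = list(demo.values())

    def step(label, keep_fn):
        nonlocal current
        kept = [r for r in current if keep_fn(r)]
        flow.append({"step": label, "persons_removed": len(current) - len(kept),
                     "persons_remaining": len(kept)})
        current = kept

    start = cfg.study_start
    cutoff = start + dt.timedelta(days=cfg.min_residency_days)
    step("linkage_status_not_accepted", lambda r: int(r["linkage_status"]) in cfg.linkage_status_accept)
    step("missing_week_of_birth", lambda r: _date(r["week_of_birth"]) is not None)
    step("invalid_sex", lambda r: r["sex"] in ("F", "M"))
    step("death_before_study_start", lambda r: _date(r["date_of_death"]) is None or _date(r["date_of_death"]) >= start)
    step("death_within_min_residency", lambda r: _date(r["date_of_death"]) is None or _date(r["date_of_death"]) >= cutoff)
    persons = {
        r["person_id"]: {
            "sex": r["sex"],
            "anchor": _monday(_date(r["week_of_birth"])),
            "dod": _date(r["date_of_death"]),
        }
        for r in current
    }
    return persons, flow


def _residency(tables, cfg: StudyConfig):
    episodes: dict[str, list[tuple[dt.date, dt.date]]] = {}
    for r in tables["residency"].to_dict("records"):
        s = _date(r["start_date"]) or cfg.study_start
        e = _date(r["end_date"]) or cfg.study_end
        s = max(s, cfg.study_start)
        e = min(e, cfg.study_end)
        if s <= e:
            episodes.setdefault(r["person_id"], []).append((s, e))
    return episodes


def _windows(persons, episodes, cfg: StudyConfig):
    win = {}
    for pid, p in persons.items():
        eps = episodes.get(pid)
        if eps:
            first = min(s for s, _ in eps)
            last = max(e for _, e in eps)
        else:
            first, last = cfg.study_start, cfg.study_end
        entry = max(cfg.study_start, first)
        base_exit = min(cfg.study_end, last)
        if p["dod"] is not None:
            base_exit = min(base_exit, p["dod"])
        for branch in ("CYP", "adult"):
            exit_d = base_exit
            if branch == "CYP":
                exit_d = min(exit_d, _add_months(p["anchor"], cfg.cyp_age_months_max) - dt.timedelta(days=1))
            if entry <= exit_d:
                win[(pid, branch)] = (entry, exit_d)
    return win


def naive_rrda(tables, codelists: CodeListCollection, reference: GrowthReference,
               cfg: StudyConfig) -> pd.DataFrame:
    """Expected RRDA, computed rule by rule with naive nested loops."""
    comps = _stage1_components(tables, codelists, cfg)
    persons, _flow = _eligible_persons(tables, comps, cfg)
    comps = [c for c in comps if c["pid"] in persons]
    episodes = _residency(tables, cfg)
    windows = _windows(persons, episodes, cfg)

    ref_rows: dict[str, list[tuple]] = {}
    for rec in reference.frame.to_dict("records"):
        ref_rows.setdefault(rec["sex"], []).append(
            (float(rec["age_months"]), float(rec["L"]), float(rec["M"]), float(rec["S"]))
        )
    for sex in ref_rows:
        ref_rows[sex].sort()
    thresholds = tuple(
        NormalDist().inv_cdf(p)
        for p in (cfg.cyp_pct_underweight, cfg.cyp_pct_overweight, cfg.cyp_pct_obese)
    )

    # births (for pregnancy flags)
    births: dict[str, list[dt.date]] = {}
    for r in tables["mids_records"].to_dict("records"):
        b = _date(r["baby_birth_date"])
        if b is not None:
            births.setdefault(r["person_id"], []).append(b)

    # ---- Stage 3: entries -------------------------------------------------
    entries: list[dict] = []

    def make_entry(eid, pid, date, value, category, source, data_type, rank,
                   height_date=None, weight_date=None):
        p = persons[pid]
        am = _months_between(p["anchor"], date)
        branch = _branch(am, cfg)
        if branch is None:
            return
        if value is not None and (value < cfg.bmi_min or value > cfg.bmi_max):
            return
        if value is not None:
            if branch == "adult":
                category = _adult_category(value, cfg.adult_cut_points)
            else:
                L, M, S = _interp_lms(ref_rows, p["sex"], float(am))
                category = _cyp_category(_lms_z(value, L, M, S), thresholds)
        preg = any(abs((date - b).days) <= cfg.pregnancy_window_days for b in births.get(pid, []))
        entries.append(
            {
                "id": eid,
                "pid": pid,
                "date": date,
                "value": value,
                "category": category,
                "source": source,
                "data_type": data_type,
                "rank": rank,
                "branch": branch,
                "age_months": am,
                "preg": preg,
                "height_date": height_date,
                "weight_date": weight_date,
            }
        )

    for c in comps:
        if c["component"] == "bmi_value":
            make_entry(c["id"], c["pid"], c["date"], c["value"], None, c["source"], c["data_type"], c["rank"])
        elif c["component"] in ("bmi_category", "obesity_dx"):
            make_entry(c["id"], c["pid"], c["date"], None, c["category"], c["source"], c["data_type"], c["rank"])

    # height/weight pairing per (person, source)
    hw: dict[tuple, dict[str, list[dict]]] = {}
    for c in comps:
        if c["component"] in ("height", "weight"):
            hw.setdefault((c["pid"], c["source"]), {"height": [], "weight": []})[c["component"]].append(c)
    for (pid, source), parts in sorted(hw.items()):
        heights = sorted(parts["height"], key=lambda h: (h["date"], h["value"], h["id"]))
        weights = sorted(parts["weight"], key=lambda w: (w["date"], w["id"]))
        if not weights:
            continue
        anchor = persons[pid]["anchor"]
        for w in weights:
            am = _months_between(anchor, w["date"])
            branch = _branch(am, cfg)
            if branch is None or not heights:
                continue
            if branch == "CYP":
                eligible = [h for h in heights if abs((h["date"] - w["date"]).days) <= cfg.hw_pair_window_days]
                if not eligible:
                    continue
                best = min(eligible, key=lambda h: (abs((h["date"] - w["date"]).days),
                                                    h["date"], h["value"], h["id"]))
            else:
                if cfg.adult_height_mode == "single":
                    last = max(h["date"] for h in heights)
                    best = [h for h in heights if h["date"] == last][0]
                else:
                    onbefore = [h for h in heights if h["date"] <= w["date"]]
                    best = onbefore[-1] if onbefore else heights[0]
                    if onbefore:
                        last = max(h["date"] for h in onbefore)
                        best = [h for h in onbefore if h["date"] == last][0]
            bmi = w["value"] / (best["value"] * best["value"])
            make_entry(w["id"], pid, w["date"], bmi, None, source, "height_weight", w["rank"],
                       height_date=best["date"], weight_date=w["date"])

    # ---- Stage 4: same-day cleaning --------------------------------------
    by_day: dict[tuple, list[dict]] = {}
    for e in entries:
        by_day.setdefault((e["pid"], e["date"]), []).append(e)
    survivors: list[dict] = []
    for key in sorted(by_day):
        group = by_day[key]
        bad = set()
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if a["value"] is not None and b["value"] is not None:
                    lo = min(a["value"], b["value"])
                    ok = abs(a["value"] - b["value"]) / lo < cfg.same_day_rel_diff and a["category"] == b["category"]
                else:
                    ok = a["category"] == b["category"]
                if not ok:
                    bad.add(i)
                    bad.add(j)
        survivors.extend(e for k, e in enumerate(group) if k not in bad)

    # ---- Stage 4: over-time cleaning (adults only) ------------------------
    by_person: dict[str, list[dict]] = {}
    for e in survivors:
        by_person.setdefault(e["pid"], []).append(e)
    kept: list[dict] = []
    for pid in sorted(by_person):
        es = sorted(by_person[pid], key=lambda e: (e["date"], e["rank"], e["id"]))
        base_v = base_d = None
        for e in es:
            if e["branch"] != "adult" or e["value"] is None or e["preg"]:
                kept.append(e)
                continue
            if base_v is None:
                base_v, base_d = e["value"], e["date"]
                kept.append(e)
                continue
            if e["date"] == base_d:
                kept.append(e)
                continue
            gap = (e["date"] - base_d).days
            allowed = cfg.overtime_max_annual_delta * max(gap, cfg.overtime_min_gap_days) / 365.0
            if abs(e["value"] - base_v) > allowed:
                continue
            base_v, base_d = e["value"], e["date"]
            kept.append(e)

    # ---- Stage 5: lowest-rank daily selection -----------------------------
    by_day = {}
    for e in kept:
        by_day.setdefault((e["pid"], e["date"]), []).append(e)
    rows = []
    for key in sorted(by_day):
        group = by_day[key]
        group.sort(
            key=lambda e: (
                e["rank"],
                e["value"] if e["value"] is not None else float("inf"),
                e["source"],
                e["id"],
            )
        )
        e = group[0]
        pid = e["pid"]
        w = windows.get((pid, e["branch"]))
        in_window = False
        if w is not None and w[0] <= e["date"] <= w[1]:
            eps = episodes.get(pid)
            in_window = True if eps is None else any(s <= e["date"] <= x for s, x in eps)
        rows.append(
            {
                "person_id": pid,
                "bmi_date": pd.Timestamp(e["date"]),
                "bmi_value": e["value"] if e["value"] is not None else float("nan"),
                "category": e["category"],
                "category_code": _CAT_CODE[e["category"]],
                "source": e["source"],
                "data_type": e["data_type"],
                "rank": e["rank"],
                "branch": e["branch"],
                "age_at_record": e["age_months"] if e["branch"] == "CYP" else e["age_months"] // 12,
                "pregnancy_flag": e["preg"],
                "height_date": pd.Timestamp(e["height_date"]) if e["height_date"] else pd.NaT,
                "weight_date": pd.Timestamp(e["weight_date"]) if e["weight_date"] else pd.NaT,
                "in_window": in_window,
            }
        )
    cols = ["person_id", "bmi_date", "bmi_value", "category", "category_code", "source",
            "data_type", "rank", "branch", "age_at_record", "pregnancy_flag",
            "height_date", "weight_date", "in_window"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["person_id", "bmi_date"], kind="mergesort").reset_index(drop=True)


def naive_exclusion_flow(tables, codelists: CodeListCollection, cfg: StudyConfig) -> pd.DataFrame:
    comps = _stage1_components(tables, codelists, cfg)
    _, flow = _eligible_persons(tables, comps, cfg)
    return pd.DataFrame(flow, columns=["step", "persons_removed", "persons_remaining"])
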