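"""Completeness and coverage analyses over a built RRDA.

These mirror the evaluation a data curator runs after building the asset:
annual coverage (share of each year's eligible population with at least one
record, using the most recent record's category), preservation windows
(who is covered if only the most recent record within a 1-year / 5-year /
full-study look-back from the study end is retained), repeat-measurement
counts, and source-overlap counts (the upset-plot numbers).
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ages import add_months, monday_anchor
from .config import CATEGORIES, StudyConfig

BRANCHES = ("CYP", "adult")
SOURCES = ("WLGP", "MIDS", "NCCH", "PEDW")


def _branch_age_interval(wob: pd.Timestamp, branch: str, config: StudyConfig) -> tuple[pd.Timestamp, pd.Timestamp]:
    """[first, last] calendar day on which a person is in the branch's ages."""
    anchor = monday_anchor(pd.Timestamp(wob).date())
    if branch == "CYP":
        first = add_months(anchor, config.cyp_age_months_min)
        last = add_months(anchor, config.cyp_age_months_max) - dt.timedelta(days=1)
    else:
        first = add_months(anchor, 12 * config.adult_age_years_min)
        last = add_months(anchor, 12 * (config.adult_age_years_max + 1)) - dt.timedelta(days=1)
    return pd.Timestamp(first), pd.Timestamp(last)


def _denominator_ids(
    persons: pd.DataFrame,
    windows: pd.DataFrame,
    branch: str,
    lo: pd.Timestamp,
    hi: pd.Timestamp,
    config: StudyConfig,
) -> set:
    """Persons whose branch window intersects [lo, hi] while branch-aged."""
    wob = persons.set_index("person_id")["week_of_birth"]
    out = set()
    for w in windows[windows["branch"] == branch].itertuples():
        a = max(w.entry_date, lo)
        b = min(w.exit_date, hi)
        if a > b:
            continue
        first, last = _branch_age_interval(wob[w.person_id], branch, config)
        if max(a, first) <= min(b, last):
            out.add(w.person_id)
    return out


def annual_coverage(
    rrda: pd.DataFrame,
    windows: pd.DataFrame,
    persons: pd.DataFrame,
    config: StudyConfig,
    years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per year and branch: eligible denominator, persons with ≥1 entry, the
    coverage proportion, and category counts of each person's most recent
    entry that year.  ``missingness`` is 1 − proportion."""
    if years is None:
        years = range(config.study_start.year, config.study_end.year + 1)
    years = list(years)
    for y in years:
        if y < config.study_start.year or y > config.study_end.year:
            raise ValueError(f"year {y} outside the study period")
    df = rrda.copy()
    df["year"] = pd.to_datetime(df["bmi_date"]).dt.year
    rows = []
    for year in years:
        lo = pd.Timestamp(dt.date(year, 1, 1))
        hi = pd.Timestamp(dt.date(year, 12, 31))
        for branch in BRANCHES:
            denom = _denominator_ids(persons, windows, branch, lo, hi, config)
            sub = df[(df["year"] == year) & (df["branch"] == branch)]
            latest = sub.sort_values(["person_id", "bmi_date"], kind="mergesort").drop_duplicates(
                "person_id", keep="last"
            )
            n_with = latest["person_id"].nunique()
            counts = latest["category"].value_counts()
            row = {
                "year": year,
                "branch": branch,
                "denominator": len(denom),
                "persons_with_record": int(n_with),
                "proportion": (n_with / len(denom)) if denom else 0.0,
                "missingness": 1.0 - ((n_with / len(denom)) if denom else 0.0),
            }
            for c in CATEGORIES:
                row[f"n_{c}"] = int(counts.get(c, 0))
            rows.append(row)
    return pd.DataFrame(rows)


def default_preservation_windows(config: StudyConfig) -> list[tuple[str, dt.date]]:
    """The three standard look-back starts anchored at the study end: the
    anchor year's 1 January, four years earlier, and the study start."""
    anchor_year = config.study_end.year
    return [
        ("1y", dt.date(anchor_year, 1, 1)),
        ("5y", dt.date(anchor_year - 4, 1, 1)),
        ("full", config.study_start),
    ]


def preservation_coverage(
    rrda: pd.DataFrame,
    windows: pd.DataFrame,
    persons: pd.DataFrame,
    config: StudyConfig,
    window_starts: Optional[Sequence[tuple[str, dt.date]]] = None,
    anchor: Optional[dt.date] = None,
) -> pd.DataFrame:
    """Coverage when only the most recent entry within each look-back window
    is preserved.  The denominator is the branch population at the anchor
    date (window contains the anchor while branch-aged)."""
    anchor = anchor or config.study_end
    anchor_ts = pd.Timestamp(anchor)
    if window_starts is None:
        window_starts = default_preservation_windows(config)
    for label, start in window_starts:
        if pd.Timestamp(start) > anchor_ts:
            raise ValueError(f"preservation window {label!r} starts after the anchor")
    dates = pd.to_datetime(rrda["bmi_date"])
    rows = []
    for branch in BRANCHES:
        denom = _denominator_ids(persons, windows, branch, anchor_ts, anchor_ts, config)
        for label, start in window_starts:
            sub = rrda[
                (rrda["branch"] == branch)
                & (dates >= pd.Timestamp(start))
                & (dates <= anchor_ts)
            ]
            covered = set(sub["person_id"]) & denom
            rows.append(
                {
                    "window": label,
                    "branch": branch,
                    "anchor": anchor,
                    "start": start,
                    "denominator": len(denom),
                    "covered": len(covered),
                    "proportion": (len(covered) / len(denom)) if denom else 0.0,
                }
            )
    return pd.DataFrame(rows)


def repeat_measurement_stats(rrda: pd.DataFrame) -> pd.DataFrame:
    """Per branch: histogram of persons by number of distinct years with ≥1
    entry, plus the count with ≥5 distinct years."""
    if rrda.empty:
        return pd.DataFrame(columns=["branch", "distinct_years", "n_persons"])
    df = rrda.copy()
    df["year"] = pd.to_datetime(df["bmi_date"]).dt.year
    per_person = (
        df.drop_duplicates(["branch", "person_id", "year"])
        .groupby(["branch", "person_id"])
        .size()
        .rename("distinct_years")
        .reset_index()
    )
    hist = (
        per_person.groupby(["branch", "distinct_years"]).size().rename("n_persons").reset_index()
    )
    return hist


def persons_with_repeat_years(rrda: pd.DataFrame, min_years: int = 5) -> dict[str, int]:
    """Count of persons per branch (and overall) with ≥ *min_years* distinct
    record years."""
    out = {b: 0 for b in BRANCHES}
    if rrda.empty:
        out["all"] = 0
        return out
    df = rrda.copy()
    df["year"] = pd.to_datetime(df["bmi_date"]).dt.year
    for branch in BRANCHES:
        per = df[df["branch"] == branch].drop_duplicates(["person_id", "year"]).groupby("person_id").size()
        out[branch] = int((per >= min_years).sum())
    per_all = df.drop_duplicates(["person_id", "year"]).groupby("person_id").size()
    out["all"] = int((per_all >= min_years).sum())
    return out


def source_overlap_counts(rrda: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Upset-plot numbers: persons per exact source combination (a partition
    of the covered population) and unconditional per-source counts."""
    if rrda.empty:
        return (
            pd.DataFrame(columns=["sources", "n_persons"]),
            pd.DataFrame(columns=["source", "n_persons"]),
        )
    per_person = rrda.groupby("person_id")["source"].agg(
        lambda s: "+".join(sorted(set(s), key=SOURCES.index))
    )
    subsets = per_person.value_counts().rename_axis("sources").rename("n_persons").reset_index()
    marginals = pd.DataFrame(
        {
            "source": list(SOURCES),
            "n_persons": [int(rrda[rrda["source"] == s]["person_id"].nunique()) for s in SOURCES],
        }
    )
    return subsets, marginals
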