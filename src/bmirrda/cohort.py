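"""Cohort construction: demographic exclusions, residency imputation,
contribution windows and branch (CYP vs adult) assignment.

Eligibility follows the published selection rules: reliable linkage status,
a recorded week of birth, a valid sex code, and being alive for more than the
minimum residency period (31 days) from the study start.  Each person's
contribution window is bounded by residency, death and — for the CYP branch —
the day before the 19th birthday.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ages import add_months, completed_months, completed_years, monday_anchor
from .config import StudyConfig

VALID_SEXES = ("F", "M")

EXCLUSION_STEPS = (
    "linkage_status_not_accepted",
    "missing_week_of_birth",
    "invalid_sex",
    "death_before_study_start",
    "death_within_min_residency",
)


@dataclass
class ExclusionFlow:
    """Ordered selection/exclusion box counts (telescoping)."""

    initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (label, removed, remaining)

    def add(self, label: str, removed: int) -> None:
        remaining = (self.steps[-1][2] if self.steps else self.initial) - removed
        if remaining < 0:
            raise ValueError("exclusion step removed more persons than remained")
        self.steps.append((label, removed, remaining))

    @property
    def remaining(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "persons_removed", "persons_remaining"])


def apply_exclusions(persons: pd.DataFrame, config: StudyConfig) -> tuple[pd.DataFrame, ExclusionFlow]:
    """Apply the fixed-order demographic exclusions.

    Order: linkage status outside the accepted set; missing week of birth;
    invalid sex code; death before the study start; death within the first
    ``min_residency_days`` of the study.
    """
    flow = ExclusionFlow(initial=len(persons))
    df = persons.copy()

    ok = df["linkage_status"].isin(list(config.linkage_status_accept))
    flow.add("linkage_status_not_accepted", int((~ok).sum()))
    df = df[ok]

    ok = df["week_of_birth"].notna()
    flow.add("missing_week_of_birth", int((~ok).sum()))
    df = df[ok]

    ok = df["sex"].isin(VALID_SEXES)
    flow.add("invalid_sex", int((~ok).sum()))
    df = df[ok]

    start = pd.Timestamp(config.study_start)
    dod = df["date_of_death"]
    ok = dod.isna() | (dod >= start)
    flow.add("death_before_study_start", int((~ok).sum()))
    df = df[ok]

    cutoff = start + pd.Timedelta(days=config.min_residency_days)
    dod = df["date_of_death"]
    ok = dod.isna() | (dod >= cutoff)
    flow.add("death_within_min_residency", int((~ok).sum()))
    df = df[ok]

    return df.reset_index(drop=True), flow


def impute_residency(episodes: pd.DataFrame, config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing episode dates with the study bounds and clip to the study.

    Returns (imputed, rejected); an episode whose intersection with the study
    window is empty is rejected.
    """
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    df = episodes.copy()
    df["start_date"] = df["start_date"].fillna(start).clip(lower=start)
    df["end_date"] = df["end_date"].fillna(end).clip(upper=end)
    ok = df["start_date"] <= df["end_date"]
    return df[ok].reset_index(drop=True), df[~ok].reset_index(drop=True)


def age_at(week_of_birth: dt.date, date: dt.date) -> tuple[int, int]:
    """(completed months, completed years) at *date*, from the Monday anchor."""
    anchor = monday_anchor(week_of_birth)
    months = completed_months(anchor, date)
    return months, months // 12


def assign_branch(age_months: int, config: StudyConfig) -> Optional[str]:
    """Branch of a record by age: CYP for [24 months, 19th birthday),
    adult for [19, 100] completed years, otherwise ``None`` (out of scope)."""
    years = age_months // 12
    if config.cyp_age_months_min <= age_months and years < config.adult_age_years_min:
        return "CYP"
    if config.adult_age_years_min <= years <= config.adult_age_years_max:
        return "adult"
    return None


def age_months_vector(anchors: pd.Series, dates: pd.Series) -> np.ndarray:
    """Vectorised completed-months (same clamping convention as
    :func:`bmirrda.ages.completed_months`); anchors must not be missing."""
    a, d = pd.DatetimeIndex(anchors), pd.DatetimeIndex(dates)
    m = (d.year - a.year) * 12 + (d.month - a.month)
    anniversary_day = np.minimum(a.day, d.days_in_month)
    m = np.asarray(m) - (np.asarray(d.day) < anniversary_day)
    if (m < 0).any():
        raise ValueError("record date precedes birth anchor")
    return m.astype(np.int64)


def monday_anchor_vector(wob: pd.Series) -> pd.Series:
    idx = pd.DatetimeIndex(wob)
    return pd.Series(idx - pd.to_timedelta(idx.weekday, unit="D"), index=wob.index)


_EXIT_PRIORITY = ("death", "moved_out", "turned_19", "study_end")


def contribution_windows(
    persons: pd.DataFrame,
    episodes: pd.DataFrame,
    config: StudyConfig,
    branches: tuple[str, ...] = ("CYP", "adult"),
) -> pd.DataFrame:
    """One contribution window per eligible person per branch.

    entry = max(study start, earliest residency start); exit = min(study end,
    death, latest residency end, and for the CYP branch the day before the
    19th birthday).  Persons with an empty window in a branch contribute no
    rows for it.  Persons with no residency episode are treated as resident
    for the whole study (fully imputed episode).
    """
    imputed, _ = impute_residency(episodes, config)
    span = imputed.groupby("person_id").agg(
        first_start=("start_date", "min"), last_end=("end_date", "max")
    )
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)

    rows = []
    for p in persons.itertuples():
        if p.person_id in span.index:
            first_start = span.loc[p.person_id, "first_start"]
            last_end = span.loc[p.person_id, "last_end"]
        else:
            first_start, last_end = start, end
        entry = max(start, first_start)
        candidates = []
        if pd.notna(p.date_of_death):
            candidates.append(("death", p.date_of_death))
        if last_end < end:
            candidates.append(("moved_out", last_end))
        for branch in branches:
            cand = list(candidates)
            if branch == "CYP":
                anchor = monday_anchor(p.week_of_birth.date())
                nineteenth = add_months(anchor, config.cyp_age_months_max)
                cand.append(("turned_19", pd.Timestamp(nineteenth) - pd.Timedelta(days=1)))
            cand.append(("study_end", end))
            exit_date = min(d for _, d in cand)
            reason = next(r for r in _EXIT_PRIORITY if any(rr == r and dd == exit_date for rr, dd in cand))
            if entry <= exit_date:
                rows.append(
                    {
                        "person_id": p.person_id,
                        "branch": branch,
                        "entry_date": entry,
                        "exit_date": exit_date,
                        "exit_reason": reason,
                    }
                )
    return pd.DataFrame(rows, columns=["person_id", "branch", "entry_date", "exit_date", "exit_reason"])


__all__ = [
    "ExclusionFlow",
    "EXCLUSION_STEPS",
    "apply_exclusions",
    "impute_residency",
    "contribution_windows",
    "age_at",
    "assign_branch",
    "age_months_vector",
    "monday_anchor_vector",
    "completed_months",
    "completed_years",
    "monday_anchor",
    "add_months",
]
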