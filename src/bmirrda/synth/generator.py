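"""Synthetic linked-EHR generator.

Emulates the structure of the four BMI sources (primary-care coded events,
hospital obesity diagnoses, maternity records, child measurements) plus the
demographics and residency tables: duplicate same-day entries across
sources, heterogeneous units, implausible values, same-day and over-time
inconsistencies, pregnancies, migration and mortality.  Realism is
structural, not statistical — the point is that every cleaning rule and
metric has known ground truth, not that Welsh demographic margins are
matched.

Every record carries exactly one truth label; the authoritative expected
output, however, is computed by running the naive reference implementation
(:func:`bmirrda.synth.naive.naive_rrda`) on the generated tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ..ages import add_months, completed_months, monday_anchor
from ..codelists import CodeListCollection, default_codelists
from ..config import StudyConfig
from ..derive import GrowthReference, categorise_adult

LB_PER_KG = 1.0 / 0.45359237


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Recording rates are events per person-year within the age window of the
    process; error-injection rates are explained field by field.  A fixed
    seed makes the whole generator byte-reproducible.
    """

    n_persons: int = 500
    seed: int = 0
    study_start: dt.date = dt.date(2000, 1, 1)
    study_end: dt.date = dt.date(2022, 12, 31)

    # recording rates (events / person-year while age-eligible)
    wlgp_bmi_rate_adult: float = 0.35
    wlgp_bmi_rate_cyp: float = 0.06
    wlgp_hw_rate_adult: float = 0.12
    wlgp_cat_rate_adult: float = 0.04
    ncch_rate: float = 0.45          # child measurement programme, ages 4-13
    mids_pregnancy_rate: float = 0.07  # pregnancies / woman-year, ages 16-45
    pedw_rate: float = 0.05          # obesity-coded admissions / year while obese
    cross_source_duplicate_rate: float = 0.15  # NCCH days copied into WLGP

    # trajectory parameters
    adult_bmi_start_mean: float = 26.5
    adult_bmi_start_sd: float = 4.0
    adult_annual_drift_sd: float = 0.4
    measurement_noise_sd: float = 0.15
    child_z_sd: float = 0.9

    # error injection
    unit_error_rate: float = 0.02        # of height/weight rows
    outlier_rate: float = 0.01           # extra implausible BMI values / person
    same_day_conflict_rate: float = 0.05  # conflict days / person event-day
    category_conflict_share: float = 0.4  # share of conflicts as category-only pairs
    overtime_jump_rate: float = 0.03     # adult males with an injected jump
    under2_rate: float = 0.05            # children given an under-2 measurement

    # demographic exclusions / censoring
    bad_linkage_rate: float = 0.04
    missing_wob_rate: float = 0.02
    invalid_sex_rate: float = 0.01
    early_dod_rate: float = 0.01
    death_rate: float = 0.01             # per person-year
    migration_out_rate: float = 0.008    # per person-year
    late_entry_rate: float = 0.08

    def __post_init__(self):
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        for name in (
            "wlgp_bmi_rate_adult", "wlgp_bmi_rate_cyp", "wlgp_hw_rate_adult",
            "wlgp_cat_rate_adult", "ncch_rate", "mids_pregnancy_rate", "pedw_rate",
            "cross_source_duplicate_rate", "unit_error_rate", "outlier_rate",
            "same_day_conflict_rate", "category_conflict_share", "overtime_jump_rate",
            "under2_rate", "bad_linkage_rate", "missing_wob_rate", "invalid_sex_rate",
            "early_dod_rate", "death_rate", "migration_out_rate", "late_entry_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def study_config(self) -> StudyConfig:
        return StudyConfig(study_start=self.study_start, study_end=self.study_end)


@dataclass
class GroundTruth:
    """Per-record truth labels, plus the oracle-computed expectations."""

    labels: pd.DataFrame                  # record_id, table, label
    expected_rrda: Optional[pd.DataFrame] = None
    expected_flow: Optional[pd.DataFrame] = None

    def ids_with_label(self, label: str) -> set[str]:
        return set(self.labels.loc[self.labels["label"] == label, "record_id"])


@dataclass
class SyntheticDataset:
    tables: dict[str, pd.DataFrame]
    codelists: CodeListCollection
    reference: GrowthReference
    config: StudyConfig
    scenario: ScenarioConfig
    truth: GroundTruth


def generate_reference(age_min: int = 24, age_max: int = 228, step: int = 4) -> GrowthReference:
    """Smooth synthetic L, M, S curves for both sexes.

    M rises from ~15.5 to ~21.5 kg/m² with a logistic shape (increasing,
    then plateauing), S grows from 0.09 to 0.14 and L from −1.6 to −0.8.
    Purely synthetic — not any published growth standard.
    """
    grid = np.arange(age_min, age_max + 1, step, dtype=float)
    if grid[-1] != age_max:
        grid = np.append(grid, float(age_max))
    frames = []
    for sex, m_off in (("F", 0.2), ("M", 0.0)):
        t = (grid - age_min) / (age_max - age_min)
        M = 15.3 + m_off + 6.3 / (1.0 + np.exp(-(grid - 150.0) / 35.0))
        S = 0.09 + 0.05 * t
        L = -1.6 + 0.8 * t
        frames.append(pd.DataFrame({"sex": sex, "age_months": grid, "L": L, "M": M, "S": S}))
    ref = pd.concat(frames, ignore_index=True)
    return GrowthReference(ref.sort_values(["sex", "age_months"]).reset_index(drop=True))


# ---------------------------------------------------------------------------


@dataclass
class _PersonSim:
    person_id: str
    anchor: dt.date               # Monday-anchored true week of birth
    sex: str                      # true sex, F/M
    recorded_sex: str
    linkage_status: int
    missing_wob: bool
    dod: Optional[dt.date]
    res_start: dt.date
    res_end: dt.date
    height_adult: float
    bmi0: float
    drift: np.ndarray             # cumulative annual BMI drift from study start
    child_z: float
    height_factor: float
    excluded: bool = False  # fails a demographic exclusion; gets no injected
    used_days: set = field(default_factory=set)  # cleaning-stage errors


def _days(a: dt.date, b: dt.date) -> int:
    return (b - a).days


class _Sim:
    def __init__(self, scenario: ScenarioConfig, reference: GrowthReference):
        self.sc = scenario
        self.ref = reference
        self.cfg = scenario.study_config()
        self.rng = np.random.default_rng(scenario.seed)
        self.rows: dict[str, list[dict]] = {k: [] for k in ("wlgp", "pedw", "mids", "ncch")}
        self.labels: dict[str, list[str]] = {k: [] for k in ("wlgp", "pedw", "mids", "ncch")}
        self.demo_rows: list[dict] = []
        self.res_rows: list[dict] = []

    # -- trajectories -----------------------------------------------------

    def _child_bmi(self, p: _PersonSim, date: dt.date) -> float:
        am = completed_months(p.anchor, date)
        am = min(max(am, 24), 228)
        L, M, S = self.ref.lookup(p.sex, float(am))
        return float(M * (1.0 + L * S * p.child_z) ** (1.0 / L))

    def _adult_bmi(self, p: _PersonSim, date: dt.date) -> float:
        y = _days(self.sc.study_start, date) / 365.25
        i = int(np.clip(np.floor(y), 0, len(p.drift) - 2))
        frac = y - i
        return float(p.bmi0 + p.drift[i] + frac * (p.drift[i + 1] - p.drift[i]))

    def true_bmi(self, p: _PersonSim, date: dt.date) -> float:
        am = completed_months(p.anchor, date)
        if am < 228:
            return self._child_bmi(p, date)
        return self._adult_bmi(p, date)

    def measured_bmi(self, p: _PersonSim, date: dt.date) -> float:
        v = self.true_bmi(p, date) + self.rng.normal(0.0, self.sc.measurement_noise_sd)
        return round(float(np.clip(v, 12.5, 95.0)), 1)

    def child_height(self, p: _PersonSim, date: dt.date) -> float:
        am = min(max(completed_months(p.anchor, date), 6), 228)
        base = 0.72 + 1.08 * (am / 228.0) ** 0.62
        sex_f = 1.0 if p.sex == "M" else 0.97
        return round(float(np.clip(base * sex_f * p.height_factor, 0.55, 2.1)), 2)

    def height_at(self, p: _PersonSim, date: dt.date) -> float:
        if completed_months(p.anchor, date) < 228:
            return self.child_height(p, date)
        return round(p.height_adult, 2)

    # -- date sampling ----------------------------------------------------

    def sample_day(self, p: _PersonSim, lo: dt.date, hi: dt.date, *, force_new=True) -> Optional[dt.date]:
        n = _days(lo, hi)
        if n < 0:
            return None
        for _ in range(12):
            d = lo + dt.timedelta(days=int(self.rng.integers(0, n + 1)))
            if not force_new or d not in p.used_days:
                p.used_days.add(d)
                return d
        return None

    def age_window(self, p: _PersonSim, lo_months: int, hi_months: int) -> Optional[tuple[dt.date, dt.date]]:
        """Overlap of the person's active window with an age interval
        [lo_months, hi_months) in completed months."""
        a0 = max(self.sc.study_start, p.res_start, add_months(p.anchor, lo_months))
        a1 = min(self.sc.study_end, p.res_end, add_months(p.anchor, hi_months) - dt.timedelta(days=1))
        if p.dod is not None:
            a1 = min(a1, p.dod)
        return (a0, a1) if a0 <= a1 else None

    # -- population -------------------------------------------------------

    def make_person(self, i: int) -> _PersonSim:
        rng, sc = self.rng, self.sc
        pid = f"P{i:06d}"
        years = _days(sc.study_start, sc.study_end) / 365.25
        # age at study start spans -study_length..95: births occur throughout
        # the study, so every branch is populated at every calendar year
        age0 = float(rng.uniform(-years, 95.0))
        birth = sc.study_start + dt.timedelta(days=int(round(-age0 * 365.25)))
        anchor = monday_anchor(birth)
        sex = "F" if rng.random() < 0.5 else "M"

        linkage = 99 if rng.random() < sc.bad_linkage_rate else int(rng.choice([1, 1, 1, 4, 39]))
        missing_wob = rng.random() < sc.missing_wob_rate
        recorded_sex = "U" if rng.random() < sc.invalid_sex_rate else sex

        dod: Optional[dt.date] = None
        if rng.random() < sc.early_dod_rate:
            if rng.random() < 0.5:
                dod = sc.study_start - dt.timedelta(days=int(rng.integers(1, 1000)))
            else:
                dod = sc.study_start + dt.timedelta(days=int(rng.integers(0, self.cfg.min_residency_days)))
        elif rng.random() < sc.death_rate * years:
            dod = sc.study_start + dt.timedelta(days=int(rng.integers(60, max(61, _days(sc.study_start, sc.study_end)))))

        res_start = sc.study_start
        res_end = sc.study_end
        if rng.random() < sc.late_entry_rate:
            res_start = sc.study_start + dt.timedelta(days=int(rng.integers(1, max(2, _days(sc.study_start, sc.study_end) // 2))))
        if rng.random() < sc.migration_out_rate * years:
            res_end = res_start + dt.timedelta(
                days=int(rng.integers(90, max(91, _days(res_start, sc.study_end))))
            )

        n_years = int(np.ceil(years)) + 2
        incr = rng.normal(0.08, sc.adult_annual_drift_sd, size=n_years)
        drift = np.concatenate([[0.0], np.cumsum(incr)])
        excluded = (
            linkage not in self.cfg.linkage_status_accept
            or missing_wob
            or recorded_sex not in ("F", "M")
            or (dod is not None and dod < sc.study_start + dt.timedelta(days=self.cfg.min_residency_days))
        )
        return _PersonSim(
            person_id=pid,
            anchor=anchor,
            sex=sex,
            recorded_sex=recorded_sex,
            linkage_status=linkage,
            missing_wob=missing_wob,
            dod=dod,
            res_start=res_start,
            res_end=res_end,
            height_adult=float(np.clip(rng.normal(1.75 if sex == "M" else 1.62, 0.07), 1.45, 2.05)),
            bmi0=float(np.clip(rng.normal(sc.adult_bmi_start_mean, sc.adult_bmi_start_sd), 16.0, 42.0)),
            drift=drift,
            child_z=float(np.clip(rng.normal(0.0, sc.child_z_sd), -2.4, 2.4)),
            height_factor=float(np.clip(rng.normal(1.0, 0.035), 0.88, 1.12)),
            excluded=excluded,
        )

    # -- row emitters ------------------------------------------------------

    def emit(self, table: str, label: str, **row) -> str:
        self.rows[table].append(row)
        self.labels[table].append(label)
        prefix = {"wlgp": "wlgp", "pedw": "pedw", "mids": "mids", "ncch": "ncch"}[table]
        return f"{prefix}:{len(self.rows[table]) - 1}"

    def emit_height_weight(self, table: str, p: _PersonSim, date: dt.date,
                           height_m: float, weight_kg: float, label: str,
                           unit_error: bool, birth_date: Optional[dt.date] = None) -> None:
        rng = self.rng
        style = rng.random()
        if unit_error:
            if rng.random() < 0.5:
                hv, hu = round(height_m * 100.0, 1), "m"          # cm recorded as m
                wv, wu = round(weight_kg, 1), "kg"
            else:
                hv, hu = round(height_m, 2), "m"
                wv, wu = round(weight_kg * LB_PER_KG, 1), "kg"    # lb recorded as kg
        elif style < 0.4:
            hv, hu = round(height_m * 100.0, 1), "cm"
            wv, wu = round(weight_kg, 1), "kg"
        elif style < 0.7:
            hv, hu = round(height_m, 2), "m"
            wv, wu = round(weight_kg, 1), "kg"
        else:
            hv, hu = round(height_m * 100.0, 1), ""               # unit-less cm (heuristic)
            wv, wu = round(weight_kg, 1), ""
        if table == "wlgp":
            self.emit("wlgp", label, person_id=p.person_id, event_date=date, code="229..",
                      numeric_value=hv, unit=hu)
            self.emit("wlgp", label, person_id=p.person_id, event_date=date, code="22A..",
                      numeric_value=wv, unit=wu)
        else:
            row = {
                "person_id": p.person_id,
                "record_date": date,
                "height_value": hv,
                "height_unit": hu,
                "weight_value": wv,
                "weight_unit": wu,
            }
            if table == "mids":
                row["baby_birth_date"] = birth_date
            self.emit(table, label, **row)

    # -- per-person event generation ---------------------------------------

    def events_for(self, p: _PersonSim) -> None:
        rng, sc, cfg = self.rng, self.sc, self.cfg
        adult_w = self.age_window(p, 12 * cfg.adult_age_years_min, 12 * (cfg.adult_age_years_max + 1))
        cyp_w = self.age_window(p, cfg.cyp_age_months_min, cfg.cyp_age_months_max)

        def years_of(w):
            return 0.0 if w is None else (_days(w[0], w[1]) + 1) / 365.25

        # WLGP direct BMI values
        for w, rate in ((adult_w, sc.wlgp_bmi_rate_adult), (cyp_w, sc.wlgp_bmi_rate_cyp)):
            for _ in range(rng.poisson(rate * years_of(w))):
                d = self.sample_day(p, *w)
                if d:
                    self.emit("wlgp", "clean", person_id=p.person_id, event_date=d,
                              code="22K..", numeric_value=self.measured_bmi(p, d), unit="")

        # WLGP adult height/weight days
        if adult_w:
            for _ in range(rng.poisson(sc.wlgp_hw_rate_adult * years_of(adult_w))):
                d = self.sample_day(p, *adult_w)
                if d is None:
                    continue
                bmi = self.measured_bmi(p, d)
                h = self.height_at(p, d)
                unit_err = rng.random() < sc.unit_error_rate
                self.emit_height_weight("wlgp", p, d, h, round(bmi * h * h, 1),
                                        "unit_error" if unit_err else "clean", unit_err)

        # WLGP adult category-only entries
        if adult_w:
            for _ in range(rng.poisson(sc.wlgp_cat_rate_adult * years_of(adult_w))):
                d = self.sample_day(p, *adult_w)
                if d:
                    cat = categorise_adult(self.measured_bmi(p, d), cfg.adult_cut_points)
                    code = {"underweight": "22K3.", "normal": "22K2.",
                            "overweight": "22K5.", "obese": "22K7."}[cat]
                    self.emit("wlgp", "clean", person_id=p.person_id, event_date=d,
                              code=code, numeric_value=np.nan, unit="")

        # NCCH child measurement programme (ages 4-13), some duplicated to WLGP
        ncch_w = self.age_window(p, 48, 156)
        if ncch_w:
            for _ in range(rng.poisson(sc.ncch_rate * years_of(ncch_w))):
                d = self.sample_day(p, *ncch_w)
                if d is None:
                    continue
                bmi = self.measured_bmi(p, d)
                h = self.child_height(p, d)
                w_kg = round(bmi * h * h, 1)
                unit_err = rng.random() < sc.unit_error_rate
                label = "unit_error" if unit_err else "clean"
                self.emit_height_weight("ncch", p, d, h, w_kg, label, unit_err)
                if not unit_err and rng.random() < sc.cross_source_duplicate_rate:
                    # deliberate same-day duplicate in primary care, identical values
                    self.emit("wlgp", "clean", person_id=p.person_id, event_date=d,
                              code="229..", numeric_value=h, unit="m")
                    self.emit("wlgp", "clean", person_id=p.person_id, event_date=d,
                              code="22A..", numeric_value=w_kg, unit="kg")

        # under-2 measurements (excluded by the methodology)
        under2_w = self.age_window(p, 6, 24)
        if under2_w and rng.random() < sc.under2_rate:
            d = self.sample_day(p, *under2_w)
            if d:
                h = self.child_height(p, d)
                self.emit_height_weight("ncch", p, d, h, round(16.5 * h * h, 1), "under_2", False)

        # MIDS pregnancies
        if p.sex == "F":
            fertile_w = self.age_window(p, 12 * 16, 12 * 46)
            if fertile_w:
                for _ in range(rng.poisson(sc.mids_pregnancy_rate * years_of(fertile_w))):
                    birth = self.sample_day(p, *fertile_w)
                    if birth is None:
                        continue
                    for _ in range(int(rng.integers(1, 3))):
                        offset = int(rng.integers(10, 270))
                        d = birth - dt.timedelta(days=offset)
                        if d < max(self.sc.study_start, p.res_start) or d in p.used_days:
                            continue
                        p.used_days.add(d)
                        gain = 4.0 * (1.0 - offset / 280.0)
                        h = self.height_at(p, d)
                        bmi = self.measured_bmi(p, d) + round(gain, 1)
                        self.emit_height_weight("mids", p, d, h, round(bmi * h * h, 1),
                                                "clean", False, birth_date=birth)

        # PEDW obesity-coded admissions (only while actually obese)
        full_w = self.age_window(p, 24, 12 * (cfg.adult_age_years_max + 1))
        if full_w:
            for _ in range(rng.poisson(sc.pedw_rate * years_of(full_w))):
                d = self.sample_day(p, *full_w)
                if d and self.true_bmi(p, d) >= 30.0:
                    self.emit("pedw", "clean", person_id=p.person_id, admission_date=d, code="E66")

        # extreme-value outliers
        if adult_w or cyp_w:
            w = adult_w or cyp_w
            for _ in range(rng.poisson(sc.outlier_rate)):
                d = self.sample_day(p, *w)
                if d:
                    v = float(rng.uniform(5.0, 11.5)) if rng.random() < 0.5 else float(rng.uniform(101.0, 160.0))
                    self.emit("wlgp", "extreme_outlier", person_id=p.person_id, event_date=d,
                              code="22K..", numeric_value=round(v, 1), unit="")

        # injected same-day conflicts: a fresh day with two mutually
        # inconsistent entries (values >= 5% apart, or two different
        # category-only codes).  Only for cohort-eligible persons — the
        # labels mean "reaches the cleaning stage and must be removed there".
        n_days = 0 if p.excluded else len(p.used_days)
        n_conf = rng.binomial(n_days, sc.same_day_conflict_rate) if n_days else 0
        for _ in range(n_conf):
            w = adult_w if (adult_w and (not cyp_w or rng.random() < 0.7)) else cyp_w
            if w is None:
                continue
            d = self.sample_day(p, *w)
            if d is None:
                continue
            as_category = adult_w is w and rng.random() < sc.category_conflict_share
            if as_category:
                self.emit("wlgp", "same_day_conflict", person_id=p.person_id, event_date=d,
                          code="22K2.", numeric_value=np.nan, unit="")
                self.emit("wlgp", "same_day_conflict", person_id=p.person_id, event_date=d,
                          code="22K5.", numeric_value=np.nan, unit="")
            else:
                v1 = self.measured_bmi(p, d)
                v2 = round(v1 * 1.3, 1) if v1 * 1.3 <= 95.0 else round(v1 * 0.7, 1)
                for v in (v1, v2):
                    self.emit("wlgp", "same_day_conflict", person_id=p.person_id, event_date=d,
                              code="22K..", numeric_value=v, unit="")

        # injected over-time jumps (adult males, pregnancy never interferes)
        if adult_w and not p.excluded and p.sex == "M" and rng.random() < sc.overtime_jump_rate:
            anchor_day = self.sample_day(p, *adult_w)
            if anchor_day is not None:
                base = self.measured_bmi(p, anchor_day)
                self.emit("wlgp", "clean", person_id=p.person_id, event_date=anchor_day,
                          code="22K..", numeric_value=base, unit="")
                d = anchor_day + dt.timedelta(days=int(rng.integers(10, 26)))
                if d <= adult_w[1] and d not in p.used_days:
                    p.used_days.add(d)
                    jump = round(min(base + 15.0, 95.0), 1)
                    self.emit("wlgp", "over_time_conflict", person_id=p.person_id, event_date=d,
                              code="22K..", numeric_value=jump, unit="")

    # -- assembly ----------------------------------------------------------

    def run(self) -> SyntheticDataset:
        sc = self.sc
        persons = [self.make_person(i) for i in range(sc.n_persons)]
        for p in persons:
            self.demo_rows.append(
                {
                    "person_id": p.person_id,
                    "sex": p.recorded_sex,
                    "week_of_birth": None if p.missing_wob else p.anchor,
                    "date_of_death": p.dod,
                    "linkage_status": p.linkage_status,
                }
            )
            hide_start = p.res_start == sc.study_start and self.rng.random() < 0.5
            hide_end = p.res_end == sc.study_end and self.rng.random() < 0.5
            self.res_rows.append(
                {
                    "person_id": p.person_id,
                    "start_date": None if hide_start else p.res_start,
                    "end_date": None if hide_end else p.res_end,
                }
            )
            if p.dod is not None and p.dod < p.res_start:
                continue
            self.events_for(p)

        tables = {
            "demographics": _typed(self.demo_rows, ["person_id", "sex", "week_of_birth", "date_of_death", "linkage_status"],
                                   dates=["week_of_birth", "date_of_death"], ints=["linkage_status"]),
            "residency": _typed(self.res_rows, ["person_id", "start_date", "end_date"],
                                dates=["start_date", "end_date"]),
            "wlgp_events": _typed(self.rows["wlgp"], ["person_id", "event_date", "code", "numeric_value", "unit"],
                                  dates=["event_date"], floats=["numeric_value"]),
            "pedw_episodes": _typed(self.rows["pedw"], ["person_id", "admission_date", "code"],
                                    dates=["admission_date"]),
            "mids_records": _typed(self.rows["mids"],
                                   ["person_id", "record_date", "height_value", "height_unit",
                                    "weight_value", "weight_unit", "baby_birth_date"],
                                   dates=["record_date", "baby_birth_date"],
                                   floats=["height_value", "weight_value"]),
            "ncch_records": _typed(self.rows["ncch"],
                                   ["person_id", "record_date", "height_value", "height_unit",
                                    "weight_value", "weight_unit"],
                                   dates=["record_date"], floats=["height_value", "weight_value"]),
        }
        label_rows = []
        for table, prefix in (("wlgp_events", "wlgp"), ("pedw_episodes", "pedw"),
                              ("mids_records", "mids"), ("ncch_records", "ncch")):
            for i, lab in enumerate(self.labels[prefix]):
                label_rows.append({"record_id": f"{prefix}:{i}", "table": table, "label": lab})
        truth = GroundTruth(labels=pd.DataFrame(label_rows, columns=["record_id", "table", "label"]))
        return SyntheticDataset(
            tables=tables,
            codelists=default_codelists(),
            reference=self.ref,
            config=self.cfg,
            scenario=sc,
            truth=truth,
        )


def _typed(rows: list[dict], columns: list[str], dates=(), floats=(), ints=()) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=columns)
    for c in dates:
        df[c] = pd.to_datetime(df[c])
    for c in floats:
        df[c] = pd.to_numeric(df[c]).astype(float)
    for c in ints:
        df[c] = df[c].astype("int64")
    for c in columns:
        if c not in dates and c not in floats and c not in ints:
            df[c] = df[c].fillna("").astype(str) if len(df) else df[c].astype(str)
    return df


def generate(scenario: ScenarioConfig, with_expected: bool = True) -> SyntheticDataset:
    """Generate one fully-labelled synthetic dataset.

    With ``with_expected`` the naive reference implementation is run on the
    generated tables and its RRDA / exclusion flow attached as the expected
    output.
    """
    ds = _Sim(scenario, generate_reference()).run()
    if with_expected:
        from .naive import naive_exclusion_flow, naive_rrda

        ds.truth.expected_rrda = naive_rrda(ds.tables, ds.codelists, ds.reference, ds.config)
        ds.truth.expected_flow = naive_exclusion_flow(ds.tables, ds.codelists, ds.config)
    return ds
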