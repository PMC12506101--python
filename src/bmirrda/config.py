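"""Study configuration.

All tunable thresholds of the harmonisation methodology live in a single
validated :class:`StudyConfig` object: the study window, plausibility bounds,
the height–weight pairing window, the same-day consistency tolerance, the
pregnancy window, the source hierarchy and the category cut-offs.  Defaults
are the published parameters of the Welsh national BMI asset (study period
2000-01-01 to 2022-12-31, BMI bounds 12–100 kg/m², 180-day pairing window,
5% same-day tolerance, ±294-day pregnancy window, 31-day minimum residency,
CYP ages 2–18 inclusive, adults 19–100, WHO adult cut-offs 18.5/25/30).
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.stats import norm

#: The six (source, data_type) rows of the source hierarchy, most trusted first.
DEFAULT_HIERARCHY: tuple[tuple[str, str, int], ...] = (
    ("WLGP", "bmi_value", 1),
    ("WLGP", "height_weight", 2),
    ("MIDS", "height_weight", 3),
    ("NCCH", "height_weight", 4),
    ("WLGP", "bmi_category", 5),
    ("PEDW", "obese_category", 6),
)

CATEGORIES = ("underweight", "normal", "overweight", "obese")


class StudyConfig(BaseModel):
    """Validated bundle of every tunable parameter of the pipeline."""

    model_config = ConfigDict(frozen=True)

    study_start: dt.date = dt.date(2000, 1, 1)
    study_end: dt.date = dt.date(2022, 12, 31)

    # plausibility bounds
    bmi_min: float = 12.0          # kg/m^2; values strictly below are removed
    bmi_max: float = 100.0         # kg/m^2; values strictly above are removed
    height_min_m: float = 0.5
    height_max_m: float = 2.5
    weight_min_kg: float = 5.0
    weight_max_kg: float = 350.0

    # windows (days)
    hw_pair_window_days: int = 180       # CYP height-weight date gap
    pregnancy_window_days: int = 294     # +/- 42 weeks around a birth
    min_residency_days: int = 31         # alive & resident > 31 days from start

    same_day_rel_diff: float = 0.05      # <5% relative difference is consistent

    # branch age bounds
    cyp_age_months_min: int = 24
    cyp_age_months_max: int = 228        # 19th birthday; CYP runs to the day before
    adult_age_years_min: int = 19
    adult_age_years_max: int = 100

    adult_cut_points: tuple[float, float, float] = (18.5, 25.0, 30.0)

    # paediatric category percentiles (z thresholds are their normal quantiles)
    cyp_pct_underweight: float = 0.02
    cyp_pct_overweight: float = 0.85
    cyp_pct_obese: float = 0.95

    hierarchy: tuple[tuple[str, str, int], ...] = DEFAULT_HIERARCHY

    # over-time cleaning (adults only); see docs/methods.md
    overtime_max_annual_delta: float = 10.0   # kg/m^2 per 365 days
    overtime_min_gap_days: int = 30           # rate floor for short gaps

    # adult height pairing: "carry_forward" (per-weight) or "single" (one
    # study-wide most recent height)
    adult_height_mode: str = "carry_forward"

    linkage_status_accept: frozenset[int] = frozenset({1, 4, 39})

    @field_validator(
        "hw_pair_window_days",
        "pregnancy_window_days",
        "min_residency_days",
        "overtime_min_gap_days",
    )
    @classmethod
    def _positive_window(cls, v: int, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("same_day_rel_diff", "overtime_max_annual_delta")
    @classmethod
    def _positive_float(cls, v: float, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v

    @field_validator("adult_height_mode")
    @classmethod
    def _height_mode(cls, v: str):
        if v not in ("carry_forward", "single"):
            raise ValueError(f"adult_height_mode must be 'carry_forward' or 'single', got {v!r}")
        return v

    @model_validator(mode="after")
    def _cross_field(self):
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        if not (0 < self.bmi_min < self.bmi_max):
            raise ValueError("require 0 < bmi_min < bmi_max")
        if not (0 < self.height_min_m < self.height_max_m):
            raise ValueError("require 0 < height_min_m < height_max_m")
        if not (0 < self.weight_min_kg < self.weight_max_kg):
            raise ValueError("require 0 < weight_min_kg < weight_max_kg")
        a, b, c = self.adult_cut_points
        if not (a < b < c):
            raise ValueError("adult_cut_points must be strictly increasing")
        if not (0 < self.cyp_pct_underweight < self.cyp_pct_overweight < self.cyp_pct_obese < 1):
            raise ValueError("cyp percentiles must be strictly increasing in (0, 1)")
        if not (0 <= self.cyp_age_months_min < self.cyp_age_months_max):
            raise ValueError("cyp age bounds must be increasing")
        if not (0 < self.adult_age_years_min < self.adult_age_years_max):
            raise ValueError("adult age bounds must be increasing")
        ranks = sorted(r for _, _, r in self.hierarchy)
        if ranks != list(range(1, len(self.hierarchy) + 1)):
            raise ValueError("hierarchy ranks must be a permutation of 1..n")
        pairs = [(s, d) for s, d, _ in self.hierarchy]
        if len(set(pairs)) != len(pairs):
            raise ValueError("hierarchy (source, data_type) pairs must be unique")
        return self

    # -- derived lookups ---------------------------------------------------

    def rank_table(self) -> dict[tuple[str, str], int]:
        """Mapping (source, data_type) -> rank."""
        return {(s, d): r for s, d, r in self.hierarchy}

    def cyp_z_thresholds(self) -> tuple[float, float, float]:
        """(z_underweight, z_overweight, z_obese) normal quantiles of the
        configured percentiles; defaults ≈ (-2.054, 1.036, 1.645)."""
        return (
            float(norm.ppf(self.cyp_pct_underweight)),
            float(norm.ppf(self.cyp_pct_overweight)),
            float(norm.ppf(self.cyp_pct_obese)),
        )


class ConfigError(ValueError):
    """Raised when a configuration file cannot be loaded or validated."""


_DATE_FIELDS = {"study_start", "study_end"}


def load_config(path) -> StudyConfig:
    """Load a :class:`StudyConfig` from a flat key-value (YAML mapping) file.

    An empty file yields all defaults.  Unknown keys and invalid values raise
    :class:`ConfigError` naming the offending field.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must be a flat key: value mapping")
    known = set(StudyConfig.model_fields)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data = dict(raw)
    for key in _DATE_FIELDS & set(data):
        if isinstance(data[key], str):
            data[key] = dt.date.fromisoformat(data[key])
    if "linkage_status_accept" in data and isinstance(data["linkage_status_accept"], Iterable):
        data["linkage_status_accept"] = frozenset(int(x) for x in data["linkage_status_accept"])
    if "hierarchy" in data:
        data["hierarchy"] = tuple(tuple(row) for row in data["hierarchy"])
    try:
        return StudyConfig(**data)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: StudyConfig, path) -> None:
    """Write a config back to the flat key-value format (round-trippable)."""
    data = config.model_dump()
    data["study_start"] = config.study_start.isoformat()
    data["study_end"] = config.study_end.isoformat()
    data["linkage_status_accept"] = sorted(config.linkage_status_accept)
    data["hierarchy"] = [list(row) for row in config.hierarchy]
    data["adult_cut_points"] = list(config.adult_cut_points)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
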