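"""Stage 3: height–weight pairing, BMI calculation and category allocation.

Children's heights change quickly, so a CYP weight is only paired with a
height recorded within ``hw_pair_window_days`` (default 180) and the nearest
such height is used.  Adult height is carried forward: each weight takes the
most recent height on or before its date (earliest later height as a
fallback), or optionally one single most-recent height for the whole study.
Pairing is done within a source so that the derived BMI inherits that
source's hierarchy rank.

Adult BMI categories use the WHO cut-offs (<18.5 underweight, [18.5, 25)
normal, [25, 30) overweight, >=30 obese).  Paediatric categories come from
the LMS growth-reference transform z = ((x/M)^L - 1)/(L*S) evaluated at the
child's sex and age in months, thresholded at configurable percentiles
(defaults: 2nd / 85th / 95th).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .audit import AuditLog
from .cohort import age_months_vector, assign_branch, monday_anchor_vector
from .config import StudyConfig

ENTRY_COLUMNS = [
    "entry_id",
    "person_id",
    "bmi_date",
    "bmi_value",
    "category",
    "source",
    "data_type",
    "rank",
    "branch",
    "age_months",
    "age_years",
    "height_date",
    "weight_date",
    "height_record_id",
]


def compute_bmi(weight_kg, height_m):
    """BMI in kg/m²; inputs must be strictly positive."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = w / (h * h)
    return float(out) if out.ndim == 0 else out


#: below this |L| the Box–Cox power transform is numerically the log transform
_LMS_L_EPS = 1e-7


def lms_zscore(x, L, M, S):
    """LMS (Box–Cox) z-score: ((x/M)^L - 1)/(L·S), or ln(x/M)/S when L ≈ 0."""
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("x, M and S must be strictly positive")
    ratio = x / M
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.abs(L) < _LMS_L_EPS, np.log(ratio) / S, (ratio ** L - 1.0) / (L * S))
    return float(z) if z.ndim == 0 else z


class ReferenceRangeError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthReference:
    """Sex- and age-indexed L, M, S triples on a strictly increasing
    age-in-months grid; lookups interpolate linearly between knots."""

    frame: pd.DataFrame  # columns: sex, age_months, L, M, S

    def __post_init__(self):
        required = {"sex", "age_months", "L", "M", "S"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"growth reference needs columns {sorted(required)}")
        for sex, grp in self.frame.groupby("sex"):
            ages = grp["age_months"].to_numpy(dtype=float)
            if not np.all(np.diff(ages) > 0):
                raise ValueError(f"age grid for sex {sex!r} must be strictly increasing")
            if np.any(grp["M"].to_numpy() <= 0) or np.any(grp["S"].to_numpy() <= 0):
                raise ValueError("M and S must be strictly positive")

    def lookup(self, sex, age_months) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (L, M, S) at the requested sex(es) and age(s)."""
        sexes = np.atleast_1d(np.asarray(sex, dtype=object))
        ages = np.atleast_1d(np.asarray(age_months, dtype=float))
        if sexes.shape != ages.shape:
            sexes = np.broadcast_to(sexes, ages.shape).copy()
        L = np.empty_like(ages)
        M = np.empty_like(ages)
        S = np.empty_like(ages)
        for s in np.unique(sexes):
            grp = self.frame[self.frame["sex"] == s]
            if grp.empty:
                raise ReferenceRangeError(f"no growth reference for sex {s!r}")
            grid = grp["age_months"].to_numpy(dtype=float)
            mask = sexes == s
            a = ages[mask]
            if np.any(a < grid[0]) or np.any(a > grid[-1]):
                raise ReferenceRangeError(
                    f"age outside reference grid [{grid[0]}, {grid[-1]}] months for sex {s!r}"
                )
            idx = np.clip(np.searchsorted(grid, a, side="right") - 1, 0, len(grid) - 2)
            a0, a1 = grid[idx], grid[idx + 1]
            frac = (a - a0) / (a1 - a0)
            for name, out in (("L", L), ("M", M), ("S", S)):
                y = grp[name].to_numpy(dtype=float)
                out[mask] = y[idx] + frac * (y[idx + 1] - y[idx])
        scalar = np.isscalar(age_months) or np.ndim(age_months) == 0
        if scalar:
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S


def read_reference(path) -> GrowthReference:
    df = pd.read_csv(path)
    return GrowthReference(df.sort_values(["sex", "age_months"]).reset_index(drop=True))


def write_reference(ref: GrowthReference, path) -> None:
    ref.frame.to_csv(path, index=False)


def reference_lookup(ref: GrowthReference, sex, age_months):
    return ref.lookup(sex, age_months)


def categorise_adult(bmi, cut_points=(18.5, 25.0, 30.0)) -> Union[str, np.ndarray]:
    """WHO adult categories on half-open intervals: [cut0, cut1) normal,
    [cut1, cut2) overweight, >= cut2 obese."""
    b = np.atleast_1d(np.asarray(bmi, dtype=float))
    under, over, obese = cut_points
    out = np.select(
        [b < under, b < over, b < obese],
        ["underweight", "normal", "overweight"],
        default="obese",
    ).astype(object)
    return str(out[0]) if np.ndim(bmi) == 0 else out


def categorise_cyp(z, z_thresholds) -> Union[str, np.ndarray]:
    """Paediatric category from an LMS z-score and (z_under, z_over, z_obese)."""
    zz = np.atleast_1d(np.asarray(z, dtype=float))
    z_under, z_over, z_obese = z_thresholds
    out = np.select(
        [zz < z_under, zz >= z_obese, zz >= z_over],
        ["underweight", "obese", "overweight"],
        default="normal",
    ).astype(object)
    return str(out[0]) if np.ndim(z) == 0 else out


# ---------------------------------------------------------------------------
# pairing

def _sorted_heights(heights: pd.DataFrame) -> pd.DataFrame:
    return heights.sort_values(["date", "value", "record_id"], kind="mergesort")


def pair_cyp(heights: pd.DataFrame, weights: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Pair each weight with the nearest-in-time height within the window.

    Ties on the absolute date gap prefer the earlier height date, then the
    smaller height value.  Weights with no eligible height yield no row.
    Returns columns: weight_record_id, height_record_id, weight_date,
    height_date, weight_kg, height_m.
    """
    rows = []
    if heights.empty or weights.empty:
        return pd.DataFrame(
            columns=["weight_record_id", "height_record_id", "weight_date", "height_date", "weight_kg", "height_m"]
        )
    h = _sorted_heights(heights)
    hdates = pd.to_datetime(h["date"]).to_numpy()
    hvals = h["value"].to_numpy(dtype=float)
    hids = h["record_id"].to_numpy(dtype=object)
    window = np.timedelta64(config.hw_pair_window_days, "D")
    for w in weights.itertuples():
        wdate = np.datetime64(pd.Timestamp(w.date), "ns")
        gaps = np.abs(hdates - wdate)
        ok = gaps <= window
        if not ok.any():
            continue
        # argmin over (gap, date, value, id); h already sorted by date/value/id
        best = None
        for j in np.flatnonzero(ok):
            key = (gaps[j],)
            if best is None or key < best[0]:
                best = (key, j)
        j = best[1]
        rows.append(
            {
                "weight_record_id": w.record_id,
                "height_record_id": hids[j],
                "weight_date": pd.Timestamp(w.date),
                "height_date": pd.Timestamp(hdates[j]),
                "weight_kg": float(w.value),
                "height_m": float(hvals[j]),
            }
        )
    return pd.DataFrame(rows)


def pair_adult(heights: pd.DataFrame, weights: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Carry-forward pairing: most recent height on or before each weight
    date, falling back to the earliest later height.  With
    ``adult_height_mode='single'`` every weight uses the person-source's
    most recent height in the study."""
    if heights.empty or weights.empty:
        return pd.DataFrame(
            columns=["weight_record_id", "height_record_id", "weight_date", "height_date", "weight_kg", "height_m"]
        )
    h = _sorted_heights(heights)
    hdates = pd.to_datetime(h["date"]).to_numpy()
    hvals = h["value"].to_numpy(dtype=float)
    hids = h["record_id"].to_numpy(dtype=object)
    rows = []
    if config.adult_height_mode == "single":
        # most recent height overall; tie -> smaller value (stable sort order)
        last_date = hdates.max()
        j = int(np.flatnonzero(hdates == last_date)[0])
        for w in weights.itertuples():
            rows.append(
                {
                    "weight_record_id": w.record_id,
                    "height_record_id": hids[j],
                    "weight_date": pd.Timestamp(w.date),
                    "height_date": pd.Timestamp(hdates[j]),
                    "weight_kg": float(w.value),
                    "height_m": float(hvals[j]),
                }
            )
        return pd.DataFrame(rows)
    for w in weights.itertuples():
        wdate = np.datetime64(pd.Timestamp(w.date), "ns")
        onbefore = np.flatnonzero(hdates <= wdate)
        if len(onbefore):
            cand_date = hdates[onbefore].max()
            j = int(onbefore[np.flatnonzero(hdates[onbefore] == cand_date)[0]])
        else:
            j = 0  # earliest height (dates sorted ascending), smallest value on ties
        rows.append(
            {
                "weight_record_id": w.record_id,
                "height_record_id": hids[j],
                "weight_date": pd.Timestamp(w.date),
                "height_date": pd.Timestamp(hdates[j]),
                "weight_kg": float(w.value),
                "height_m": float(hvals[j]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# entry derivation

def derive_entries(
    components: pd.DataFrame,
    persons: pd.DataFrame,
    reference: GrowthReference,
    config: StudyConfig,
    audit: Optional[AuditLog] = None,
) -> pd.DataFrame:
    """Build harmonised BMI entry candidates from standardised components.

    Direct BMI values, BMI categories and obesity diagnoses become entries
    dated at their event; heights and weights are paired per person-source
    and the derived BMI is dated at the weight date.  Every candidate is
    branch-assigned by age at the BMI date; under-2 and over-100 records are
    dropped to the audit log, as are derived BMIs outside the plausible
    range and weights that could not be paired.
    """
    audit = audit if audit is not None else AuditLog()
    if components.empty:
        return pd.DataFrame(columns=ENTRY_COLUMNS)
    pers = persons.set_index("person_id")
    comp = components[components["person_id"].isin(pers.index)].copy()

    entries: list[pd.DataFrame] = []

    direct = comp[comp["component"].isin(["bmi_value", "bmi_category", "obesity_dx"])]
    if not direct.empty:
        d = direct.copy()
        d = d.rename(columns={"record_id": "entry_id", "date": "bmi_date"})
        d["bmi_value"] = np.where(d["component"] == "bmi_value", d["value"], np.nan)
        d["height_date"] = pd.NaT
        d["weight_date"] = pd.NaT
        d["height_record_id"] = None
        entries.append(d)

    hw = comp[comp["component"].isin(["height", "weight"])]
    pair_rows = []
    for (pid, source), grp in hw.groupby(["person_id", "source"], sort=True):
        heights = grp[grp["component"] == "height"]
        weights = grp[grp["component"] == "weight"].sort_values(["date", "record_id"], kind="mergesort")
        if weights.empty:
            continue
        anchor = pd.Timestamp(pers.at[pid, "week_of_birth"]) - pd.Timedelta(
            days=int(pd.Timestamp(pers.at[pid, "week_of_birth"]).weekday())
        )
        wmonths = age_months_vector(
            pd.Series([anchor] * len(weights)), pd.Series(pd.to_datetime(weights["date"]).to_numpy())
        )
        branches = np.array([assign_branch(int(m), config) for m in wmonths], dtype=object)
        for branch_name, pair_fn in (("CYP", pair_cyp), ("adult", pair_adult)):
            sel = branches == branch_name
            if not sel.any():
                continue
            paired = pair_fn(heights, weights[sel], config)
            matched_ids = set(paired["weight_record_id"]) if not paired.empty else set()
            for w in weights[sel].itertuples():
                if w.record_id not in matched_ids:
                    audit.add("derive", "unpaired_weight", pid, w.date, source, w.record_id)
            rank = int(grp["rank"].iloc[0])
            for p in paired.itertuples():
                pair_rows.append(
                    {
                        "entry_id": p.weight_record_id,
                        "person_id": pid,
                        "bmi_date": p.weight_date,
                        "bmi_value": compute_bmi(p.weight_kg, p.height_m),
                        "category": None,
                        "source": source,
                        "data_type": "height_weight",
                        "rank": rank,
                        "height_date": p.height_date,
                        "weight_date": p.weight_date,
                        "height_record_id": p.height_record_id,
                        "component": "derived_bmi",
                    }
                )
    if pair_rows:
        entries.append(pd.DataFrame(pair_rows))

    if not entries:
        return pd.DataFrame(columns=ENTRY_COLUMNS)
    ent = pd.concat(entries, ignore_index=True)

    # age and branch at the BMI date
    wob = pers.loc[ent["person_id"], "week_of_birth"].reset_index(drop=True)
    anchors = monday_anchor_vector(pd.Series(pd.to_datetime(wob.to_numpy())))
    ent["age_months"] = age_months_vector(anchors, pd.Series(pd.to_datetime(ent["bmi_date"]).to_numpy()))
    ent["age_years"] = ent["age_months"] // 12
    ent["branch"] = [assign_branch(int(m), config) for m in ent["age_months"]]

    out_of_branch = ent["branch"].isna()
    under2 = out_of_branch & (ent["age_months"] < config.cyp_age_months_min)
    for row in ent[under2].itertuples():
        audit.add("derive", "under_2", row.person_id, row.bmi_date, row.source, row.entry_id)
    for row in ent[out_of_branch & ~under2].itertuples():
        audit.add("derive", "out_of_branch", row.person_id, row.bmi_date, row.source, row.entry_id)
    ent = ent[~out_of_branch].reset_index(drop=True)

    # derived BMI plausibility (direct BMI values were filtered at Stage 1)
    derived_bad = (
        (ent["component"] == "derived_bmi")
        & ((ent["bmi_value"] < config.bmi_min) | (ent["bmi_value"] > config.bmi_max))
    )
    for row in ent[derived_bad].itertuples():
        audit.add("derive", "derived_bmi_out_of_range", row.person_id, row.bmi_date, row.source, row.entry_id)
    ent = ent[~derived_bad].reset_index(drop=True)

    # categorise value-bearing entries
    has_value = ent["bmi_value"].notna()
    adult = has_value & (ent["branch"] == "adult")
    if adult.any():
        ent.loc[adult, "category"] = categorise_adult(
            ent.loc[adult, "bmi_value"].to_numpy(), config.adult_cut_points
        )
    cyp = has_value & (ent["branch"] == "CYP")
    if cyp.any():
        sexes = pers.loc[ent.loc[cyp, "person_id"], "sex"].to_numpy(dtype=object)
        L, M, S = reference.lookup(sexes, ent.loc[cyp, "age_months"].to_numpy(dtype=float))
        z = lms_zscore(ent.loc[cyp, "bmi_value"].to_numpy(), L, M, S)
        ent.loc[cyp, "category"] = categorise_cyp(z, config.cyp_z_thresholds())

    ent = ent.drop(columns=["component", "value"], errors="ignore")
    ent = ent.sort_values(["person_id", "bmi_date", "rank", "entry_id"], kind="mergesort").reset_index(drop=True)
    return ent[ENTRY_COLUMNS]
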