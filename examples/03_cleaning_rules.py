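"""The two-stage deterministic cleaning rules, on hand-made entries.

Same-day rule: entries on one person-day are pairwise consistent only if
values differ by <5% (relative to the smaller) AND categories agree;
category-only pairs must agree exactly.  Every entry in a violating pair is
removed.  Over-time rule (adults only): an entry whose BMI change against
the last kept value exceeds 10 kg/m2 per year (30-day floor on the gap) is
removed; pregnancy-window entries are exempt.
"""

import pandas as pd

from bmirrda.config import StudyConfig
from bmirrda.harmonise import over_time_clean, same_day_clean

config = StudyConfig()


def entries(rows):
    df = pd.DataFrame(rows, columns=["entry_id", "bmi_date", "bmi_value", "category"])
    df["bmi_date"] = pd.to_datetime(df["bmi_date"])
    df["person_id"] = "P"
    df["rank"] = 1
    df["source"] = "WLGP"
    df["branch"] = "adult"
    df["pregnancy_flag"] = False
    return df


same_day = entries(
    [
        ("a", "2010-03-01", 24.0, "normal"),      # consistent pair: kept
        ("b", "2010-03-01", 24.5, "normal"),
        ("c", "2010-07-01", 24.0, "normal"),      # category disagreement: both removed
        ("d", "2010-07-01", 25.0, "overweight"),
    ]
)
kept, removed, decisions = same_day_clean(same_day, config)
print("same-day: kept", sorted(kept["entry_id"]), "removed", sorted(removed["entry_id"]))
for d in decisions:
    print("  decision:", d["rule"], "->", d["records_removed"])

over_time = entries(
    [
        ("a", "2010-01-01", 25.0, "overweight"),
        ("b", "2010-01-31", 45.0, "obese"),        # +20 kg/m2 in 30 days: implausible
        ("c", "2010-06-01", 25.8, "overweight"),   # compared against 'a', kept
    ]
)
kept, removed, decisions = over_time_clean(over_time, config)
print("over-time: kept", sorted(kept["entry_id"]), "removed", sorted(removed["entry_id"]))
print("  detail:", decisions[0]["detail"])
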