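"""Build a BMI research-ready data asset end to end.

Generates a small synthetic linked-EHR dataset (four sources plus
demographics and residency), runs the Stage 1->5 harmonisation pipeline,
and prints the resulting one-entry-per-person-per-day table together with
the exclusion flow and record accounting.
"""

import datetime as dt

from bmirrda.harmonise import build_rrda
from bmirrda.synth import ScenarioConfig, generate

scenario = ScenarioConfig(
    n_persons=150, seed=42, study_start=dt.date(2000, 1, 1), study_end=dt.date(2009, 12, 31)
)
ds = generate(scenario, with_expected=False)
result = build_rrda(ds.tables, ds.codelists, ds.reference, ds.config)

print("Exclusion flow (persons with >=1 BMI component):")
print(result.exclusion_flow.to_frame().to_string(index=False))

print("\nFirst RRDA entries (one per person-day, lowest-rank source wins):")
cols = ["person_id", "bmi_date", "bmi_value", "category", "source", "rank", "branch", "pregnancy_flag"]
print(result.rrda[cols].head(8).to_string(index=False))

print("\nRecord accounting (every entry candidate ends up exactly once):")
for k, v in result.accounting.items():
    print(f"  {k:>22}: {v}")
# 'entries' always equals removed_same_day + removed_over_time +
# deduplicated_same_day + rrda: nothing is silently dropped.
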