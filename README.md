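# bmirrda

Build a longitudinal **BMI research-ready data asset (RRDA)** from linked
electronic health records.

BMI is recorded opportunistically in routine care, split across sources that
capture different *components* — direct BMI values and categories in primary
care, obesity diagnoses in hospital episodes, heights and weights in
maternity and child-measurement programmes — with heterogeneous units,
implausible values and mutually contradictory same-day entries. `bmirrda`
implements a reproducible five-stage methodology that turns those raw coded
events into one harmonised BMI entry per person per day, and quantifies how
complete the resulting asset is:

1. **Extract & collate** — match Read v2 / ICD-10 coded events against user
   supplied code lists, standardise heights and weights to SI units, remove
   extreme values (BMI below 12 or over 100 kg/m²), collapse exact
   duplicates, and rank every record by a source hierarchy
   (primary-care BMI value = 1 … hospital obesity code = 6).
2. **Cohort** — demographic exclusions (linkage quality, missing week of
   birth, invalid sex, death within 31 days of study start) and per-person
   contribution windows censored by death, out-migration and — for the
   child branch — the 19th birthday.
3. **Derive** — pair weights with heights (children: nearest height within
   180 days; adults: carry the most recent height forward), compute
   BMI = weight/height², and allocate categories: adults by the WHO
   cut-offs (<18.5 / 25 / 30), children (2–18 y) by LMS growth-reference
   z-scores, z = ((x/M)^L − 1)/(L·S), at the 2nd/85th/95th percentiles.
4. **Clean** — deterministic two-stage cleaning: same-day entries must agree
   in category and (when value-bearing) differ by <5%; adult entries whose
   change over time is implausibly fast are removed, with pregnancy-window
   exemptions.
5. **Resolve** — keep the lowest-rank (most trusted) entry per person-day
   and flag records within ±294 days of a recorded birth.

The `metrics` module reports annual coverage, 1-year / 5-year / full-study
preservation windows, repeat-measurement counts and source-overlap (upset
plot) numbers. The `synth` module generates fully-labelled synthetic linked
EHR inputs — including injected unit errors, outliers and inconsistencies —
and contains an independent, deliberately naive reference implementation of
the whole methodology used for differential testing: the pipeline must
reproduce its output record for record.

## Worked example

```python
from bmirrda.config import StudyConfig
from bmirrda.derive import categorise_cyp, lms_zscore, reference_lookup
from bmirrda.synth import generate_reference

config = StudyConfig()
reference = generate_reference()   # synthetic L,M,S curves for both sexes

for age_months in (36, 132, 225):
    L, M, S = reference_lookup(reference, "F", age_months)
    z = lms_zscore(21.0, L, M, S)
    print(age_months, round(z, 2), categorise_cyp(z, config.cyp_z_thresholds()))
```

prints

```
36 2.5 obese
132 1.27 overweight
225 -0.05 normal
```

— the same BMI of 21 kg/m² is far above the median for a 3-year-old girl
(obese), but essentially median for an 18-year-old (normal weight): this is
why the paediatric branch cannot use fixed cut-offs.

Running the full pipeline on a generated dataset
(`python examples/01_build_rrda.py`) prints the exclusion flow, the first
RRDA rows and the record accounting, e.g.

```
entries: 595  removed_same_day: 52  removed_over_time: 3
deduplicated_same_day: 9  rrda: 531
```

where every entry candidate is accounted for exactly once — nothing is
silently dropped. See `examples/` for cleaning-rule and coverage-metric
walk-throughs, and the `bmirrda` CLI (`simulate`, `run`, `metrics`) to drive
the same steps from a shell against delimited input files.

## Layout

- `src/bmirrda/` — `config`, `codelists`, `io`, `extract`, `cohort`,
  `derive`, `harmonise`, `metrics`, `synth` (generator + naive oracle),
  `cli`.
- `examples/` — short narrative scripts, one per capability.
- `tests/` — unit, property (hypothesis) and acceptance suites.
- `docs/methods.md` — the modelling and design notes.
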