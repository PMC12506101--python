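# Methods

This note records the model, the parameters that matter, the design choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## The harmonisation model

The asset is built from four linked sources that capture BMI *components*
rather than BMI itself: primary-care events coded in Read v2 (direct BMI
values, heights, weights, BMI categories), hospital episodes coded in
ICD-10 (obesity diagnoses only — hospitals record the diagnosis, not the
measurement), maternity records and child-measurement records (heights and
weights). Each (source, data-type) pair carries a trust rank:

| source | data type | rank |
|---|---|---|
| primary care (WLGP) | BMI value | 1 |
| primary care (WLGP) | height & weight | 2 |
| maternity (MIDS) | height & weight | 3 |
| child measurement (NCCH) | height & weight | 4 |
| primary care (WLGP) | BMI category | 5 |
| hospital (PEDW) | obese diagnosis | 6 |

Lower rank = more trusted; the daily resolution step keeps the lowest-rank
consistent entry. Height–weight pairing is done **within a source**, so
that the derived BMI's rank is well defined.

### Ages

Birth dates arrive at week granularity (anonymisation). All ages are
computed from the **Monday** of the recorded week, using calendar-month
arithmetic with end-of-month clamping, so ages are deterministic integers.
A record belongs to the CYP (children and young people) branch when the
person is 24 completed months up to the day before the 19th birthday, and
to the adult branch from the 19th birthday to age 100 inclusive. The
nominal CYP upper bound of 228 months *is* the 19th birthday; treating 228
months as adult is the only reading consistent with "the 19th birthday ends
the CYP contribution" and with the requirement that no record can belong to
both branches on the same day. Under-2 records are excluded (BMI
categorisation is not routine at those ages).

### Pairing and categorisation

* CYP: each weight takes the nearest-dated height within
  `hw_pair_window_days` (default 180 d — children grow too fast for longer
  carry-forward); ties prefer the earlier height. The BMI date is the
  weight date (weight varies faster than height).
* Adults: each weight takes the most recent height on or before its date,
  falling back to the earliest later height. A config switch
  (`adult_height_mode="single"`) instead uses one study-wide most recent
  height per person-source; the per-weight carry-forward is the default
  because height loss with ageing makes a single terminal height worse for
  early-study weights. Height loss itself is *not* modelled — a known
  limitation of any carry-forward scheme on long intervals.
* Adult categories: half-open WHO intervals [18.5, 25) normal, [25, 30)
  overweight, ≥30 obese. Published one-decimal ranges like "25–29.9" are
  summaries of the same convention; BMI exactly 30 is obese.
* CYP categories: LMS transform z = ((x/M)^L − 1)/(L·S) (log form when
  |L| < 1e−7, where the power transform is numerically the log transform)
  against a sex/age-indexed L,M,S table, linearly interpolated in age.
  Threshold percentiles default to 2nd/85th/95th and are configurable
  because jurisdictions differ (e.g. 91st/98th clinical cut-offs in the
  UK); their z-equivalents are computed, not hard-coded. The growth
  reference is **user-supplied data**; the packaged one
  (`synth.generate_reference`) is synthetic, for tests and examples only.

### Cleaning

Both cleaning rules are deterministic; every removal is logged with a
reason, and kept + removed always partitions the input.

*Same day.* Entries sharing a person and date are compared pairwise.
Value-bearing pairs are consistent only if the relative difference —
denominator the **smaller** value, the symmetric-conservative choice — is
below `same_day_rel_diff` (5%) *and* the categories agree. Pairs involving
a category-only entry are consistent only if categories agree; a
two-category disagreement cannot be more trustworthy than a one-category
one, so any disagreement is removed. Every entry in a violating pair is
removed (the rule cannot know which side is wrong).

*Over time* (adult branch only — children's BMI legitimately changes fast,
so only same-day cleaning applies to them). Scanning chronologically, a
value-bearing entry is removed when |ΔBMI| against the last kept
value-bearing entry on an earlier date exceeds
`overtime_max_annual_delta` × max(Δdays, `overtime_min_gap_days`)/365,
defaults 10 kg/m²/year with a 30-day floor. The floor makes same-week jumps
detectable without flagging ordinary measurement noise on adjacent-day
records. Entries within ±294 days of a recorded birth are exempt and never
serve as the comparison baseline (pregnancy weight change is real, not an
error). The constants are configuration, not claims about any particular
deployment: the rule is deliberately swappable.

### Resolution

Per person-day the minimum-rank survivor is kept; ties break by ascending
BMI value (missing values last), then source name, then record identifier,
so runs are bit-reproducible. The output schema includes provenance
(source, data type, rank, height/weight dates), the encoded category
(underweight=1 … obese=4), the pregnancy flag, and an `in_window` flag
marking entries inside the person's residency-based contribution window
(entries outside — e.g. in residency gaps — are retained but flagged, and
excluded from metric denominators).

## Metrics conventions

* Annual coverage: the year-Y, branch-B denominator is everyone whose
  contribution window intersects year Y *while aged within B* at some point
  of the intersection; the numerator keeps each person's most recent entry
  of the year.
* Preservation: denominator is the branch population at the anchor (study
  end) — window contains the anchor while branch-aged; a person is covered
  by a look-back window if they have ≥1 branch entry inside it. Coverage is
  monotone in the window by construction.
* "Population at a date" is operationalised from contribution windows;
  no external census or GP-registration denominators are used (a
  deployment with registration data could substitute its own denominator).

## Configuration

All constants live in `StudyConfig` (validated, frozen): study dates
(2000-01-01 to 2022-12-31), BMI bounds 12/100 kg/m², height 0.5–2.5 m and
weight 5–350 kg plausibility bounds (the height/weight bounds are not
standardised anywhere; they are deliberately configurable and logged — the
weight range is the union of child and adult plausibility since Stage 1
runs before branch assignment), 180-day pairing window, 5% same-day
tolerance, ±294-day pregnancy window, 31-day minimum survival, branch age
bounds, adult cut-offs, CYP percentiles, the hierarchy table, the
over-time rule constants, and the accepted linkage-status codes {1, 4, 39}.

## Synthetic data: what it shows and what it does not

The generator emulates the *structure* of the real sources: persons born
throughout and before the study, deaths, migrations, late entries, missing
weeks of birth, invalid sex codes and unreliable linkage; child
trajectories that follow the synthetic growth reference with a stable
person-level z; adult trajectories with a random-walk annual drift;
same-day duplicates across sources (identical measurements recorded twice);
unit heterogeneity (m/cm/unit-less heights, kg weights) with injected
cm-as-m and lb-as-kg errors; implausible outliers; same-day conflicts
(≥5% value disagreements and category-only disagreements) at a configurable
share of person-days; over-time jumps; pregnancies with elevated BMI around
recorded births. Every record carries exactly one intent label. Injected
cleaning-stage errors are only given to cohort-eligible persons, so the
labels mean "reaches the cleaning stage and must be removed there"; an
lb-as-kg error can yield a physiologically plausible value that correctly
survives, so unit-error labels mark injection, not guaranteed removal.

The expected output is **not** derived from the labels but computed by an
independent naive implementation of the same rules
(`bmirrda.synth.naive`) — plain nested loops, its own date and
interpolation arithmetic, `statistics.NormalDist` instead of scipy — and
the differential tests require the pipeline to match it record for record
across many random scenarios. This demonstrates that the production code
implements the stated rules exactly. It does *not* demonstrate that the
rules are clinically optimal, nor that real EHR data (free-text artefacts,
coding-practice drift, linkage error structure, realistic demographic
margins) would behave like the generator: realism here is structural, not
statistical, and headline coverage percentages from synthetic runs are
properties of the chosen recording rates, not estimates of any real
population.

Problem sizes: the differential suite uses 200-person, 10-year scenarios
(about 1 000–1 500 events each) over 100+ seeds, and study-scale metric
runs use 500 persons over the full 23 years — small enough to iterate
quickly, large enough that every rule fires many times per scenario.

## Numerical notes

* Same-day and over-time comparisons use exact IEEE arithmetic on the
  stated expressions; both implementations share the expressions, so
  differential agreement is bit-exact rather than tolerance-based.
* LMS interpolation is piecewise-linear with exact values at knots;
  out-of-grid ages are errors, not extrapolations.
* The z thresholds are normal quantiles computed at run time (scipy in the
  pipeline, `statistics.NormalDist` in the oracle); they agree to ~1e−15,
  and a category flip would require a z exactly at a threshold.
* Unit heuristic: a unit-less height above 3 is read as centimetres — no
  human height is ambiguous around 3 m. Unit-less weights pass through
  as kg.
* Empty inputs, persons with no residency rows (treated as resident for
  the whole study, matching the missing-date imputation rule), weights with
  no pairable height, and empty cleaning groups are all defined, tested
  cases, not errors.

## Known limitations

* The over-time rule is a declared stand-in with configurable constants,
  not a validated clinical algorithm; growthcleanr-style longitudinal
  cleaning or averaging of same-day values are deliberate non-goals.
* No imputation of missing BMI; missingness is measured, not filled.
* Eating-disorder diagnoses are not used as category evidence (no defined
  category mapping), only obesity codes.
* The shipped Read v2 / ICD-10 code list is illustrative; real extractions
  must supply their governance-approved lists.
* Residency gaps: person-time is the union of clipped episodes; records in
  gaps are kept but flagged, a convention rather than a modelled choice.
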