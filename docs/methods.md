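# Methods

## Label knowledge base

Each of the 24 respiratory compounds carries, per ATC code and label
snapshot year (2004 and 2008), a minimum approved age in completed years
(`0` = no restriction) and a set of approved indications expressed as
ICD-10-GM **prefixes**. Prefix semantics were chosen over exact code lists
because regulatory labels state indications at the level of disease
concepts ("asthma", "COPD"), which correspond to ICD-10 blocks whose
terminal codes vary at the digit level; `J45` covers every `J45.x`.

The concept → prefix mapping is a knowledge-base asset (editable CSV), not
code: asthma → {J45, J46}; COPD / chronic obstructive bronchitis → {J44};
pulmonary emphysema → {J43}; chronic bronchitis → {J41, J42}; acute
bronchitis → {J20}; obstructive respiratory diseases → {J43–J46};
"respiratory diseases requiring inhaled corticosteroids" → {J41–J46}.
Regulatory labels use general prose here and any such mapping carries
uncertainty; this one is surfaced in configuration precisely so it can be
substituted.

When several label versions exist for one ATC code (years, devices,
products), the **effective label** takes the minimum age restriction and
the union of indication sets — the permissive convention appropriate when
the prescription record cannot identify which product variant was
dispensed. Resolution is idempotent and monotone: adding a record can only
lower the age bar and widen the indications.

## Classification rules

Per prescription, with the child's completed age at the dispense date and
the set of diagnoses linked from the same billing quarter (configurable to
same calendar year):

* `age_ok` — age ≥ label minimum age (boundary inclusive);
* `ind_ok` — **any** linked diagnosis matches an approved prefix.

Any-match is the standard drug-utilisation convention and the permissive
counterpart of the widest-indication label resolution: a prescription is
off-label by indication only when *every* linked diagnosis is
non-approved. The four combinations give on-label and the three off-label
types. A prescription with no linked diagnosis is INDETERMINATE under the
default policy and reported as its own column; policies `on_label` and
`off_label_indication` force `ind_ok` for sensitivity analyses, since how a
given study treated such prescriptions is generally not recoverable from
published tables.

Ages are computed two ways, both deliberate: **dispense-date age** for
label checks (event-accurate) and **December-31 age** for prevalence strata
(matching the year-end population denominator). A child dispensed at 18 who
turns 19 before December 31 is excluded from that year's PPR numerator —
they are not in the ≤18 year-end denominator population — which keeps
stratified numerators summing exactly to the unstratified numerator.

## Period prevalence

`PPR = scale × n_users / (population × coverage_fraction)` with
`n_users` the count of *distinct* children with ≥1 prescription of the
drug in the year (duplicating prescriptions cannot change it), `scale`
10,000 by default, and `coverage_fraction` 0.85 by default (the statutory
health-insurance share of the child population; the same factor is applied
uniformly across age and gender strata). Drugs enter the analysis when
their unstratified PPR in the inclusion year reaches 0.1 per 10,000,
boundary inclusive. Trends are reported as absolute change, percentage
change and fold change; relative measures are n.a. on a zero baseline.

## Synthetic claims generator

The generator emulates the structure of a statutory-insurance paediatric
claims database: children 0–18, quarterly diagnosis coding, per-drug
prescription streams. Per patient-year and drug, prescription counts are
Poisson with the drug's annual rate; each prescription draws one diagnosis
from the drug's mixture (or none, with the missing-diagnosis probability),
placed in the dispense quarter, with an optional independent co-diagnosis
draw to exercise multiple counting. The fired component is stored in a
sidecar truth table. Cohort ages are anchored at December 31 of the last
simulated year, so younger children are born mid-study (a dynamic cohort)
and no simulated child ever exceeds the paediatric age limit. The emitted
population table is the realised year-end head count divided by the
coverage fraction and rounded, making prevalence denominators internally
consistent with the cohort.

Determinism: one master seed; the population stream and each drug stream
use fixed offsets from it, so outputs are byte-identical across runs and
platforms for a fixed scenario.

The default scenario ships four drugs spanning the rule space — an
unrestricted broad-indication inhaled SABA at 0.30 prescriptions per
child-year, an age-restricted (≥4) SABA at 0.02, an adults-only
narrow-indication LAMA at 0.001, and an oral fixed combination at 0.25 with
a 10% co-diagnosis rate — with diagnosis mixtures spanning approved and
non-approved codes and 10–20% missing diagnoses. These rates are in the
range typical of the most- and least-prescribed respiratory compounds in
paediatric cohorts; absolute calibration to any particular region is out of
scope since the underlying counts are not published.

What the generator does **not** emulate: seasonality, comorbidity
correlation, prescriber clustering, or repeat-prescription dependence
within patients beyond the Poisson law. Passing tests therefore demonstrate
the correctness of the classification and aggregation arithmetic under
known ground truth, not the realism of any particular prevalence figure.

### A quantified artefact of quarter-level linkage

Because diagnoses are linked by billing quarter, a prescription can pick up
an approved diagnosis generated by *another* prescription of the same
patient in the same quarter and flip from off-label to on-label under the
any-match rule. In the parameter-recovery setting (single drug, rate 0.05
per child-year, one year, ~50,000 prescriptions) this affects ≈0.25% of
prescriptions, biasing the recovered off-label proportion downward by about
0.25 percentage points relative to the generator's truth table. This is a
real property of quarter-granular claims data, not an implementation error;
the acceptance script reports both the deviation from the nominal mixture
probability and the deviation from the realised truth share so the two
effects (binomial sampling noise vs linkage contamination) are separable.

## Numerical and reporting choices

* Percentages are computed at full precision and displayed at one decimal,
  rounded half away from zero, matching utilisation-table conventions.
* The indication breakdown uses multiple counting — each off-label
  diagnosis on a prescription increments its category — so category
  percentages can sum above 100%. Prescriptions without any linked
  diagnosis are excluded from the breakdown denominator. Reporting defaults:
  top 3 categories, compounds with ≥5,000 prescriptions (CLI `report`).
* The diagnosis-category grouper is ordered with first-match-wins
  semantics; specific blocks (J00–J06, J20, J30–J39, J40, J21–J22,
  J43–J44) precede a `J` catch-all ("Other respiratory diseases") and a
  non-respiratory fallback.
* Degenerate inputs: empty prescription tables produce valid empty outputs;
  an empty label KB, mixed-ATC resolution, orphan events, duplicate
  identifiers and missing population strata raise named validation errors.
* Problem sizes in the test suite: the shared simulated cohort uses 1,500
  patients; the oracle-equivalence check runs 100 random datasets of up to
  1,000 prescriptions against an independent per-prescription
  re-evaluation; parameter recovery uses a one-million-child, one-year,
  low-rate scenario yielding ~50,000 prescriptions.

## Known limitations

* Off-label assessment is compound-level, not device-level; with the
  lowest-age/widest-indication resolution this understates off-label use
  for compounds whose devices differ in label.
* The indication mapping from label prose to ICD prefixes is an explicit,
  configurable choice; alternative mappings change indication-related
  off-label counts.
* How diagnoses should be temporally joined to prescriptions in quarterly
  claims is not uniquely defined; both windows are implemented
  (`same_quarter` default, `same_year` always a superset) and the choice is
  recorded in every output manifest.
* No inferential statistics are computed; the analysis is descriptive, and
  all reported uncertainties in tests are simple binomial standard errors.
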