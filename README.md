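# pedrx

Drug-utilisation and off-label analysis of paediatric respiratory
prescriptions in claims-style data.

## The problem

Respiratory drugs (inhaled and oral beta-2-agonists, muscarinic
antagonists, inhaled corticosteroids, leukotriene antagonists, cromoglicic
acid, theophylline) are widely prescribed to children, yet many of these
compounds are only approved for asthma or COPD and only from a minimum age
onwards. Claims databases record every filled prescription (ATC-coded) and
every quarterly ambulatory diagnosis (ICD-10-GM-coded), which makes two
quantities measurable at population scale:

* the **annual period prevalence rate (PPR)** of each drug — distinct
  children with at least one prescription during the year, divided by the
  year-end child population corrected for the insured share, per 10,000
  children:

  `PPR = 10,000 × n_users / (population × 0.85)`

* the **off-label proportion** of prescriptions, split into three types:
  *age* (child younger than the approved minimum), *indication* (no
  approved diagnosis documented in the linkage window), and
  *age&indication* (both).

`pedrx` implements this analysis as a tested, reusable pipeline for
pharmacoepidemiologists and health-services researchers: a drug-label
knowledge base covering 24 respiratory compounds (lowest approved age and
widest approved ICD-10 indication set per ATC code), a five-way
per-prescription classifier (on-label, the three off-label types, and
indeterminate when no diagnosis is linked), period-prevalence machinery with
stratification by one-year age group and gender, trend measures, and a
synthetic claims generator with ground truth so every stage is testable
without access to a real (confidential) claims database.

## Worked example

```python
import pedrx
from pedrx.classify import summarize_offlabel, round_half_up

scenario = pedrx.default_scenario(n_patients=2000, seed=1)
ds, population, truth = pedrx.generate_dataset(scenario)

cfg = pedrx.AnalysisConfig()            # coverage 0.85, per-10,000 scale
labels = pedrx.build_effective_labels(pedrx.default_label_kb())
classified = pedrx.classify_claims(pedrx.filter_study_population(ds, cfg), labels, cfg)

summary = summarize_offlabel(classified, "compound")
summary["pct_offlabel"] = summary["pct_offlabel"].map(round_half_up)
print(summary.to_string(index=False))
```

```
  group  n_all  n_offlabel_overall  pct_offlabel  n_age_only  n_indication_only  n_age_and_indication  n_indeterminate
R03AC02   2696                1046          38.8           0               1046                     0              222
R03AC04    194                  75          38.7          42                 22                    11               12
R03BB04      9                   9         100.0           4                  0                     5                0
R03CC63   2239                 870          38.9           0                870                     0              389
  TOTAL   5138                2000          38.9          46               1938                    16              623
```

Reading the table: of 2,696 simulated prescriptions of inhaled salbutamol
(R03AC02, no age restriction, broad obstructive-airway indications), 1,046
(38.8%) were off-label — all due to indication, because the simulated
diagnosis mixture sends a quarter of prescriptions out with acute
bronchitis or upper-respiratory-infection codes that the label does not
cover. Tiotropium (R03BB04, approved ≥18 years for COPD only) is almost
always off-label in a paediatric cohort. The 222 indeterminate
prescriptions had no diagnosis documented in the dispense quarter. On every
row `n_offlabel_overall = n_age_only + n_indication_only +
n_age_and_indication` exactly.

Period prevalence for the same cohort:

```python
ppr = pedrx.period_prevalence(ds, population, "R03AC02", 2008, (), cfg)
```

```
atc_code  year age_years gender  n_users  population  corrected_denominator         ppr
 R03AC02  2008       ALL    ALL      506        2352                 1999.2 2531.012405
```

506 distinct children (of a notional population of 2,352, corrected by the
0.85 insured share) received at least one salbutamol prescription in 2008 —
a PPR of 2,531 per 10,000. Pass `("age", "gender")` as strata for the
one-year-age × gender table; stratified numerators always sum to the
unstratified numerator.

The same pipeline is available from the shell:

```bash
pedrx run --out-dir out/demo --seed 1        # generate → classify → prevalence → report
pedrx checks                                  # verify the reported-count arithmetic
```

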