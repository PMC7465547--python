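# crctriage

Rule-based referral triage for patients with suspected colorectal cancer
(CRC), plus the statistical machinery to evaluate the triage rules on
retrospective cohorts of confirmed-CRC patients.

## The problem

Patients who present to primary care with rectal bleeding may harbour an
underlying colorectal cancer, and delayed referral for colonoscopy delays
diagnosis. A pragmatic answer is a checklist classifier: a small set of
evidence-based clinical criteria — each selected because its median
positive predictive value (PPV) for CRC across the source studies was at
least 10% — mapped deterministically to a referral urgency. `crctriage`
implements such a classifier and everything needed to evaluate it:

| Priority | Criteria | Recommended action |
|---|---|---|
| **Immediate** | palpable rectal mass suspicious for CRC; abnormal abdominal imaging suspicious for CRC | referral ≤ 24 h, endoscopy ≤ 2 weeks |
| **Urgent** | unexplained rectal bleeding with ≥ 1 of: dark blood, blood mixed with stool, no perianal symptoms, change in bowel habits, weight loss; or unexplained iron-deficiency anemia with Hb ≤ 110 g/L (male) / ≤ 100 g/L (nonmenstruating female) | consultation ≤ 4 weeks, endoscopy ≤ 8 weeks |
| **Possible priority** | isolated bleeding (perianal symptoms present, nothing else); or any sub-threshold sign with a risk modifier (age > 59, male sex, first-degree relative with CRC) | clinician's discretion |
| **No action** | none of the above | — |

Tiers apply with strict precedence (immediate > urgent > possible
priority > no action). Clinical findings are *tri-state* — present,
absent, or unknown — because chart review often cannot distinguish "not
present" from "not recorded". A `MissingDataPolicy` resolves unknowns
before triage: the **base** policy reads an unrecorded perianal-symptom
field as absent; the **conservative** policy reads it as present, which
demotes bleeding-only patients and drives the missing-data sensitivity
analysis.

For evaluation on a cohort of histologically confirmed CRC cases, an
immediate or urgent recommendation is a positive test result, so the one
estimable characteristic is sensitivity,

&nbsp;&nbsp;&nbsp;&nbsp;sens = (# immediate or urgent) / (# confirmed CRC),

reported with a binomial 95% confidence interval — the Wilson score
interval by default, the exact Clopper–Pearson interval on request — and
judged against a pre-specified 90% adequacy threshold. Unweighted Cohen's
kappa is provided for rater-agreement checks. Specificity, NPV and PPV of
the instrument are deliberately out of scope: a single-gate cohort of
confirmed cases cannot yield them.

The package also ships a deterministic **validation fixture**: a
281-record confirmed-CRC cohort of rectal-bleeding presenters
reconstructed from published per-priority criterion marginals (69
immediate / 211 urgent / 1 possible priority / 0 no action; 158 male;
23 urgent charts with unrecorded perianal symptoms), and a seeded random
cohort generator for property testing.

## Worked example

Build the validation cohort and evaluate it under both policies:

```sh
crctriage fixture cohort.csv
crctriage evaluate cohort.csv
```

```
Cohort evaluation (n=281, policy=base, CI method=wilson)
  Priority counts:
    IMMEDIATE            69  (24.6%)
    URGENT              211  (75.1%)
    POSSIBLE_PRIORITY     1  (0.4%)
    NO_ACTION             0  (0.0%)
  Sensitivity: 99.6% (95% CI 98.0 to 99.9%)
  Verdict: meets the pre-specified 90.0% sensitivity threshold
```

280 of 281 confirmed cancers receive a positive (immediate or urgent)
recommendation: sensitivity 99.6%, Wilson 95% CI 98.0–99.9%. Under the
conservative policy (`--policy conservative`) the 23 patients whose only
urgent qualifier was bleeding-without-perianal-symptoms — with that field
unrecorded — are demoted to possible priority, and sensitivity drops to
91.5%, still above the 90% threshold:

```
Cohort evaluation (n=281, policy=conservative, CI method=wilson)
  Priority counts:
    IMMEDIATE            69  (24.6%)
    URGENT              188  (66.9%)
    POSSIBLE_PRIORITY    24  (8.5%)
    NO_ACTION             0  (0.0%)
  Sensitivity: 91.5% (95% CI 87.6 to 94.2%)
  Verdict: meets the pre-specified 90.0% sensitivity threshold
  Demotions vs base policy: 23 (P258, P259, ..., P280)
```

The same pipeline from Python, for a single patient:

```python
from crctriage import (PatientRecord, Sex, TriState, MissingDataPolicy,
                       triage, render_report)

rec = PatientRecord(id="A017", age=66, sex=Sex.MALE, hemoglobin=104.0,
                    ida=TriState.PRESENT, rectal_bleeding=TriState.PRESENT,
                    perianal_symptoms=TriState.UNKNOWN,
                    bowel_habit_change=TriState.PRESENT)
print(render_report(triage(rec, MissingDataPolicy.BASE), "text"))
```

```
Patient A017
  Referral priority : URGENT
  Action            : expected consultation within 4 weeks; expected endoscopy within 8 weeks
  Missing-data mode : base
  Satisfied criteria: bleeding_without_perianal, bleeding_with_habit_change, ida_with_low_hb
```

This 66-year-old man qualifies for urgent referral three ways: bleeding
with no (recorded) perianal symptoms, bleeding with a change in bowel
habits, and iron-deficiency anemia at Hb 104 ≤ 110 g/L.

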