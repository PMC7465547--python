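# Methods

## Decision model

The classifier is a total, deterministic function from a patient record
to one of four referral urgencies, applied with strict precedence
IMMEDIATE > URGENT > POSSIBLE_PRIORITY > NO_ACTION. The criteria and
their thresholds live in `crctriage.rules`; every numeric constant is
collected in `RuleConstants` and overridable:

| Constant | Default | Meaning |
|---|---|---|
| `hb_threshold_male` | 110 g/L | anemia route qualifies at Hb ≤ threshold (inclusive) |
| `hb_threshold_nonmenstruating_female` | 100 g/L | as above, nonmenstruating women only |
| `modifier_age_cutoff` | 59 y | age modifier fires strictly above the cutoff |

Conventions where the criterion set leaves room:

* **Tri-state resolution.** Unknown findings resolve to absent under both
  missing-data policies, with the single exception of perianal symptoms,
  which resolve to present under the CONSERVATIVE policy. That exception
  is the entire mechanism of the missing-data sensitivity analysis; no
  other finding was inconsistently recorded in the motivating cohort, so
  no other finding is policy-dependent.
* **Anemia on incomplete data.** Unknown sex, unknown hemoglobin, or (for
  women) unknown menstrual status all fail the anemia criterion. The
  engine never triages on an imputed laboratory value; a woman of unknown
  menstrual status is treated as menstruating, symmetric with the
  conservative perianal default.
* **Possible-priority tier.** The source criteria attach risk modifiers
  (age > 59, male, family history) to "any of the above signs or
  symptoms", which would already trigger a higher tier; read literally the
  tier would be unreachable. It is operationalized as two bases evaluated
  only when the higher tiers are empty: (a) *isolated bleeding* — rectal
  bleeding present but blocked from the urgent tier by present perianal
  symptoms; (b) *modifier basis* — any sub-threshold CRC sign plus a
  modifier. Perianal symptoms do not count as a sign for (b): they argue
  for a benign anorectal source.
* **Monotonicity.** Adding any CRC sign to a record never lowers its
  priority; this is asserted by exhaustive enumeration. Perianal symptoms
  are deliberately *anti*-monotone — their presence explains bleeding away
  — so they are excluded from that property.
* **Post-test probability.** The tool's registry of per-criterion median
  PPVs is user-supplied. No combination formula for multiple positive
  criteria is published, so the default aggregator is the maximum of the
  satisfied criteria's PPVs — the weakest defensible choice, since any
  single satisfied criterion already establishes its own PPV as a lower
  bound while the criteria's joint behaviour is unknown. With no satisfied
  criterion the registry's pre-test probability is returned. A criterion
  missing from the registry raises, never silently contributes zero.

## Evaluation statistics

A triage run over a confirmed-CRC cohort binarizes priorities (immediate/
urgent positive, possible-priority/no-action negative) and reports
sensitivity with a binomial confidence interval.

* **Interval method.** Wilson score by default. The method behind the
  published interval for 280/281 is unstated, but Wilson reproduces both
  printed bounds (98.0–99.9%) at one decimal, whereas Clopper–Pearson's
  upper bound rounds to 100.0%; Clopper–Pearson (exact beta-quantile) is
  retained as an option. For the conservative re-analysis (257/281)
  neither method reproduces the published 87.4–94.3% at one decimal
  (Wilson: 87.6–94.2; Clopper–Pearson: 87.6–94.5), consistent with the
  authors having used some continuity-corrected variant; that interval is
  therefore not a validation target.
* **Interval conventions.** Wilson bounds are exactly 0 at x = 0 and
  exactly 1 at x = n (the closed form's value there, computed without
  floating-point drift). Clopper–Pearson uses the standard one-sided
  collapse at the boundaries (low = 0 at x = 0, high = 1 at x = n). On
  interior counts the exact interval is never narrower than the score
  interval — asserted over a grid — but at the boundaries its one-sided
  form can undercut Wilson's width slightly; the tests encode exactly
  this.
* **Percentages** render as ×100 with round-half-up to one decimal
  (`decimal.ROUND_HALF_UP`), matching clinical-report style; Python's
  banker's rounding would print some values differently.
* **Cohen's kappa** is unweighted (priorities are nominal labels for
  agreement purposes). The degenerate case of two identical constant
  rating vectors (observed = expected agreement = 1) is defined as 1.0.
  The implementation is the direct confusion-count formula,
  cross-checked against scikit-learn in the tests.
* **Threshold verdict.** Reports compare sensitivity against a
  pre-specified adequacy threshold, default 0.90.

## The validation fixture

`build_validation_fixture` reconstructs a 281-record cohort whose
per-priority-group criterion tallies match the published marginal table.
Only marginals are published — the joint distribution of findings within
a group is unknowable — so the builder fixes one canonical cohort among
the many consistent with the constraints:

* Every record has rectal bleeding present (the cohort inclusion
  criterion) and confirmed CRC. The first 158 records are male.
* **Immediate group (69).** Each criterion occupies a lowest-index
  contiguous block (mass: records 1–54; IDA: 1–8; …), except abnormal
  imaging, which occupies the *highest* 19 indices so that mass and
  imaging overlap by exactly 54 + 19 − 69 = 4 records while covering the
  whole group — the overlap is an arithmetic consequence of the
  marginals, the placement a documented canonical choice.
* **Urgent group (211).** The 13 records with perianal symptoms present
  come first and are covered by the bowel-habit-change block (128), which
  starts there; the 175 with perianal symptoms absent follow; the last 23
  have perianal symptoms *unknown* and carry no other urgent qualifier.
  Under the base policy those 23 qualify through
  bleeding-without-perianal; under the conservative policy they demote to
  possible priority — reproducing the published demotion count exactly,
  which also encodes the published implication that none of the 23 held a
  second urgent qualifier.
* **Possible-priority group (1).** Bleeding with perianal symptoms
  present and nothing else, age 45, female, no family history — no urgent
  qualifier and no modifier.
* IDA-flagged records get Hb 95 g/L (below both sex thresholds), all
  others 123 g/L (the cohort mean to the nearest integer). Ages cycle
  through 61/67/73 (mean 67) purely for realism; neither age nor Hb of
  non-IDA records affects any fixture triage outcome.

`verify_marginals` re-triages any cohort and reports every cell that
deviates from the spec; the fixture yields an empty report, and the
infeasibility checks reject specs whose marginals cannot cover their
groups (with the violated constraint named).

## The random cohort generator

`generate_random_cohort` draws independent records for property tests:
findings are Bernoulli at configurable prevalences (defaults equal the
validation cohort's marginal frequencies), perianal symptoms are masked
to unknown at rate 23/281, demographics are normal draws matching the
cohort summary statistics (age 67 ± 13.4 y clipped to [18, 120];
Hb 123.3 ± 22.3 g/L clipped to [40, 180]; 56.2% male). Blood character
findings (dark blood, blood mixed with stool) are forced absent when
bleeding is not present, respecting the structural invariant. The same
seed always reproduces the identical cohort.

What the generator does *not* emulate: correlations between findings
(real signs co-occur), age- or sex-dependence of prevalences, and
non-CRC patients. Green property tests therefore demonstrate engine
correctness and statistical-machinery calibration on the stated marginal
conditions, not performance of the rules on real mixed populations — in
particular, nothing here estimates specificity.

## Problem sizes

The deterministic pipeline (fixture build + two policy runs + marginal
verification) completes in well under a second. Exhaustive rule checks
enumerate all 3^9 tri-state assignments of the nine findings per
demographic profile and policy; interval calibration uses 2,000 seeded
binomial draws at p = 0.9, n = 281; the generator's statistical contract
is checked at n = 10,000 with an exact binomial test at α = 0.001.

## Known limitations

* The fixture is *one* cohort consistent with the published marginals;
  patient-level joint statistics beyond the encoded constraints are
  constructions, not data.
* The published inter-rater kappa (0.92) rests on 25 unpublished chart
  ratings and cannot be recomputed; only the kappa machinery is tested,
  against hand-computed and library values.
* The post-test probability aggregator is a design choice (maximum), not
  a published formula, and is flagged as such in report metadata.
* The engine validates plausibility bounds (age 18–120, Hb 0–250 g/L)
  but performs no clinical consistency checking beyond the
  bleeding/blood-character implication.
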