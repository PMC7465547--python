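"""The referral-triage decision rules.

The rules map a patient record to one of four referral urgencies. They
derive from the Cancer Care Ontario criterion set for suspected colorectal
cancer, in which every criterion carried a median positive predictive value
of at least 10% across the underlying evidence base:

* IMMEDIATE - a palpable rectal mass suspicious for CRC, or an abnormal
  abdominal imaging result suspicious for CRC.
* URGENT - unexplained rectal bleeding together with at least one
  qualifier (dark blood, blood mixed with stool, absence of perianal
  symptoms, change in bowel habits, weight loss), or unexplained
  iron-deficiency anemia with a sex-specific low hemoglobin
  (<=110 g/L male, <=100 g/L nonmenstruating female).
* POSSIBLE PRIORITY - findings that fall short of the urgent tier but are
  upgraded either because bleeding is present on its own (isolated
  bleeding with perianal symptoms) or because a risk modifier applies
  (age > 59, male sex, or a first-degree relative with CRC).
* NO ACTION - none of the above.

Tiers are evaluated with strict precedence IMMEDIATE > URGENT >
POSSIBLE_PRIORITY > NO_ACTION. Unknown findings are resolved first under a
:class:`~crctriage.records.MissingDataPolicy`; only the perianal-symptom
field distinguishes the two policies.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Optional, Tuple

from .records import (
    ACTION_WINDOWS,
    BASIS_ISOLATED_BLEEDING,
    BASIS_MODIFIER_AGE,
    BASIS_MODIFIER_FAMILY_HISTORY,
    BASIS_MODIFIER_MALE,
    CRITERION_ABNORMAL_IMAGING,
    CRITERION_BLEEDING_WITH_HABIT_CHANGE,
    CRITERION_BLEEDING_WITH_WEIGHT_LOSS,
    CRITERION_BLEEDING_WITHOUT_PERIANAL,
    CRITERION_DARK_BLOOD,
    CRITERION_IDA_WITH_LOW_HB,
    CRITERION_MIXED_WITH_STOOL,
    CRITERION_PALPABLE_MASS,
    DEFAULT_CONSTANTS,
    FINDING_FIELDS,
    MissingDataPolicy,
    PatientRecord,
    PPVRegistry,
    Priority,
    Recommendation,
    RuleConstants,
    Sex,
    TriState,
)

#: Findings that count as "signs or symptoms" for the possible-priority
#: modifier basis. Perianal symptoms are excluded: they argue for a benign
#: anorectal source and never raise suspicion of CRC on their own.
_MODIFIER_SIGN_FIELDS: Tuple[str, ...] = (
    "ida",
    "palpable_mass",
    "abnormal_imaging",
    "rectal_bleeding",
    "dark_blood",
    "blood_mixed_stool",
    "bowel_habit_change",
    "weight_loss",
)


def resolve(record: PatientRecord, policy: MissingDataPolicy) -> PatientRecord:
    """Resolve every unknown tri-state finding per the missing-data policy.

    Under BASE an unknown perianal-symptom field becomes absent; under
    CONSERVATIVE it becomes present (the patient is assumed to have a
    benign explanation for bleeding, which demotes bleeding-only
    presentations). All other unknown findings become absent under both
    policies. Demographics and labs are untouched; records with no
    unknowns pass through unchanged.
    """
    record.validate()
    updates = {}
    for name in FINDING_FIELDS:
        if getattr(record, name) is TriState.UNKNOWN:
            if name == "perianal_symptoms" and policy is MissingDataPolicy.CONSERVATIVE:
                updates[name] = TriState.PRESENT
            else:
                updates[name] = TriState.ABSENT
    return replace(record, **updates) if updates else record


def anemia_qualifies(
    sex: Sex,
    menstruating: TriState,
    hemoglobin: Optional[float],
    ida: TriState,
    constants: RuleConstants = DEFAULT_CONSTANTS,
) -> bool:
    """Does unexplained iron-deficiency anemia meet the urgent criterion?

    Requires the clinician-asserted IDA flag plus a hemoglobin at or below
    the sex-specific threshold; the female route applies only to
    nonmenstruating women. Unknown sex or unknown hemoglobin never
    qualifies: the rules do not triage on imputed laboratory values. A
    woman whose menstrual status is unknown is treated as menstruating,
    which blocks the hemoglobin route (conservative, and symmetric with
    the perianal-symptom default).
    """
    if ida is not TriState.PRESENT or hemoglobin is None:
        return False
    if sex is Sex.MALE:
        return hemoglobin <= constants.hb_threshold_male
    if sex is Sex.FEMALE and menstruating is TriState.ABSENT:
        return hemoglobin <= constants.hb_threshold_nonmenstruating_female
    return False


def evaluate_immediate(record: PatientRecord) -> List[str]:
    """Satisfied immediate-tier criteria of a resolved record."""
    satisfied = []
    if record.palpable_mass is TriState.PRESENT:
        satisfied.append(CRITERION_PALPABLE_MASS)
    if record.abnormal_imaging is TriState.PRESENT:
        satisfied.append(CRITERION_ABNORMAL_IMAGING)
    return satisfied


def evaluate_urgent(
    record: PatientRecord, constants: RuleConstants = DEFAULT_CONSTANTS
) -> List[str]:
    """Satisfied urgent-tier criteria of a resolved record.

    The five bleeding qualifiers all require rectal bleeding to be
    present; the anemia criterion stands on its own and does not.
    """
    satisfied = []
    if record.rectal_bleeding is TriState.PRESENT:
        if record.dark_blood is TriState.PRESENT:
            satisfied.append(CRITERION_DARK_BLOOD)
        if record.blood_mixed_stool is TriState.PRESENT:
            satisfied.append(CRITERION_MIXED_WITH_STOOL)
        if record.perianal_symptoms is TriState.ABSENT:
            satisfied.append(CRITERION_BLEEDING_WITHOUT_PERIANAL)
        if record.bowel_habit_change is TriState.PRESENT:
            satisfied.append(CRITERION_BLEEDING_WITH_HABIT_CHANGE)
        if record.weight_loss is TriState.PRESENT:
            satisfied.append(CRITERION_BLEEDING_WITH_WEIGHT_LOSS)
    if anemia_qualifies(
        record.sex, record.menstruating, record.hemoglobin, record.ida, constants
    ):
        satisfied.append(CRITERION_IDA_WITH_LOW_HB)
    return satisfied


def evaluate_possible_priority(
    record: PatientRecord, constants: RuleConstants = DEFAULT_CONSTANTS
) -> List[str]:
    """Bases for a possible-priority referral, given both higher tiers empty.

    Two routes: (a) isolated bleeding - rectal bleeding present but, with
    perianal symptoms present and no other qualifier, short of the urgent
    tier; (b) the modifier basis - any sub-threshold sign combined with a
    risk modifier (age above the cutoff, male sex, or a first-degree
    relative with CRC).
    """
    bases = []
    if record.rectal_bleeding is TriState.PRESENT:
        bases.append(BASIS_ISOLATED_BLEEDING)
    any_sign = any(
        getattr(record, name) is TriState.PRESENT for name in _MODIFIER_SIGN_FIELDS
    )
    if any_sign:
        if record.age is not None and record.age > constants.modifier_age_cutoff:
            bases.append(BASIS_MODIFIER_AGE)
        if record.sex is Sex.MALE:
            bases.append(BASIS_MODIFIER_MALE)
        if record.fdr_family_history is TriState.PRESENT:
            bases.append(BASIS_MODIFIER_FAMILY_HISTORY)
    return bases


def posttest_probability(
    satisfied_criteria: Tuple[str, ...] | List[str], registry: PPVRegistry
) -> float:
    """Post-test CRC probability from a registry of per-criterion PPVs.

    The combination rule is the maximum registry PPV over the satisfied
    criteria - the weakest defensible aggregator given criteria whose
    joint behaviour is unknown. With no satisfied criterion the pre-test
    probability is returned. Only criteria of the two positive tiers
    (immediate/urgent vocabulary) are looked up; possible-priority bases
    carry no registry PPV.
    """
    values = []
    for criterion in satisfied_criteria:
        if criterion not in registry.ppv:
            raise KeyError(
                f"criterion {criterion!r} missing from PPV registry; "
                "supply a PPV for every criterion the cohort can satisfy"
            )
        values.append(registry.ppv[criterion])
    if not values:
        return registry.pretest_probability
    return max(values)


def triage(
    record: PatientRecord,
    policy: MissingDataPolicy = MissingDataPolicy.BASE,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    registry: Optional[PPVRegistry] = None,
) -> Recommendation:
    """Assign a referral priority to one patient record.

    Resolves unknowns under ``policy``, then applies the tiers with
    strict precedence. For the two positive tiers the recommendation
    lists every satisfied immediate and urgent criterion (an immediate
    referral may additionally satisfy urgent criteria); for the
    possible-priority tier it lists the bases; for NO_ACTION the list is
    empty. When ``registry`` is supplied a post-test probability is
    attached, computed from the satisfied positive-tier criteria.
    """
    resolved = resolve(record, policy)
    immediate = evaluate_immediate(resolved)
    urgent = evaluate_urgent(resolved, constants)

    if immediate:
        priority = Priority.IMMEDIATE
        criteria: Tuple[str, ...] = tuple(immediate + urgent)
    elif urgent:
        priority = Priority.URGENT
        criteria = tuple(urgent)
    else:
        bases = evaluate_possible_priority(resolved, constants)
        if bases:
            priority = Priority.POSSIBLE_PRIORITY
            criteria = tuple(bases)
        else:
            priority = Priority.NO_ACTION
            criteria = ()

    posttest = None
    if registry is not None:
        positive_criteria = tuple(immediate + urgent)
        posttest = posttest_probability(positive_criteria, registry)

    return Recommendation(
        record_id=record.id,
        priority=priority,
        satisfied_criteria=criteria,
        referral_window=ACTION_WINDOWS[priority],
        policy=policy,
        posttest_probability=posttest,
    )
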