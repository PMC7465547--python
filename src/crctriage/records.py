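"""Domain types for colorectal-cancer referral triage.

The central object is :class:`PatientRecord`: one patient's demographics,
hemoglobin, and a set of tri-state clinical findings (present / absent /
unknown). The third state exists because retrospective chart review often
cannot establish whether a finding was truly absent or simply not recorded;
how unknowns are resolved is governed by :class:`MissingDataPolicy`.

Criterion identifiers are a fixed public vocabulary of stable strings; they
appear in recommendations, PPV registries, reports and CSV headers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Tuple


class ValidationError(ValueError):
    """A record or configuration value violates an invariant.

    ``field`` names the offending attribute so callers (e.g. the CSV
    reader) can report row-level errors precisely.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class TriState(str, enum.Enum):
    """A clinical finding recorded as present, absent, or unknown."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str, field_name: str = "tristate") -> "TriState":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                field_name,
                f"invalid tri-state token {token!r}; "
                f"expected one of 'present', 'absent', 'unknown'",
            ) from None


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str, field_name: str = "sex") -> "Sex":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                field_name,
                f"invalid sex token {token!r}; "
                f"expected one of 'male', 'female', 'unknown'",
            ) from None


class Confirmation(str, enum.Enum):
    """Outcome label: histologically confirmed CRC status.

    Used only by the evaluation machinery; the triage rules never read it.
    """

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str, field_name: str = "crc_confirmed") -> "Confirmation":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                field_name,
                f"invalid confirmation token {token!r}; "
                f"expected one of 'yes', 'no', 'unknown'",
            ) from None


class Priority(enum.IntEnum):
    """Referral urgency, ordered so comparisons mean clinical urgency.

    NO_ACTION < POSSIBLE_PRIORITY < URGENT < IMMEDIATE.
    """

    NO_ACTION = 0
    POSSIBLE_PRIORITY = 1
    URGENT = 2
    IMMEDIATE = 3


class MissingDataPolicy(str, enum.Enum):
    """How unknown tri-state findings are resolved before triage.

    BASE resolves unknown perianal symptoms to absent (the primary
    analysis); CONSERVATIVE resolves them to present, which pushes
    bleeding-only patients out of the urgent tier. Every other finding
    resolves unknown -> absent under both modes, since the absence of a
    positive assertion in a chart is ordinarily read as absence.
    """

    BASE = "base"
    CONSERVATIVE = "conservative"


# --- public criterion vocabulary ------------------------------------------

CRITERION_PALPABLE_MASS = "palpable_mass"
CRITERION_ABNORMAL_IMAGING = "abnormal_imaging"
CRITERION_DARK_BLOOD = "dark_blood"
CRITERION_MIXED_WITH_STOOL = "mixed_with_stool"
CRITERION_BLEEDING_WITHOUT_PERIANAL = "bleeding_without_perianal"
CRITERION_BLEEDING_WITH_HABIT_CHANGE = "bleeding_with_habit_change"
CRITERION_BLEEDING_WITH_WEIGHT_LOSS = "bleeding_with_weight_loss"
CRITERION_IDA_WITH_LOW_HB = "ida_with_low_hb"
BASIS_ISOLATED_BLEEDING = "isolated_bleeding"
BASIS_MODIFIER_AGE = "modifier_age"
BASIS_MODIFIER_MALE = "modifier_male"
BASIS_MODIFIER_FAMILY_HISTORY = "modifier_family_history"

IMMEDIATE_CRITERIA: Tuple[str, ...] = (
    CRITERION_PALPABLE_MASS,
    CRITERION_ABNORMAL_IMAGING,
)
URGENT_CRITERIA: Tuple[str, ...] = (
    CRITERION_DARK_BLOOD,
    CRITERION_MIXED_WITH_STOOL,
    CRITERION_BLEEDING_WITHOUT_PERIANAL,
    CRITERION_BLEEDING_WITH_HABIT_CHANGE,
    CRITERION_BLEEDING_WITH_WEIGHT_LOSS,
    CRITERION_IDA_WITH_LOW_HB,
)
POSSIBLE_PRIORITY_BASES: Tuple[str, ...] = (
    BASIS_ISOLATED_BLEEDING,
    BASIS_MODIFIER_AGE,
    BASIS_MODIFIER_MALE,
    BASIS_MODIFIER_FAMILY_HISTORY,
)

#: Names of the tri-state clinical findings on a record, in schema order.
FINDING_FIELDS: Tuple[str, ...] = (
    "ida",
    "palpable_mass",
    "abnormal_imaging",
    "rectal_bleeding",
    "dark_blood",
    "blood_mixed_stool",
    "perianal_symptoms",
    "bowel_habit_change",
    "weight_loss",
)


@dataclass(frozen=True)
class RuleConstants:
    """Numeric thresholds of the decision rules.

    Hemoglobin thresholds are sex-specific and inclusive: anemia qualifies
    at Hb <= 110 g/L for males and <= 100 g/L for nonmenstruating females.
    ``modifier_age_cutoff`` is the strict lower age bound (age > 59) for
    the age modifier on sub-threshold findings.
    """

    hb_threshold_male: float = 110.0
    hb_threshold_nonmenstruating_female: float = 100.0
    modifier_age_cutoff: int = 59


DEFAULT_CONSTANTS = RuleConstants()


@dataclass(frozen=True)
class PatientRecord:
    """One patient's demographics, labs and tri-state findings.

    ``age`` and ``hemoglobin`` use ``None`` for unknown. Validation
    enforces plausibility bounds (age 18-120, Hb in (0, 250] g/L) and the
    structural implication that dark blood or blood mixed with stool can
    only be recorded when rectal bleeding itself is present.
    """

    id: str
    age: Optional[int] = None
    sex: Sex = Sex.UNKNOWN
    menstruating: TriState = TriState.UNKNOWN
    hemoglobin: Optional[float] = None
    ida: TriState = TriState.UNKNOWN
    palpable_mass: TriState = TriState.UNKNOWN
    abnormal_imaging: TriState = TriState.UNKNOWN
    rectal_bleeding: TriState = TriState.UNKNOWN
    dark_blood: TriState = TriState.UNKNOWN
    blood_mixed_stool: TriState = TriState.UNKNOWN
    perianal_symptoms: TriState = TriState.UNKNOWN
    bowel_habit_change: TriState = TriState.UNKNOWN
    weight_loss: TriState = TriState.UNKNOWN
    fdr_family_history: TriState = TriState.UNKNOWN
    crc_confirmed: Confirmation = Confirmation.UNKNOWN

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated field."""
        if not isinstance(self.id, str) or not self.id:
            raise ValidationError("id", "must be a non-empty string")
        if self.age is not None:
            if not isinstance(self.age, int) or isinstance(self.age, bool):
                raise ValidationError("age", "must be an integer or unknown")
            if not (18 <= self.age <= 120):
                raise ValidationError("age", f"{self.age} outside [18, 120]")
        if self.hemoglobin is not None:
            hb = self.hemoglobin
            if not isinstance(hb, (int, float)) or isinstance(hb, bool) or math.isnan(hb):
                raise ValidationError("hemoglobin", "must be a number or unknown")
            if not (0 < hb <= 250):
                raise ValidationError("hemoglobin", f"{hb} g/L outside (0, 250]")
        for name in FINDING_FIELDS + ("menstruating", "fdr_family_history"):
            value = getattr(self, name)
            if not isinstance(value, TriState):
                raise ValidationError(name, f"expected TriState, got {value!r}")
        if not isinstance(self.sex, Sex):
            raise ValidationError("sex", f"expected Sex, got {self.sex!r}")
        if not isinstance(self.crc_confirmed, Confirmation):
            raise ValidationError(
                "crc_confirmed", f"expected Confirmation, got {self.crc_confirmed!r}"
            )
        for name in ("dark_blood", "blood_mixed_stool"):
            if (
                getattr(self, name) is TriState.PRESENT
                and self.rectal_bleeding is not TriState.PRESENT
            ):
                raise ValidationError(
                    name, "present requires rectal_bleeding=present"
                )

    def with_findings(self, **updates: TriState) -> "PatientRecord":
        """Return a copy with the given finding fields replaced."""
        return replace(self, **updates)


@dataclass(frozen=True)
class PPVRegistry:
    """Median positive predictive values per criterion, plus a pre-test prior.

    Supplying a registry enables the post-test probability output; the
    registry may be empty, in which case that output stays absent.
    """

    ppv: Mapping[str, float] = field(default_factory=dict)
    pretest_probability: float = 0.0

    def __post_init__(self) -> None:
        for criterion, value in self.ppv.items():
            if not (0.0 <= value <= 1.0):
                raise ValidationError(
                    "ppv", f"PPV for {criterion!r} is {value}; must lie in [0, 1]"
                )
        if not (0.0 <= self.pretest_probability <= 1.0):
            raise ValidationError(
                "pretest_probability",
                f"{self.pretest_probability} must lie in [0, 1]",
            )


#: Action windows attached to each priority tier. The immediate and urgent
#: texts carry the clinically meaningful windows; the lower two tiers have
#: neutral defaults and may be overridden via configuration.
ACTION_WINDOWS: Mapping[Priority, str] = {
    Priority.IMMEDIATE: "referral within 24 hours; expected endoscopy within 2 weeks",
    Priority.URGENT: (
        "expected consultation within 4 weeks; expected endoscopy within 8 weeks"
    ),
    Priority.POSSIBLE_PRIORITY: (
        "consider priority referral at the clinician's discretion"
    ),
    Priority.NO_ACTION: "no specific action recommended",
}


@dataclass(frozen=True)
class Recommendation:
    """Output of the triage engine for one patient."""

    record_id: str
    priority: Priority
    satisfied_criteria: Tuple[str, ...]
    referral_window: str
    policy: MissingDataPolicy
    posttest_probability: Optional[float] = None
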