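"""Deterministic and random cohort construction.

Two generators live here:

* :func:`build_validation_fixture` reconstructs, without randomness, a
  confirmed-CRC cohort of rectal-bleeding presenters whose per-priority
  criterion tallies match a published marginal table. Only the marginal
  counts are known - the joint distribution of findings within a group is
  not - so a canonical block-assignment scheme fixes one concrete cohort
  among the many consistent with the marginals (see the methods note).
* :func:`generate_random_cohort` draws seeded random cohorts for property
  tests, with configurable prevalences, unknown rates and demographics.

:func:`verify_marginals` re-triages a cohort and checks every tally
against the spec, producing a line-per-cell discrepancy report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .records import (
    Confirmation,
    MissingDataPolicy,
    PatientRecord,
    Priority,
    Sex,
    TriState,
    ValidationError,
)
from .rules import resolve, triage

#: Row vocabulary of the per-group marginal table. Each is a predicate on
#: a resolved record; ``bleeding_only`` means rectal bleeding with none of
#: the other eight variables.
TABLE_VARIABLES: Tuple[str, ...] = (
    "palpable_mass",
    "abnormal_imaging",
    "ida",
    "bleeding_with_weight_loss",
    "bleeding_mixed_with_stool",
    "bleeding_without_perianal",
    "bleeding_with_habit_change",
    "dark_bleeding",
    "bleeding_only",
)

_P = TriState.PRESENT
_A = TriState.ABSENT
_U = TriState.UNKNOWN


def tally_variables(resolved: PatientRecord) -> List[str]:
    """Which marginal-table variables a resolved record exhibits."""
    out = []
    bleeding = resolved.rectal_bleeding is _P
    if resolved.palpable_mass is _P:
        out.append("palpable_mass")
    if resolved.abnormal_imaging is _P:
        out.append("abnormal_imaging")
    if resolved.ida is _P:
        out.append("ida")
    if bleeding and resolved.weight_loss is _P:
        out.append("bleeding_with_weight_loss")
    if bleeding and resolved.blood_mixed_stool is _P:
        out.append("bleeding_mixed_with_stool")
    if bleeding and resolved.perianal_symptoms is _A:
        out.append("bleeding_without_perianal")
    if bleeding and resolved.bowel_habit_change is _P:
        out.append("bleeding_with_habit_change")
    if bleeding and resolved.dark_blood is _P:
        out.append("dark_bleeding")
    if bleeding and not out:
        out.append("bleeding_only")
    return out


def _default_marginals() -> Dict[Priority, Dict[str, int]]:
    zeros = {v: 0 for v in TABLE_VARIABLES}
    return {
        Priority.IMMEDIATE: {
            **zeros,
            "palpable_mass": 54,
            "abnormal_imaging": 19,
            "ida": 8,
            "bleeding_with_weight_loss": 25,
            "bleeding_mixed_with_stool": 28,
            "bleeding_without_perianal": 62,
            "bleeding_with_habit_change": 39,
            "dark_bleeding": 5,
        },
        Priority.URGENT: {
            **zeros,
            "ida": 41,
            "bleeding_with_weight_loss": 56,
            "bleeding_mixed_with_stool": 96,
            "bleeding_without_perianal": 198,
            "bleeding_with_habit_change": 128,
            "dark_bleeding": 17,
        },
        Priority.POSSIBLE_PRIORITY: {**zeros, "bleeding_only": 1},
        Priority.NO_ACTION: dict(zeros),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Marginal constraints the deterministic fixture must satisfy.

    Defaults encode the published validation cohort: 281 confirmed-CRC
    patients presenting with rectal bleeding, of whom 69 were assigned
    immediate referral, 211 urgent, 1 possible priority and 0 no action;
    158 were male; 23 urgent-group charts had unrecorded perianal-symptom
    status (and no other urgent qualifier).
    """

    group_sizes: Mapping[Priority, int] = field(
        default_factory=lambda: {
            Priority.IMMEDIATE: 69,
            Priority.URGENT: 211,
            Priority.POSSIBLE_PRIORITY: 1,
            Priority.NO_ACTION: 0,
        }
    )
    marginals: Mapping[Priority, Mapping[str, int]] = field(
        default_factory=_default_marginals
    )
    unknown_perianal_count: int = 23
    male_count: int = 158
    n: int = 281

    def __post_init__(self) -> None:
        # normalize to complete mappings (absent groups/cells count zero)
        sizes = {p: int(self.group_sizes.get(p, 0)) for p in Priority}
        cells = {
            p: {
                v: int(self.marginals.get(p, {}).get(v, 0))
                for v in TABLE_VARIABLES
            }
            for p in Priority
        }
        for group, given in self.marginals.items():
            for variable in given:
                if variable not in TABLE_VARIABLES:
                    raise InfeasibleSpecError(
                        f"unknown marginal variable {variable!r}"
                    )
        object.__setattr__(self, "group_sizes", sizes)
        object.__setattr__(self, "marginals", cells)

    def check_feasible(self) -> None:
        """Raise :class:`InfeasibleSpecError` naming any violated constraint."""
        if sum(self.group_sizes.values()) != self.n:
            raise InfeasibleSpecError(
                f"group sizes sum to {sum(self.group_sizes.values())}, not n={self.n}"
            )
        if not (0 <= self.male_count <= self.n):
            raise InfeasibleSpecError(f"male_count {self.male_count} outside [0, n]")
        for group, cells in self.marginals.items():
            size = self.group_sizes.get(group, 0)
            for variable, count in cells.items():
                if variable not in TABLE_VARIABLES:
                    raise InfeasibleSpecError(
                        f"unknown marginal variable {variable!r}"
                    )
                if not (0 <= count <= size):
                    raise InfeasibleSpecError(
                        f"{group.name}/{variable} count {count} exceeds "
                        f"group size {size}"
                    )
        gi = self.group_sizes[Priority.IMMEDIATE]
        imm = self.marginals[Priority.IMMEDIATE]
        if imm["palpable_mass"] + imm["abnormal_imaging"] < gi:
            raise InfeasibleSpecError(
                "immediate group cannot be covered: palpable_mass + "
                "abnormal_imaging < group size"
            )
        gu = self.group_sizes[Priority.URGENT]
        urg = self.marginals[Priority.URGENT]
        if urg["palpable_mass"] or urg["abnormal_imaging"]:
            raise InfeasibleSpecError(
                "urgent group must carry no immediate-tier findings"
            )
        if urg["bleeding_without_perianal"] < self.unknown_perianal_count:
            raise InfeasibleSpecError(
                "unknown_perianal_count exceeds the urgent "
                "bleeding-without-perianal marginal"
            )
        perianal_present = gu - urg["bleeding_without_perianal"]
        if perianal_present < 0:
            raise InfeasibleSpecError(
                "urgent bleeding-without-perianal marginal exceeds group size"
            )
        if urg["bleeding_with_habit_change"] < perianal_present:
            raise InfeasibleSpecError(
                "urgent records with perianal symptoms present cannot all be "
                "covered by the bowel-habit-change marginal"
            )
        assignable = gu - self.unknown_perianal_count
        for variable in (
            "ida",
            "bleeding_with_weight_loss",
            "bleeding_mixed_with_stool",
            "bleeding_with_habit_change",
            "dark_bleeding",
        ):
            if urg[variable] > assignable:
                raise InfeasibleSpecError(
                    f"urgent {variable} marginal {urg[variable]} collides with "
                    f"the {self.unknown_perianal_count} qualifier-free "
                    f"unknown-perianal records (assignable: {assignable})"
                )
        if self.group_sizes[Priority.NO_ACTION] != 0:
            raise InfeasibleSpecError(
                "a rectal-bleeding cohort cannot contain no-action records"
            )
        if self.group_sizes[Priority.POSSIBLE_PRIORITY] != self.marginals[
            Priority.POSSIBLE_PRIORITY
        ]["bleeding_only"]:
            raise InfeasibleSpecError(
                "possible-priority group must consist of bleeding-only records"
            )


class InfeasibleSpecError(ValueError):
    """The marginal constraints admit no cohort under the canonical scheme."""


DEFAULT_FIXTURE_SPEC = FixtureSpec()

#: Ages cycle through this triple (mean 67 y) purely for realism; age plays
#: no role in fixture triage outcomes.
_AGE_CYCLE = (61, 67, 73)
_HB_NORMAL = 123.0
_HB_ANEMIC = 95.0  # below both sex-specific thresholds


def build_validation_fixture(
    spec: FixtureSpec = DEFAULT_FIXTURE_SPEC,
) -> List[PatientRecord]:
    """Build the deterministic validation cohort.

    Every record presents with rectal bleeding and has confirmed CRC.
    Within each priority group, each marginal-table variable is assigned
    to a contiguous block of records starting at the lowest index, with
    two deliberate exceptions: abnormal imaging occupies the *highest*
    indices of the immediate group (so mass and imaging overlap by
    exactly ``mass + imaging - group_size`` records while covering the
    whole group), and in the urgent group the perianal-present block
    comes first and is covered by the bowel-habit-change assignment.
    The last ``unknown_perianal_count`` urgent records carry unknown
    perianal status and no other urgent qualifier - under the base policy
    they qualify through bleeding-without-perianal; under the
    conservative policy they demote to possible priority.
    """
    spec.check_feasible()
    records: List[PatientRecord] = []
    n_digits = len(str(spec.n))

    def base_kwargs(index: int) -> dict:
        male = index < spec.male_count
        return dict(
            id=f"P{index + 1:0{n_digits}d}",
            age=_AGE_CYCLE[index % len(_AGE_CYCLE)],
            sex=Sex.MALE if male else Sex.FEMALE,
            menstruating=_A if not male else _U,
            hemoglobin=_HB_NORMAL,
            rectal_bleeding=_P,
            dark_blood=_A,
            blood_mixed_stool=_A,
            perianal_symptoms=_A,
            bowel_habit_change=_A,
            weight_loss=_A,
            ida=_A,
            palpable_mass=_A,
            abnormal_imaging=_A,
            fdr_family_history=_A,
            crc_confirmed=Confirmation.YES,
        )

    # --- immediate group ---------------------------------------------------
    gi = spec.group_sizes[Priority.IMMEDIATE]
    imm = spec.marginals[Priority.IMMEDIATE]
    for local in range(gi):
        kw = base_kwargs(len(records))
        kw["palpable_mass"] = _P if local < imm["palpable_mass"] else _A
        kw["abnormal_imaging"] = _P if local >= gi - imm["abnormal_imaging"] else _A
        kw["ida"] = _P if local < imm["ida"] else _A
        kw["weight_loss"] = _P if local < imm["bleeding_with_weight_loss"] else _A
        kw["blood_mixed_stool"] = (
            _P if local < imm["bleeding_mixed_with_stool"] else _A
        )
        kw["perianal_symptoms"] = (
            _A if local < imm["bleeding_without_perianal"] else _P
        )
        kw["bowel_habit_change"] = (
            _P if local < imm["bleeding_with_habit_change"] else _A
        )
        kw["dark_blood"] = _P if local < imm["dark_bleeding"] else _A
        if kw["ida"] is _P:
            kw["hemoglobin"] = _HB_ANEMIC
        records.append(PatientRecord(**kw))

    # --- urgent group ------------------------------------------------------
    gu = spec.group_sizes[Priority.URGENT]
    urg = spec.marginals[Priority.URGENT]
    n_unknown = spec.unknown_perianal_count
    n_present = gu - urg["bleeding_without_perianal"]  # perianal symptoms present
    unknown_start = gu - n_unknown
    for local in range(gu):
        kw = base_kwargs(len(records))
        if local < n_present:
            kw["perianal_symptoms"] = _P
        elif local >= unknown_start:
            kw["perianal_symptoms"] = _U
        else:
            kw["perianal_symptoms"] = _A
        if local < unknown_start:
            kw["ida"] = _P if local < urg["ida"] else _A
            kw["weight_loss"] = (
                _P if local < urg["bleeding_with_weight_loss"] else _A
            )
            kw["blood_mixed_stool"] = (
                _P if local < urg["bleeding_mixed_with_stool"] else _A
            )
            kw["bowel_habit_change"] = (
                _P if local < urg["bleeding_with_habit_change"] else _A
            )
            kw["dark_blood"] = _P if local < urg["dark_bleeding"] else _A
        if kw["ida"] is _P:
            kw["hemoglobin"] = _HB_ANEMIC
        records.append(PatientRecord(**kw))

    # --- possible-priority group -------------------------------------------
    for _ in range(spec.group_sizes[Priority.POSSIBLE_PRIORITY]):
        kw = base_kwargs(len(records))
        # isolated bleeding: perianal symptoms present, nothing else, and no
        # risk modifier (age under the cutoff; sex fixed to female here)
        kw["perianal_symptoms"] = _P
        kw["age"] = 45
        kw["sex"] = Sex.FEMALE
        kw["menstruating"] = _A
        records.append(PatientRecord(**kw))

    return records


def verify_marginals(
    cohort: Sequence[PatientRecord],
    spec: FixtureSpec = DEFAULT_FIXTURE_SPEC,
    policy: MissingDataPolicy = MissingDataPolicy.BASE,
) -> List[str]:
    """Check a cohort's per-group tallies against a marginal spec.

    Triaged under ``policy``, each record contributes its marginal-table
    variables to its priority group. Returns one human-readable line per
    discrepancy; an empty list means the cohort reproduces every cell.
    """
    report: List[str] = []
    if len(cohort) != spec.n:
        report.append(f"cohort size {len(cohort)} != expected n {spec.n}")
    sizes: Dict[Priority, int] = {p: 0 for p in Priority}
    tallies: Dict[Priority, Dict[str, int]] = {
        p: {v: 0 for v in TABLE_VARIABLES} for p in Priority
    }
    for record in cohort:
        rec = triage(record, policy)
        sizes[rec.priority] += 1
        resolved = resolve(record, policy)
        for variable in tally_variables(resolved):
            tallies[rec.priority][variable] += 1
    for group in Priority:
        expected_size = spec.group_sizes.get(group, 0)
        if sizes[group] != expected_size:
            report.append(
                f"{group.name}: group size {sizes[group]} != expected {expected_size}"
            )
        expected_cells = spec.marginals.get(group, {})
        for variable in TABLE_VARIABLES:
            expected = expected_cells.get(variable, 0)
            if tallies[group][variable] != expected:
                report.append(
                    f"{group.name}/{variable}: tally {tallies[group][variable]} "
                    f"!= expected {expected}"
                )
    return report


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the seeded random cohort generator.

    Defaults mirror the validation cohort's summary statistics: age
    67.0 +/- 13.4 years, hemoglobin 123.3 +/- 22.3 g/L, 56.2% male, and
    finding prevalences equal to the marginal totals over the 281
    patients. ``unknown_rate`` applies to perianal symptoms (the one
    inconsistently recorded finding, unknown for 23/281 charts);
    ``unknown_rate_other`` to the remaining tri-states.
    """

    n: int = 281
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "palpable_mass": 54 / 281,
            "abnormal_imaging": 19 / 281,
            "ida": 49 / 281,
            "rectal_bleeding": 1.0,
            "dark_blood": 22 / 281,
            "blood_mixed_stool": 124 / 281,
            "perianal_symptoms": 21 / 281,
            "bowel_habit_change": 167 / 281,
            "weight_loss": 81 / 281,
            "fdr_family_history": 0.1,
        }
    )
    unknown_rate: float = 23 / 281
    unknown_rate_other: float = 0.0
    age_mean: float = 67.0
    age_sd: float = 13.4
    male_fraction: float = 158 / 281
    hb_mean: float = 123.3
    hb_sd: float = 22.3
    seed: int = 0

    def check_valid(self) -> None:
        if self.n <= 0:
            raise ValidationError("n", "cohort size must be positive")
        for name, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    "prevalence", f"{name} prevalence {p} outside [0, 1]"
                )
        for name, rate in (
            ("unknown_rate", self.unknown_rate),
            ("unknown_rate_other", self.unknown_rate_other),
            ("male_fraction", self.male_fraction),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(name, f"{rate} outside [0, 1]")


def generate_random_cohort(spec: GeneratorSpec = GeneratorSpec()) -> List[PatientRecord]:
    """Draw a seeded random cohort of confirmed-CRC records.

    Findings are independent Bernoulli draws at the spec prevalences,
    then masked to unknown at the spec unknown rates; dark blood and
    blood mixed with stool are forced absent when rectal bleeding is not
    present, respecting the structural invariant. The same seed always
    yields the identical cohort.
    """
    spec.check_valid()
    rng = np.random.default_rng(spec.seed)
    n_digits = len(str(spec.n))
    records = []

    def draw_tristate(name: str, unknown_rate: float) -> TriState:
        if rng.random() < unknown_rate:
            return _U
        return _P if rng.random() < spec.prevalence.get(name, 0.0) else _A

    for i in range(spec.n):
        male = rng.random() < spec.male_fraction
        age = int(np.clip(round(rng.normal(spec.age_mean, spec.age_sd)), 18, 120))
        hb = float(np.clip(rng.normal(spec.hb_mean, spec.hb_sd), 40.0, 180.0))
        bleeding = draw_tristate("rectal_bleeding", spec.unknown_rate_other)
        dark = (
            draw_tristate("dark_blood", spec.unknown_rate_other)
            if bleeding is _P
            else _A
        )
        mixed = (
            draw_tristate("blood_mixed_stool", spec.unknown_rate_other)
            if bleeding is _P
            else _A
        )
        records.append(
            PatientRecord(
                id=f"R{i + 1:0{n_digits}d}",
                age=age,
                sex=Sex.MALE if male else Sex.FEMALE,
                menstruating=_U if male else (_A if age >= 50 else _P),
                hemoglobin=round(hb, 1),
                ida=draw_tristate("ida", spec.unknown_rate_other),
                palpable_mass=draw_tristate("palpable_mass", spec.unknown_rate_other),
                abnormal_imaging=draw_tristate(
                    "abnormal_imaging", spec.unknown_rate_other
                ),
                rectal_bleeding=bleeding,
                dark_blood=dark,
                blood_mixed_stool=mixed,
                perianal_symptoms=draw_tristate("perianal_symptoms", spec.unknown_rate),
                bowel_habit_change=draw_tristate(
                    "bowel_habit_change", spec.unknown_rate_other
                ),
                weight_loss=draw_tristate("weight_loss", spec.unknown_rate_other),
                fdr_family_history=draw_tristate(
                    "fdr_family_history", spec.unknown_rate_other
                ),
                crc_confirmed=Confirmation.YES,
            )
        )
    return records
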