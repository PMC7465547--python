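"""Independent flat decision-table oracle for the triage rules.

Deliberately written as a single nested-if function over plain strings
and numbers, sharing no code with the package, so that equivalence tests
compare two independently coded statements of the decision logic.
"""

from typing import Dict, Optional

FINDINGS = (
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


def flat_table_priority(
    findings: Dict[str, str],
    age: Optional[int],
    sex: str,
    menstruating: str,
    hemoglobin: Optional[float],
    fdr: str,
    policy: str,
) -> str:
    """Priority name for raw tri-state findings under a missing-data policy."""

    def on(name: str) -> bool:
        token = findings[name]
        if token == "unknown":
            return name == "perianal_symptoms" and policy == "conservative"
        return token == "present"

    if on("palpable_mass") or on("abnormal_imaging"):
        return "IMMEDIATE"

    anemia = (
        findings["ida"] == "present"
        and hemoglobin is not None
        and (
            (sex == "male" and hemoglobin <= 110)
            or (
                sex == "female"
                and menstruating == "absent"
                and hemoglobin <= 100
            )
        )
    )
    bleeding = on("rectal_bleeding")
    if anemia or (
        bleeding
        and (
            on("dark_blood")
            or on("blood_mixed_stool")
            or not on("perianal_symptoms")
            or on("bowel_habit_change")
            or on("weight_loss")
        )
    ):
        return "URGENT"

    if bleeding:
        return "POSSIBLE_PRIORITY"
    any_sign = any(
        on(name) for name in FINDINGS if name != "perianal_symptoms"
    )
    if any_sign and (
        (age is not None and age > 59) or sex == "male" or fdr == "present"
    ):
        return "POSSIBLE_PRIORITY"
    return "NO_ACTION"
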