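"""Cohort CSV input/output and report rendering.

The cohort file is a UTF-8 CSV with one row per patient and a fixed
header drawn from the public field vocabulary. Tri-state findings use the
literal tokens ``present`` / ``absent`` / ``unknown``; unknown numerics
are empty cells, so a missing value is never conflated with zero.
Round-tripping a cohort through :func:`write_cohort` and
:func:`read_cohort` reproduces it exactly, unknowns included.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple, Union

from .records import (
    Confirmation,
    MissingDataPolicy,
    PatientRecord,
    Priority,
    Recommendation,
    Sex,
    TriState,
    ValidationError,
)
from .stats import CIMethod, CohortEvaluation, render_percent

#: Column order of the cohort CSV schema.
CSV_COLUMNS: Tuple[str, ...] = (
    "id",
    "age",
    "sex",
    "menstruating",
    "hemoglobin",
    "ida",
    "palpable_mass",
    "abnormal_imaging",
    "rectal_bleeding",
    "dark_blood",
    "blood_mixed_stool",
    "perianal_symptoms",
    "bowel_habit_change",
    "weight_loss",
    "fdr_family_history",
    "crc_confirmed",
)

_TRISTATE_COLUMNS = (
    "menstruating",
    "ida",
    "palpable_mass",
    "abnormal_imaging",
    "rectal_bleeding",
    "dark_blood",
    "blood_mixed_stool",
    "perianal_symptoms",
    "bowel_habit_change",
    "weight_loss",
    "fdr_family_history",
)


class CohortSchemaError(ValueError):
    """The file as a whole cannot be read (missing columns, no header)."""


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class ReadResult:
    """Records read from a cohort file plus any lenient-mode exclusions."""

    records: List[PatientRecord]
    excluded: List[RowError]

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_row(row: dict, line: int) -> PatientRecord:
    def opt_int(name: str) -> Optional[int]:
        token = (row.get(name) or "").strip()
        if token == "":
            return None
        try:
            return int(token)
        except ValueError:
            raise ValidationError(name, f"line {line}: not an integer: {token!r}")

    def opt_float(name: str) -> Optional[float]:
        token = (row.get(name) or "").strip()
        if token == "":
            return None
        try:
            return float(token)
        except ValueError:
            raise ValidationError(name, f"line {line}: not a number: {token!r}")

    kwargs = {
        "id": (row.get("id") or "").strip(),
        "age": opt_int("age"),
        "sex": Sex.parse((row.get("sex") or "unknown").strip() or "unknown"),
        "hemoglobin": opt_float("hemoglobin"),
        "crc_confirmed": Confirmation.parse(
            (row.get("crc_confirmed") or "unknown").strip() or "unknown"
        ),
    }
    for name in _TRISTATE_COLUMNS:
        token = (row.get(name) or "unknown").strip() or "unknown"
        kwargs[name] = TriState.parse(token, name)
    try:
        return PatientRecord(**kwargs)
    except ValidationError as err:
        raise ValidationError(err.field, f"line {line}: {err}") from None


def read_cohort(path: Union[str, Path], strict: bool = True) -> ReadResult:
    """Read a cohort CSV.

    Strict mode rejects the whole file on any invalid row. Lenient mode
    skips invalid rows, recording a :class:`RowError` per exclusion so
    exclusions are always accounted for, never silent. A missing column
    is a hard :class:`CohortSchemaError` in both modes.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, expected a CSV header")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortSchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        records: List[PatientRecord] = []
        excluded: List[RowError] = []
        for line, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, line))
            except ValidationError as err:
                if strict:
                    raise
                excluded.append(RowError(line=line, message=str(err)))
    return ReadResult(records=records, excluded=excluded)


def write_cohort(cohort: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write a cohort to the CSV schema; inverse of :func:`read_cohort`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for record in cohort:
            row = []
            for column in CSV_COLUMNS:
                value = getattr(record, column)
                if value is None:
                    row.append("")
                elif isinstance(value, (TriState, Sex, Confirmation)):
                    row.append(value.value)
                else:
                    row.append(str(value))
            writer.writerow(row)


# --- reports ---------------------------------------------------------------


def recommendation_to_dict(rec: Recommendation) -> dict:
    return {
        "record_id": rec.record_id,
        "priority": rec.priority.name,
        "satisfied_criteria": list(rec.satisfied_criteria),
        "referral_window": rec.referral_window,
        "policy": rec.policy.value,
        "posttest_probability": rec.posttest_probability,
    }


def recommendation_from_dict(data: dict) -> Recommendation:
    return Recommendation(
        record_id=data["record_id"],
        priority=Priority[data["priority"]],
        satisfied_criteria=tuple(data["satisfied_criteria"]),
        referral_window=data["referral_window"],
        policy=MissingDataPolicy(data["policy"]),
        posttest_probability=data["posttest_probability"],
    )


def evaluation_to_dict(ev: CohortEvaluation, threshold: float = 0.90) -> dict:
    return {
        "n": ev.n,
        "policy": ev.policy.value,
        "counts": {p.name: ev.counts[p] for p in Priority},
        "percentages": {
            p.name: render_percent(ev.counts[p] / ev.n) for p in Priority
        },
        "positives": ev.positives,
        "n_confirmed": ev.n_confirmed,
        "sensitivity": ev.sensitivity,
        "sensitivity_percent": render_percent(ev.sensitivity),
        "ci_low": ev.ci_low,
        "ci_high": ev.ci_high,
        "ci_percent": [render_percent(ev.ci_low), render_percent(ev.ci_high)],
        "ci_method": ev.ci_method.value,
        "confidence": ev.confidence,
        "threshold": threshold,
        "meets_threshold": ev.meets_threshold(threshold),
        "demoted": list(ev.demoted),
        "warnings": list(ev.warnings),
    }


def _recommendation_text(rec: Recommendation) -> str:
    lines = [
        f"Patient {rec.record_id}",
        f"  Referral priority : {rec.priority.name}",
        f"  Action            : {rec.referral_window}",
        f"  Missing-data mode : {rec.policy.value}",
    ]
    if rec.satisfied_criteria:
        lines.append(
            "  Satisfied criteria: " + ", ".join(rec.satisfied_criteria)
        )
    else:
        lines.append("  Satisfied criteria: none")
    if rec.posttest_probability is not None:
        lines.append(
            f"  Post-test CRC probability: "
            f"{render_percent(rec.posttest_probability)}% "
            f"(max of criterion PPVs)"
        )
    return "\n".join(lines)


def _evaluation_text(ev: CohortEvaluation, threshold: float) -> str:
    width = max(len(p.name) for p in Priority)
    lines = [
        f"Cohort evaluation (n={ev.n}, policy={ev.policy.value}, "
        f"CI method={ev.ci_method.value})",
        "  Priority counts:",
    ]
    for p in (
        Priority.IMMEDIATE,
        Priority.URGENT,
        Priority.POSSIBLE_PRIORITY,
        Priority.NO_ACTION,
    ):
        pct = render_percent(ev.counts[p] / ev.n)
        lines.append(f"    {p.name:<{width}} {ev.counts[p]:>5}  ({pct}%)")
    level = f"{ev.confidence * 100:g}%"
    lines.append(
        f"  Sensitivity: {render_percent(ev.sensitivity)}% "
        f"({level} CI {render_percent(ev.ci_low)} to {render_percent(ev.ci_high)}%)"
    )
    verdict = "meets" if ev.meets_threshold(threshold) else "fails"
    lines.append(
        f"  Verdict: {verdict} the pre-specified "
        f"{render_percent(threshold)}% sensitivity threshold"
    )
    if ev.policy is MissingDataPolicy.CONSERVATIVE:
        lines.append(
            f"  Demotions vs base policy: {len(ev.demoted)} "
            f"({', '.join(ev.demoted) if ev.demoted else 'none'})"
        )
    for warning in ev.warnings:
        lines.append(f"  Warning: {warning}")
    return "\n".join(lines)


def render_report(
    obj: Union[Recommendation, CohortEvaluation],
    format: str = "text",
    threshold: float = 0.90,
) -> str:
    """Render a per-patient recommendation or a cohort evaluation.

    ``format`` is ``"text"`` (aligned, human-readable) or ``"json"``.
    """
    if format not in ("text", "json"):
        raise ValueError(f"unknown report format {format!r}; use 'text' or 'json'")
    if isinstance(obj, Recommendation):
        if format == "json":
            return json.dumps(recommendation_to_dict(obj), indent=2)
        return _recommendation_text(obj)
    if isinstance(obj, CohortEvaluation):
        if format == "json":
            return json.dumps(evaluation_to_dict(obj, threshold), indent=2)
        return _evaluation_text(obj, threshold)
    raise TypeError(f"cannot render object of type {type(obj).__name__}")
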