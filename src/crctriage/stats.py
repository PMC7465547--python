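"""Evaluation statistics for triage runs on confirmed-CRC cohorts.

A cohort of histologically confirmed CRC patients is triaged; immediate
and urgent recommendations count as positive test results, possible
priority and no action as negative. With only diseased patients in the
cohort the one estimable test characteristic is sensitivity, reported
with a binomial confidence interval (Wilson score by default,
Clopper-Pearson on request). Chart-review reliability is quantified with
unweighted Cohen's kappa over the nominal priority labels.
"""

from __future__ import annotations

import decimal
import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats as _sps

from .records import (
    DEFAULT_CONSTANTS,
    Confirmation,
    MissingDataPolicy,
    PatientRecord,
    Priority,
    RuleConstants,
    ValidationError,
)
from .rules import triage


class CIMethod(str, enum.Enum):
    WILSON = "wilson"
    CLOPPER_PEARSON = "clopper_pearson"


def binarize(priority: Priority) -> bool:
    """Map a priority to a positive (True) / negative (False) test result.

    Immediate or urgent referral is positive; possible priority or no
    action is negative.
    """
    return priority in (Priority.IMMEDIATE, Priority.URGENT)


def sensitivity(positives: int, total_with_disease: int) -> float:
    """Fraction of diseased patients with a positive recommendation."""
    if total_with_disease <= 0:
        raise ValidationError(
            "total_with_disease",
            "sensitivity is undefined on a cohort with no confirmed cases",
        )
    if not (0 <= positives <= total_with_disease):
        raise ValidationError(
            "positives", f"{positives} outside [0, {total_with_disease}]"
        )
    return positives / total_with_disease


def _check_counts(successes: int, n: int, confidence: float) -> None:
    if n <= 0:
        raise ValidationError("n", "must be positive")
    if not (0 <= successes <= n):
        raise ValidationError("successes", f"{successes} outside [0, {n}]")
    if not (0.0 < confidence < 1.0):
        raise ValidationError("confidence", f"{confidence} outside (0, 1)")


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Obtained by inverting the score test: the interval is the set of p
    with |p_hat - p| <= z * sqrt(p (1-p) / n). Well-behaved near 0 and 1,
    where the Wald interval degenerates; bounds are clipped to [0, 1].
    """
    _check_counts(successes, n, confidence)
    z = _sps.norm.ppf(0.5 + confidence / 2.0)
    p_hat = successes / n
    denom = 1.0 + z * z / n
    centre = (p_hat + z * z / (2.0 * n)) / denom
    half = (z / denom) * math.sqrt(p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n))
    # at the boundaries the closed form is exactly 0 (resp. 1); avoid
    # floating-point drift there
    low = 0.0 if successes == 0 else max(0.0, centre - half)
    high = 1.0 if successes == n else min(1.0, centre + half)
    return low, high


def clopper_pearson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval from beta quantiles.

    Conservative: coverage is at least the nominal level for every p, so
    the interval always contains the Wilson interval for the same input.
    Lower bound is exactly 0 when successes = 0, upper exactly 1 when
    successes = n.
    """
    _check_counts(successes, n, confidence)
    alpha = 1.0 - confidence
    low = 0.0 if successes == 0 else float(
        _sps.beta.ppf(alpha / 2.0, successes, n - successes + 1)
    )
    high = 1.0 if successes == n else float(
        _sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
    )
    return low, high


def binomial_interval(
    successes: int, n: int, confidence: float = 0.95, method: CIMethod = CIMethod.WILSON
) -> Tuple[float, float]:
    if method is CIMethod.WILSON:
        return wilson_interval(successes, n, confidence)
    return clopper_pearson_interval(successes, n, confidence)


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two raters over nominal labels.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of the raters' marginal label frequencies. When both raters
    use a single identical label, p_o = p_e = 1 and the formula is
    indeterminate; that degenerate case is defined as 1.0 (perfect
    observed agreement).
    """
    if len(ratings_a) != len(ratings_b):
        raise ValidationError(
            "ratings", f"length mismatch: {len(ratings_a)} vs {len(ratings_b)}"
        )
    n = len(ratings_a)
    if n == 0:
        raise ValidationError("ratings", "kappa is undefined on empty ratings")
    p_o = sum(a == b for a, b in zip(ratings_a, ratings_b)) / n
    marg_a = Counter(ratings_a)
    marg_b = Counter(ratings_b)
    p_e = sum(marg_a[label] * marg_b.get(label, 0) for label in marg_a) / (n * n)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def render_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percentage, round-half-up.

    Matches conventional clinical-report style: 0.24555 -> '24.6'.
    """
    quantum = decimal.Decimal(1).scaleb(-decimals)
    value = decimal.Decimal(repr(float(fraction) * 100.0)).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return str(value)


@dataclass(frozen=True)
class CohortEvaluation:
    """Summary of one triage run over a confirmed-CRC cohort.

    ``demoted`` lists ids whose priority dropped relative to a BASE run;
    it is populated only for CONSERVATIVE evaluations. ``warnings``
    carries metadata such as a mixed-confirmation notice.
    """

    n: int
    policy: MissingDataPolicy
    counts: Dict[Priority, int]
    positives: int
    n_confirmed: int
    sensitivity: float
    ci_low: float
    ci_high: float
    ci_method: CIMethod
    confidence: float
    demoted: Tuple[str, ...] = ()
    warnings: Tuple[str, ...] = ()

    @property
    def proportions(self) -> Dict[Priority, float]:
        return {p: c / self.n for p, c in self.counts.items()}

    def meets_threshold(self, threshold: float = 0.90) -> bool:
        return self.sensitivity >= threshold


def evaluate_cohort(
    cohort: Sequence[PatientRecord],
    policy: MissingDataPolicy = MissingDataPolicy.BASE,
    constants: RuleConstants = DEFAULT_CONSTANTS,
    ci_method: CIMethod = CIMethod.WILSON,
    confidence: float = 0.95,
) -> CohortEvaluation:
    """Triage a cohort and compute the evaluation statistics.

    Sensitivity is computed over the records with ``crc_confirmed=yes``;
    if the cohort mixes confirmation statuses a warning is recorded and
    the confirmed subset is used. A CONSERVATIVE run re-triages under
    BASE to build the demotion ledger (ids whose priority dropped when
    unknown perianal symptoms were assumed present).
    """
    if not cohort:
        raise ValidationError("cohort", "cannot evaluate an empty cohort")

    counts: Dict[Priority, int] = {p: 0 for p in Priority}
    confirmed_positive = 0
    n_confirmed = 0
    demoted: List[str] = []
    warnings: List[str] = []

    for record in cohort:
        rec = triage(record, policy, constants)
        counts[rec.priority] += 1
        if record.crc_confirmed is Confirmation.YES:
            n_confirmed += 1
            if binarize(rec.priority):
                confirmed_positive += 1
        if policy is MissingDataPolicy.CONSERVATIVE:
            base_rec = triage(record, MissingDataPolicy.BASE, constants)
            if rec.priority < base_rec.priority:
                demoted.append(record.id)

    if n_confirmed == 0:
        raise ValidationError(
            "cohort",
            "sensitivity is undefined: no record has crc_confirmed=yes",
        )
    if n_confirmed < len(cohort):
        warnings.append(
            f"mixed confirmation status: sensitivity computed over the "
            f"{n_confirmed} confirmed records of {len(cohort)}"
        )

    sens = sensitivity(confirmed_positive, n_confirmed)
    ci_low, ci_high = binomial_interval(
        confirmed_positive, n_confirmed, confidence, ci_method
    )
    return CohortEvaluation(
        n=len(cohort),
        policy=policy,
        counts=counts,
        positives=counts[Priority.IMMEDIATE] + counts[Priority.URGENT],
        n_confirmed=n_confirmed,
        sensitivity=sens,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_method=ci_method,
        confidence=confidence,
        demoted=tuple(demoted),
        warnings=tuple(warnings),
    )
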