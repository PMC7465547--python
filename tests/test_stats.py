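"""Evaluation statistics: sensitivity, binomial intervals, Cohen's kappa."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from crctriage import (
    CIMethod,
    Confirmation,
    MissingDataPolicy,
    PatientRecord,
    Priority,
    Sex,
    TriState,
    ValidationError,
    binarize,
    clopper_pearson_interval,
    cohens_kappa,
    evaluate_cohort,
    render_percent,
    sensitivity,
    wilson_interval,
)

P, A = TriState.PRESENT, TriState.ABSENT


class TestBinarize:
    @pytest.mark.parametrize(
        "priority, expected",
        [
            (Priority.IMMEDIATE, True),
            (Priority.URGENT, True),
            (Priority.POSSIBLE_PRIORITY, False),
            (Priority.NO_ACTION, False),
        ],
    )
    def test_positive_iff_immediate_or_urgent(self, priority, expected):
        assert binarize(priority) is expected


class TestSensitivity:
    def test_values_and_rendering(self):
        assert sensitivity(280, 281) == pytest.approx(280 / 281)
        assert render_percent(sensitivity(280, 281)) == "99.6"
        assert sensitivity(0, 281) == 0.0
        assert render_percent(sensitivity(257, 281)) == "91.5"

    def test_undefined_on_empty_denominator(self):
        with pytest.raises(ValidationError):
            sensitivity(0, 0)

    def test_rejects_impossible_counts(self):
        with pytest.raises(ValidationError):
            sensitivity(5, 3)


class TestRenderPercent:
    @pytest.mark.parametrize(
        "fraction, expected",
        [
            (69 / 281, "24.6"),
            (211 / 281, "75.1"),
            (1 / 281, "0.4"),
            (0.0, "0.0"),
            (0.1225, "12.3"),  # half-up, where banker's rounding gives 12.2
            (0.1235, "12.4"),
        ],
    )
    def test_round_half_up_one_decimal(self, fraction, expected):
        assert render_percent(fraction) == expected


class TestWilsonInterval:
    def test_reproduces_printed_ci_bounds(self):
        low, high = wilson_interval(280, 281)
        assert round(low, 3) == 0.980
        assert round(high, 3) == 0.999

    def test_hand_computed_midrange_case(self):
        low, high = wilson_interval(50, 100)
        assert low == pytest.approx(0.4038, abs=5e-5)
        assert high == pytest.approx(0.5962, abs=5e-5)

    def test_boundary_clipping(self):
        low, _ = wilson_interval(0, 10)
        assert low == 0.0
        _, high = wilson_interval(10, 10)
        assert high == 1.0

    @pytest.mark.parametrize("x, n", [(0, 5), (3, 7), (50, 100), (280, 281)])
    def test_matches_statsmodels(self, x, n):
        low, high = wilson_interval(x, n)
        sm_low, sm_high = proportion_confint(x, n, method="wilson")
        assert low == pytest.approx(sm_low, abs=1e-12)
        assert high == pytest.approx(sm_high, abs=1e-12)

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValidationError):
            wilson_interval(6, 5)
        with pytest.raises(ValidationError):
            wilson_interval(1, 0)


class TestClopperPearsonInterval:
    def test_boundary_conventions_exact(self):
        assert clopper_pearson_interval(0, 10)[0] == 0.0
        assert clopper_pearson_interval(10, 10)[1] == 1.0

    @pytest.mark.parametrize("x, n", [(0, 5), (3, 7), (50, 100), (280, 281)])
    def test_matches_statsmodels_beta(self, x, n):
        low, high = clopper_pearson_interval(x, n)
        sm_low, sm_high = proportion_confint(x, n, method="beta")
        assert low == pytest.approx(sm_low, abs=1e-12)
        assert high == pytest.approx(sm_high, abs=1e-12)

    def test_strictly_contains_wilson_midrange(self):
        w = wilson_interval(5, 10)
        cp = clopper_pearson_interval(5, 10)
        assert cp[0] < w[0] and cp[1] > w[1]


def test_clopper_pearson_never_narrower_than_wilson_on_grid():
    """Exact interval is at least as wide as the score interval for every
    interior (0 < x < n) cell of an (x, n) grid, and both intervals always
    contain the point estimate.

    The guarantee is on width, not nesting: near the boundary the two
    intervals shift relative to one another. At x=0 and x=n themselves
    Clopper-Pearson collapses to its one-sided form, which can undercut
    Wilson slightly; those cells are covered by the boundary-convention
    tests instead.
    """
    for n in (1, 2, 5, 10, 25, 100, 281):
        for x in range(n + 1):
            w_low, w_high = wilson_interval(x, n)
            cp_low, cp_high = clopper_pearson_interval(x, n)
            if 0 < x < n:
                assert cp_high - cp_low >= w_high - w_low - 1e-12, (x, n)
            p_hat = x / n
            assert w_low <= p_hat <= w_high
            assert cp_low <= p_hat <= cp_high


def test_wilson_coverage_near_nominal():
    """95% Wilson coverage lies in [93%, 97%] at p=0.9, n=281 (seeded)."""
    rng = np.random.default_rng(20190522)
    p, n, draws = 0.9, 281, 2000
    successes = rng.binomial(n, p, size=draws)
    covered = 0
    for x in successes:
        low, high = wilson_interval(int(x), n)
        covered += low <= p <= high
    assert 0.93 <= covered / draws <= 0.97


class TestCohensKappa:
    def test_perfect_agreement(self):
        ratings = ["IMMEDIATE", "URGENT", "URGENT", "NO_ACTION"] * 5
        assert cohens_kappa(ratings, list(ratings)) == 1.0

    def test_hand_computed_two_by_two_table(self):
        # agreement table a=15, b=2, c=3, d=5: p_o = 0.8, p_e = 0.5792
        ratings_a = ["pos"] * 17 + ["neg"] * 8
        ratings_b = ["pos"] * 15 + ["neg"] * 2 + ["pos"] * 3 + ["neg"] * 5
        assert cohens_kappa(ratings_a, ratings_b) == pytest.approx(0.5247, abs=5e-5)

    def test_chance_level_agreement_is_zero(self):
        ratings_a = ["x", "y"] * 10
        ratings_b = ["x"] * 20
        assert cohens_kappa(ratings_a, ratings_b) == pytest.approx(0.0)

    def test_symmetric_and_label_permutation_invariant(self):
        rng = np.random.default_rng(7)
        a = list(rng.choice(["i", "u", "p", "n"], size=60))
        b = list(rng.choice(["i", "u", "p", "n"], size=60))
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(b, a))
        relabel = {"i": "Z", "u": "Y", "p": "X", "n": "W"}
        assert cohens_kappa(
            [relabel[x] for x in a], [relabel[x] for x in b]
        ) == pytest.approx(cohens_kappa(a, b))

    def test_matches_scikit_learn(self):
        rng = np.random.default_rng(11)
        a = rng.choice(["i", "u", "p"], size=100)
        b = rng.choice(["i", "u", "p"], size=100)
        assert cohens_kappa(list(a), list(b)) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_degenerate_single_label_defined_as_one(self):
        assert cohens_kappa(["u"] * 10, ["u"] * 10) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa(["a"], ["a", "b"])


class TestEvaluateCohort:
    def make_record(self, rid, **overrides):
        kwargs = dict(
            id=rid,
            age=60,
            sex=Sex.FEMALE,
            menstruating=A,
            hemoglobin=120.0,
            ida=A,
            palpable_mass=A,
            abnormal_imaging=A,
            rectal_bleeding=A,
            dark_blood=A,
            blood_mixed_stool=A,
            perianal_symptoms=A,
            bowel_habit_change=A,
            weight_loss=A,
            fdr_family_history=A,
            crc_confirmed=Confirmation.YES,
        )
        kwargs.update(overrides)
        return PatientRecord(**kwargs)

    def test_single_negative_record(self):
        # age 60 exceeds the modifier cutoff, but with no sign present the
        # record still maps to NO_ACTION
        cohort = [self.make_record("Q1")]
        ev = evaluate_cohort(cohort)
        assert ev.counts[Priority.NO_ACTION] == 1
        assert ev.sensitivity == 0.0
        assert ev.positives == 0

    def test_counts_conserve_n(self, validation_cohort):
        ev = evaluate_cohort(validation_cohort)
        assert sum(ev.counts.values()) == ev.n == 281
        assert ev.positives == ev.counts[Priority.IMMEDIATE] + ev.counts[Priority.URGENT]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_cohort([])

    def test_no_confirmed_cases_rejected(self):
        cohort = [self.make_record("Q1", crc_confirmed=Confirmation.NO)]
        with pytest.raises(ValidationError):
            evaluate_cohort(cohort)

    def test_mixed_confirmation_warns_and_restricts(self):
        cohort = [
            self.make_record("Q1", rectal_bleeding=P),
            self.make_record("Q2", rectal_bleeding=P, crc_confirmed=Confirmation.NO),
        ]
        ev = evaluate_cohort(cohort)
        assert ev.n_confirmed == 1
        assert ev.sensitivity == 1.0
        assert any("mixed confirmation" in w for w in ev.warnings)

    def test_demotion_ledger_only_for_conservative_runs(self, validation_cohort):
        base = evaluate_cohort(validation_cohort, MissingDataPolicy.BASE)
        assert base.demoted == ()
        cons = evaluate_cohort(validation_cohort, MissingDataPolicy.CONSERVATIVE)
        assert len(cons.demoted) == 23

    def test_ci_method_selection(self, validation_cohort):
        wilson = evaluate_cohort(validation_cohort, ci_method=CIMethod.WILSON)
        cp = evaluate_cohort(validation_cohort, ci_method=CIMethod.CLOPPER_PEARSON)
        assert wilson.ci_low <= wilson.sensitivity <= wilson.ci_high
        assert cp.ci_low <= cp.sensitivity <= cp.ci_high
        assert cp.ci_high - cp.ci_low >= wilson.ci_high - wilson.ci_low
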