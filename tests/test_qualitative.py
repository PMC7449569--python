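"""Process tracing and crisp-set QCA, checked against exact enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

import designdiag as dd
from designdiag.qualitative import (DNFExpression, LikelihoodTable,
                                    TruthTable, build_truth_table,
                                    classify_test, expression_equal,
                                    inus_marginal_effect,
                                    joint_cpo_distribution, pt_posterior,
                                    pt_strategy_diagnosis, qmc_minimize,
                                    regression_qca)

STRAW = (0.75, 0.25)
GUN = (0.30, 0.05)
TABLE = LikelihoodTable((STRAW[0], GUN[0]), (STRAW[1], GUN[1]))


def single_cpo_expected_error(prior, p_h, p_nh):
    """Four-branch enumeration oracle for a one-clue strategy."""
    total = 0.0
    for h, p_truth in ((1, prior), (0, 1 - prior)):
        for e in (0, 1):
            like_h = p_h if e else 1 - p_h
            like_nh = p_nh if e else 1 - p_nh
            p_branch = p_truth * (like_h if h else like_nh)
            post = prior * like_h / (prior * like_h + (1 - prior) * like_nh)
            total += p_branch * abs(h - post)
    return total


class TestPtPosterior:
    def test_straw_in_the_wind_seen(self):
        assert pt_posterior(0.5, TABLE, [1, None]) == pytest.approx(0.75)

    def test_smoking_gun_seen(self):
        assert pt_posterior(0.5, TABLE, [None, 1]) == pytest.approx(6 / 7)

    def test_certain_prior_stays_certain(self):
        for pattern in ([1, None], [0, None], [None, 0]):
            assert pt_posterior(1.0, TABLE, pattern) == 1.0

    def test_no_observations_return_prior(self):
        for prior in (0.2, 0.5, 0.9):
            assert pt_posterior(prior, TABLE, [None, None]) == \
                pytest.approx(prior)

    def test_zero_probability_pattern_errors(self):
        table = LikelihoodTable((1.0,), (1.0,))
        with pytest.raises(ValueError):
            pt_posterior(0.5, table, [0])


class TestStrategyDiagnosis:
    def test_straw_matches_enumeration(self):
        oracle = single_cpo_expected_error(0.5, *STRAW)
        assert oracle == pytest.approx(0.375, abs=1e-12)
        assert pt_strategy_diagnosis(0.5, TABLE, "cpo1_only") == \
            pytest.approx(oracle, abs=1e-10)

    def test_smoking_gun_matches_enumeration(self):
        oracle = single_cpo_expected_error(0.5, *GUN)
        assert oracle == pytest.approx(0.445887445887, abs=1e-9)
        assert pt_strategy_diagnosis(0.5, TABLE, "cpo2_only") == \
            pytest.approx(oracle, abs=1e-10)

    def test_straw_beats_smoking_gun_on_average(self):
        assert pt_strategy_diagnosis(0.5, TABLE, "cpo1_only") < \
            pt_strategy_diagnosis(0.5, TABLE, "cpo2_only")

    def test_doubly_decisive_has_zero_error(self):
        table = LikelihoodTable((1.0,), (0.0,))
        assert pt_strategy_diagnosis(0.5, table, (0,)) == 0.0

    def test_informative_tests_strictly_reduce_error(self):
        """Any clue with Pr(E|H) != Pr(E|not-H) beats not looking at all,
        whose error is min(prior, 1 - prior)."""
        prior = 0.5
        baseline = min(prior, 1 - prior)
        for p_h in np.linspace(0.05, 0.95, 7):
            for p_nh in np.linspace(0.05, 0.95, 7):
                table = LikelihoodTable((p_h,), (p_nh,))
                err = pt_strategy_diagnosis(prior, table, (0,))
                if abs(p_h - p_nh) > 1e-9:
                    assert err < baseline - 1e-12
                else:
                    assert err == pytest.approx(baseline, abs=1e-12)

    def test_negatively_correlated_clues_help_more(self):
        # +/-0.1 keeps the joint feasible for these likelihoods under both
        # hypotheses (stronger negative values hit the Frechet bound)
        err_neg = pt_strategy_diagnosis(0.5, TABLE, "both", rho=-0.1)
        err_pos = pt_strategy_diagnosis(0.5, TABLE, "both", rho=+0.1)
        assert err_neg < err_pos


class TestJointDistribution:
    def test_independent_is_product(self):
        joint = joint_cpo_distribution(TABLE)
        for h, marg in ((True, TABLE.p_given_h), (False, TABLE.p_given_not_h)):
            for pattern, prob in joint[h].items():
                expected = np.prod([p if e else 1 - p
                                    for e, p in zip(pattern, marg)])
                assert prob == pytest.approx(expected)

    def test_upper_frechet_bound_couples_evidence(self):
        table = LikelihoodTable((0.4, 0.4), (0.2, 0.2))
        joint = joint_cpo_distribution(table, rho=1.0)
        assert joint[True][(1, 1)] == pytest.approx(0.4)
        assert joint[True][(1, 0)] == pytest.approx(0.0)

    def test_infeasible_rho_clipped_with_warning(self):
        # both clues near-certain under H: strong negative correlation is
        # infeasible (Frechet lower bound binds) and must be clipped
        table = LikelihoodTable((0.9, 0.8), (0.5, 0.5))
        with pytest.warns(UserWarning):
            joint = joint_cpo_distribution(table, rho=-1.0)
        assert all(v >= 0 for v in joint[True].values())
        assert sum(joint[True].values()) == pytest.approx(1.0)


class TestClassifyTest:
    @pytest.mark.parametrize("p_h, p_nh, expected", [
        (0.30, 0.05, "smoking_gun"),
        (0.75, 0.25, "straw_in_the_wind"),
        (1.0, 0.0, "doubly_decisive"),
        (0.95, 0.6, "hoop"),
    ])
    def test_classification(self, p_h, p_nh, expected):
        assert classify_test(p_h, p_nh) == expected


class TestTruthTable:
    def test_two_causes_four_rows(self):
        df = pd.DataFrame({"A": [0, 1, 0, 1], "B": [0, 0, 1, 1],
                           "Y": [0, 0, 1, 0]})
        tt = build_truth_table(df, ["A", "B"], "Y")
        assert len(tt.table) == 4

    def test_majority_coding(self):
        df = pd.DataFrame({"A": [1] * 10, "B": [1] * 10,
                           "Y": [1] * 7 + [0] * 3})
        tt = build_truth_table(df, ["A", "B"], "Y")
        row = tt.table[(tt.table["A"] == 1) & (tt.table["B"] == 1)].iloc[0]
        assert row["coded"] == 1 and row["consistency"] == pytest.approx(0.7)

    def test_unseen_configuration_is_remainder(self):
        df = pd.DataFrame({"A": [0, 0], "B": [0, 1], "Y": [0, 1]})
        tt = build_truth_table(df, ["A", "B"], "Y")
        assert (1, 0) in tt.remainders() and (1, 1) in tt.remainders()

    def test_non_binary_input_rejected(self):
        df = pd.DataFrame({"A": [0, 2], "B": [0, 1], "Y": [0, 1]})
        with pytest.raises(ValueError):
            build_truth_table(df, ["A", "B"], "Y")


def tt_from_positions(causes, positives, remainders=()):
    rows = []
    for config in itertools.product((0, 1), repeat=len(causes)):
        coded = (1 if config in positives
                 else "remainder" if config in remainders else 0)
        row = dict(zip(causes, config))
        row.update(n_cases=0 if coded == "remainder" else 5,
                   n_positive=5 if coded == 1 else 0,
                   consistency=np.nan if coded == "remainder" else float(coded == 1),
                   coded=coded)
        rows.append(row)
    return TruthTable(tuple(causes), pd.DataFrame(rows))


class TestQmcMinimize:
    def test_recovers_ab_plus_c(self):
        causes = ("A", "B", "C")
        target = DNFExpression.from_string("AB + C", causes)
        tt = tt_from_positions(causes, target.expand())
        result = qmc_minimize(tt)
        assert expression_equal(result, target)
        assert result.render() == "C + AB"

    def test_recovers_not_a_and_b(self):
        causes = ("A", "B")
        target = DNFExpression.from_string("aB", causes)
        tt = tt_from_positions(causes, {(0, 1)})
        assert expression_equal(qmc_minimize(tt), target)

    def test_all_positive_is_tautology(self):
        causes = ("A", "B")
        tt = tt_from_positions(causes, set(itertools.product((0, 1),
                                                             repeat=2)))
        result = qmc_minimize(tt)
        assert result.render() == "1"

    def test_no_positive_rows_empty_expression(self):
        tt = tt_from_positions(("A", "B"), set())
        assert qmc_minimize(tt).render() == "0"

    def test_sound_and_complete_all_k2_labelings(self):
        """Exhaustive check over every outcome labeling of the 2-cause
        truth table: the minimized expression expands to exactly the
        positive rows."""
        causes = ("A", "B")
        configs = list(itertools.product((0, 1), repeat=2))
        for labeling in itertools.product((0, 1), repeat=4):
            positives = {c for c, y in zip(configs, labeling) if y}
            tt = tt_from_positions(causes, positives)
            assert set(qmc_minimize(tt).expand()) == positives

    @pytest.mark.parametrize("k", [3, 4])
    def test_sound_and_complete_random_labelings(self, k, rng):
        causes = tuple("ABCD"[:k])
        configs = list(itertools.product((0, 1), repeat=k))
        for _ in range(200):
            labeling = rng.integers(0, 2, size=2 ** k)
            positives = {c for c, y in zip(configs, labeling) if y}
            tt = tt_from_positions(causes, positives)
            assert set(qmc_minimize(tt).expand()) == positives

    def test_dont_care_remainders_enable_merging(self):
        causes = ("A", "B")
        tt = tt_from_positions(causes, {(1, 1)}, remainders={(1, 0)})
        excl = qmc_minimize(tt, "exclude")
        dont = qmc_minimize(tt, "dont_care")
        assert excl.render() == "AB"
        assert dont.render() == "A"


class TestRegressionQca:
    def test_error_free_recovery(self, rng):
        a = rng.integers(0, 2, 200)
        b = rng.integers(0, 2, 200)
        y = ((1 - a) * b).astype(float)
        df = pd.DataFrame({"A": a, "B": b, "Y": y})
        result = regression_qca(df, ["A", "B"], "Y")
        assert expression_equal(result,
                                DNFExpression.from_string("aB", ("A", "B")))

    def test_robust_to_ten_percent_flip_noise(self, rng):
        """With 10% outcome misclassification at n=500, the majority rule
        still recovers the generating configuration nearly always."""
        target = DNFExpression.from_string("aB", ("A", "B"))
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.integers(0, 2, 500)
            b = rng.integers(0, 2, 500)
            y = ((1 - a) * b).astype(float)
            flip = rng.random(500) < 0.10
            y = np.where(flip, 1 - y, y)
            df = pd.DataFrame({"A": a, "B": b, "Y": y})
            hits += expression_equal(regression_qca(df, ["A", "B"], "Y"),
                                     target)
        assert hits / reps >= 0.95

    def test_all_zero_outcomes_empty(self):
        df = pd.DataFrame({"A": [0, 1, 0, 1], "B": [0, 0, 1, 1],
                           "Y": [0, 0, 0, 0]})
        assert regression_qca(df, ["A", "B"], "Y").render() == "0"


class TestDnfExpression:
    def test_equality_is_order_invariant(self):
        causes = ("A", "B", "C")
        e1 = DNFExpression.from_string("AB + C", causes)
        e2 = DNFExpression.from_string("C + AB", causes)
        assert expression_equal(e1, e2)

    def test_equality_is_semantic(self):
        causes = ("A", "B")
        e1 = DNFExpression.from_string("A", causes)
        e2 = DNFExpression.from_string("AB + Ab", causes)
        assert expression_equal(e1, e2)

    def test_different_expressions_unequal(self):
        causes = ("A", "B")
        assert not expression_equal(DNFExpression.from_string("A", causes),
                                    DNFExpression.from_string("B", causes))

    def test_mismatched_universes_error(self):
        with pytest.raises(ValueError):
            expression_equal(DNFExpression.from_string("A", ("A",)),
                             DNFExpression.from_string("B", ("B",)))

    def test_subsumed_implicants_dropped(self):
        e = DNFExpression.from_terms(("A", "B"), [{"A": 1},
                                                  {"A": 1, "B": 1}])
        assert e.render() == "A"


class TestInusMarginalEffect:
    def test_max_ab_c_effect_of_a(self):
        # Y = max(AB, C): A is difference-making exactly when B=1, C=0
        dnf = DNFExpression.from_string("AB + C", ("A", "B", "C"))
        assert inus_marginal_effect(dnf, "A") == pytest.approx(0.25)

    def test_absent_cause_zero_effect(self):
        dnf = DNFExpression.from_string("B", ("A", "B"))
        assert inus_marginal_effect(dnf, "A") == 0.0

    def test_sole_cause_unit_effect(self):
        dnf = DNFExpression.from_string("A", ("A", "B"))
        assert inus_marginal_effect(dnf, "A") == 1.0

    def test_cause_of_effects_inquiry_on_binary_table(self):
        """Pr(Y(0)=0 | X=1, Y(1)=1) computed over the conditioning set."""
        df = pd.DataFrame({
            "X": [1, 1, 1, 0, 1],
            "Y_X_0": [0, 1, 0, 0, 0],
            "Y_X_1": [1, 1, 1, 1, 0],
        })
        step = dd.declare_inquiry("coe", "cause_of_effects", outcome="Y",
                                  cause="X")
        from designdiag.core import DataTable
        rows = step.transform(DataTable(df))
        # conditioning set: rows 0, 1, 2; Y_X_0 == 0 in two of three
        assert rows[0]["value"] == pytest.approx(2 / 3)
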