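"""Diagnosand formulas on hand-built and simulated tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import designdiag as dd
from designdiag import diagnosands as dg


def sims_table(**cols):
    n = max(len(v) for v in cols.values())
    base = {
        "run": np.arange(n), "run_seed": np.arange(n),
        "estimator_label": ["E"] * n, "estimand_label": ["I"] * n,
        "estimand": [np.nan] * n, "estimate": [np.nan] * n,
        "std_error": [np.nan] * n, "p_value": [np.nan] * n,
        "ci_low": [np.nan] * n, "ci_high": [np.nan] * n, "df": [np.nan] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestPower:
    def test_two_of_three_significant(self):
        value, n_undef = dg.power(sims_table(p_value=[0.01, 0.20, 0.04]))
        assert value == pytest.approx(2 / 3)
        assert n_undef == 0

    def test_all_null(self):
        value, _ = dg.power(sims_table(p_value=[1.0, 1.0]))
        assert value == 0.0

    def test_monotone_in_alpha(self):
        t = sims_table(p_value=[0.003, 0.02, 0.04, 0.2, 0.7])
        assert dg.power(t, alpha=0.01)[0] <= dg.power(t, alpha=0.05)[0]


class TestBiasRmse:
    def test_symmetric_errors(self):
        t = sims_table(estimate=[1.2, 0.8], estimand=[1.0, 1.0])
        assert dg.bias(t)[0] == pytest.approx(0.0)
        assert dg.rmse(t)[0] == pytest.approx(0.2)

    def test_perfect_estimates(self):
        t = sims_table(estimate=[1.0, 1.0], estimand=[1.0, 1.0])
        assert dg.bias(t)[0] == 0.0 and dg.rmse(t)[0] == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=40),
           st.floats(-3, 3))
    @settings(max_examples=60, deadline=None)
    def test_rmse_identity(self, estimates, estimand):
        """rmse^2 = bias^2 + sd^2 (m-1)/m on any simulation table."""
        m = len(estimates)
        t = sims_table(estimate=estimates, estimand=[estimand] * m)
        rmse = dg.rmse(t)[0]
        bias = dg.bias(t)[0]
        sd = dg.sd_estimates(t)[0]
        assert rmse ** 2 == pytest.approx(
            bias ** 2 + sd ** 2 * (m - 1) / m, abs=1e-10)


class TestCoverage:
    def test_hit_and_miss(self):
        t = sims_table(ci_low=[0.0, 2.0], ci_high=[2.0, 3.0],
                       estimand=[1.0, 1.0])
        assert dg.coverage(t)[0] == 0.5


class TestConditionalDiagnosands:
    def test_type_s_and_exaggeration_on_fixture(self):
        t = sims_table(estimate=[2.0, -1.0], estimand=[1.0, 1.0],
                       p_value=[0.01, 0.01])
        assert dg.type_s_rate(t)[0] == 0.5
        assert dg.exaggeration_ratio(t)[0] == 1.5

    def test_no_significant_rows_undefined(self):
        t = sims_table(estimate=[2.0, -1.0], estimand=[1.0, 1.0],
                       p_value=[0.5, 0.6])
        value, n_undef = dg.exaggeration_ratio(t)
        assert np.isnan(value) and n_undef == 2

    def test_zero_estimand_counted_undefined(self):
        t = sims_table(estimate=[2.0, 1.0], estimand=[0.0, 1.0],
                       p_value=[0.01, 0.01])
        value, n_undef = dg.exaggeration_ratio(t)
        assert value == 1.0 and n_undef == 1


class TestSdAndSamplingBias:
    def test_constant_estimates_zero_sd(self):
        t = sims_table(estimate=[1.0, 1.0, 1.0])
        assert dg.sd_estimates(t)[0] == 0.0

    def test_sampling_bias_requires_both_labels(self):
        t = sims_table(estimand=[1.0, 1.0])
        with pytest.raises(dd.ConfigurationError):
            dg.sampling_bias(t, "PATE", "SATE")

    def test_sampling_bias_zero_under_random_sampling(self):
        """Simple random sampling is unbiased for the mean: PATE - SATE
        averages to zero over runs in a heterogeneous-effects design."""
        steps = [
            dd.declare_population(
                80, {"u": {"normal": [0, 1]}, "tau": {"normal": [1, 0.8]}}),
            dd.declare_potential_outcomes(
                "Y", dd.ConditionSet("Z", [0, 1]),
                lambda df, z: df["u"].to_numpy() + df["tau"].to_numpy() * z),
            dd.declare_inquiry("PATE", "summary", expr="mean(Y_Z_1 - Y_Z_0)"),
            dd.declare_sampling("simple", n=30),
            dd.declare_inquiry("SATE", "summary", expr="mean(Y_Z_1 - Y_Z_0)"),
            dd.declare_assignment("complete", m=15),
            dd.declare_reveal("Y", "Z"),
            dd.declare_estimator(dd.difference_in_means, "DIM",
                                 estimand="SATE", outcome="Y",
                                 assignment="Z"),
        ]
        d = dd.compose_design(steps, "sampling_bias_check")
        diag = dd.diagnose_design(
            d, [dg.get_diagnosand("sampling_bias",
                                  population_label="PATE",
                                  sample_label="SATE")],
            m=800, n_bootstrap=80, seed=21)
        row = diag.iloc[0]
        assert abs(row["estimate"]) < 3 * row["bootstrap_se"]

    def test_homogeneous_effects_degenerate(self, tiny_canonical):
        sims = dd.simulate_design(tiny_canonical, 30, seed=1)
        assert dg.sd_estimands(sims)[0] == 0.0


class TestImbalance:
    def test_identical_arms_zero(self):
        df = pd.DataFrame({"X": [1., 2., 1., 2.], "Z": [1., 1., 0., 0.]})
        assert dg.covariate_imbalance(df, ["X"], "Z") == 0.0

    def test_unit_standardized_difference(self):
        x = np.concatenate([np.zeros(50), np.ones(50)])
        x = x + np.linspace(0, 1e-9, 100)  # avoid exactly zero variance
        df = pd.DataFrame({"X": x, "Z": np.concatenate([np.zeros(50),
                                                        np.ones(50)])})
        pooled = np.std(x, ddof=1)
        expected = abs(x[50:].mean() - x[:50].mean()) / pooled
        assert dg.covariate_imbalance(df, ["X"], "Z") == pytest.approx(expected)

    def test_zero_variance_covariate_skipped(self):
        df = pd.DataFrame({"X": np.ones(10), "W": np.arange(10.0),
                           "Z": np.repeat([0., 1.], 5)})
        with pytest.warns(UserWarning):
            value = dg.covariate_imbalance(df, ["X", "W"], "Z")
        assert np.isfinite(value)


class TestRobustness:
    @staticmethod
    def joint_table(p_a, p_b):
        n = len(p_a)
        rows = []
        for i in range(n):
            rows.append({"run": i, "estimator_label": "A", "p_value": p_a[i],
                         "estimand_label": "I"})
            rows.append({"run": i, "estimator_label": "B", "p_value": p_b[i],
                         "estimand_label": "I"})
        return pd.DataFrame(rows)

    def test_singleton_set_equals_power(self):
        t = sims_table(p_value=[0.01, 0.2, 0.03])
        assert dg.robustness(t, ["E"])[0] == dg.power(t)[0]

    def test_independent_tests_multiply(self, rng):
        p_a = rng.random(2000) * np.where(rng.random(2000) < 0.5, 0.05, 1)
        p_b = rng.random(2000) * np.where(rng.random(2000) < 0.5, 0.05, 1)
        t = self.joint_table(p_a, p_b)
        joint = dg.robustness(t, ["A", "B"])[0]
        pa = np.mean(p_a <= 0.05)
        pb = np.mean(p_b <= 0.05)
        assert joint == pytest.approx(pa * pb, abs=3 * np.sqrt(0.25 / 2000) + 0.02)

    def test_unknown_label_errors(self):
        t = sims_table(p_value=[0.01])
        with pytest.raises(dd.ConfigurationError):
            dg.robustness(t, ["nope"])

    def test_always_null_member_bounds_joint(self, rng):
        p_a = rng.random(500)  # uniform null p-values
        p_b = np.full(500, 0.001)
        t = self.joint_table(p_a, p_b)
        assert dg.robustness(t, ["A", "B"])[0] <= 0.10


class TestValueForMoney:
    def test_all_positive_funded(self):
        t = sims_table(estimate=[1.0, 2.0], estimand=[1.0, 1.0])
        value, _ = dg.value_for_money(
            t, decision_rule=lambda e: e > 0, benefit_fn=lambda a: a)
        assert value == 1.0

    def test_zero_benefit_flagged(self):
        t = sims_table(estimate=[1.0], estimand=[0.0])
        value, n_flag = dg.value_for_money(
            t, decision_rule=lambda e: e > 0, benefit_fn=lambda a: a)
        assert value == 1.0 and n_flag == 1

    def test_threshold_rule_matches_hand_count(self):
        est = [0.5, 1.5, 2.5, -1.0, 3.0, 0.1, 2.1, 1.9, 2.2, -0.2]
        t = sims_table(estimate=est, estimand=[1.0] * 10)
        value, _ = dg.value_for_money(
            t, decision_rule=lambda e: e > 2.0, benefit_fn=lambda a: a)
        hand = np.mean([e > 2.0 for e in est])  # benefit>0: fund is correct
        assert value == pytest.approx(hand)


class TestPosteriorShift:
    def test_no_data_identity(self):
        row = dd.beta_binomial_posterior(0, 0, 0.5, 0.2)
        t = sims_table(estimate=[row["estimate"]])
        t["aux_posterior_sd"] = row["aux_posterior_sd"]
        t["aux_prior_mean"] = row["aux_prior_mean"]
        t["aux_prior_sd"] = row["aux_prior_sd"]
        loc, scale = dg.posterior_shift(t)
        assert loc == pytest.approx(0.0, abs=1e-12)
        assert scale == pytest.approx(1.0, abs=1e-12)

    def test_missing_auxiliary_fields_error(self):
        t = sims_table(estimate=[0.5])
        with pytest.raises(dd.ConfigurationError):
            dg.posterior_shift(t)

    def test_informative_prior_more_certain(self):
        """The informative prior yields the more certain posterior: its
        absolute posterior sd (scale ratio times its own prior sd) is
        smaller than the uniform-prior posterior sd.  Relative to its own
        prior, the informative posterior necessarily moves less, so the
        raw scale ratios order the other way."""
        d = dd.make_design("bayes_descriptive")
        diag = dd.diagnose_design(d, ["posterior_scale_ratio"], m=200,
                                  n_bootstrap=0, seed=3)
        by = dict(zip(diag["estimator_label"], diag["estimate"]))
        assert by["informative_prior"] * 0.11 < by["uniform_prior"] * 0.29
        assert by["informative_prior"] > by["uniform_prior"]


class TestRegistry:
    def test_probability_diagnosands_in_unit_interval(self, tiny_canonical):
        diag = dd.diagnose_design(tiny_canonical,
                                  ["power", "coverage"], m=60,
                                  n_bootstrap=0, seed=2)
        assert ((diag["estimate"] >= 0) & (diag["estimate"] <= 1)).all()

    def test_unknown_name_suggests_close_match(self):
        with pytest.raises(dd.ConfigurationError, match="power"):
            dd.get_diagnosand("powr")
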