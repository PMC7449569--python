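"""Step primitives: population generators, potential outcomes, sampling,
assignment allocation, measurement error, outcome revelation."""

import numpy as np
import pytest

import designdiag as dd
from designdiag.core import DataTable
from designdiag.steps import MeasurementSpec, level_suffix


def run_steps(steps, seed=0):
    """Execute data-stage steps directly and return the final DataTable."""
    rng = np.random.default_rng(seed)
    dt = DataTable()
    for step in steps:
        dt = step.transform(dt, rng) or dt
    return dt


class TestPopulation:
    def test_normal_column_mean_near_zero(self):
        dt = run_steps([dd.declare_population(
            200, {"u": {"normal": [0, 1]}})])
        assert dt.n_rows == 200
        assert abs(dt.df["u"].mean()) < 3 / np.sqrt(200)

    def test_single_row_table(self):
        dt = run_steps([dd.declare_population(1, {"u": {"normal": [0, 1]}})])
        assert dt.n_rows == 1

    def test_degenerate_bernoulli_all_ones(self):
        dt = run_steps([dd.declare_population(50, {"b": {"bernoulli": 1.0}})])
        assert (dt.df["b"] == 1.0).all()

    def test_expression_uses_earlier_columns(self):
        dt = run_steps([dd.declare_population(
            20, {"a": {"uniform": [0, 1]}, "b": "a * 2"})])
        np.testing.assert_allclose(dt.df["b"], dt.df["a"] * 2)

    def test_forward_reference_is_declaration_error(self):
        with pytest.raises(dd.DeclarationError, match="later|not yet"):
            dd.declare_population(10, {"a": "b + 1", "b": {"normal": [0, 1]}})


class TestPotentialOutcomes:
    def test_canonical_po_columns(self):
        steps = [
            dd.declare_population(10, {"u": {"normal": [0, 1]}}),
            dd.declare_potential_outcomes(
                "Y", dd.ConditionSet("Z", [0, 1]), "Z + u"),
        ]
        dt = run_steps(steps)
        np.testing.assert_allclose(dt.df["Y_Z_0"], dt.df["u"])
        np.testing.assert_allclose(dt.df["Y_Z_1"], dt.df["u"] + 1)
        assert dt.roles["Y_Z_1"] == "potential_outcome"

    def test_constant_po_identical_columns(self):
        steps = [
            dd.declare_population(10, {"u": {"normal": [0, 1]}}),
            dd.declare_potential_outcomes(
                "W", dd.ConditionSet("Z", [0, 1]), lambda df, z: np.full(10, 3.0)),
        ]
        dt = run_steps(steps)
        np.testing.assert_array_equal(dt.df["W_Z_0"], dt.df["W_Z_1"])

    def test_name_collision_rejected(self):
        steps = [
            dd.declare_population(10, {"Y_Z_0": {"normal": [0, 1]},
                                       "u": {"normal": [0, 1]}}),
            dd.declare_potential_outcomes(
                "Y", dd.ConditionSet("Z", [0, 1]), "Z + u"),
        ]
        with pytest.raises(dd.DeclarationError, match="already exists"):
            run_steps(steps)

    def test_factorial_po_four_columns(self):
        cs = dd.ConditionSet("cell", ["00", "10", "01", "11"])
        steps = [
            dd.declare_population(8, {"u": {"normal": [0, 1]}}),
            dd.declare_potential_outcomes(
                "Y", cs, lambda df, lv:
                df["u"].to_numpy() + int(lv[0]) + 2 * int(lv[1])),
        ]
        dt = run_steps(steps)
        for lv in cs.levels:
            assert f"Y_cell_{lv}" in dt.df.columns
        np.testing.assert_allclose(dt.df["Y_cell_11"] - dt.df["Y_cell_00"], 3)


class TestLinearProjection:
    def test_quadratic_on_symmetric_grid_has_unit_slope(self):
        grid = np.linspace(0, 1, 11)
        alpha, beta = dd.linear_projection_estimand(
            lambda x: np.array([x ** 2]), grid)
        # numeric-integration oracle: cov(x, x^2)/var(x) on the same grid
        f = np.full(len(grid), 1 / len(grid))
        xw = np.sum(f * grid)
        oracle = (np.sum(f * (grid - xw) * (grid ** 2 - np.sum(f * grid ** 2)))
                  / np.sum(f * (grid - xw) ** 2))
        assert beta == pytest.approx(oracle, abs=1e-12)
        assert beta == pytest.approx(1.0, abs=1e-12)

    def test_constant_outcome_zero_slope(self):
        _, beta = dd.linear_projection_estimand(
            lambda x: np.array([5.0]), [0, 0.5, 1])
        assert beta == 0.0

    def test_linear_outcome_any_density(self):
        _, beta = dd.linear_projection_estimand(
            lambda x: np.array([2 * x]), [0, 0.25, 0.5, 1],
            density=[0.1, 0.2, 0.3, 0.4])
        assert beta == pytest.approx(2.0, abs=1e-12)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(dd.DeclarationError):
            dd.linear_projection_estimand(lambda x: np.array([x]), [1, 1, 1])


class TestSampling:
    def test_simple_exact_count(self):
        steps = [dd.declare_population(200, {"u": {"normal": [0, 1]}}),
                 dd.declare_sampling("simple", n=100)]
        dt = run_steps(steps)
        assert dt.n_rows == 100 and (dt.df["S"] == 1).all()

    def test_full_sample(self):
        steps = [dd.declare_population(30, {"u": {"normal": [0, 1]}}),
                 dd.declare_sampling("simple", n=30)]
        assert run_steps(steps).n_rows == 30

    def test_oversampling_is_run_error(self):
        steps = [dd.declare_population(10, {"u": {"normal": [0, 1]}}),
                 dd.declare_sampling("simple", n=11)]
        with pytest.raises(dd.RunError):
            run_steps(steps)

    def test_stratified_every_stratum_represented(self):
        steps = [
            dd.declare_population(
                90, {"area": lambda df, rng: np.repeat([0., 1., 2.], 30)}),
            dd.declare_sampling("stratified", strata="area", n_per_stratum=5),
        ]
        dt = run_steps(steps)
        assert sorted(dt.df["area"].unique()) == [0.0, 1.0, 2.0]
        assert dt.n_rows == 15


class TestAssignment:
    def test_complete_exact_count_every_run(self):
        steps = [dd.declare_population(100, {"u": {"normal": [0, 1]}}),
                 dd.declare_assignment("complete", m=50)]
        for seed in range(5):
            dt = run_steps(steps, seed)
            assert dt.df["Z"].sum() == 50
            assert (dt.df["Z_prob"] == 0.5).all()

    def test_multi_arm_equal_thirds(self):
        steps = [dd.declare_population(99, {"u": {"normal": [0, 1]}}),
                 dd.declare_assignment("multi_arm", variable="W",
                                       arms=["c", "t1", "t2"],
                                       probs=[1 / 3] * 3)]
        dt = run_steps(steps)
        counts = dt.df["W"].value_counts()
        assert set(counts) == {33}

    def test_factorial_quarter_cells(self):
        steps = [dd.declare_population(100, {"u": {"normal": [0, 1]}}),
                 dd.declare_assignment("factorial")]
        dt = run_steps(steps)
        counts = dt.df["cell"].value_counts()
        assert set(counts) == {25}
        np.testing.assert_array_equal(
            dt.df["Z1"], [int(c[0]) for c in dt.df["cell"]])

    def test_blocked_probability_outside_unit_interval_rejected(self):
        with pytest.raises(dd.DeclarationError):
            dd.declare_assignment("blocked", block="b", probs={0: 1.5})

    def test_blocked_respects_block_probabilities(self):
        steps_f = [
            dd.declare_population(
                60, {"b": lambda df, rng: np.repeat([0., 1.], 30)}),
            dd.declare_assignment("blocked", block="b",
                                  probs={0.0: 0.2, 1.0: 0.7}),
        ]
        shares = {0.0: [], 1.0: []}
        for seed in range(400):
            dt = run_steps(steps_f, seed)
            for b in (0.0, 1.0):
                sub = dt.df[dt.df["b"] == b]
                shares[b].append(sub["Z"].mean())
        for b, p in ((0.0, 0.2), (1.0, 0.7)):
            se = np.std(shares[b], ddof=1) / np.sqrt(len(shares[b]))
            assert abs(np.mean(shares[b]) - p) < max(3 * se, 1e-9)


class TestMeasurement:
    def test_rate_zero_is_identity(self):
        steps = [dd.declare_population(50, {"x": {"bernoulli": 0.4}}),
                 dd.declare_measurement(MeasurementSpec("binary_flip", "x", 0.0))]
        dt = run_steps(steps)
        np.testing.assert_array_equal(dt.df["x_obs"], dt.df["x"])

    def test_rate_one_flips_everything(self):
        steps = [dd.declare_population(50, {"x": {"bernoulli": 0.4}}),
                 dd.declare_measurement(MeasurementSpec("binary_flip", "x", 1.0))]
        dt = run_steps(steps)
        np.testing.assert_array_equal(dt.df["x_obs"], 1 - dt.df["x"])

    def test_overreport_expected_rate(self):
        # latent rate 0.4, overreport rate 0.3 among zeros:
        # expected observed rate 0.4 + 0.6 * 0.3 = 0.58
        steps = [dd.declare_population(4000, {"x": {"bernoulli": 0.4}}),
                 dd.declare_measurement(MeasurementSpec("overreport", "x", 0.3))]
        rates = [run_steps(steps, s).df["x_obs"].mean() for s in range(30)]
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 0.58) < 3 * se

    def test_invalid_rate_rejected(self):
        with pytest.raises(dd.DeclarationError):
            MeasurementSpec("binary_flip", "x", 1.2)


class TestReveal:
    def test_reveal_selects_po_by_assignment(self):
        steps = [
            dd.declare_population(4, {
                "Y_Z_0": lambda df, rng: np.array([0., 0., 0., 0.]),
                "Y_Z_1": lambda df, rng: np.array([5., 5., 5., 5.]),
                "Z": lambda df, rng: np.array([1., 0., 1., 0.]),
            }),
            dd.declare_reveal("Y", "Z"),
        ]
        dt = run_steps(steps)
        np.testing.assert_array_equal(dt.df["Y"], [5, 0, 5, 0])

    def test_all_one_arm_equals_that_po_column(self):
        steps = [
            dd.declare_population(5, {"u": {"normal": [0, 1]}}),
            dd.declare_potential_outcomes(
                "Y", dd.ConditionSet("Z", [0, 1]), "Z * 2 + u"),
            dd.declare_population(5, {"Z": {"bernoulli": 1.0}},
                                  label="assign_all"),
        ]
        # manually wire Z then reveal
        rng = np.random.default_rng(0)
        dt = DataTable()
        for step in steps[:2]:
            dt = step.transform(dt, rng)
        dt.add("Z", np.ones(5), role="assignment")
        dt = dd.declare_reveal("Y", "Z").transform(dt, rng)
        np.testing.assert_array_equal(dt.df["Y"], dt.df["Y_Z_1"])

    def test_missing_po_level_is_run_error(self):
        rng = np.random.default_rng(0)
        dt = DataTable()
        dt = dd.declare_population(
            5, {"Y_Z_0": {"normal": [0, 1]}}).transform(dt, rng)
        dt.add("Z", np.array([0., 0., 1., 0., 0.]), role="assignment")
        with pytest.raises(dd.RunError, match="Y_Z_1"):
            dd.declare_reveal("Y", "Z").transform(dt, rng)

    def test_reveal_invariant_to_po_declaration_order(self):
        cs01 = dd.ConditionSet("Z", [0, 1])
        cs10 = dd.ConditionSet("Z", [1, 0])
        out = {}
        for key, cs in (("01", cs01), ("10", cs10)):
            rng = np.random.default_rng(3)
            dt = dd.declare_population(
                20, {"u": {"normal": [0, 1]}}).transform(DataTable(), rng)
            dt = dd.declare_potential_outcomes("Y", cs, "Z + u"
                                               ).transform(dt, rng)
            dt.add("Z", np.repeat([0., 1.], 10), role="assignment")
            dt = dd.declare_reveal("Y", "Z").transform(dt, rng)
            out[key] = dt.df["Y"].to_numpy()
        np.testing.assert_array_equal(out["01"], out["10"])


def test_level_suffix_canonical_forms():
    assert level_suffix(0) == "0"
    assert level_suffix(1.0) == "1"
    assert level_suffix(0.5) == "0.5"
    assert level_suffix("both") == "both"
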