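"""A catalogue of fully declared designs, from textbook experiments to
qualitative strategies and a truncation-by-death replication.

Every entry is a parameterized factory returning a ready-to-run
:class:`~designdiag.core.Design`; defaults are documented illustrative
magnitudes (effect sizes, noise SDs, baseline rates) chosen to put each
design in the regime it is meant to study -- e.g. heterogeneous
assignment probabilities strong enough that unweighted estimators are
visibly biased, or cluster counts at which a mortality effect is
detectable only part of the time.  See ``docs/methods.md`` for the
reasoning behind each default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (DataTable, DeclarationError, Design, RunError, Step,
                   compose_design)
from .estimators import (beta_binomial_posterior, declare_estimator,
                         difference_in_means, ipw_weights, matching_att,
                         ols, rd_polynomial_fit, split_sample_answer)
from .qualitative import (DNFExpression, LikelihoodTable, build_truth_table,
                          expression_equal, joint_cpo_distribution,
                          pt_posterior, qmc_minimize, regression_qca)
from .steps import (ConditionSet, MeasurementSpec, declare_assignment,
                    declare_inquiry, declare_measurement, declare_population,
                    declare_potential_outcomes, declare_reveal,
                    declare_sampling, declare_step)

__all__ = [
    "CatalogueError",
    "SchemaError",
    "DesignCatalogEntry",
    "CATALOGUE",
    "available_designs",
    "describe_design",
    "make_design",
    "truncation_replication_design",
    "blocked_model_steps",
    "factorial_model_steps",
]


class CatalogueError(KeyError):
    """Unknown catalogue entry."""


class SchemaError(ValueError):
    """A design parameter is unknown or outside its allowed range."""


@dataclass
class ParamSpec:
    default: Any
    kind: str = "float"  # float | int | str | list | bool
    bounds: tuple | None = None
    choices: tuple | None = None
    help: str = ""

    def validate(self, name: str, value):
        if self.choices is not None and value not in self.choices:
            raise SchemaError(
                f"parameter {name!r}={value!r} not in {self.choices}")
        if self.bounds is not None:
            lo, hi = self.bounds
            if not (lo <= value <= hi):
                raise SchemaError(
                    f"parameter {name!r}={value!r} outside [{lo}, {hi}]")
        return value


@dataclass
class DesignCatalogEntry:
    """A named, parameterized design factory with a parameter schema."""

    name: str
    builder: Callable[..., Design]
    schema: dict[str, ParamSpec] = field(default_factory=dict)
    description: str = ""

    def build(self, **params) -> Design:
        unknown = set(params) - set(self.schema)
        if unknown:
            raise SchemaError(
                f"unknown parameter(s) {sorted(unknown)} for design "
                f"{self.name!r}; known: {sorted(self.schema)}")
        merged = {k: spec.default for k, spec in self.schema.items()}
        merged.update(params)
        for k, v in merged.items():
            self.schema[k].validate(k, v)
        design = self.builder(**merged)
        design.name = self.name
        design.params = merged
        return design

    def schema_json(self) -> dict:
        return {k: {"default": s.default, "type": s.kind,
                    "bounds": s.bounds, "choices": s.choices, "help": s.help}
                for k, s in self.schema.items()}


CATALOGUE: dict[str, DesignCatalogEntry] = {}


def _entry(name, schema, description=""):
    def wrap(fn):
        CATALOGUE[name] = DesignCatalogEntry(name, fn, schema, description)
        return fn
    return wrap


def available_designs() -> list[str]:
    return sorted(CATALOGUE)


def describe_design(name: str) -> DesignCatalogEntry:
    if name not in CATALOGUE:
        raise CatalogueError(
            f"unknown design {name!r}; available: {available_designs()}")
    return CATALOGUE[name]


def make_design(name: str, **params) -> Design:
    """Build a catalogue design by name with validated parameters."""
    return describe_design(name).build(**params)


# ---------------------------------------------------------------------------
# canonical two-arm experiment

@_entry("table3_canonical", {
    "n_pop": ParamSpec(200, "int", (2, 10 ** 6)),
    "n_samp": ParamSpec(100, "int", (2, 10 ** 6)),
    "m_treat": ParamSpec(50, "int", (1, 10 ** 6)),
    "effect": ParamSpec(1.0, "float"),
}, "Two-arm experiment: N units with standard-normal noise, a constant "
   "additive treatment effect, simple sampling, complete assignment, and a "
   "difference-in-means answer targeting the average treatment effect.")
def _table3_canonical(n_pop, n_samp, m_treat, effect):
    if n_samp > n_pop or m_treat > n_samp:
        raise SchemaError("need m_treat <= n_samp <= n_pop")
    cs = ConditionSet("Z", [0, 1])
    steps = [
        declare_population(n_pop, {"u": {"normal": [0, 1]}}),
        declare_potential_outcomes(
            "Y", cs, lambda df, z: df["u"].to_numpy() + effect * z),
        declare_inquiry("ATE", "summary", expr="mean(Y_Z_1 - Y_Z_0)"),
        declare_sampling("simple", n=n_samp),
        declare_assignment("complete", m=m_treat),
        declare_reveal("Y", "Z"),
        declare_estimator(difference_in_means, "DIM", estimand="ATE",
                          outcome="Y", assignment="Z"),
    ]
    return compose_design(steps, "table3_canonical")


# ---------------------------------------------------------------------------
# confounded regression

@_entry("confounded_regression", {
    "b": ParamSpec(0.0, "float"),
    "n": ParamSpec(10000, "int", (10, 10 ** 6)),
}, "Observational model Y = b X + Z + e_Y with X = Z + e_X (all noise "
   "standard normal): regressing Y on X alone suffers omitted-variable "
   "bias cov(X, Z)/var(X) = 1/2; conditioning on Z removes it.")
def _confounded_regression(b, n):
    steps = [
        declare_population(n, {
            "Z": {"normal": [0, 1]},
            "eps_X": {"normal": [0, 1]},
            "eps_Y": {"normal": [0, 1]},
            "X": "Z + eps_X",
            "Y": f"{b} * (Z + eps_X) + Z + eps_Y",
        }),
        declare_inquiry("effect_of_X", "summary", fn=lambda df: b),
        declare_estimator(ols, "ols_unadjusted", estimand="effect_of_X",
                          outcome="Y", regressors=["X"], target="X"),
        declare_estimator(ols, "ols_adjusted", estimand="effect_of_X",
                          outcome="Y", regressors=["X", "Z"], target="X"),
    ]
    return compose_design(steps, "confounded_regression")


# ---------------------------------------------------------------------------
# blocked experiment with heterogeneous assignment probabilities

_BLOCK_SIZES = (40, 80, 120, 160, 200)
_BLOCK_PROBS = (0.5, 0.4, 0.3, 0.15, 0.05)
_BLOCK_EFFECTS = (0.1, 0.3, 0.5, 0.7, 0.9)


def blocked_model_steps(block_sizes=_BLOCK_SIZES, block_probs=_BLOCK_PROBS,
                        block_effects=_BLOCK_EFFECTS, noise_sd=2.0
                        ) -> list[Step]:
    """Model steps for the blocked design: block-varying effect sizes
    (correlated with block size) and a unit noise term.  Pass constant
    ``block_effects`` to obtain the constant-effects alternative model."""
    sizes = tuple(int(s) for s in block_sizes)
    effects = dict(enumerate(block_effects))

    def populate(dt: DataTable, rng) -> DataTable:
        n = sum(sizes)
        block = np.repeat(np.arange(len(sizes)), sizes)
        out = DataTable(pd.DataFrame(index=range(n)))
        out.add("block", block.astype(float))
        out.add("u", rng.normal(0, noise_sd, size=n))
        out.add("tau", np.array([effects[int(b)] for b in block]))
        return out

    cs = ConditionSet("Z", [0, 1])
    return [
        declare_step("population", "population", populate),
        declare_potential_outcomes(
            "Y", cs,
            lambda df, z: df["u"].to_numpy() + df["tau"].to_numpy() * z),
    ]


def _ipw_bfe(df, outcome, assignment, prob_column, blocks):
    # conventional weighted-least-squares uncertainty: the common practice
    # of plugging IPW weights into a weighted regression and reading off
    # its model-based variance, which mistakes them for precision weights
    work = df.copy()
    work["_w"] = ipw_weights(work, assignment, prob_column)
    return ols(work, outcome, [assignment], target=assignment,
               weights="_w", blocks=blocks, cov="classical")


@_entry("blocked_hetero", {
    "block_sizes": ParamSpec(list(_BLOCK_SIZES), "list"),
    "block_probs": ParamSpec(list(_BLOCK_PROBS), "list"),
    "block_effects": ParamSpec(list(_BLOCK_EFFECTS), "list"),
    "noise_sd": ParamSpec(2.0, "float", (0.0, 100.0)),
    "estimators": ParamSpec(["DIM", "BFE", "BFE_IPW"], "list"),
}, "Blocked experiment in which assignment probabilities are heterogeneous "
   "by block and effect sizes correlate with block size, so unweighted "
   "answers (difference in means, block fixed effects) are biased for the "
   "average treatment effect while inverse-probability-weighted block "
   "fixed effects are not -- at a price in variance and CI calibration.")
def _blocked_hetero(block_sizes, block_probs, block_effects, noise_sd,
                    estimators):
    if not (len(block_sizes) == len(block_probs) == len(block_effects)):
        raise SchemaError("block_sizes, block_probs, block_effects must "
                          "have equal length")
    steps = blocked_model_steps(block_sizes, block_probs, block_effects,
                                noise_sd)
    steps += [
        declare_inquiry("ATE", "summary", expr="mean(Y_Z_1 - Y_Z_0)"),
        declare_assignment("blocked", block="block",
                           probs={float(i): p
                                  for i, p in enumerate(block_probs)}),
        declare_reveal("Y", "Z"),
    ]
    answers = {
        "DIM": declare_estimator(difference_in_means, "DIM", estimand="ATE",
                                 outcome="Y", assignment="Z"),
        "BFE": declare_estimator(ols, "BFE", estimand="ATE", outcome="Y",
                                 regressors=["Z"], target="Z",
                                 blocks="block"),
        "BFE_IPW": declare_estimator(_ipw_bfe, "BFE_IPW", estimand="ATE",
                                     outcome="Y", assignment="Z",
                                     prob_column="Z_prob", blocks="block"),
    }
    for label in estimators:
        if label not in answers:
            raise SchemaError(f"unknown estimator {label!r}")
        steps.append(answers[label])
    return compose_design(steps, "blocked_hetero")


# ---------------------------------------------------------------------------
# factorial vs three-arm

def factorial_model_steps(b1=0.3, b2=0.3, interaction=0.0, noise_sd=1.0,
                          n=96, arms=("00", "10", "01", "11")) -> list[Step]:
    """Model steps for the two-treatment experiment over cell labels
    "00"/"10"/"01"/"11" (treatment 1 then treatment 2)."""
    cs = ConditionSet("cell", list(arms))

    def po(df, level):
        z1, z2 = int(level[0]), int(level[1])
        return (df["u"].to_numpy() + b1 * z1 + b2 * z2
                + interaction * z1 * z2)

    return [
        declare_population(n, {"u": {"normal": [0, noise_sd]}}),
        declare_potential_outcomes("Y", cs, po),
    ]


@_entry("factorial_vs_three_arm", {
    "arm_scheme": ParamSpec("factorial", "str",
                            choices=("factorial", "three_arm")),
    "interaction": ParamSpec(0.0, "float", (-0.5, 0.5)),
    "b1": ParamSpec(0.3, "float"),
    "b2": ParamSpec(0.3, "float"),
    "noise_sd": ParamSpec(1.0, "float", (0.0, 100.0)),
    "n": ParamSpec(96, "int", (8, 10 ** 6)),
}, "Two treatments, inquiry: the effect of treatment 1 with treatment 2 at "
   "control.  The factorial data strategy assigns the four cells with "
   "probability 1/4 each; the three-arm strategy drops the 'both' cell and "
   "assigns the rest with probability 1/3.  The answer regresses the "
   "outcome on both treatment indicators without an interaction, so the "
   "factorial answer absorbs half the interaction as bias.")
def _factorial_vs_three_arm(arm_scheme, interaction, b1, b2, noise_sd, n):
    arms = ("00", "10", "01", "11") if arm_scheme == "factorial" else \
        ("00", "10", "01")
    steps = factorial_model_steps(b1, b2, interaction, noise_sd, n, arms)
    steps.append(declare_inquiry(
        "ATE1_ctrl2", "summary", expr="mean(Y_cell_10 - Y_cell_00)"))
    if arm_scheme == "factorial":
        steps.append(declare_assignment("factorial",
                                        variables=("Z1", "Z2"),
                                        cell_name="cell"))
    else:
        steps.append(declare_assignment(
            "multi_arm", variable="cell", arms=list(arms),
            probs=[1 / 3, 1 / 3, 1 / 3]))

        def indicators(dt: DataTable, rng):
            out = DataTable(dt.df.copy(), dict(dt.roles))
            out.add("Z1", out.df["cell_10"].to_numpy(dtype=float),
                    role="assignment")
            out.add("Z2", out.df["cell_01"].to_numpy(dtype=float),
                    role="assignment")
            return out

        steps.append(declare_step("indicators", "measurement", indicators))
    steps += [
        declare_reveal("Y", "cell"),
        declare_estimator(ols, "ols_main_effects", estimand="ATE1_ctrl2",
                          outcome="Y", regressors=["Z1", "Z2"],
                          target="Z1"),
    ]
    return compose_design(steps, f"factorial_vs_three_arm[{arm_scheme}]")


# ---------------------------------------------------------------------------
# process tracing

@_entry("process_tracing", {
    "prior": ParamSpec(0.5, "float", (0.0, 1.0)),
    "p1_h": ParamSpec(0.75, "float", (0.0, 1.0)),
    "p1_nh": ParamSpec(0.25, "float", (0.0, 1.0)),
    "p2_h": ParamSpec(0.30, "float", (0.0, 1.0)),
    "p2_nh": ParamSpec(0.05, "float", (0.0, 1.0)),
    "rho": ParamSpec(0.0, "float", (-1.0, 1.0)),
    "strategy": ParamSpec("cpo1_only", "str",
                          choices=("cpo1_only", "cpo2_only", "both")),
}, "A single case selected because X and Y are both present; the "
   "hypothesis that X caused Y holds with the prior probability.  Two "
   "causal-process observations are available -- a straw-in-the-wind "
   "(0.75/0.25) and a smoking gun (0.30/0.05), possibly correlated -- and "
   "the answer is the Bayesian posterior from the sought clue(s).")
def _process_tracing(prior, p1_h, p1_nh, p2_h, p2_nh, rho, strategy):
    table = LikelihoodTable((p1_h, p2_h), (p1_nh, p2_nh),
                            rho if rho else None)
    sought = {"cpo1_only": (0,), "cpo2_only": (1,), "both": (0, 1)}[strategy]

    def populate(dt: DataTable, rng) -> DataTable:
        h = bool(rng.random() < prior)
        joint = joint_cpo_distribution(table)
        patterns = sorted(joint[h])
        probs = np.array([joint[h][p] for p in patterns])
        pick = patterns[rng.choice(len(patterns), p=probs / probs.sum())]
        out = DataTable(pd.DataFrame(index=[0]))
        out.add("H", [float(h)])
        out.add("E1", [float(pick[0])])
        out.add("E2", [float(pick[1])])
        return out

    def posterior(df, rng=None):
        observed: list = [None, None]
        for idx in sought:
            observed[idx] = int(df[f"E{idx + 1}"].iloc[0])
        est = pt_posterior(prior, table, observed)
        return {"estimate": float(est)}

    steps = [
        declare_step("case", "population", populate),
        declare_inquiry("H", "summary", expr="mean(H)"),
        declare_estimator(posterior, f"posterior_{strategy}", estimand="H"),
    ]
    return compose_design(steps, f"process_tracing[{strategy}]")


# ---------------------------------------------------------------------------
# crisp-set QCA

@_entry("qca_crisp", {
    "truth": ParamSpec("aB", "str"),
    "causes": ParamSpec(["A", "B"], "list"),
    "n": ParamSpec(100, "int", (4, 10 ** 6)),
    "error_rate": ParamSpec(0.0, "float", (0.0, 1.0)),
    "answer": ParamSpec("qmc", "str", choices=("qmc", "regression")),
}, "Crisp-set QCA: binary causes drawn uniformly, the outcome present "
   "exactly where the generating configuration holds (default: first "
   "cause absent AND second present), optional outcome measurement error; "
   "the answer minimizes the observed truth table (Quine-McCluskey) or "
   "codes configurations by a saturated regression, and records whether "
   "the recovered expression equals the generating one.")
def _qca_crisp(truth, causes, n, error_rate, answer):
    causes = tuple(causes)
    dnf = (truth if isinstance(truth, DNFExpression)
           else DNFExpression.from_string(truth, causes))

    def populate(dt: DataTable, rng) -> DataTable:
        out = DataTable(pd.DataFrame(index=range(n)))
        for c in causes:
            out.add(c, (rng.random(n) < 0.5).astype(float))
        y = np.array([float(dnf.evaluate(row))
                      for row in out.df[list(causes)].to_numpy()])
        out.add("Y", y)
        return out

    def recover(df, rng=None):
        if answer == "qmc":
            expr = qmc_minimize(build_truth_table(df, causes, "Y_obs"),
                                remainder_policy="exclude")
        else:
            expr = regression_qca(df, causes, "Y_obs")
        try:
            hit = expression_equal(expr, dnf)
        except ValueError:
            hit = False
        return {"estimate": float(hit), "aux_expression": expr.render()}

    steps = [
        declare_step("cases", "population", populate),
        declare_measurement(MeasurementSpec("binary_flip", "Y", error_rate)),
        declare_inquiry("configuration", "qca_configuration", dnf=dnf),
        declare_estimator(recover, f"qca_{answer}", estimand="configuration"),
    ]
    return compose_design(steps, f"qca_crisp[{answer}]")


# ---------------------------------------------------------------------------
# likely-voter survey

def _proportion_row(x: np.ndarray, alpha: float = 0.05) -> dict:
    n = len(x)
    p = float(np.mean(x))
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n)) if n > 1 else float("nan")
    z = sps.norm.ppf(1 - alpha / 2)
    return {"estimate": p, "std_error": se,
            "p_value": float(2 * sps.norm.sf(abs(p / se))) if se else 1.0,
            "ci_low": p - z * se, "ci_high": p + z * se, "df": float("nan"),
            "aux_n": float(n)}


@_entry("likely_voter_survey", {
    "n_pop": ParamSpec(10000, "int", (100, 10 ** 7)),
    "n_samp": ParamSpec(1000, "int", (10, 10 ** 6)),
    "turnout_rate": ParamSpec(0.5, "float", (0.01, 0.99)),
    "support_voters": ParamSpec(0.55, "float", (0.0, 1.0)),
    "support_nonvoters": ParamSpec(0.40, "float", (0.0, 1.0)),
    "overreport_rate": ParamSpec(0.3, "float", (0.0, 1.0)),
}, "Survey estimator of candidate support among likely voters: latent "
   "turnout and support are correlated, and non-voters overstate their "
   "propensity to vote at the overreport rate, so the likely-voter screen "
   "admits non-voters and biases estimated support toward their level.  "
   "The misreporting magnitudes are illustrative, exposed parameters.")
def _likely_voter_survey(n_pop, n_samp, turnout_rate, support_voters,
                         support_nonvoters, overreport_rate):
    def support(df, rng):
        p = np.where(df["V"].to_numpy() == 1, support_voters,
                     support_nonvoters)
        return (rng.random(len(df)) < p).astype(float)

    def likely_voter_mean(df, rng=None):
        mask = df["V_obs"].to_numpy() == 1
        if mask.sum() == 0:
            raise RunError("no respondents report being likely voters")
        return _proportion_row(df.loc[mask, "support"].to_numpy())

    steps = [
        declare_population(n_pop, {"V": {"bernoulli": turnout_rate},
                                   "support": support}),
        declare_inquiry("support_among_voters", "summary",
                        fn=lambda df: float(
                            df.loc[df["V"] == 1, "support"].mean())),
        declare_sampling("simple", n=n_samp),
        declare_measurement(MeasurementSpec("overreport", "V",
                                            overreport_rate)),
        declare_estimator(likely_voter_mean, "likely_voter_mean",
                          estimand="support_among_voters"),
    ]
    return compose_design(steps, "likely_voter_survey")


# ---------------------------------------------------------------------------
# Bayesian descriptive inference

@_entry("bayes_descriptive", {
    "n": ParamSpec(20, "int", (1, 10 ** 5)),
    "prior_mean": ParamSpec(0.5, "float", (0.01, 0.99)),
    "prior_sd_uniform": ParamSpec(0.29, "float", (0.001, 0.5)),
    "prior_sd_informative": ParamSpec(0.11, "float", (0.001, 0.5)),
}, "A latent probability of success (drawn uniformly each run) generates "
   "one binomial draw per unit for a small sample; two answer strategies "
   "report the beta-binomial posterior mean under a near-uniform prior "
   "(mean 0.50, sd 0.29) and an informative prior concentrated at 0.50 "
   "(sd 0.11).  The informative prior yields more certain and, away from "
   "0.50, more biased inferences.")
def _bayes_descriptive(n, prior_mean, prior_sd_uniform, prior_sd_informative):
    def populate(dt: DataTable, rng) -> DataTable:
        pi = rng.random()
        out = DataTable(pd.DataFrame(index=range(n)))
        out.add("pi", np.full(n, pi))
        out.add("y", (rng.random(n) < pi).astype(float))
        return out

    def bayes(df, prior_sd, rng=None):
        return beta_binomial_posterior(int(df["y"].sum()), len(df),
                                       prior_mean, prior_sd)

    steps = [
        declare_step("population", "population", populate),
        declare_inquiry("pi", "summary", fn=lambda df: float(df["pi"].iloc[0])),
        declare_estimator(bayes, "uniform_prior", estimand="pi",
                          prior_sd=prior_sd_uniform),
        declare_estimator(bayes, "informative_prior", estimand="pi",
                          prior_sd=prior_sd_informative),
    ]
    return compose_design(steps, "bayes_descriptive")


# ---------------------------------------------------------------------------
# nonlinear regression and the linear-projection estimand

_X_GRID = [round(i / 10, 1) for i in range(11)]


@_entry("nonlinear_regression", {
    "po_expr": ParamSpec("x ** 2", "str"),
    "n": ParamSpec(500, "int", (10, 10 ** 6)),
    "noise_sd": ParamSpec(0.5, "float", (0.0, 100.0)),
    "assignment_probs": ParamSpec(None, "list"),
}, "The outcome is a nonlinear function of a condition x on a grid over "
   "[0, 1]; the estimand is the slope of the linear projection of the "
   "potential outcomes on x under a uniform density of interest.  OLS of "
   "the realized data recovers it without bias when x is assigned "
   "uniformly, and loses unbiasedness when assignment probabilities "
   "differ across x.")
def _nonlinear_regression(po_expr, n, noise_sd, assignment_probs):
    grid = _X_GRID
    if assignment_probs is None:
        probs = [1 / len(grid)] * len(grid)
    else:
        if len(assignment_probs) != len(grid):
            raise SchemaError(
                f"assignment_probs needs {len(grid)} entries (grid {grid})")
        total = float(sum(assignment_probs))
        probs = [p / total for p in assignment_probs]
    cs = ConditionSet("x", grid)
    steps = [
        declare_population(n, {"u": {"normal": [0, noise_sd]}}),
        declare_potential_outcomes("Y", cs, po_expr + " + u"),
        declare_inquiry("beta", "linear_projection", outcome="Y",
                        variable="x", levels=grid),
        declare_assignment("multi_arm", variable="x", arms=grid,
                           probs=probs),
        declare_reveal("Y", "x"),
        declare_estimator(ols, "ols_linear", estimand="beta",
                          outcome="Y", regressors=["x"], target="x"),
    ]
    return compose_design(steps, "nonlinear_regression")


# ---------------------------------------------------------------------------
# matching on observables

@_entry("matching_probit", {
    "n": ParamSpec(400, "int", (20, 10 ** 6)),
    "tau": ParamSpec(1.0, "float"),
    "match_covariates": ParamSpec(["X1", "X2"], "list"),
    "noise_sd": ParamSpec(1.0, "float", (0.0, 100.0)),
}, "Three observed covariates drive treatment through a probit process "
   "and all three raise the outcome.  The inquiry is the effect on the "
   "treated; answers are Mahalanobis matching on a covariate subset "
   "(default: the third confounder withheld, so matching reduces MSE "
   "relative to the naive comparison yet remains biased) and the naive "
   "difference in means.")
def _matching_probit(n, tau, match_covariates, noise_sd):
    def treat(df, rng):
        index = 0.5 * (df["X1"] + df["X2"] + df["X3"]).to_numpy()
        return (rng.random(len(df)) < sps.norm.cdf(index)).astype(float)

    cs = ConditionSet("Z", [0, 1])
    steps = [
        declare_population(n, {
            "X1": {"normal": [0, 1]}, "X2": {"normal": [0, 1]},
            "X3": {"normal": [0, 1]}, "u": {"normal": [0, noise_sd]},
            "Z": treat,
        }),
        declare_potential_outcomes(
            "Y", cs, lambda df, z:
            (df["X1"] + df["X2"] + df["X3"] + df["u"]).to_numpy() + tau * z),
        declare_inquiry("ATT", "summary", fn=lambda df: float(
            (df.loc[df["Z"] == 1, "Y_Z_1"]
             - df.loc[df["Z"] == 1, "Y_Z_0"]).mean())),
        declare_reveal("Y", "Z"),
        declare_estimator(matching_att, "matching", estimand="ATT",
                          outcome="Y", treatment="Z",
                          covariates=list(match_covariates)),
        declare_estimator(difference_in_means, "naive_dim", estimand="ATT",
                          outcome="Y", assignment="Z"),
    ]
    return compose_design(steps, "matching_probit")


# ---------------------------------------------------------------------------
# regression discontinuity

@_entry("rd_polynomial", {
    "n": ParamSpec(1000, "int", (50, 10 ** 6)),
    "tau": ParamSpec(0.5, "float"),
    "cutoff": ParamSpec(0.0, "float", (-0.9, 0.9)),
    "noise_sd": ParamSpec(0.3, "float", (0.0, 100.0)),
}, "Sharp regression discontinuity: a running variable on [-1, 1], "
   "treatment for units at or above the cutoff, curved potential-outcome "
   "functions, and an answer regressing the outcome on treatment "
   "interacted with a fourth-order polynomial of the running variable.  "
   "The estimand is the jump between the two conditional-expectation "
   "functions at the cutoff.")
def _rd_polynomial(n, tau, cutoff, noise_sd):
    f0 = lambda x: x + 0.5 * x ** 2 - 0.25 * x ** 3  # noqa: E731
    f1 = lambda x: f0(x) + tau + 0.25 * x  # noqa: E731
    cs = ConditionSet("Z", [0, 1])

    def po(df, z):
        x = df["x"].to_numpy()
        base = f1(x) if z == 1 else f0(x)
        return base + df["u"].to_numpy()

    def assign(dt: DataTable, rng):
        out = DataTable(dt.df.copy(), dict(dt.roles))
        out.add("Z", (out.df["x"].to_numpy() >= cutoff).astype(float),
                role="assignment")
        return out

    steps = [
        declare_population(n, {"x": {"uniform": [-1, 1]},
                               "u": {"normal": [0, noise_sd]}}),
        declare_potential_outcomes("Y", cs, po),
        declare_inquiry("jump_at_cutoff", "rd_limit", cutoff=cutoff,
                        control_fn=f0, treat_fn=f1),
        declare_step("assignment", "assignment", assign),
        declare_reveal("Y", "Z"),
        declare_estimator(rd_polynomial_fit, "rd_poly4",
                          estimand="jump_at_cutoff", outcome="Y",
                          treatment="Z", running="x", cutoff=cutoff,
                          order=4),
    ]
    return compose_design(steps, "rd_polynomial")


# ---------------------------------------------------------------------------
# split-sample discovery

@_entry("split_sample_discovery", {
    "n": ParamSpec(400, "int", (20, 10 ** 6)),
    "tau": ParamSpec(0.3, "float"),
    "moderator_effect": ParamSpec(0.5, "float"),
    "n_moderators": ParamSpec(3, "int", (1, 10)),
    "split_fraction": ParamSpec(0.5, "float", (0.05, 0.95)),
    "alpha": ParamSpec(0.05, "float", (0.001, 0.5)),
}, "Discovery-oriented experiment: several binary candidate moderators, "
   "of which only the first truly modifies the treatment effect.  The "
   "principled answer searches for an interaction on a random training "
   "half and re-estimates the selected interaction on the holdout; the "
   "unprincipled analogue selects and estimates on the full data, "
   "inflating the discovered interaction.")
def _split_sample_discovery(n, tau, moderator_effect, n_moderators,
                            split_fraction, alpha):
    mods = [f"W{k + 1}" for k in range(n_moderators)]
    gens: dict[str, Any] = {w: {"bernoulli": 0.5} for w in mods}
    gens["u"] = {"normal": [0, 1]}
    cs = ConditionSet("Z", [0, 1])
    steps = [
        declare_population(n, gens),
        declare_potential_outcomes(
            "Y", cs, lambda df, z: df["u"].to_numpy()
            + z * (tau + moderator_effect * df["W1"].to_numpy())),
        declare_inquiry("interaction_W1", "summary",
                        fn=lambda df: moderator_effect),
        declare_assignment("complete", m=n // 2),
        declare_reveal("Y", "Z"),
        declare_estimator(split_sample_answer, "split_sample",
                          estimand="interaction_W1", outcome="Y",
                          treatment="Z", moderators=mods,
                          split_fraction=split_fraction, alpha=alpha),
    ]
    return compose_design(steps, "split_sample_discovery")


# ---------------------------------------------------------------------------
# truncation-by-death replication

_CBO_ANSWERS = ("cbo_ignore", "cbo_include", "cbo_include_if_imbalanced",
                "cbo_include_interaction")
_WEIGHT_ANSWERS = ("naive_survivors", "always_survivor_subset")


def _cluster_frame(df: pd.DataFrame) -> pd.DataFrame:
    cl = df["cluster"].to_numpy().astype(int)
    ids, first = np.unique(cl, return_index=True)
    idx = np.searchsorted(ids, cl)
    counts = np.bincount(idx)
    alive = np.bincount(idx, weights=df["alive"].to_numpy()) / counts
    return pd.DataFrame({"cluster": ids.astype(float), "alive": alive,
                         "Z": df["Z"].to_numpy()[first],
                         "CBO": df["CBO"].to_numpy()[first]})


def _cbo_strategy(df, strategy, rng=None):
    cl = _cluster_frame(df)
    if strategy == "cbo_ignore":
        return ols(cl, "alive", ["Z"], target="Z")
    if strategy == "cbo_include":
        return ols(cl, "alive", ["Z", "CBO"], target="Z")
    if strategy == "cbo_include_if_imbalanced":
        bal = difference_in_means(cl, "CBO", "Z")
        p = bal["p_value"]
        if np.isfinite(p) and p <= 0.05:
            row = ols(cl, "alive", ["Z", "CBO"], target="Z")
            row["aux_included_cbo"] = 1.0
        else:
            row = ols(cl, "alive", ["Z"], target="Z")
            row["aux_included_cbo"] = 0.0
        return row
    if strategy == "cbo_include_interaction":
        work = cl.copy()
        work["ZxCBO"] = work["Z"] * work["CBO"]
        return ols(work, "alive", ["Z", "CBO", "ZxCBO"], target="Z")
    raise ValueError(strategy)


def _weight_strategy(df, strategy, rng=None):
    alive = df["alive"].to_numpy() == 1
    sub = df.loc[alive]
    if strategy == "always_survivor_subset":
        sub = sub.loc[sub["age_old"] == 1]
    if sub.empty or sub["Z"].nunique() < 2:
        raise RunError("no surviving units in one of the arms")
    return difference_in_means(sub, "weight", "Z")


def truncation_replication_design(n_clusters: int = 50,
                                  households_per_cluster: int = 20,
                                  survival_shift: float = 0.6,
                                  weight_effect: float = 0.2,
                                  health_weight_corr: float = 1.0,
                                  community_sd: float = 0.4,
                                  survival_threshold: float = -1.38,
                                  cbo_share: float = 0.56,
                                  cbo_health_coef: float = 0.0,
                                  answers: Sequence[str] | None = None
                                  ) -> Design:
    """Cluster-randomized community-monitoring design with truncation by death.

    Latent community health (cluster level, optionally correlated with the
    presence of a community-based organisation, CBO) and family health
    jointly determine both whether infants survive and their
    weight-for-age.  Treatment saves marginal low-health infants -- only
    among the young stratum, so older infants' survival is
    treatment-independent -- which makes the naive survivor comparison of
    weights biased downward.  Estimands: the cluster-level survival effect
    and the weight effect among always-survivors.  Answer strategies: the
    naive survivor comparison and the always-survivor (older-stratum)
    subset for weight; and for the survival effect, four replicator
    strategies that ignore CBO presence, include it, include it only when
    significantly imbalanced at the 0.05 level, or include it plus its
    interaction with treatment.
    """
    if n_clusters < 4:
        raise SchemaError("need at least 4 clusters")
    answers = tuple(answers) if answers is not None else \
        _WEIGHT_ANSWERS + _CBO_ANSWERS

    def populate(dt: DataTable, rng) -> DataTable:
        k, hh = int(n_clusters), int(households_per_cluster)
        n = k * hh
        cluster = np.repeat(np.arange(k), hh)
        cbo = (rng.random(k) < cbo_share).astype(float)
        community = (rng.normal(0, community_sd, size=k)
                     + cbo_health_coef * (cbo - cbo_share))
        family = rng.normal(0, 1, size=n)
        health = community[cluster] + family
        out = DataTable(pd.DataFrame(index=range(n)))
        out.add("cluster", cluster.astype(float))
        out.add("CBO", cbo[cluster])
        out.add("health", health)
        out.add("age_old", (rng.random(n) < 0.5).astype(float))
        out.add("weight_noise", rng.normal(0, 1, size=n))
        return out

    def po(dt: DataTable, rng) -> DataTable:
        out = DataTable(dt.df.copy(), dict(dt.roles))
        h = out.df["health"].to_numpy()
        old = out.df["age_old"].to_numpy() == 1
        alive0 = (h > survival_threshold).astype(float)
        alive1 = np.where(old, alive0,
                          (h > survival_threshold - survival_shift)
                          .astype(float))
        out.add("alive_Z_0", alive0, role="potential_outcome")
        out.add("alive_Z_1", alive1, role="potential_outcome")
        base = health_weight_corr * h + out.df["weight_noise"].to_numpy()
        out.add("weight_Z_0", base, role="potential_outcome")
        out.add("weight_Z_1", base + weight_effect, role="potential_outcome")
        return out

    def reveal(dt: DataTable, rng) -> DataTable:
        out = DataTable(dt.df.copy(), dict(dt.roles))
        z = out.df["Z"].to_numpy()
        alive = np.where(z == 1, out.df["alive_Z_1"], out.df["alive_Z_0"])
        weight = np.where(z == 1, out.df["weight_Z_1"], out.df["weight_Z_0"])
        out.add("alive", alive, role="realized")
        out.add("weight", np.where(alive == 1, weight, np.nan),
                role="realized")
        return out

    def survival_ate(df) -> float:
        cl = df["cluster"].to_numpy().astype(int)
        ids = np.unique(cl)
        idx = np.searchsorted(ids, cl)
        counts = np.bincount(idx)
        diff = (df["alive_Z_1"].to_numpy() - df["alive_Z_0"].to_numpy())
        return float((np.bincount(idx, weights=diff) / counts).mean())

    def sace_weight(df) -> float:
        always = (df["alive_Z_0"] == 1) & (df["alive_Z_1"] == 1)
        sub = df.loc[always]
        return float((sub["weight_Z_1"] - sub["weight_Z_0"]).mean())

    steps: list[Step] = [
        declare_step("population", "population", populate),
        declare_step("po", "potential_outcomes", po),
        declare_inquiry("survival_ATE", "summary", fn=survival_ate),
        declare_inquiry("SACE_weight", "summary", fn=sace_weight),
        declare_sampling("stratified", strata="cluster"),
        declare_assignment("clustered", cluster="cluster",
                           m_clusters=n_clusters // 2),
        declare_step("reveal", "reveal", reveal),
        declare_estimator(
            lambda df, rng=None: difference_in_means(_cluster_frame(df),
                                                     "alive", "Z"),
            "mortality_dim_cluster", estimand="survival_ATE"),
    ]
    for label in answers:
        if label in _WEIGHT_ANSWERS:
            steps.append(declare_estimator(
                _weight_strategy, label, estimand="SACE_weight",
                strategy=label))
        elif label in _CBO_ANSWERS:
            steps.append(declare_estimator(
                _cbo_strategy, label, estimand="survival_ATE",
                strategy=label))
        else:
            raise SchemaError(f"unknown answer strategy {label!r}")
    return compose_design(steps, "truncation_replication")


CATALOGUE["truncation_replication"] = DesignCatalogEntry(
    "truncation_replication", truncation_replication_design, {
        "n_clusters": ParamSpec(50, "int", (4, 10 ** 4)),
        "households_per_cluster": ParamSpec(20, "int", (1, 10 ** 4)),
        "survival_shift": ParamSpec(0.6, "float", (0.0, 5.0)),
        "weight_effect": ParamSpec(0.2, "float"),
        "health_weight_corr": ParamSpec(1.0, "float", (-5.0, 5.0)),
        "community_sd": ParamSpec(0.4, "float", (0.0, 5.0)),
        "survival_threshold": ParamSpec(-1.38, "float", (-5.0, 5.0)),
        "cbo_share": ParamSpec(0.56, "float", (0.0, 1.0)),
        "cbo_health_coef": ParamSpec(0.0, "float", (-5.0, 5.0)),
        "answers": ParamSpec(None, "list"),
    },
    "Design replication of a cluster-randomized community-monitoring "
    "study: latent family and community health drive both infant survival "
    "and weight-for-age, so an effect on mortality truncates the weight "
    "outcome and biases naive survivor comparisons downward; includes the "
    "always-survivor subset answer and four replicator strategies for "
    "conditioning on community-based-organisation presence.")
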