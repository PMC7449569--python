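"""Diagnosands: summaries of the distribution of per-run diagnostic statistics.

Each diagnosand maps a SimulationTable group (one row per run for a given
estimator/estimand pair, or the whole table for design-scope diagnosands)
to ``(value, n_undefined)``, where ``n_undefined`` counts runs excluded by
conditioning -- e.g. non-significant runs for the exaggeration ratio -- or
runs whose required fields are missing.  The standard set:

===================  ======================================================
power                Pr(p <= alpha): probability of rejecting the null
bias                 E[estimate - estimand]
rmse                 sqrt(E[(estimate - estimand)^2])
coverage             Pr(ci_low <= estimand <= ci_high)
sd_estimates         SD of estimates across runs (m-1 denominator)
sd_estimands         SD of estimands across runs
sampling_bias        E[population estimand - sample estimand]
type_s_rate          Pr(sign wrong | significant)
exaggeration_ratio   E[|estimate| / |estimand| | significant]
imbalance            mean absolute standardized mean difference of
                     covariates across arms (recorded per run)
robustness           Pr(all tests in a set significant jointly)
value_for_money      Pr(decision based on the estimate is correct)
posterior_*          shift in posterior location / scale vs the prior
===================  ======================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .core import ConfigurationError

__all__ = [
    "DiagnosandSpec",
    "get_diagnosand",
    "available_diagnosands",
    "power",
    "bias",
    "rmse",
    "coverage",
    "sd_estimates",
    "sd_estimands",
    "sampling_bias",
    "type_s_rate",
    "exaggeration_ratio",
    "imbalance",
    "covariate_imbalance",
    "robustness",
    "value_for_money",
    "posterior_shift",
]


@dataclass
class DiagnosandSpec:
    """A named diagnosand: a function over a SimulationTable group.

    ``fn(group, **options) -> (value, n_undefined)``.  ``requires`` lists
    SimulationTable columns that must carry data; ``preference`` states
    what "better" means when designs are compared (``smaller_abs`` for
    bias-like, ``smaller`` for RMSE-like, ``larger`` for power-like).
    ``scope`` is ``"pair"`` (applied per estimator/estimand pair) or
    ``"design"`` (applied once to the whole table, e.g. robustness).
    """

    name: str
    fn: Callable
    requires: tuple[str, ...] = ()
    preference: str | None = None
    scope: str = "pair"
    allow_inquiry_only: bool = False
    options: dict = field(default_factory=dict)

    def with_options(self, **options) -> "DiagnosandSpec":
        merged = dict(self.options)
        merged.update(options)
        return replace(self, options=merged)

    def check(self, group: pd.DataFrame, design=None) -> None:
        for col in self.requires:
            if col not in group.columns or group[col].isna().all():
                who = ""
                labels = group.get("estimator_label")
                if labels is not None and len(labels):
                    who = f" for estimator {labels.iloc[0]!r}"
                hint = ""
                if col == "estimand":
                    hint = " (does the design declare an inquiry?)"
                raise ConfigurationError(
                    f"diagnosand {self.name!r} requires {col!r}{who}"
                    f" but it is missing{hint}"
                )


def _valid(group: pd.DataFrame, *cols: str) -> pd.DataFrame:
    mask = np.ones(len(group), dtype=bool)
    for c in cols:
        mask &= group[c].notna().to_numpy()
    return group.loc[mask]


def power(group: pd.DataFrame, alpha: float = 0.05) -> tuple[float, int]:
    """Probability of rejecting the null of no effect at level ``alpha``."""
    ok = _valid(group, "p_value")
    if len(ok) == 0:
        return float("nan"), len(group)
    return float(np.mean(ok["p_value"] <= alpha)), len(group) - len(ok)


def bias(group: pd.DataFrame) -> tuple[float, int]:
    """Expected difference between estimate and estimand."""
    ok = _valid(group, "estimate", "estimand")
    if len(ok) == 0:
        return float("nan"), len(group)
    e = ok["estimate"].to_numpy() - ok["estimand"].to_numpy()
    return float(np.mean(e)), len(group) - len(ok)


def rmse(group: pd.DataFrame) -> tuple[float, int]:
    """Root mean-squared error of the estimate about the estimand."""
    ok = _valid(group, "estimate", "estimand")
    if len(ok) == 0:
        return float("nan"), len(group)
    e = ok["estimate"].to_numpy() - ok["estimand"].to_numpy()
    return float(np.sqrt(np.mean(e ** 2))), len(group) - len(ok)


def coverage(group: pd.DataFrame) -> tuple[float, int]:
    """Probability the confidence interval contains the estimand."""
    ok = _valid(group, "ci_low", "ci_high", "estimand")
    if len(ok) == 0:
        return float("nan"), len(group)
    hit = (ok["ci_low"] <= ok["estimand"]) & (ok["estimand"] <= ok["ci_high"])
    return float(np.mean(hit)), len(group) - len(ok)


def sd_estimates(group: pd.DataFrame) -> tuple[float, int]:
    """Standard deviation of estimates across runs (m-1 denominator)."""
    ok = _valid(group, "estimate")
    if len(ok) < 2:
        return float("nan"), len(group) - len(ok)
    return float(np.std(ok["estimate"], ddof=1)), len(group) - len(ok)


def sd_estimands(group: pd.DataFrame) -> tuple[float, int]:
    """Standard deviation of estimands across runs."""
    ok = _valid(group, "estimand")
    if len(ok) < 2:
        return float("nan"), len(group) - len(ok)
    return float(np.std(ok["estimand"], ddof=1)), len(group) - len(ok)


def sampling_bias(sims: pd.DataFrame, population_label: str = "PATE",
                  sample_label: str = "SATE") -> tuple[float, int]:
    """Expected difference between a population- and a sample-level estimand.

    Requires two inquiry labels in the table: one computed on the full
    population table and one computed after sampling.
    """
    diffs = []
    n_undef = 0
    for _, g in sims.groupby("run", sort=True):
        by = dict(zip(g["estimand_label"], g["estimand"]))
        if population_label not in by or sample_label not in by:
            raise ConfigurationError(
                f"sampling_bias needs estimand rows {population_label!r} and "
                f"{sample_label!r}; the design must declare both inquiries"
            )
        p, s = by[population_label], by[sample_label]
        if np.isnan(p) or np.isnan(s):
            n_undef += 1
        else:
            diffs.append(p - s)
    if not diffs:
        return float("nan"), n_undef
    return float(np.mean(diffs)), n_undef


def type_s_rate(group: pd.DataFrame, alpha: float = 0.05) -> tuple[float, int]:
    """Probability the estimate has the wrong sign, given significance.

    Significant runs with an estimand of exactly zero have no defined sign
    to get wrong; they are counted in ``n_undefined``, not dropped silently.
    """
    ok = _valid(group, "p_value", "estimate", "estimand")
    sig = ok.loc[ok["p_value"] <= alpha]
    defined = sig.loc[sig["estimand"] != 0]
    n_undef = len(group) - len(defined)
    if len(defined) == 0:
        return float("nan"), n_undef
    wrong = np.sign(defined["estimate"]) != np.sign(defined["estimand"])
    return float(np.mean(wrong)), n_undef


def exaggeration_ratio(group: pd.DataFrame, alpha: float = 0.05
                       ) -> tuple[float, int]:
    """Expected |estimate| / |estimand|, given statistical significance."""
    ok = _valid(group, "p_value", "estimate", "estimand")
    sig = ok.loc[ok["p_value"] <= alpha]
    defined = sig.loc[sig["estimand"] != 0]
    n_undef = len(group) - len(defined)
    if len(defined) == 0:
        return float("nan"), n_undef
    ratio = np.abs(defined["estimate"]) / np.abs(defined["estimand"])
    return float(np.mean(ratio)), n_undef


def covariate_imbalance(df: pd.DataFrame, covariates, assignment: str = "Z"
                        ) -> float:
    """Average absolute standardized mean difference across arms, one dataset.

    The per-covariate statistic is |mean(treated) - mean(control)| divided
    by the pooled standard deviation; zero-variance covariates are skipped
    with a warning.  This is the distance metric behind the ``imbalance``
    diagnosand (other metrics can be recorded via a custom statistic step).
    """
    z = np.asarray(df[assignment]) != 0
    stats = []
    for cov in covariates:
        x = np.asarray(df[cov], dtype=float)
        pooled = np.std(x, ddof=1)
        if pooled == 0 or np.isnan(pooled):
            warnings.warn(f"covariate {cov!r} has zero variance; skipped")
            continue
        stats.append(abs(x[z].mean() - x[~z].mean()) / pooled)
    if not stats:
        return float("nan")
    return float(np.mean(stats))


def imbalance(group: pd.DataFrame, covariates=None, assignment: str = "Z"
              ) -> tuple[float, int] | float:
    """Expected covariate distance across treatment conditions.

    Two call forms: with ``covariates`` given, ``group`` is one run's unit
    data and the standardized-mean-difference statistic is returned
    directly; without, ``group`` holds per-run recorded imbalance
    statistics (see :func:`designdiag.estimators.imbalance_statistic`) and
    their mean over runs is returned with an undefined-count.
    """
    if covariates is not None:
        return covariate_imbalance(group, covariates, assignment)
    ok = _valid(group, "estimate")
    if len(ok) == 0:
        return float("nan"), len(group)
    return float(np.mean(ok["estimate"])), len(group) - len(ok)


def robustness(sims: pd.DataFrame, test_set=(), alpha: float = 0.05
               ) -> tuple[float, int]:
    """Joint probability of rejecting the null across every test in a set."""
    test_set = list(test_set)
    if not test_set:
        raise ConfigurationError("robustness requires a non-empty test_set")
    present = set(sims["estimator_label"])
    unknown = [t for t in test_set if t not in present]
    if unknown:
        raise ConfigurationError(
            f"robustness test_set labels not in simulations: {unknown}"
        )
    joint = []
    n_undef = 0
    for _, g in sims.groupby("run", sort=True):
        ps = g.loc[g["estimator_label"].isin(test_set), "p_value"]
        if len(ps) < len(test_set) or ps.isna().any():
            n_undef += 1
            continue
        joint.append(bool((ps <= alpha).all()))
    if not joint:
        return float("nan"), n_undef
    return float(np.mean(joint)), n_undef


def value_for_money(group: pd.DataFrame, decision_rule=None, benefit_fn=None
                    ) -> tuple[float, int]:
    """Probability that funding decisions based on the estimate are correct.

    ``decision_rule(estimate) -> bool`` (fund or not); ``benefit_fn`` maps
    the estimand to a net benefit.  A decision is correct when it funds a
    non-negative benefit or declines a negative one.  Runs with benefit
    exactly zero are counted correct by convention and flagged through
    ``n_undefined``.
    """
    if decision_rule is None or benefit_fn is None:
        raise ConfigurationError(
            "value_for_money needs both a decision_rule and a benefit_fn"
        )
    ok = _valid(group, "estimate", "estimand")
    if len(ok) == 0:
        return float("nan"), len(group)
    correct = []
    n_zero = 0
    for est, estd in zip(ok["estimate"], ok["estimand"]):
        fund = bool(decision_rule(est))
        benefit = benefit_fn(estd)
        if benefit == 0:
            n_zero += 1
        correct.append(fund == (benefit >= 0))
    return float(np.mean(correct)), (len(group) - len(ok)) + n_zero


def _posterior_cols(group: pd.DataFrame) -> pd.DataFrame:
    needed = ["estimate", "aux_posterior_sd", "aux_prior_mean", "aux_prior_sd"]
    for c in needed:
        if c not in group.columns or group[c].isna().all():
            raise ConfigurationError(
                "posterior-shift diagnosands need Bayesian estimate rows "
                f"with auxiliary fields; missing {c!r}"
            )
    return _valid(group, *needed)


def posterior_shift(group: pd.DataFrame) -> tuple[float, float]:
    """Expected shift in posterior location and scale relative to the prior.

    Returns ``(mean |posterior mean - prior mean|, mean posterior sd /
    prior sd)``.  With no data the posterior equals the prior: shift 0,
    ratio 1.
    """
    ok = _posterior_cols(group)
    loc = float(np.mean(np.abs(ok["estimate"] - ok["aux_prior_mean"])))
    scale = float(np.mean(ok["aux_posterior_sd"] / ok["aux_prior_sd"]))
    return loc, scale


def _posterior_location(group, **_):
    ok = _posterior_cols(group)
    val = float(np.mean(np.abs(ok["estimate"] - ok["aux_prior_mean"])))
    return val, len(group) - len(ok)


def _posterior_scale(group, **_):
    ok = _posterior_cols(group)
    val = float(np.mean(ok["aux_posterior_sd"] / ok["aux_prior_sd"]))
    return val, len(group) - len(ok)


def mean_absolute_error(group: pd.DataFrame) -> tuple[float, int]:
    """Expected |estimate - estimand|; e.g. the average posterior error of a
    process-tracing strategy against the case's true causal status."""
    ok = _valid(group, "estimate", "estimand")
    if len(ok) == 0:
        return float("nan"), len(group)
    e = np.abs(ok["estimate"].to_numpy() - ok["estimand"].to_numpy())
    return float(np.mean(e)), len(group) - len(ok)


_REGISTRY: dict[str, DiagnosandSpec] = {}


def _register(spec: DiagnosandSpec) -> DiagnosandSpec:
    _REGISTRY[spec.name] = spec
    return spec


_register(DiagnosandSpec("power", power, requires=("p_value",),
                         preference="larger"))
_register(DiagnosandSpec("bias", bias, requires=("estimate", "estimand"),
                         preference="smaller_abs"))
_register(DiagnosandSpec("rmse", rmse, requires=("estimate", "estimand"),
                         preference="smaller"))
_register(DiagnosandSpec("coverage", coverage,
                         requires=("ci_low", "ci_high", "estimand"),
                         preference="larger"))
_register(DiagnosandSpec("mean_absolute_error", mean_absolute_error,
                         requires=("estimate", "estimand"),
                         preference="smaller"))
_register(DiagnosandSpec("sd_estimates", sd_estimates,
                         requires=("estimate",), preference="smaller"))
_register(DiagnosandSpec("sd_estimands", sd_estimands,
                         requires=("estimand",), allow_inquiry_only=True))
_register(DiagnosandSpec("sampling_bias", sampling_bias, scope="design",
                         preference="smaller_abs"))
_register(DiagnosandSpec("type_s_rate", type_s_rate,
                         requires=("p_value", "estimate", "estimand"),
                         preference="smaller"))
_register(DiagnosandSpec("exaggeration_ratio", exaggeration_ratio,
                         requires=("p_value", "estimate", "estimand")))
_register(DiagnosandSpec("imbalance", imbalance, requires=("estimate",),
                         preference="smaller"))
_register(DiagnosandSpec("robustness", robustness, scope="design",
                         preference="larger"))
_register(DiagnosandSpec("value_for_money", value_for_money,
                         requires=("estimate", "estimand"),
                         preference="larger"))
_register(DiagnosandSpec("posterior_location_shift", _posterior_location,
                         requires=("estimate",)))
_register(DiagnosandSpec("posterior_scale_ratio", _posterior_scale,
                         requires=("estimate",)))
_register(DiagnosandSpec("mean_estimate",
                         lambda g, **kw: (
                             (float("nan"), len(g)) if g["estimate"].isna().all()
                             else (float(np.mean(_valid(g, "estimate")["estimate"])),
                                   int(g["estimate"].isna().sum()))),
                         requires=("estimate",)))
_register(DiagnosandSpec("mean_estimand",
                         lambda g, **kw: (
                             (float("nan"), len(g)) if g["estimand"].isna().all()
                             else (float(np.mean(_valid(g, "estimand")["estimand"])),
                                   int(g["estimand"].isna().sum()))),
                         requires=("estimand",), allow_inquiry_only=True))


def available_diagnosands() -> list[str]:
    return sorted(_REGISTRY)


def get_diagnosand(name: str, **options) -> DiagnosandSpec:
    """Look up a diagnosand by name, optionally overriding its options."""
    if name not in _REGISTRY:
        import difflib

        close = difflib.get_close_matches(name, _REGISTRY, n=1)
        hint = f"; did you mean {close[0]!r}?" if close else ""
        raise ConfigurationError(f"unknown diagnosand {name!r}{hint}")
    spec = _REGISTRY[name]
    return spec.with_options(**options) if options else spec
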