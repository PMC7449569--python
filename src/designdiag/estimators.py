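"""Answer strategies: estimators producing estimate rows with uncertainty.

Every estimator returns one or more *estimate rows*: dicts with fields
``estimator_label``, ``estimand_label``, ``estimate``, ``std_error``,
``p_value``, ``ci_low``, ``ci_high``, ``df`` and flattened auxiliary
fields prefixed ``aux_`` (posterior sd, discovery flags, ...).  Ordinary
least squares goes through statsmodels with HC2 heteroskedasticity-robust
standard errors by default, the convention for randomized designs; tests
are two-sided at level 0.05 unless stated otherwise.
"""

from __future__ import annotations

import inspect
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core import DataTable, EstimatorFailure, RunError, Step

__all__ = [
    "declare_estimator",
    "difference_in_means",
    "ols",
    "rd_polynomial_fit",
    "ipw_weights",
    "beta_binomial_posterior",
    "matching_att",
    "split_sample_answer",
    "imbalance_statistic",
]


def _t_row(estimate: float, se: float, dof: float, alpha: float = 0.05
           ) -> dict:
    if not np.isfinite(se) or se <= 0 or not np.isfinite(dof) or dof <= 0:
        return {"estimate": float(estimate), "std_error": float("nan"),
                "p_value": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "df": float("nan")}
    t = estimate / se
    crit = stats.t.ppf(1 - alpha / 2, dof)
    return {
        "estimate": float(estimate),
        "std_error": float(se),
        "p_value": float(2 * stats.t.sf(abs(t), dof)),
        "ci_low": float(estimate - crit * se),
        "ci_high": float(estimate + crit * se),
        "df": float(dof),
    }


def difference_in_means(df: pd.DataFrame, outcome: str, assignment: str = "Z",
                        alpha: float = 0.05) -> dict:
    """Difference in means with the Neyman variance estimator.

    estimate = mean(treated) - mean(control); SE^2 = s_t^2/n_t + s_c^2/n_c;
    two-sided t test with Welch-Satterthwaite degrees of freedom and 95% t
    confidence interval.  An arm with fewer than 2 units still yields the
    estimate, with the SE marked unavailable.
    """
    z = np.asarray(df[assignment], dtype=float) != 0
    y = np.asarray(df[outcome], dtype=float)
    yt, yc = y[z], y[~z]
    if len(yt) == 0 or len(yc) == 0:
        raise RunError("difference in means needs both arms non-empty")
    est = yt.mean() - yc.mean()
    if len(yt) < 2 or len(yc) < 2:
        row = _t_row(est, float("nan"), float("nan"), alpha)
        return row
    vt, vc = yt.var(ddof=1) / len(yt), yc.var(ddof=1) / len(yc)
    se = np.sqrt(vt + vc)
    if se == 0:
        return {"estimate": float(est), "std_error": 0.0,
                "p_value": 0.0 if est != 0 else 1.0,
                "ci_low": float(est), "ci_high": float(est),
                "df": float(len(y) - 2)}
    dof = (vt + vc) ** 2 / (vt ** 2 / (len(yt) - 1) + vc ** 2 / (len(yc) - 1))
    return _t_row(est, se, dof, alpha)


def _design_matrix(df: pd.DataFrame, regressors: Sequence[str],
                   blocks: str | None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["(intercept)"]
    for r in regressors:
        cols.append(np.asarray(df[r], dtype=float))
        names.append(r)
    if blocks is not None:
        dummies = pd.get_dummies(df[blocks], prefix=blocks, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def ols(df: pd.DataFrame, outcome: str, regressors: Sequence[str],
        target: str, weights=None, blocks: str | None = None,
        cluster: str | None = None, cov: str = "HC2",
        alpha: float = 0.05) -> dict:
    """(Weighted) least squares for a target coefficient.

    Block fixed effects enter as indicator columns (``blocks`` names the
    block column).  The default covariance is heteroskedasticity-robust
    HC2 (cluster-robust when ``cluster`` names a cluster column);
    ``cov="classical"`` reads off the conventional model-based variance
    instead, which treats any weights as precision weights -- the naive
    practice whose consequences the weighted designs diagnose.  A
    rank-deficient design matrix raises :class:`EstimatorFailure`, which
    the engine records as a missing run rather than aborting.
    """
    import statsmodels.api as sm

    for col in list(regressors) + [outcome]:
        if col not in df.columns:
            raise RunError(f"column {col!r} not present in data")
    X, names = _design_matrix(df, regressors, blocks)
    y = np.asarray(df[outcome], dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimatorFailure("design matrix is rank deficient")
    w = np.ones(len(y)) if weights is None else np.asarray(df[weights]
                                                           if isinstance(weights, str)
                                                           else weights,
                                                           dtype=float)
    model = sm.WLS(y, X, weights=w)
    try:
        if cluster is not None:
            fit = model.fit(cov_type="cluster",
                            cov_kwds={"groups": np.asarray(df[cluster])})
        elif cov == "classical":
            fit = model.fit()
        else:
            fit = model.fit(cov_type=cov)
    except np.linalg.LinAlgError as exc:
        raise EstimatorFailure(f"least-squares fit failed: {exc}") from exc
    j = names.index(target)
    est = float(fit.params[j])
    se = float(fit.bse[j])
    dof = float(fit.df_resid)
    row = _t_row(est, se, dof, alpha)
    row["aux_n"] = float(len(y))
    return row


def rd_polynomial_fit(df: pd.DataFrame, outcome: str, treatment: str,
                      running: str, cutoff: float = 0.0, order: int = 4,
                      alpha: float = 0.05) -> dict:
    """Regression-discontinuity fit: treatment interacted with a polynomial.

    The running variable is centered at the cutoff and entered as a
    polynomial of the given order, fully interacted with the treatment
    indicator; the target is the treatment coefficient, i.e. the jump in
    the fitted conditional expectation at the cutoff.
    """
    work = df.copy()
    x = np.asarray(work[running], dtype=float) - float(cutoff)
    regs = [treatment]
    for k in range(1, order + 1):
        work[f"_x{k}"] = x ** k
        work[f"_zx{k}"] = np.asarray(work[treatment], dtype=float) * x ** k
        regs += [f"_x{k}", f"_zx{k}"]
    return ols(work, outcome, regs, target=treatment, alpha=alpha)


def ipw_weights(df: pd.DataFrame, assignment: str = "Z",
                prob_column: str = "Z_prob") -> np.ndarray:
    """Inverse-probability weights w = Z/p + (1 - Z)/(1 - p)."""
    z = np.asarray(df[assignment], dtype=float)
    p = np.asarray(df[prob_column], dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise RunError(
            "assignment probabilities must lie strictly in (0, 1); "
            "a unit with p in {0, 1} cannot be weighted"
        )
    return z / p + (1 - z) / (1 - p)


def beta_binomial_posterior(successes: int, trials: int, prior_mean: float,
                            prior_sd: float, alpha: float = 0.05) -> dict:
    """Conjugate beta-binomial update with a moment-matched Beta prior.

    The prior shape is solved from its mean and standard deviation
    (a = mean (mean(1-mean)/sd^2 - 1), b likewise); a mean of 0.50 with sd
    0.29 is the (near) uniform Beta(1, 1) prior and sd 0.11 an informative
    Beta(9.8, 9.8).  The estimate is the posterior mean, the ci fields a
    central 95% credible interval, and the posterior sd travels in the
    auxiliary fields.
    """
    mu, sd = float(prior_mean), float(prior_sd)
    if not 0.0 < mu < 1.0 or sd <= 0 or sd ** 2 >= mu * (1 - mu):
        raise ValueError(
            f"prior moments (mean={mu}, sd={sd}) do not define a Beta prior"
        )
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    nu = mu * (1 - mu) / sd ** 2 - 1
    a, b = mu * nu + successes, (1 - mu) * nu + (trials - successes)
    post_mean = a / (a + b)
    post_sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    lo, hi = stats.beta.ppf([alpha / 2, 1 - alpha / 2], a, b)
    return {
        "estimate": float(post_mean),
        "std_error": float(post_sd),
        "p_value": float("nan"),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "df": float("nan"),
        "aux_posterior_sd": float(post_sd),
        "aux_prior_mean": mu,
        "aux_prior_sd": sd,
        "aux_prior_a": float(mu * nu),
        "aux_prior_b": float((1 - mu) * nu),
    }


def matching_att(df: pd.DataFrame, outcome: str, treatment: str,
                 covariates: Sequence[str], alpha: float = 0.05) -> dict:
    """1-nearest-neighbour Mahalanobis matching with replacement for the ATT.

    Each treated unit is matched to its nearest control on the Mahalanobis
    distance over the covariates (ties broken by lowest control index, so
    results are deterministic); the ATT is the mean within-pair outcome
    difference.  The SE is the matched-pair variance approximation
    sd(pair differences)/sqrt(n_treated) -- it ignores the re-use of
    controls, a documented simplification of the matched-pair variance.
    Covariates with zero variance trigger a fall back to Euclidean
    distance on the raw scale, with a warning.
    """
    z = np.asarray(df[treatment], dtype=float) != 0
    if z.sum() == 0 or (~z).sum() == 0:
        raise RunError("matching needs at least one treated and one control")
    X = np.asarray(df[list(covariates)], dtype=float)
    y = np.asarray(df[outcome], dtype=float)
    Xt, Xc = X[z], X[~z]
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.any(np.diag(cov) == 0) or np.linalg.matrix_rank(cov) < cov.shape[0]:
        warnings.warn(
            "degenerate covariate covariance; matching on Euclidean distance"
        )
        D = cdist(Xt, Xc, metric="euclidean")
    else:
        D = cdist(Xt, Xc, metric="mahalanobis", VI=np.linalg.inv(cov))
    match = D.argmin(axis=1)  # argmin takes the lowest index on ties
    diffs = y[z] - y[~z][match]
    est = float(diffs.mean())
    n_t = int(z.sum())
    if n_t < 2:
        row = _t_row(est, float("nan"), float("nan"), alpha)
    else:
        se = float(diffs.std(ddof=1) / np.sqrt(n_t))
        row = _t_row(est, se, n_t - 1, alpha)
    row["aux_n_treated"] = float(n_t)
    row["aux_n_matched_controls"] = float(len(np.unique(match)))
    return row


def _interaction_fit(df: pd.DataFrame, outcome: str, treatment: str,
                     moderator: str, alpha: float) -> dict:
    work = df.copy()
    work["_zw"] = (np.asarray(work[treatment], dtype=float)
                   * np.asarray(work[moderator], dtype=float))
    return ols(work, outcome, [treatment, moderator, "_zw"], target="_zw",
               alpha=alpha)


def split_sample_answer(df: pd.DataFrame, outcome: str, treatment: str,
                        moderators: Sequence[str], rng,
                        split_fraction: float = 0.5, alpha: float = 0.05
                        ) -> tuple[list[dict], bool]:
    """Principled split-sample discovery of treatment-effect heterogeneity.

    Stage 1 fits a treatment-by-moderator interaction for each candidate
    moderator on a random training split and selects the moderator with the
    smallest interaction p-value, provided it is below ``alpha`` (the
    selection rule is one concrete "preferred procedure"; no discovery
    otherwise).  Stage 2 re-estimates the selected interaction on the
    held-out data only.  The "unprincipled" analogue runs selection and
    estimation on the full data.  Returns ``(rows, result_produced)``
    where the flag is true when stage 1 discovered a moderator and the
    stage-2 estimate is itself significant at ``alpha``.
    """
    if not moderators:
        raise ValueError("split_sample_answer needs candidate moderators")
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    n = len(df)
    n_train = int(round(split_fraction * n))
    if n_train == 0 or n_train == n:
        raise RunError("split leaves an empty training or holdout set")
    perm = rng.permutation(n)
    train = df.iloc[perm[:n_train]]
    hold = df.iloc[perm[n_train:]]

    def select(data):
        best, best_p = None, np.inf
        for w in moderators:
            try:
                p = _interaction_fit(data, outcome, treatment, w, alpha
                                     )["p_value"]
            except EstimatorFailure:
                continue
            if np.isfinite(p) and p < best_p:
                best, best_p = w, p
        return (best, best_p) if best_p < alpha else (None, best_p)

    rows: list[dict] = []
    selected, _ = select(train)
    if selected is None:
        rows.append({"estimator_label": "principled",
                     "estimate": float("nan"), "aux_discovered": 0.0,
                     "aux_result_produced": 0.0})
        produced = False
    else:
        row = _interaction_fit(hold, outcome, treatment, selected, alpha)
        produced = bool(row["p_value"] <= alpha)
        row.update({"estimator_label": "principled", "aux_discovered": 1.0,
                    "aux_selected": float(moderators.index(selected)),
                    "aux_result_produced": float(produced)})
        rows.append(row)

    sel_full, _ = select(df)
    if sel_full is None:
        rows.append({"estimator_label": "unprincipled",
                     "estimate": float("nan"), "aux_discovered": 0.0,
                     "aux_result_produced": 0.0})
    else:
        row = _interaction_fit(df, outcome, treatment, sel_full, alpha)
        row.update({"estimator_label": "unprincipled", "aux_discovered": 1.0,
                    "aux_selected": float(moderators.index(sel_full)),
                    "aux_result_produced":
                        float(row["p_value"] <= alpha)})
        rows.append(row)
    return rows, produced


def imbalance_statistic(df: pd.DataFrame, covariates: Sequence[str],
                        assignment: str = "Z") -> dict:
    """Record the run's covariate imbalance as a diagnostic-statistic row."""
    from .diagnosands import covariate_imbalance

    return {"estimate": covariate_imbalance(df, covariates, assignment)}


def declare_estimator(fn: Callable, label: str, estimand: str | None = None,
                      **options) -> Step:
    """Wrap an estimator function as an answer-strategy step.

    ``fn(df, **options)`` should return an estimate row (dict), a list of
    rows, or ``(rows, flag)``; functions with an ``rng`` parameter (e.g.
    :func:`split_sample_answer`) receive the run's generator.
    """
    wants_rng = "rng" in inspect.signature(fn).parameters

    def transform(dt: DataTable, rng):
        kwargs = dict(options)
        if wants_rng:
            kwargs["rng"] = rng
        out = fn(dt.df, **kwargs)
        if isinstance(out, tuple):
            out = out[0]
        rows = out if isinstance(out, list) else [out]
        for row in rows:
            row.setdefault("estimator_label", label)
            row.setdefault("estimand_label", estimand)
        return rows

    return Step(label=label, stage="estimator", transform=transform,
                estimand_label=estimand)
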