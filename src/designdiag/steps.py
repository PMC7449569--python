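"""Factories for the step primitives that encode the model, inquiry and
data strategy of a design.

Population steps draw background variables; potential-outcome steps add
one column per treatment condition (``Y_Z_0``, ``Y_Z_1``, ...); inquiry
steps emit estimand rows; sampling, assignment, measurement and reveal
steps implement the data strategy.  Variable generators and
potential-outcome functions can be given either as Python callables or as
small string expressions evaluated over the existing columns (with a
numpy-flavoured namespace: ``mean``, ``where``, ``exp`` ...).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DataTable, DeclarationError, RunError, Step

__all__ = [
    "ConditionSet",
    "MeasurementSpec",
    "declare_population",
    "declare_potential_outcomes",
    "declare_inquiry",
    "linear_projection_estimand",
    "declare_sampling",
    "declare_assignment",
    "declare_measurement",
    "declare_reveal",
    "declare_step",
]

_EXPR_NS: dict[str, Any] = {
    "np": np,
    "mean": np.mean,
    "sum": np.sum,
    "abs": np.abs,
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "where": np.where,
    "maximum": np.maximum,
    "minimum": np.minimum,
    "clip": np.clip,
    "sign": np.sign,
}


def _expr_names(expr: str) -> set[str]:
    tree = ast.parse(expr, mode="eval")
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


def _eval_expr(expr: str, env: Mapping[str, Any]):
    try:
        return eval(compile(expr, "<design-expr>", "eval"),
                    {"__builtins__": {}}, {**_EXPR_NS, **env})
    except NameError as exc:
        raise RunError(f"expression {expr!r}: {exc}") from None


def _column_env(df: pd.DataFrame) -> dict[str, np.ndarray]:
    return {c: df[c].to_numpy() for c in df.columns}


def level_suffix(level) -> str:
    """Canonical text form of a condition level for column naming."""
    if isinstance(level, float) and level == int(level):
        return str(int(level))
    return str(level)


@dataclass
class ConditionSet:
    """A treatment variable and its ordered set of condition levels."""

    variable: str
    levels: Sequence[Any]

    def __post_init__(self):
        if len(self.levels) < 2:
            raise DeclarationError("a condition set needs at least 2 levels")
        if len(set(map(level_suffix, self.levels))) != len(self.levels):
            raise DeclarationError("condition levels must be unique")

    def column(self, outcome: str, level) -> str:
        return f"{outcome}_{self.variable}_{level_suffix(level)}"


@dataclass
class MeasurementSpec:
    """How a latent column is mapped, possibly with error, into an observed one.

    ``binary_flip`` flips a binary latent value with probability ``rate``;
    ``overreport`` sets the observed value to 1 with probability ``rate``
    among latent zeros (survey-style overstating); ``none`` copies.  When
    ``dependence`` names a column, ``rate`` may be a mapping from that
    column's values to error rates.
    """

    kind: str
    target: str
    rate: float | Mapping = 0.0
    dependence: str | None = None
    observed: str | None = None

    def __post_init__(self):
        if self.kind not in ("binary_flip", "overreport", "none"):
            raise DeclarationError(f"unknown measurement kind {self.kind!r}")
        rates = (self.rate.values() if isinstance(self.rate, Mapping)
                 else [self.rate])
        for r in rates:
            if not 0.0 <= float(r) <= 1.0:
                raise DeclarationError(f"measurement rate {r} outside [0, 1]")

    @property
    def observed_name(self) -> str:
        return self.observed or f"{self.target}_obs"


# ---------------------------------------------------------------------------
# population

def _make_sampler(name: str, spec, earlier: set[str]) -> Callable:
    """Normalize a distribution spec into ``(df, rng, n) -> array``."""
    if callable(spec):
        return lambda df, rng, n: np.asarray(spec(df, rng))
    if isinstance(spec, str):
        unknown = _expr_names(spec) - earlier - set(_EXPR_NS)
        if unknown:
            raise DeclarationError(
                f"generator for {name!r} references column(s) not yet "
                f"declared: {sorted(unknown)}"
            )
        return lambda df, rng, n, e=spec: np.broadcast_to(
            np.asarray(_eval_expr(e, _column_env(df))), (n,)).copy()
    if isinstance(spec, Mapping):
        ((dist, args),) = spec.items()
        args = args if isinstance(args, (list, tuple)) else [args]
    elif isinstance(spec, (list, tuple)):
        dist, *args = spec
    else:
        raise DeclarationError(f"cannot interpret generator spec {spec!r}")
    dist = str(dist)
    if dist == "normal":
        mean_, sd = (list(args) + [0.0, 1.0])[:2] if args else (0.0, 1.0)
        return lambda df, rng, n: rng.normal(float(mean_), float(sd), size=n)
    if dist == "uniform":
        lo, hi = args if len(args) == 2 else (0.0, 1.0)
        return lambda df, rng, n: rng.uniform(float(lo), float(hi), size=n)
    if dist == "bernoulli":
        (p,) = args
        if not 0.0 <= float(p) <= 1.0:
            raise DeclarationError(f"bernoulli p={p} outside [0, 1]")
        return lambda df, rng, n: (rng.random(n) < float(p)).astype(float)
    raise DeclarationError(f"unknown distribution {dist!r} for {name!r}")


def declare_population(n: int, generators: Mapping[str, Any] | None = None,
                       label: str = "population", **kw_generators) -> Step:
    """Population step: ``n`` units with columns generated in declared order.

    Supported generator specs: ``{"normal": [mean, sd]}``,
    ``{"uniform": [lo, hi]}``, ``{"bernoulli": p}`` (equivalently tuples
    ``("normal", mean, sd)``), a string expression over earlier columns,
    or a callable ``(df, rng) -> array``.
    """
    if n < 1:
        raise DeclarationError(f"population size must be >= 1, got {n}")
    gens = dict(generators or {})
    gens.update(kw_generators)
    samplers = []
    earlier: set[str] = set()
    for name, spec in gens.items():
        samplers.append((name, _make_sampler(name, spec, set(earlier))))
        earlier.add(name)

    def transform(dt: DataTable, rng) -> DataTable:
        df = dt.df if dt.n_rows else pd.DataFrame(index=range(int(n)))
        out = DataTable(df.copy(), dict(dt.roles))
        for name, sampler in samplers:
            out.add(name, sampler(out.df, rng, int(n)), role="latent")
        return out

    return Step(label=label, stage="population", transform=transform)


# ---------------------------------------------------------------------------
# potential outcomes

def declare_potential_outcomes(outcome: str, condition_set: ConditionSet,
                               po_function, label: str | None = None) -> Step:
    """Add one potential-outcome column per condition level.

    ``po_function`` is a string expression in which the condition variable
    name is bound to each level in turn (e.g. ``"Z + u"``), or a callable
    ``(df, level) -> array``.
    """
    label = label or f"po_{outcome}"

    def transform(dt: DataTable, rng) -> DataTable:
        out = DataTable(dt.df.copy(), dict(dt.roles))
        for level in condition_set.levels:
            col = condition_set.column(outcome, level)
            if col in out.df.columns:
                raise DeclarationError(
                    f"potential-outcome column {col!r} already exists"
                )
            if callable(po_function):
                values = po_function(out.df, level)
            else:
                env = _column_env(out.df)
                env[condition_set.variable] = level
                values = _eval_expr(po_function, env)
            out.add(col, np.broadcast_to(np.asarray(values, dtype=float),
                                         (out.n_rows or len(np.atleast_1d(values)),)).copy(),
                    role="potential_outcome")
        return out

    return Step(label=label, stage="potential_outcomes", transform=transform)


# ---------------------------------------------------------------------------
# inquiries

def linear_projection_estimand(po_function, grid, density=None
                               ) -> tuple[float, float]:
    """Weighted linear projection of pooled potential outcomes on (1, x).

    ``po_function`` maps each grid value x to the vector of unit-level
    potential outcomes Y_i(x) (or is a units-by-grid matrix).  The returned
    ``(alpha, beta)`` minimise the density-weighted squared error
    sum_i sum_j f(x_j) (Y_i(x_j) - alpha - beta x_j)^2: the regression
    coefficient one would get by regressing all potential outcomes on all
    conditions under the density of interest.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise DeclarationError("linear projection grid needs >= 3 points")
    if np.unique(grid).size < 2:
        raise DeclarationError("degenerate grid: slope undefined")
    if density is None:
        density = np.ones_like(grid)
    f = np.asarray(density, dtype=float)
    if np.any(f < 0) or f.sum() <= 0:
        raise DeclarationError("density must be non-negative with mass > 0")
    f = f / f.sum()
    if callable(po_function):
        ymat = np.column_stack([np.atleast_1d(po_function(x)) for x in grid])
    else:
        ymat = np.asarray(po_function, dtype=float)
    ybar = ymat.mean(axis=0)  # average over units per grid point
    xw = float(np.sum(f * grid))
    yw = float(np.sum(f * ybar))
    var = float(np.sum(f * (grid - xw) ** 2))
    cov = float(np.sum(f * (grid - xw) * (ybar - yw)))
    beta = cov / var
    alpha = yw - beta * xw
    return alpha, beta


_INQUIRY_KINDS = ("summary", "cause_of_effects", "linear_projection",
                  "qca_configuration", "rd_limit")


def declare_inquiry(label: str, kind: str = "summary", **spec) -> Step:
    """Inquiry step: emits one estimand row per run.

    Kinds:

    * ``summary`` -- ``expr`` (string over columns, e.g.
      ``"mean(Y_Z_1 - Y_Z_0)"``) or ``fn`` callable on the DataFrame;
    * ``cause_of_effects`` -- Pr(Y(0) = 0 | X = 1, Y(1) = 1) over the
      conditioning set, with ``outcome`` and ``cause`` column roots;
    * ``linear_projection`` -- slope of the pooled potential outcomes on
      the condition variable under a density of interest (``outcome``,
      ``variable``, ``levels``, optional ``density``);
    * ``qca_configuration`` -- the estimand is a causal configuration
      (see :mod:`designdiag.qualitative`); the numeric row value is 1.0
      and answer strategies record an exact-recovery indicator;
    * ``rd_limit`` -- difference of the two conditional-expectation
      functions at the ``cutoff`` (``control_fn``, ``treat_fn``).
    """
    if kind not in _INQUIRY_KINDS:
        raise DeclarationError(
            f"unknown inquiry kind {kind!r}; expected one of {_INQUIRY_KINDS}"
        )

    def value(dt: DataTable) -> float:
        df = dt.df
        if kind == "summary":
            if "fn" in spec:
                return float(spec["fn"](df))
            expr = spec["expr"]
            missing = (_expr_names(expr) - set(df.columns) - set(_EXPR_NS))
            if missing:
                raise RunError(
                    f"inquiry {label!r} references missing column(s): "
                    f"{sorted(missing)}"
                )
            return float(_eval_expr(expr, _column_env(df)))
        if kind == "cause_of_effects":
            outcome, cause = spec["outcome"], spec["cause"]
            dt.require(cause, f"{outcome}_{cause}_0", f"{outcome}_{cause}_1")
            cond = (df[cause].to_numpy() == 1) & \
                   (df[f"{outcome}_{cause}_1"].to_numpy() == 1)
            if cond.sum() == 0:
                return float("nan")
            return float(np.mean(
                df.loc[cond, f"{outcome}_{cause}_0"].to_numpy() == 0))
        if kind == "linear_projection":
            outcome, var = spec["outcome"], spec["variable"]
            levels = spec["levels"]
            cols = [f"{outcome}_{var}_{level_suffix(lv)}" for lv in levels]
            dt.require(*cols)
            ymat = df[cols].to_numpy(dtype=float)
            _, beta = linear_projection_estimand(
                ymat, levels, spec.get("density"))
            return float(beta)
        if kind == "qca_configuration":
            return 1.0
        # rd_limit
        cutoff = spec["cutoff"]
        return float(spec["treat_fn"](cutoff) - spec["control_fn"](cutoff))

    def transform(dt: DataTable):
        return [{"inquiry_label": label, "value": value(dt)}]

    step = Step(label=label, stage="inquiry", transform=transform)
    if kind == "qca_configuration":
        step.dnf = spec.get("dnf")  # carried for QCA answer strategies
    return step


# ---------------------------------------------------------------------------
# data strategy

def declare_sampling(kind: str = "simple", n: int | None = None,
                     strata: str | None = None,
                     n_per_stratum: int | Mapping | None = None,
                     label: str = "sampling") -> Step:
    """Sampling step: marks sampled rows (column ``S``) and restricts the
    table so downstream estimators see sampled rows only."""
    if kind not in ("simple", "stratified"):
        raise DeclarationError(f"unknown sampling kind {kind!r}")

    def transform(dt: DataTable, rng) -> DataTable:
        df = dt.df
        if kind == "simple":
            if n is None or n > len(df):
                raise RunError(
                    f"sample size {n} exceeds population size {len(df)}"
                )
            idx = rng.choice(len(df), size=int(n), replace=False)
        else:
            dt.require(strata)
            parts = []
            for value, g in df.groupby(strata, sort=True):
                k = (n_per_stratum.get(value)
                     if isinstance(n_per_stratum, Mapping) else n_per_stratum)
                if k is None:
                    k = len(g)
                if k > len(g):
                    raise RunError(
                        f"stratum {value!r} has {len(g)} rows, needs {k}"
                    )
                parts.append(rng.choice(g.index.to_numpy(), size=int(k),
                                        replace=False))
            idx = np.concatenate(parts)
        mask = np.zeros(len(df), dtype=bool)
        mask[np.asarray(sorted(idx))] = True
        out = dt.subset(mask)
        out.add("S", np.ones(out.n_rows), role="sampling_indicator")
        return out

    return Step(label=label, stage="sampling", transform=transform)


def _complete_count(prob: float, size: int, rng) -> int:
    """Deterministic floor/remainder allocation of probability x size."""
    base = int(np.floor(prob * size))
    frac = prob * size - base
    return base + int(rng.random() < frac)


def _complete_assign(size: int, m: int, rng) -> np.ndarray:
    z = np.zeros(size, dtype=float)
    if m > 0:
        z[rng.choice(size, size=int(m), replace=False)] = 1.0
    return z


def declare_assignment(scheme: str = "complete", variable: str = "Z",
                       label: str = "assignment", **spec) -> Step:
    """Assignment step.  Schemes:

    * ``complete`` -- ``m`` treated of the sample (or ``prob`` with
      floor/remainder allocation);
    * ``blocked`` -- ``block`` column plus ``probs`` (mapping block value
      to treatment probability); complete assignment within each block; a
      per-unit probability column ``{variable}_prob`` is recorded;
    * ``clustered`` -- ``cluster`` column; ``m_clusters`` (or ``prob``)
      clusters treated, all their units alike;
    * ``factorial`` -- two binary factors assigned to the four cells in
      equal shares; adds both factor columns and a ``cell`` label column
      (``"00"``, ``"10"``, ``"01"``, ``"11"`` as factor1 then factor2);
    * ``multi_arm`` -- ``arms`` labels with ``probs`` summing to 1;
      realized counts are the floor allocation with remainders assigned by
      draw; adds the arm column plus one indicator column per arm.
    """
    schemes = ("complete", "blocked", "clustered", "factorial", "multi_arm")
    if scheme not in schemes:
        raise DeclarationError(f"unknown assignment scheme {scheme!r}")
    if scheme == "blocked":
        for p in dict(spec["probs"]).values():
            if not 0.0 < float(p) < 1.0:
                raise DeclarationError(
                    f"block probability {p} outside (0, 1)")
    if scheme == "multi_arm":
        probs = np.asarray(spec["probs"], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise DeclarationError("arm probabilities must sum to 1")

    def transform(dt: DataTable, rng) -> DataTable:
        out = DataTable(dt.df.copy(), dict(dt.roles))
        n = out.n_rows
        if scheme == "complete":
            m = spec.get("m")
            prob = spec.get("prob")
            if m is None:
                m = _complete_count(float(prob), n, rng)
            if m > n:
                raise RunError(f"cannot treat m={m} of n={n} units")
            out.add(variable, _complete_assign(n, m, rng), role="assignment")
            out.add(f"{variable}_prob", np.full(n, m / n), role="assignment")
        elif scheme == "blocked":
            dt.require(spec["block"])
            block = out.df[spec["block"]].to_numpy()
            probs = dict(spec["probs"])
            z = np.zeros(n)
            p_unit = np.zeros(n)
            for value in pd.unique(block):
                idx = np.flatnonzero(block == value)
                p = float(probs[value])
                m_b = _complete_count(p, len(idx), rng)
                z[idx[rng.choice(len(idx), size=m_b, replace=False)]] = 1.0
                p_unit[idx] = p
            out.add(variable, z, role="assignment")
            out.add(f"{variable}_prob", p_unit, role="assignment")
        elif scheme == "clustered":
            dt.require(spec["cluster"])
            clusters = pd.unique(out.df[spec["cluster"]])
            k = len(clusters)
            m_c = spec.get("m_clusters")
            if m_c is None:
                m_c = _complete_count(float(spec["prob"]), k, rng)
            treated = set(clusters[rng.choice(k, size=int(m_c),
                                              replace=False)])
            z = out.df[spec["cluster"]].isin(treated).to_numpy(dtype=float)
            out.add(variable, z, role="assignment")
            out.add(f"{variable}_prob", np.full(n, m_c / k),
                    role="assignment")
        elif scheme == "factorial":
            v1, v2 = spec.get("variables", ("Z1", "Z2"))
            cell_name = spec.get("cell_name", "cell")
            cells = ["00", "10", "01", "11"]
            counts = _allocate_counts(np.full(4, 0.25), n, rng)
            labels = np.repeat(cells, counts)
            rng.shuffle(labels)
            out.add(cell_name, labels, role="assignment")
            out.add(v1, np.array([int(c[0]) for c in labels], dtype=float),
                    role="assignment")
            out.add(v2, np.array([int(c[1]) for c in labels], dtype=float),
                    role="assignment")
        else:  # multi_arm
            arms = list(spec["arms"])
            probs = np.asarray(spec["probs"], dtype=float)
            counts = _allocate_counts(probs, n, rng)
            labels = np.repeat(np.asarray(arms, dtype=object), counts)
            rng.shuffle(labels)
            out.add(variable, labels, role="assignment")
            for arm in arms:
                out.add(f"{variable}_{arm}",
                        (labels == arm).astype(float), role="assignment")
        return out

    return Step(label=label, stage="assignment", transform=transform)


def _allocate_counts(probs: np.ndarray, n: int, rng) -> np.ndarray:
    """Floor allocation of probability x n with remainders assigned by draw."""
    base = np.floor(probs * n).astype(int)
    leftover = n - base.sum()
    if leftover > 0:
        frac = probs * n - base
        total = frac.sum()
        p = frac / total if total > 0 else np.full(len(probs), 1 / len(probs))
        extra = rng.choice(len(probs), size=leftover, replace=False, p=p)
        base[extra] += 1
    return base


def declare_measurement(spec: MeasurementSpec, label: str | None = None
                        ) -> Step:
    """Measurement step: maps a latent column into an observed ``*_obs``
    column, retaining the latent column for estimand computation."""

    def transform(dt: DataTable, rng) -> DataTable:
        dt.require(spec.target)
        out = DataTable(dt.df.copy(), dict(dt.roles))
        latent = out.df[spec.target].to_numpy(dtype=float)
        if isinstance(spec.rate, Mapping):
            dt.require(spec.dependence)
            dep = out.df[spec.dependence].to_numpy()
            rate = np.array([float(spec.rate[v]) for v in dep])
        else:
            rate = np.full(len(latent), float(spec.rate))
        if spec.kind == "none":
            observed = latent.copy()
        elif spec.kind == "binary_flip":
            flip = rng.random(len(latent)) < rate
            observed = np.where(flip, 1.0 - latent, latent)
        else:  # overreport
            lie = rng.random(len(latent)) < rate
            observed = np.where((latent == 0) & lie, 1.0, latent)
        out.add(spec.observed_name, observed, role="realized")
        return out

    return Step(label=label or f"measure_{spec.target}",
                stage="measurement", transform=transform)


def declare_reveal(outcome: str, assignment: str, label: str | None = None
                   ) -> Step:
    """Reveal step: the realized outcome is the potential-outcome column
    selected by each unit's assigned condition (a deterministic selector)."""

    def transform(dt: DataTable, rng) -> DataTable:
        dt.require(assignment)
        out = DataTable(dt.df.copy(), dict(dt.roles))
        z = out.df[assignment].to_numpy()
        realized = np.empty(out.n_rows, dtype=float)
        for level in pd.unique(z):
            suffix = level_suffix(level)
            col = f"{outcome}_{assignment}_{suffix}"
            if col not in out.df.columns:
                raise RunError(
                    f"no potential-outcome column {col!r} for assigned "
                    f"level {level!r}"
                )
            mask = z == level
            realized[mask] = out.df.loc[mask, col].to_numpy(dtype=float)
        out.add(outcome, realized, role="realized")
        return out

    return Step(label=label or f"reveal_{outcome}", stage="reveal",
                transform=transform)


def declare_step(label: str, stage: str, transform: Callable) -> Step:
    """Escape hatch: wrap an arbitrary transform as a declared step."""
    return Step(label=label, stage=stage, transform=transform)
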