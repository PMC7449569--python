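"""Declare, simulate, and diagnose research designs.

A research design is declared as an ordered sequence of *steps* covering
four elements: a model of the world (population and potential-outcome
steps), one or more *inquiries* defining estimands, a data strategy
(sampling, assignment, measurement, outcome revelation), and an answer
strategy (estimator steps).  Running the design once draws a population,
computes each estimand on the full potential-outcome table, realizes the
data the researcher would actually see, and applies the estimators to it.
Simulating the design ``m`` times and summarising the distribution of
diagnostic statistics (estimate - estimand, significance indicators, CI
hits, ...) yields *diagnosands* -- power, bias, RMSE, coverage, Type-S
rate, exaggeration ratio and friends -- each reported with a
nonparametric-bootstrap standard error obtained by resampling whole
simulation runs.

The central objects are:

``Step``
    label + stage + transform.  Data-stage transforms map
    ``(DataTable, rng) -> DataTable`` and may only add columns; inquiry
    and estimator transforms emit result rows without mutating the data.
``Design``
    a named, validated, ordered list of steps.
``SimulationTable``
    a :class:`pandas.DataFrame` with one row per
    (run, estimator_label, estimand_label) and columns
    ``run, run_seed, estimator_label, estimand_label, estimand, estimate,
    std_error, p_value, ci_low, ci_high, df`` plus flattened auxiliary
    columns prefixed ``aux_``.
``DiagnosisResult``
    a :class:`pandas.DataFrame` with one row per diagnosand and
    (estimator, estimand) pair and columns ``design, estimator_label,
    estimand_label, diagnosand, estimate, bootstrap_se, n_sims,
    n_bootstrap, n_undefined``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DATA_STAGES",
    "RESULT_STAGES",
    "STAGES",
    "DeclarationError",
    "RunError",
    "ConfigurationError",
    "EstimatorFailure",
    "DataTable",
    "Step",
    "Design",
    "RunResult",
    "compose_design",
    "run_once",
    "simulate_design",
    "diagnose_design",
    "compare_designs",
    "table_to_csv",
    "table_to_json",
]

DATA_STAGES = (
    "population",
    "potential_outcomes",
    "sampling",
    "assignment",
    "measurement",
    "reveal",
)
RESULT_STAGES = ("inquiry", "estimator")
STAGES = DATA_STAGES + RESULT_STAGES

#: Column order of a SimulationTable (auxiliary columns follow these).
SIMULATION_COLUMNS = [
    "run",
    "run_seed",
    "estimator_label",
    "estimand_label",
    "estimand",
    "estimate",
    "std_error",
    "p_value",
    "ci_low",
    "ci_high",
    "df",
]

DIAGNOSIS_COLUMNS = [
    "design",
    "estimator_label",
    "estimand_label",
    "diagnosand",
    "estimate",
    "bootstrap_se",
    "n_sims",
    "n_bootstrap",
    "n_undefined",
]


class DeclarationError(ValueError):
    """A design or step is declared inconsistently."""


class RunError(RuntimeError):
    """A single simulation run cannot proceed (missing column, empty sample)."""


class ConfigurationError(ValueError):
    """A diagnosand or comparison is configured against an unsuitable design."""


class EstimatorFailure(RuntimeError):
    """A recoverable estimator failure within one run (e.g. singular fit).

    Runs that raise this are recorded as missing estimate rows and counted;
    they are not fatal, so that diagnosands such as the probability of
    producing a result at all can be computed.
    """


class DataTable:
    """Rectangular units-by-variables table with per-column role tags.

    Thin wrapper around a :class:`pandas.DataFrame`; the ``roles`` mapping
    tags columns as ``latent``, ``potential_outcome``, ``realized``,
    ``sampling_indicator`` or ``assignment``.  Potential-outcome columns
    follow the ``outcome_variable_level`` naming convention (the outcome Y
    under Z = 1 is stored as ``Y_Z_1``, distinct from ``Y_Z_0``).
    """

    def __init__(self, df: pd.DataFrame | None = None,
                 roles: dict[str, str] | None = None):
        self.df = df if df is not None else pd.DataFrame()
        self.roles = dict(roles or {})

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def add(self, name: str, values, role: str = "latent") -> None:
        self.df[name] = np.asarray(values)
        self.roles[name] = role

    def col(self, name: str) -> np.ndarray:
        try:
            return self.df[name].to_numpy()
        except KeyError:
            raise RunError(f"column {name!r} not present in data") from None

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise RunError(
                "missing column(s): " + ", ".join(repr(n) for n in missing)
            )

    def subset(self, mask) -> "DataTable":
        return DataTable(self.df.loc[np.asarray(mask, dtype=bool)]
                         .reset_index(drop=True), self.roles)

    def copy(self) -> "DataTable":
        return DataTable(self.df.copy(), dict(self.roles))


@dataclass
class Step:
    """One declared design step.

    ``transform`` contracts by stage:

    * data stages (population / potential_outcomes / sampling / assignment /
      measurement / reveal): ``(DataTable, numpy Generator) -> DataTable``;
      the result must retain every pre-existing column.
    * inquiry: ``DataTable -> list of {"inquiry_label", "value"}`` rows.
    * estimator: ``(DataTable, numpy Generator) -> list of estimate rows``
      (dicts with at least ``estimator_label`` and ``estimate``).
    """

    label: str
    stage: str
    transform: Callable
    estimand_label: str | None = None  # estimator steps: inquiry they target

    def __post_init__(self):
        if self.stage not in STAGES:
            raise DeclarationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )


@dataclass
class Design:
    """An ordered, named sequence of steps encoding M, I, D, and A."""

    steps: list[Step]
    name: str = "design"
    params: dict[str, Any] = field(default_factory=dict)

    def with_model(self, model_steps: Sequence[Step], name: str | None = None
                   ) -> "Design":
        """Return a copy whose model-stage steps are replaced by ``model_steps``."""
        rest = [s for s in self.steps
                if s.stage not in ("population", "potential_outcomes")]
        return compose_design(list(model_steps) + rest,
                              name or self.name, params=dict(self.params))


@dataclass
class RunResult:
    """Estimands and estimates from a single simulation run."""

    estimands: list[dict]
    estimates: list[dict]
    failures: list[tuple[str, str]] = field(default_factory=list)


def compose_design(steps: Sequence[Step], name: str = "design",
                   params: dict | None = None) -> Design:
    """Validate and assemble steps into a :class:`Design`.

    Requires a non-empty step list with unique labels and at least one
    inquiry or estimator step.  Column-dependency checking is deferred to
    the first run, where a missing column raises :class:`RunError` naming it.
    """
    steps = list(steps)
    if not steps:
        raise DeclarationError("a design needs at least one step")
    labels = [s.label for s in steps]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise DeclarationError(f"duplicate step labels: {sorted(dupes)}")
    if not any(s.stage in RESULT_STAGES for s in steps):
        raise DeclarationError(
            "a design needs at least one inquiry or estimator step"
        )
    return Design(steps=steps, name=name, params=dict(params or {}))


def _run_seed(seed: int, index: int) -> int:
    """Derive the per-run substream seed: counter-based, independent of m."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(0, int(index)))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def run_once(design: Design, seed: int) -> RunResult:
    """Execute one simulation of ``design``, deterministic given (design, seed).

    Steps run in declared order: estimands are computed on the table as it
    stands at the inquiry's position (before sampling/assignment when the
    inquiry is declared before them, as in the canonical ordering), while
    estimators see only the data revealed by the data-strategy steps.
    """
    rng = np.random.default_rng(int(seed))
    dt = DataTable()
    estimands: list[dict] = []
    estimates: list[dict] = []
    failures: list[tuple[str, str]] = []

    for step in design.steps:
        if step.stage in DATA_STAGES:
            before = set(dt.df.columns)
            out = step.transform(dt, rng)
            if out is None:
                out = dt
            lost = before - set(out.df.columns)
            if lost:
                raise RunError(
                    f"step {step.label!r} deleted column(s) {sorted(lost)}"
                )
            dt = out
        elif step.stage == "inquiry":
            rows = step.transform(dt)
            for row in rows:
                row.setdefault("inquiry_label", step.label)
                estimands.append(row)
        else:  # estimator
            if dt.n_rows == 0:
                raise RunError(
                    f"estimator {step.label!r} applied to an empty sample"
                )
            try:
                rows = step.transform(dt, rng)
            except EstimatorFailure as exc:
                failures.append((step.label, str(exc)))
                estimates.append({
                    "estimator_label": step.label,
                    "estimand_label": step.estimand_label,
                    "estimate": np.nan,
                    "aux_failed": 1.0,
                })
                continue
            for row in rows:
                row.setdefault("estimator_label", step.label)
                row.setdefault("estimand_label", step.estimand_label)
                estimates.append(row)
    return RunResult(estimands=estimands, estimates=estimates,
                     failures=failures)


def _rows_from_run(result: RunResult, run: int, run_seed: int) -> list[dict]:
    estimand_by_label = {r["inquiry_label"]: r["value"]
                         for r in result.estimands}
    rows = []
    targeted: set[str] = set()
    for est in result.estimates:
        row = {"run": run, "run_seed": run_seed}
        row.update(est)
        label = est.get("estimand_label")
        if label is not None:
            targeted.add(label)
            row["estimand"] = estimand_by_label.get(label, np.nan)
        else:
            row["estimand_label"] = ""
            row["estimand"] = np.nan
        rows.append(row)
    for label, value in estimand_by_label.items():
        if label not in targeted:
            rows.append({
                "run": run, "run_seed": run_seed,
                "estimator_label": "", "estimand_label": label,
                "estimand": value, "estimate": np.nan,
            })
    return rows


def simulate_design(design: Design, m: int, seed: int = 0) -> pd.DataFrame:
    """Run ``design`` ``m`` times on non-overlapping substreams.

    Returns the SimulationTable: one row per (run, estimator_label,
    estimand_label).  Per-run seeds are derived by counter from the master
    seed, so run ``i`` is reproducible independently of ``m``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    all_rows: list[dict] = []
    for i in range(int(m)):
        rs = _run_seed(seed, i)
        result = run_once(design, rs)
        all_rows.extend(_rows_from_run(result, i, rs))
    sims = pd.DataFrame(all_rows)
    for col in SIMULATION_COLUMNS:
        if col not in sims.columns:
            sims[col] = np.nan
    aux = sorted(c for c in sims.columns if c.startswith("aux_"))
    return sims[SIMULATION_COLUMNS + aux]


def _resolve_diagnosands(diagnosands) -> list:
    from . import diagnosands as dmod

    specs = []
    for d in diagnosands:
        if isinstance(d, str):
            specs.append(dmod.get_diagnosand(d))
        else:
            specs.append(d)
    return specs


def _bootstrap_se(group: pd.DataFrame, fn, options: dict,
                  n_bootstrap: int, rng: np.random.Generator) -> float:
    """SE of a diagnosand by resampling whole runs with replacement."""
    if n_bootstrap < 1:
        return float("nan")
    codes, _ = pd.factorize(group["run"], sort=True)
    n_runs = int(codes.max()) + 1
    positions = [np.flatnonzero(codes == r) for r in range(n_runs)]
    one_row_per_run = all(len(p) == 1 for p in positions)
    stats = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_runs, size=n_runs)
        if one_row_per_run:
            pos = idx
            new_run = np.arange(n_runs)
        else:
            pos = np.concatenate([positions[i] for i in idx])
            new_run = np.repeat(np.arange(n_runs),
                                [len(positions[i]) for i in idx])
        resampled = group.iloc[pos].reset_index(drop=True)
        # relabel so resampled copies of the same run stay distinct
        resampled["run"] = new_run
        stats[b], _ = fn(resampled, **options)
    if np.all(np.isnan(stats)):
        return float("nan")
    return float(np.nanstd(stats, ddof=1))


def diagnose_design(design: Design, diagnosands: Iterable, m: int,
                    n_bootstrap: int = 100, seed: int = 0,
                    sims: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate ``design`` and summarise each diagnosand with a bootstrap SE.

    ``diagnosands`` may mix names (looked up in the registry) and
    :class:`~designdiag.diagnosands.DiagnosandSpec` objects.  The bootstrap
    resamples whole simulation runs, never individual rows.  With
    ``n_bootstrap=0`` the SE column is NaN (unavailable).  A precomputed
    SimulationTable can be passed via ``sims`` to avoid re-simulation.
    """
    if m < 2 and n_bootstrap > 0:
        raise ValueError("m must be >= 2 for bootstrap standard errors")
    specs = _resolve_diagnosands(diagnosands)
    if sims is None:
        sims = simulate_design(design, m, seed)
    boot_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))

    out_rows = []
    pair_groups = list(sims.groupby(["estimator_label", "estimand_label"],
                                    dropna=False, sort=True))
    for spec in specs:
        if spec.scope == "design":
            targets = [(("*", "*"), sims)]
        else:
            targets = [(key, g) for key, g in pair_groups
                       if key[0] != "" or spec.allow_inquiry_only]
        for (est_label, estd_label), group in targets:
            spec.check(group, design)
            group = group.reset_index(drop=True)
            value, n_undefined = spec.fn(group, **spec.options)
            se = _bootstrap_se(group, spec.fn, spec.options, n_bootstrap,
                               boot_rng)
            out_rows.append({
                "design": design.name,
                "estimator_label": est_label,
                "estimand_label": estd_label,
                "diagnosand": spec.name,
                "estimate": value,
                "bootstrap_se": se,
                "n_sims": int(sims["run"].nunique()),
                "n_bootstrap": int(n_bootstrap),
                "n_undefined": int(n_undefined),
            })
    return pd.DataFrame(out_rows, columns=DIAGNOSIS_COLUMNS)


def _cell_value(diagnosis: pd.DataFrame, diagnosand: str
                ) -> tuple[float, float]:
    rows = diagnosis[(diagnosis["diagnosand"] == diagnosand)
                     & (diagnosis["estimator_label"] != "")]
    if len(rows) == 0:
        rows = diagnosis[diagnosis["diagnosand"] == diagnosand]
    row = rows.iloc[0]
    return float(row["estimate"]), float(row["bootstrap_se"])


def _score(value: float, preference: str) -> float:
    if preference == "smaller_abs":
        return abs(value)
    if preference == "smaller":
        return value
    if preference == "larger":
        return -value
    raise ConfigurationError(
        f"diagnosand has no comparison preference ({preference!r})"
    )


def compare_designs(designs: Sequence[Design],
                    models: Sequence[tuple[str, Sequence[Step]]],
                    diagnosand, m: int, seed: int = 0,
                    n_bootstrap: int = 100,
                    z: float = 2.0) -> tuple[pd.DataFrame, str | None]:
    """Diagnose each design under each alternative model bundle.

    Returns a comparison table with one row per (design, model) cell and,
    when exactly two designs and two models are supplied (original first),
    a verdict adjudicating the alternative answer strategy:

    * ``home_ground_dominance`` -- the alternative beats the original even
      under the original's model;
    * ``robustness_to_alternative_models`` -- ties under the original model
      but wins under the alternative model;
    * ``model_plausibility`` -- anything else; which strategy is better
      depends on which model one finds plausible.

    "Beats" means a better score (per the diagnosand's preference: smaller
    absolute bias, smaller RMSE, larger power, ...) by more than ``z``
    combined bootstrap SEs; within that margin is a tie.
    """
    (spec,) = _resolve_diagnosands([diagnosand])
    cells: dict[tuple[str, str], tuple[float, float]] = {}
    rows = []
    for d in designs:
        for model_name, model_steps in models:
            variant = d.with_model(model_steps, name=d.name)
            try:
                diag = diagnose_design(variant, [spec], m,
                                       n_bootstrap=n_bootstrap, seed=seed)
            except RunError as exc:
                raise ConfigurationError(
                    f"design {d.name!r} is incompatible with model "
                    f"{model_name!r}: {exc}"
                ) from exc
            value, se = _cell_value(diag, spec.name)
            cells[(d.name, model_name)] = (value, se)
            rows.append({"design": d.name, "model": model_name,
                         "diagnosand": spec.name, "estimate": value,
                         "bootstrap_se": se})
    table = pd.DataFrame(rows)
    if len(designs) != 2 or len(models) != 2:
        return table, None

    orig, alt = designs[0].name, designs[1].name
    m0, m1 = models[0][0], models[1][0]

    def beats(a, b, model):
        va, sa = cells[(a, model)]
        vb, sb = cells[(b, model)]
        tol = z * math.sqrt(sa ** 2 + sb ** 2)
        return _score(va, spec.preference) < _score(vb, spec.preference) - tol

    if beats(alt, orig, m0):
        verdict = "home_ground_dominance"
    elif not beats(orig, alt, m0) and beats(alt, orig, m1):
        verdict = "robustness_to_alternative_models"
    else:
        verdict = "model_plausibility"
    return table, verdict


# ---------------------------------------------------------------------------
# serialization

def table_to_csv(table: pd.DataFrame, path) -> None:
    """Write a SimulationTable or DiagnosisResult as UTF-8 CSV ('.' decimal)."""
    table.to_csv(path, index=False, encoding="utf-8")


def table_to_json(table: pd.DataFrame, path=None) -> str | None:
    """Serialize a result table as a JSON list of objects (NaN -> null)."""
    records = []
    for _, row in table.iterrows():
        rec = {}
        for key, value in row.items():
            if isinstance(value, float) and math.isnan(value):
                rec[key] = None
            elif isinstance(value, (np.integer,)):
                rec[key] = int(value)
            elif isinstance(value, (np.floating,)):
                rec[key] = float(value)
            else:
                rec[key] = value
        records.append(rec)
    text = json.dumps(records, indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None
    return text
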