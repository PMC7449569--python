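"""Qualitative answer strategies: Bayesian process tracing and crisp-set QCA.

Process tracing treats within-case clues (causal process observations,
CPOs) as evidence whose probability differs under rival hypotheses:
Bayes' rule converts a prior on "X caused Y" plus per-clue likelihoods
Pr(E|H) and Pr(E|not-H) into a posterior.  Clues classify into the
familiar test types -- hoop, smoking gun, doubly decisive,
straw-in-the-wind -- and strategies that seek one or several (possibly
correlated) clues can be diagnosed by enumerating truth and evidence.

Crisp-set QCA represents causal knowledge as a truth table over binary
causes and seeks the minimal set of sufficient configurations for the
outcome.  The classical Quine-McCluskey algorithm (prime implicants by
iterative merging, then an exact minimal cover) is implemented here, as
is the saturated-regression alternative that codes a configuration
positive when its predicted outcome probability exceeds one half.
Expressions are rendered in configurational notation: uppercase for a
present cause, lowercase for an absent one, "+" for OR (``aB + C``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LikelihoodTable",
    "TruthTable",
    "DNFExpression",
    "pt_posterior",
    "pt_strategy_diagnosis",
    "joint_cpo_distribution",
    "classify_test",
    "build_truth_table",
    "qmc_minimize",
    "regression_qca",
    "expression_equal",
    "inus_marginal_effect",
]

TEST_TYPES = ("hoop", "smoking_gun", "doubly_decisive", "straw_in_the_wind")


# ---------------------------------------------------------------------------
# DNF expressions

@dataclass(frozen=True)
class DNFExpression:
    """A canonical sum-of-products over binary causes.

    Each implicant maps a subset of causes to required values (1 = must be
    present, 0 = must be absent; unmentioned causes are free).  The stored
    form is canonical: implicants are tuples aligned with ``causes``
    (entries 0, 1 or None), no implicant subsumes another, and rendering
    sorts terms, so semantically equal expressions print identically.
    """

    causes: tuple[str, ...]
    implicants: frozenset = field(default_factory=frozenset)

    @staticmethod
    def from_terms(causes: Sequence[str],
                   terms: Sequence[Mapping[str, int]]) -> "DNFExpression":
        causes = tuple(causes)
        imps = set()
        for term in terms:
            unknown = set(term) - set(causes)
            if unknown:
                raise ValueError(f"unknown cause(s) {sorted(unknown)}")
            imps.add(tuple(term.get(c) for c in causes))
        return DNFExpression(causes, _drop_subsumed(imps))

    @staticmethod
    def from_string(text: str, causes: Sequence[str]) -> "DNFExpression":
        """Parse configurational notation like ``"aB + C"``.

        Cause names must be single characters (declared in uppercase);
        uppercase in a term means present, lowercase absent.
        """
        causes = tuple(causes)
        if any(len(c) != 1 for c in causes):
            raise ValueError("string parsing needs single-character causes")
        upper = {c.upper(): c for c in causes}
        terms = []
        for raw in text.split("+"):
            raw = raw.strip()
            if not raw:
                continue
            if raw == "1":
                terms.append({})
                continue
            term: dict[str, int] = {}
            for ch in raw:
                if ch in "·* ":
                    continue
                if ch.upper() not in upper:
                    raise ValueError(f"unknown literal {ch!r}")
                term[upper[ch.upper()]] = 1 if ch.isupper() else 0
            terms.append(term)
        return DNFExpression.from_terms(causes, terms)

    @staticmethod
    def empty(causes: Sequence[str]) -> "DNFExpression":
        return DNFExpression(tuple(causes), frozenset())

    @staticmethod
    def tautology(causes: Sequence[str]) -> "DNFExpression":
        causes = tuple(causes)
        return DNFExpression(causes, frozenset({(None,) * len(causes)}))

    def evaluate(self, assignment) -> bool:
        """Truth value under an assignment (mapping or 0/1 sequence)."""
        if isinstance(assignment, Mapping):
            values = tuple(int(assignment[c]) for c in self.causes)
        else:
            values = tuple(int(v) for v in assignment)
        return any(
            all(req is None or req == values[i] for i, req in enumerate(imp))
            for imp in self.implicants
        )

    def expand(self) -> frozenset:
        """The set of minterms (full assignments) where the expression holds."""
        k = len(self.causes)
        return frozenset(m for m in itertools.product((0, 1), repeat=k)
                         if self.evaluate(m))

    def render(self) -> str:
        if not self.implicants:
            return "0"
        terms = []
        for imp in sorted(self.implicants,
                          key=lambda t: tuple(-1 if v is None else v
                                              for v in t)):
            lits = []
            for name, req in zip(self.causes, imp):
                if req == 1:
                    lits.append(name.upper())
                elif req == 0:
                    lits.append(name.lower())
            if not lits:
                return "1"
            joiner = "" if all(len(l) == 1 for l in lits) else "·"
            terms.append(joiner.join(lits))
        return " + ".join(sorted(terms, key=lambda t: (len(t), t.upper(), t)))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _drop_subsumed(imps: set) -> frozenset:
    def subsumes(general, specific):
        return all(g is None or g == s for g, s in zip(general, specific))

    keep = set()
    for imp in imps:
        if any(other != imp and subsumes(other, imp) for other in imps):
            continue
        keep.add(imp)
    return frozenset(keep)


def expression_equal(e1: DNFExpression, e2: DNFExpression) -> bool:
    """Semantic equality: identical truth-table expansions."""
    if set(e1.causes) != set(e2.causes):
        raise ValueError("expressions are over different cause universes")
    if e1.causes == e2.causes:
        return e1.expand() == e2.expand()
    # rebuild e2's minterms in e1's cause order before comparing
    expanded2 = frozenset(
        tuple(m[e2.causes.index(c)] for c in e1.causes)
        for m in e2.expand())
    return e1.expand() == expanded2


def inus_marginal_effect(dnf: DNFExpression, target: str,
                         context_dist: Mapping | None = None) -> float:
    """Expected difference in the outcome from switching one cause.

    Enumerates the contexts (assignments of the other causes), computing
    E[Y(target = 1, context) - Y(target = 0, context)] under the supplied
    context distribution (uniform by default): the conditions under which
    the target is difference-making.
    """
    if target not in dnf.causes:
        raise ValueError(f"{target!r} is not among the causes {dnf.causes}")
    others = [c for c in dnf.causes if c != target]
    total = 0.0
    for ctx in itertools.product((0, 1), repeat=len(others)):
        if context_dist is None:
            p = 1.0 / 2 ** len(others)
        else:
            p = float(context_dist.get(ctx, 0.0))
        a1 = dict(zip(others, ctx))
        a0 = dict(a1)
        a1[target], a0[target] = 1, 0
        total += p * (int(dnf.evaluate(a1)) - int(dnf.evaluate(a0)))
    return total


# ---------------------------------------------------------------------------
# truth tables and Quine-McCluskey minimization

@dataclass
class TruthTable:
    """All 2^k configurations of k binary causes with outcome codings.

    ``table`` has one row per configuration with the cause columns,
    ``n_cases``, ``n_positive``, ``consistency`` (share of cases with the
    outcome present; NaN for empty rows) and ``coded`` in {0, 1,
    "remainder"}.
    """

    causes: tuple[str, ...]
    table: pd.DataFrame

    def positives(self) -> list[tuple[int, ...]]:
        rows = self.table[self.table["coded"] == 1]
        return [tuple(int(r[c]) for c in self.causes)
                for _, r in rows.iterrows()]

    def remainders(self) -> list[tuple[int, ...]]:
        rows = self.table[self.table["coded"] == "remainder"]
        return [tuple(int(r[c]) for c in self.causes)
                for _, r in rows.iterrows()]


def build_truth_table(data: pd.DataFrame, causes: Sequence[str],
                      outcome: str, threshold: float = 0.5) -> TruthTable:
    """Encode case data into a crisp-set truth table.

    A configuration is coded 1 when its consistency (share of cases with
    the outcome present) strictly exceeds ``threshold`` (default 0.5,
    mirroring the majority rule used for the regression answer strategy),
    0 otherwise, and ``"remainder"`` when no case exhibits it (limited
    diversity).
    """
    causes = tuple(causes)
    for col in list(causes) + [outcome]:
        values = set(pd.unique(data[col].dropna()))
        if not values <= {0, 1, 0.0, 1.0, True, False}:
            raise ValueError(f"column {col!r} is not binary: {values}")
    rows = []
    grouped = data.groupby([data[c].astype(int) for c in causes]).agg(
        n_cases=(outcome, "size"), n_positive=(outcome, "sum"))
    for config in itertools.product((0, 1), repeat=len(causes)):
        key = config if len(causes) > 1 else config[0]
        if key in grouped.index:
            n, npos = (int(grouped.loc[key, "n_cases"]),
                       int(grouped.loc[key, "n_positive"]))
            consistency = npos / n
            coded = 1 if consistency > threshold else 0
        else:
            n, npos, consistency, coded = 0, 0, float("nan"), "remainder"
        row = dict(zip(causes, config))
        row.update(n_cases=n, n_positive=npos, consistency=consistency,
                   coded=coded)
        rows.append(row)
    return TruthTable(causes, pd.DataFrame(rows))


def _try_merge(a: tuple, b: tuple):
    diff = None
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            continue
        if x is None or y is None or diff is not None:
            return None
        diff = i
    if diff is None:
        return None
    return a[:diff] + (None,) + a[diff + 1:]


def _prime_implicants(minterms: set) -> set:
    current = set(minterms)
    primes: set = set()
    while current:
        merged = set()
        used = set()
        cur = sorted(current, key=str)
        for i, a in enumerate(cur):
            for b in cur[i + 1:]:
                m = _try_merge(a, b)
                if m is not None:
                    merged.add(m)
                    used.add(a)
                    used.add(b)
        primes |= current - used
        current = merged
    return primes


def _literal_count(imp: tuple) -> int:
    return sum(1 for v in imp if v is not None)


def _minimal_cover(primes: list, required: list, exhaustive: bool) -> list:
    cover_of = {p: {m for m in required
                    if all(v is None or v == m[i] for i, v in enumerate(p))}
                for p in primes}
    chosen: list = []
    remaining = set(required)
    # essential primes: sole coverers of some minterm
    changed = True
    while changed:
        changed = False
        for m in list(remaining):
            holders = [p for p in primes if m in cover_of[p]]
            if len(holders) == 1 and holders[0] not in chosen:
                chosen.append(holders[0])
                remaining -= cover_of[holders[0]]
                changed = True
    candidates = [p for p in primes if p not in chosen
                  and cover_of[p] & remaining]
    if remaining:
        if exhaustive and len(candidates) <= 20:
            best = None
            for size in range(1, len(candidates) + 1):
                options = []
                for combo in itertools.combinations(candidates, size):
                    covered = set().union(*(cover_of[p] for p in combo))
                    if remaining <= covered:
                        options.append(combo)
                if options:
                    best = min(options, key=lambda c: (
                        sum(_literal_count(p) for p in c), str(sorted(c, key=str))))
                    break
            chosen.extend(best)
        else:  # greedy fallback for large problems
            while remaining:
                pick = max(candidates, key=lambda p: (
                    len(cover_of[p] & remaining), -_literal_count(p), str(p)))
                chosen.append(pick)
                remaining -= cover_of[pick]
                candidates.remove(pick)
    return chosen


def qmc_minimize(tt: TruthTable, remainder_policy: str = "exclude"
                 ) -> DNFExpression:
    """Quine-McCluskey minimization of a coded truth table.

    Prime implicants are found by iterative pairwise merging of terms
    differing in one literal; a minimal cover of the positive-coded rows
    is then selected exactly (Petrick-style exhaustive search, feasible
    for up to ~6 causes) with a greedy fallback beyond that.  Remainder
    rows (no observed cases) are treated as negative under ``"exclude"``
    (the default) or as don't-cares available for merging under
    ``"dont_care"``; don't-cares never need to be covered.  With no
    positive rows the empty expression is returned.
    """
    if remainder_policy not in ("exclude", "dont_care"):
        raise ValueError(f"unknown remainder policy {remainder_policy!r}")
    positives = tt.positives()
    if not positives:
        return DNFExpression.empty(tt.causes)
    minterms = set(positives)
    if remainder_policy == "dont_care":
        minterms |= set(tt.remainders())
    primes = sorted(_prime_implicants(minterms), key=str)
    chosen = _minimal_cover(primes, positives,
                            exhaustive=len(tt.causes) <= 6)
    return DNFExpression(tt.causes, _drop_subsumed(set(chosen)))


def regression_qca(data: pd.DataFrame, causes: Sequence[str], outcome: str,
                   threshold: float = 0.5) -> DNFExpression:
    """QCA by saturated least squares on configuration indicators.

    A saturated regression of the outcome on indicators for every observed
    configuration fits each configuration's outcome share exactly;
    configurations predicted above ``threshold`` form the set of
    sufficient conditions, which is then minimized with Quine-McCluskey.
    Unobserved configurations are remainders and excluded.
    """
    causes = tuple(causes)
    tt = build_truth_table(data, causes, outcome, threshold)  # validates
    config = np.column_stack([data[c].astype(int) for c in causes])
    keys = [tuple(row) for row in config]
    uniq = sorted(set(keys))
    X = np.column_stack([[1.0 if k == u else 0.0 for k in keys]
                         for u in uniq])
    y = np.asarray(data[outcome], dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    predicted = dict(zip(uniq, coef))
    rows = []
    for _, r in tt.table.iterrows():
        cfg = tuple(int(r[c]) for c in causes)
        if cfg in predicted:
            coded = 1 if predicted[cfg] > threshold else 0
        else:
            coded = "remainder"
        row = dict(zip(causes, cfg))
        row.update(n_cases=r["n_cases"], n_positive=r["n_positive"],
                   consistency=r["consistency"], coded=coded)
        rows.append(row)
    return qmc_minimize(TruthTable(causes, pd.DataFrame(rows)),
                        remainder_policy="exclude")


# ---------------------------------------------------------------------------
# Bayesian process tracing

@dataclass
class LikelihoodTable:
    """Per-clue likelihoods Pr(E_k | H) and Pr(E_k | not-H).

    ``rho`` optionally correlates two clues (a correlation between the
    evidence indicators, applied under each hypothesis); values outside
    the feasible Frechet bounds for the given marginals are clipped with
    a warning.
    """

    p_given_h: tuple[float, ...]
    p_given_not_h: tuple[float, ...]
    rho: float | None = None

    def __post_init__(self):
        self.p_given_h = tuple(float(p) for p in self.p_given_h)
        self.p_given_not_h = tuple(float(p) for p in self.p_given_not_h)
        if len(self.p_given_h) != len(self.p_given_not_h):
            raise ValueError("likelihood vectors must have equal length")
        for p in self.p_given_h + self.p_given_not_h:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"likelihood {p} outside [0, 1]")
        if self.rho is not None and len(self.p_given_h) != 2:
            raise ValueError("clue correlation is defined for exactly 2 CPOs")

    @property
    def n_cpos(self) -> int:
        return len(self.p_given_h)


def _joint_two(p1: float, p2: float, rho: float) -> dict:
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    s1, s2 = p1 * (1 - p1), p2 * (1 - p2)
    p11 = p1 * p2 + rho * np.sqrt(s1 * s2)
    if p11 < lo - 1e-12 or p11 > hi + 1e-12:
        warnings.warn(
            f"clue correlation {rho} infeasible for marginals "
            f"({p1}, {p2}); clipped to the Frechet bound"
        )
    p11 = float(np.clip(p11, lo, hi))
    cells = {(1, 1): p11, (1, 0): p1 - p11, (0, 1): p2 - p11,
             (0, 0): 1 - p1 - p2 + p11}
    return {k: max(v, 0.0) for k, v in cells.items()}


def joint_cpo_distribution(table: LikelihoodTable, rho: float | None = None
                           ) -> dict[bool, dict]:
    """Joint evidence-pattern probabilities under each hypothesis.

    Returns ``{True: {pattern: prob}, False: {...}}`` where a pattern is a
    tuple of 0/1 evidence indicators.  With ``rho`` (or ``table.rho``)
    unset or zero, clues are independent given the hypothesis.
    """
    rho = table.rho if rho is None else rho
    out: dict[bool, dict] = {}
    for h, marginals in ((True, table.p_given_h),
                         (False, table.p_given_not_h)):
        if rho and table.n_cpos == 2:
            out[h] = _joint_two(marginals[0], marginals[1], float(rho))
        else:
            cells = {}
            for pattern in itertools.product((0, 1), repeat=table.n_cpos):
                prob = 1.0
                for e, p in zip(pattern, marginals):
                    prob *= p if e else (1 - p)
                cells[pattern] = prob
            out[h] = cells
    return out


def _pattern_likelihood(cells: dict, observed: Sequence) -> float:
    total = 0.0
    for pattern, prob in cells.items():
        if all(o is None or o == e for o, e in zip(observed, pattern)):
            total += prob
    return total


def pt_posterior(prior: float, table: LikelihoodTable,
                 observed: Sequence) -> float:
    """Posterior Pr(H | evidence pattern) by exact Bayes.

    ``observed`` has one entry per clue: 1 (sought and seen), 0 (sought
    and not seen), or None (not sought -- marginalized out, so a pattern
    with no observations returns the prior).
    """
    if not 0.0 <= prior <= 1.0:
        raise ValueError(f"prior {prior} outside [0, 1]")
    joint = joint_cpo_distribution(table)
    lh = _pattern_likelihood(joint[True], observed)
    lnh = _pattern_likelihood(joint[False], observed)
    denom = prior * lh + (1 - prior) * lnh
    if denom == 0:
        raise ValueError("observed evidence pattern has zero probability")
    return prior * lh / denom


_STRATEGIES = {"cpo1_only": (0,), "cpo2_only": (1,), "both": (0, 1)}


def pt_strategy_diagnosis(prior: float, table: LikelihoodTable,
                          strategy="both", rho: float | None = None
                          ) -> float:
    """Expected absolute posterior error of a clue-seeking strategy.

    Enumerates truth (H with the prior probability) and evidence patterns
    for the sought clues, scoring each branch |1(H) - posterior|; the
    return value is the expectation, so a lower value means better
    inferences on average.  ``strategy`` is ``"cpo1_only"``,
    ``"cpo2_only"``, ``"both"``, or an explicit tuple of clue indices.
    """
    sought = _STRATEGIES.get(strategy, strategy)
    sought = tuple(sought)
    k = table.n_cpos
    if rho is not None:
        table = LikelihoodTable(table.p_given_h, table.p_given_not_h, rho)
    joint = joint_cpo_distribution(table)
    expected = 0.0
    for h, p_h in ((True, prior), (False, 1 - prior)):
        if p_h == 0:
            continue
        for pattern in itertools.product((0, 1), repeat=len(sought)):
            observed: list = [None] * k
            for idx, e in zip(sought, pattern):
                observed[idx] = e
            p_pattern = _pattern_likelihood(joint[h], observed)
            if p_pattern == 0:
                continue
            post = pt_posterior(prior, table, observed)
            expected += p_h * p_pattern * abs(float(h) - post)
    return expected


def classify_test(pr_e_h: float, pr_e_nh: float) -> str:
    """Classify a clue by its likelihoods into the four ideal test types.

    Documented thresholds: hoop if Pr(E|H) >= 0.9 (nearly certain to be
    seen when true); smoking gun if Pr(E|not-H) <= 0.1 (very unlikely when
    false); doubly decisive if both; straw-in-the-wind otherwise.
    """
    for p in (pr_e_h, pr_e_nh):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"likelihood {p} outside [0, 1]")
    hoop = pr_e_h >= 0.9
    gun = pr_e_nh <= 0.1
    if hoop and gun:
        return "doubly_decisive"
    if hoop:
        return "hoop"
    if gun:
        return "smoking_gun"
    return "straw_in_the_wind"
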