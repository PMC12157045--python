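"""Exact probabilistic queries on fitted networks.

Evidence-setting ("clamping") follows the evidence semantics of GeNIe-
style simulators: clamped variables are conditioned on, and every other
variable's exact conditional marginal is read off. Queries run by
variable elimination with a min-fill ordering; at the variable counts
this pipeline produces (tens of variables) that is exact and fast. The
module also ranks k-gene state combinations by their exact conditional
probability under a condition clamp.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ImpossibleEvidenceError, InvalidArgumentError, KeyNotFoundError
from .model import NetworkModel


@dataclass
class Factor:
    """A non-negative table over named discrete variables (axes in order)."""

    variables: tuple[str, ...]
    table: np.ndarray

    def marginal(self, var: str) -> np.ndarray:
        axes = tuple(i for i, v in enumerate(self.variables) if v != var)
        out = self.table.sum(axis=axes)
        return out / out.sum()


def _factor_multiply(a: Factor, b: Factor) -> Factor:
    out_vars = a.variables + tuple(v for v in b.variables if v not in a.variables)
    ax = {v: i for i, v in enumerate(out_vars)}

    def expand(f: Factor) -> np.ndarray:
        src = [ax[v] for v in f.variables]
        order = np.argsort(src)  # destination axes must come out ascending
        t = f.table.transpose(order)
        shape = [1] * len(out_vars)
        for v, s in zip([f.variables[i] for i in order], t.shape):
            shape[ax[v]] = s
        return t.reshape(shape)

    return Factor(out_vars, expand(a) * expand(b))


def _sum_out(f: Factor, var: str) -> Factor:
    i = f.variables.index(var)
    return Factor(f.variables[:i] + f.variables[i + 1:], f.table.sum(axis=i))


def _reduce(f: Factor, var: str, state: int) -> Factor:
    i = f.variables.index(var)
    return Factor(f.variables[:i] + f.variables[i + 1:],
                  np.take(f.table, state, axis=i))


def _cpt_factor(model: NetworkModel, v: str) -> Factor:
    s = model.structure
    parents = s.parents(v)
    shape = tuple(s.arity(p) for p in parents) + (s.arity(v),)
    return Factor(parents + (v,), model.cpts[v].reshape(shape))


def _validate_assignment(model: NetworkModel, assignment: dict) -> None:
    s = model.structure
    for v, state in assignment.items():
        if v not in s.index:
            raise KeyNotFoundError(f"unknown variable {v!r}")
        if not 0 <= state < s.arity(v):
            raise InvalidArgumentError(
                f"state {state} invalid for {v!r} (arity {s.arity(v)})")


def joint_probability(model: NetworkModel, assignment: dict) -> float:
    """Product of CPT entries for a full assignment of every variable."""
    s = model.structure
    if set(assignment) != set(s.variables):
        raise InvalidArgumentError("assignment must cover every variable")
    _validate_assignment(model, assignment)
    p = 1.0
    for v in s.variables:
        parents = s.parents(v)
        arities = tuple(s.arity(q) for q in parents)
        j = int(np.ravel_multi_index(
            tuple(assignment[q] for q in parents), arities)) if parents else 0
        p *= float(model.cpts[v][j, assignment[v]])
    return p


def _min_fill_order(factors: list[Factor], eliminate: set[str]) -> list[str]:
    """Greedy min-fill elimination ordering on the factor interaction graph."""
    neighbors: dict[str, set[str]] = {v: set() for f in factors for v in f.variables}
    for f in factors:
        for a, b in itertools.combinations(f.variables, 2):
            neighbors[a].add(b)
            neighbors[b].add(a)
    order = []
    remaining = set(eliminate)
    while remaining:
        def fill_cost(v: str) -> int:
            nb = neighbors[v] & set(neighbors)
            return sum(1 for a, b in itertools.combinations(nb, 2)
                       if b not in neighbors[a])
        v = min(sorted(remaining), key=fill_cost)
        nb = neighbors.pop(v)
        for a in nb:
            if a in neighbors:
                neighbors[a] |= (nb - {a})
                neighbors[a].discard(v)
        order.append(v)
        remaining.discard(v)
    return order


def _eliminate(factors: list[Factor], eliminate: set[str]) -> list[Factor]:
    for v in _min_fill_order(factors, eliminate):
        touching = [f for f in factors if v in f.variables]
        rest = [f for f in factors if v not in f.variables]
        prod = touching[0]
        for f in touching[1:]:
            prod = _factor_multiply(prod, f)
        factors = rest + [_sum_out(prod, v)]
    return factors


def _reduced_factors(model: NetworkModel, evidence: dict) -> list[Factor]:
    factors = [_cpt_factor(model, v) for v in model.structure.variables]
    out = []
    for f in factors:
        for v, state in evidence.items():
            if v in f.variables:
                f = _reduce(f, v, state)
        out.append(f)
    return out


def query(model: NetworkModel, targets, evidence: dict | None = None) -> Factor:
    """Exact joint conditional P(targets | evidence) by variable elimination.

    Raises :class:`ImpossibleEvidenceError` when the clamped evidence has
    probability zero under the model.
    """
    targets = list(targets)
    evidence = dict(evidence or {})
    _validate_assignment(model, evidence)
    _validate_assignment(model, {t: 0 for t in targets})
    if set(targets) & set(evidence):
        raise InvalidArgumentError("targets must be disjoint from evidence")
    factors = _reduced_factors(model, evidence)
    all_vars = {v for f in factors for v in f.variables}
    factors = _eliminate(factors, all_vars - set(targets))
    result = factors[0]
    for f in factors[1:]:
        result = _factor_multiply(result, f)
    # order axes as requested
    if result.variables:
        order = [result.variables.index(t) for t in targets]
        result = Factor(tuple(targets), result.table.transpose(order))
    z = float(result.table.sum())
    if z <= 0:
        raise ImpossibleEvidenceError(f"evidence {evidence} has probability 0")
    return Factor(result.variables, result.table / z)


def probability_of_evidence(model: NetworkModel, evidence: dict) -> float:
    """Exact P(evidence) by eliminating every other variable."""
    _validate_assignment(model, evidence)
    factors = _reduced_factors(model, evidence)
    all_vars = {v for f in factors for v in f.variables}
    factors = _eliminate(factors, all_vars)
    p = 1.0
    for f in factors:
        p *= float(f.table.sum()) if f.variables else float(f.table)
    return p


@dataclass
class EvidenceScenario:
    """A GeNIe-style simulation: clamp some variables, read all other marginals."""

    clamped: dict[str, int]
    query_vars: list[str] | None = None  # default: all unclamped variables


def simulate_scenario(model: NetworkModel, scenario: EvidenceScenario):
    """Per-variable conditional marginals under the clamped evidence.

    Returns a DataFrame (rows = variables, columns = P(state=k)); binary
    variables leave state 2 as NaN.
    """
    import pandas as pd

    s = model.structure
    targets = scenario.query_vars or [v for v in s.variables
                                      if v not in scenario.clamped]
    max_r = max(s.arity(v) for v in targets) if targets else 2
    rows = {}
    for v in targets:
        dist = query(model, [v], scenario.clamped).table
        rows[v] = list(dist) + [np.nan] * (max_r - len(dist))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"P(state={k})" for k in range(max_r)])


def scenario_contrast(model: NetworkModel, scenario_a: EvidenceScenario,
                      scenario_b: EvidenceScenario):
    """Side-by-side marginals for two scenarios (e.g. PiZ=1 vs PiZ=0)."""
    import pandas as pd

    a = simulate_scenario(model, scenario_a)
    b = simulate_scenario(model, scenario_b)
    return pd.concat({"A": a, "B": b}, axis=1)


@dataclass
class CombinationRow:
    assignment: dict[str, int]
    p_states_given_condition: float
    p_condition_given_states: float | None


@dataclass
class CombinationResult:
    """Ranked k-gene state combinations under a condition clamp."""

    k: int
    candidates: tuple[str, ...]
    condition: dict[str, int]
    ranked: list[CombinationRow] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [{"assignment": r.assignment,
                 "p_states_given_condition": r.p_states_given_condition,
                 "p_condition_given_states": r.p_condition_given_states}
                for r in self.ranked]


def top_state_combinations(model: NetworkModel, candidates, k: int,
                           condition: dict | None = None) -> CombinationResult:
    """Rank all C(n, k) * prod(arity) k-variable state assignments.

    Each assignment is scored by the exact P(states | condition); ties
    break lexicographically by (variable names, states) so the ranking is
    deterministic. P(condition | states) is reported alongside.
    """
    candidates = [c for c in candidates]
    condition = dict(condition or {})
    if k > len(candidates):
        raise InvalidArgumentError(f"k={k} exceeds {len(candidates)} candidates")
    if set(candidates) & set(condition):
        raise InvalidArgumentError("candidates must be disjoint from the condition")
    _validate_assignment(model, condition)
    s = model.structure
    p_cond = probability_of_evidence(model, condition) if condition else 1.0
    if condition and p_cond <= 0:
        raise ImpossibleEvidenceError(f"condition {condition} has probability 0")
    rows: list[CombinationRow] = []
    for combo in itertools.combinations(candidates, k):
        for states in itertools.product(*(range(s.arity(v)) for v in combo)):
            assign = dict(zip(combo, states))
            p_joint = probability_of_evidence(model, {**assign, **condition})
            p_states = probability_of_evidence(model, assign) if condition else p_joint
            rows.append(CombinationRow(
                assign,
                p_joint / p_cond,
                (p_joint / p_states) if (condition and p_states > 0) else None))
    rows.sort(key=lambda r: (-r.p_states_given_condition,
                             tuple(sorted(r.assignment.items()))))
    return CombinationResult(k, tuple(candidates), condition, rows)


def minimal_necessary_set(model: NetworkModel, candidates,
                          condition: dict | None = None,
                          threshold: float = 0.5, max_k: int | None = None) -> int:
    """Smallest k whose top assignment's conditional probability exceeds
    ``threshold``; returns 0 if no k up to ``max_k`` (default: all) does."""
    candidates = list(candidates)
    max_k = max_k or len(candidates)
    for k in range(1, max_k + 1):
        result = top_state_combinations(model, candidates, k, condition)
        if result.ranked and result.ranked[0].p_states_given_condition > threshold:
            return k
    return 0
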