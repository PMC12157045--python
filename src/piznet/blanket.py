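"""Markov-blanket extraction and Markov-condition verification.

The first-degree Markov blanket of a node is its parents, children and
co-parents (parents of its children); conditioning on it renders the
node independent of the rest of the network. The second-degree blanket
unions the first-degree blanket with each member's own first-degree
blanket. Both exclude the target node itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import KeyNotFoundError
from .model import DagStructure, NetworkModel


def _check_var(s: DagStructure, x: str) -> None:
    if x not in s.index:
        raise KeyNotFoundError(f"unknown variable {x!r}")


def first_degree_mb(s: DagStructure, x: str) -> set[str]:
    """parents(x) | children(x) | parents-of-children(x), excluding x."""
    _check_var(s, x)
    children = set(s.children(x))
    mb = set(s.parents(x)) | children
    for c in children:
        mb |= set(s.parents(c))
    mb.discard(x)
    return mb


def second_degree_mb(s: DagStructure, x: str) -> set[str]:
    """MB(x) plus the first-degree blanket of every member, excluding x."""
    mb = first_degree_mb(s, x)
    out = set(mb)
    for y in mb:
        out |= first_degree_mb(s, y)
    out.discard(x)
    return out


@dataclass
class BlanketReport:
    """First- and second-degree blanket membership with per-member roles.

    Roles: 'parent', 'child', 'spouse' (co-parent) for first-degree
    members (a member can hold several), 'second-degree' for members only
    reachable through the blanket expansion.
    """

    target: str
    first_degree: set[str]
    second_degree: set[str]
    roles: dict[str, set[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "first_degree": sorted(self.first_degree),
            "second_degree": sorted(self.second_degree),
            "roles": {v: sorted(r) for v, r in sorted(self.roles.items())},
        }


def blanket_report(s: DagStructure, target: str) -> BlanketReport:
    """Both blankets of ``target`` with member roles."""
    first = first_degree_mb(s, target)
    second = second_degree_mb(s, target)
    parents = set(s.parents(target))
    children = set(s.children(target))
    spouses = set()
    for c in children:
        spouses |= set(s.parents(c)) - {target}
    roles: dict[str, set[str]] = {}
    for v in second:
        r = set()
        if v in parents:
            r.add("parent")
        if v in children:
            r.add("child")
        if v in spouses:
            r.add("spouse")
        if not r:
            r.add("second-degree")
        roles[v] = r
    return BlanketReport(target, first, second, roles)


@dataclass
class IndependenceReport:
    """Outcome of one Markov-condition check.

    ``applicable`` is False when y is a descendant of x (the condition
    makes no claim there); ``independent`` records whether
    P(x | parents(x), y) matched P(x | parents(x)) on every positive-
    probability configuration; ``max_deviation`` is the largest absolute
    difference observed.
    """

    x: str
    y: str
    conditioning: tuple[str, ...]
    applicable: bool
    independent: bool
    max_deviation: float


def conditional_independence_check(model: NetworkModel, x: str, y: str,
                                   conditioning=None, tol: float = 1e-9,
                                   ) -> IndependenceReport:
    """Verify X independent of Y given parents(X) by exact enumeration.

    Checks the Markov condition on the fitted joint: for every
    configuration of (parents(x), y) with positive probability,
    P(x | parents(x), y) must equal P(x | parents(x)) within ``tol``.
    Applicable only when y is not a descendant of x.
    """
    from .errors import ImpossibleEvidenceError
    from .inference import query  # local import: inference depends on model only

    s = model.structure
    for v in (x, y):
        _check_var(s, v)
    g = s.to_networkx()
    if y in nx.descendants(g, x):
        return IndependenceReport(x, y, (), False, False, float("nan"))
    cond = tuple(conditioning) if conditioning is not None else s.parents(x)
    if y in cond:
        # conditioning on y itself: X | (cond, y) == X | cond trivially
        return IndependenceReport(x, y, cond, True, True, 0.0)
    max_dev = 0.0
    for pa_states in np.ndindex(*(s.arity(p) for p in cond)):
        evidence = dict(zip(cond, (int(v) for v in pa_states)))
        try:
            base = query(model, [x], evidence).table
        except ImpossibleEvidenceError:
            continue  # zero-probability parent configuration
        for ys in range(s.arity(y)):
            try:
                with_y = query(model, [x], {**evidence, y: ys}).table
            except ImpossibleEvidenceError:
                continue  # zero-probability (parents, y) configuration
            max_dev = max(max_dev, float(np.abs(with_y - base).max()))
    return IndependenceReport(x, y, cond, True, max_dev <= tol, max_dev)
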