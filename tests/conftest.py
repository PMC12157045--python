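"""Shared fixtures and independent oracles used across the suite."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from piznet import DagStructure, DiscreteDataset, NetworkModel

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_dataset(states: dict[str, list[int]], arities: dict[str, int] | None = None,
                 ) -> DiscreteDataset:
    """Build a DiscreteDataset from per-variable state lists."""
    n = len(next(iter(states.values())))
    frame = pd.DataFrame(states, index=[f"s{i}" for i in range(n)]).T
    return DiscreteDataset(frame, arities or {v: 3 for v in states})


def random_model(n_vars: int, seed: int, edge_prob: float = 0.4,
                 arity: int = 3) -> NetworkModel:
    """Random DAG + random CPTs, built directly (not via the search stack)."""
    rng = np.random.default_rng(seed)
    names = tuple(chr(ord("A") + i) for i in range(n_vars))
    arcs = set()
    for i, j in itertools.combinations(range(n_vars), 2):
        if rng.random() < edge_prob:
            arcs.add((names[i], names[j]))  # i < j: acyclic by construction
    s = DagStructure(names, tuple([arity] * n_vars), frozenset(arcs))
    cpts = {}
    for v in names:
        q = int(np.prod([s.arity(p) for p in s.parents(v)])) or 1
        cpts[v] = rng.dirichlet(np.ones(s.arity(v)), size=q)
    return NetworkModel(s, cpts, 0.0, 0.0)


def enumerate_joint(model: NetworkModel) -> dict[tuple[int, ...], float]:
    """Brute-force joint distribution by explicit CPT products (oracle)."""
    s = model.structure
    out = {}
    for assign in itertools.product(*(range(s.arity(v)) for v in s.variables)):
        a = dict(zip(s.variables, assign))
        p = 1.0
        for v in s.variables:
            parents = s.parents(v)
            j = 0
            for par in parents:  # mixed radix, first parent most significant
                j = j * s.arity(par) + a[par]
            p *= float(model.cpts[v][j, a[v]])
        out[assign] = p
    return out


def brute_force_query(model: NetworkModel, targets, evidence) -> np.ndarray:
    """Oracle conditional P(targets | evidence) by joint summation."""
    s = model.structure
    joint = enumerate_joint(model)
    idx = {v: i for i, v in enumerate(s.variables)}
    shape = tuple(s.arity(t) for t in targets)
    table = np.zeros(shape)
    for assign, p in joint.items():
        if all(assign[idx[v]] == st for v, st in evidence.items()):
            table[tuple(assign[idx[t]] for t in targets)] += p
    z = table.sum()
    if z == 0:
        raise ZeroDivisionError("evidence has probability zero")
    return table / z


def brute_force_first_degree_mb(s: DagStructure, x: str) -> set[str]:
    """Literal re-derivation: parents, children, parents-of-children."""
    parents = {u for (u, v) in s.arcs if v == x}
    children = {v for (u, v) in s.arcs if u == x}
    coparents = {u for (u, v) in s.arcs if v in children}
    return (parents | children | coparents) - {x}


def random_dag(n_nodes: int, seed: int, edge_prob: float = 0.3) -> DagStructure:
    rng = np.random.default_rng(seed)
    names = tuple(f"n{i}" for i in range(n_nodes))
    perm = rng.permutation(n_nodes)
    arcs = set()
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                arcs.add((names[perm[a]], names[perm[b]]))
    return DagStructure(names, tuple([3] * n_nodes), frozenset(arcs))
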