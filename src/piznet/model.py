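"""Discrete Bayesian-network representation and BDe scoring.

A network is a DAG over the dataset's variables plus one conditional
probability table (CPT) per variable. Structures are scored with the
Bayesian Dirichlet equivalent (BDe) marginal likelihood under a uniform
structure prior: with pseudo-counts alpha_ijk = ESS/(q_i*r_i) the score
of a family (node i, parent configuration j, child state k) is

    sum_j [lnG(a_ij) - lnG(a_ij + N_ij)]
      + sum_jk [lnG(a_ijk + N_ijk) - lnG(a_ijk)]

which makes Markov-equivalent DAGs score identically (likelihood
equivalence). CPTs are posterior means theta_ijk = (N_ijk + a_ijk) /
(N_ij + a_ij).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import networkx as nx
from scipy.special import gammaln

from .errors import InvalidArgumentError, KeyNotFoundError
from .preprocess import DiscreteDataset

Arc = tuple[str, str]


@dataclass(frozen=True)
class DagStructure:
    """Directed acyclic graph over named discrete variables.

    ``variables`` fixes the canonical ordering (used for deterministic
    parent ordering and mixed-radix parent-configuration indexing);
    ``arities`` is parallel to it; ``arcs`` is a set of (parent, child)
    pairs.
    """

    variables: tuple[str, ...]
    arities: tuple[int, ...]
    arcs: frozenset[Arc] = frozenset()

    def __post_init__(self) -> None:
        if len(self.variables) != len(set(self.variables)):
            raise InvalidArgumentError("duplicate variable names")
        if len(self.arities) != len(self.variables):
            raise InvalidArgumentError("arities must parallel variables")
        idx = self.index
        for u, v in self.arcs:
            if u not in idx or v not in idx:
                raise KeyNotFoundError(f"arc ({u}, {v}) uses unknown variable")
            if u == v:
                raise InvalidArgumentError(f"self-arc on {u}")

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def arity(self, v: str) -> int:
        return self.arities[self.index[v]]

    def parents(self, v: str) -> tuple[str, ...]:
        """Parents of ``v`` in canonical (variable-order) sequence."""
        idx = self.index
        ps = [u for u, c in self.arcs if c == v]
        return tuple(sorted(ps, key=idx.__getitem__))

    def children(self, v: str) -> tuple[str, ...]:
        idx = self.index
        cs = [c for u, c in self.arcs if u == v]
        return tuple(sorted(cs, key=idx.__getitem__))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.arcs)
        return g

    def with_arcs(self, arcs) -> "DagStructure":
        return replace(self, arcs=frozenset(arcs))

    def induced_subgraph(self, variables) -> "DagStructure":
        """Restriction to ``variables``: keeps arcs with both ends retained."""
        keep = [v for v in self.variables if v in set(variables)]
        idx = self.index
        return DagStructure(
            tuple(keep), tuple(self.arities[idx[v]] for v in keep),
            frozenset((u, v) for u, v in self.arcs
                      if u in set(keep) and v in set(keep)))

    @staticmethod
    def empty(data: DiscreteDataset) -> "DagStructure":
        """Edgeless structure over a dataset's variables."""
        vs = tuple(data.variables)
        return DagStructure(vs, tuple(data.arities[v] for v in vs))


def validate_dag(s: DagStructure) -> list[str] | None:
    """Return ``None`` if acyclic, else one offending cycle as a node list."""
    g = s.to_networkx()
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [u for u, _ in cycle]


@dataclass
class ScoreParams:
    """BDe prior: equivalent sample size (total pseudo-count mass)."""

    ess: float = 1.0

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise InvalidArgumentError("ess must be > 0")


@dataclass
class FamilyCounts:
    """Sufficient statistics N_ijk for one node given its parent set.

    ``counts`` has shape (q, r): q parent configurations (mixed-radix index
    over parents in canonical order, first parent most significant; q = 1
    if parentless) by r child states.
    """

    node: str
    parents: tuple[str, ...]
    counts: np.ndarray
    parent_arities: tuple[int, ...]

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def r(self) -> int:
        return self.counts.shape[1]


def family_counts(data: DiscreteDataset, node: str, parents) -> FamilyCounts:
    """Cross-tabulate a node's states against its parents' joint configuration."""
    parents = tuple(parents)
    for v in (node, *parents):
        if v not in data.states.index:
            raise KeyNotFoundError(f"unknown variable {v!r}")
    if node in parents:
        raise InvalidArgumentError(f"{node!r} cannot be its own parent")
    x = data.states.loc[node].to_numpy().astype(np.intp)  # empty rows are float
    r = data.arities[node]
    if parents:
        p_arities = tuple(data.arities[p] for p in parents)
        rows = data.states.loc[list(parents)].to_numpy().astype(np.intp)
        j = np.ravel_multi_index(rows, p_arities)
        q = int(np.prod(p_arities))
    else:
        p_arities = ()
        j = np.zeros(x.shape[0], dtype=np.intp)
        q = 1
    counts = np.bincount(j * r + x, minlength=q * r).reshape(q, r)
    return FamilyCounts(node, parents, counts, p_arities)


def bde_family_score(counts: FamilyCounts, prior: ScoreParams | None = None) -> float:
    """Log marginal likelihood of one family under the BDe Dirichlet prior."""
    prior = prior or ScoreParams()
    q, r = counts.q, counts.r
    a_ijk = prior.ess / (q * r)
    a_ij = prior.ess / q
    n = counts.counts
    n_ij = n.sum(axis=1)
    score = float(np.sum(gammaln(a_ij) - gammaln(a_ij + n_ij))
                  + np.sum(gammaln(a_ijk + n) - gammaln(a_ijk)))
    return score


def bde_network_score(s: DagStructure, data: DiscreteDataset,
                      prior: ScoreParams | None = None) -> tuple[float, float]:
    """Decomposable network score: sum of family scores, plus its normalized form.

    The normalized score divides by (n_samples * n_variables); only relative
    comparisons of normalized scores are meaningful (the search stopping
    rule), so any fixed positive normalization would do.
    """
    if set(s.variables) != set(data.variables):
        raise InvalidArgumentError("structure and data variables differ")
    log_score = sum(
        bde_family_score(family_counts(data, v, s.parents(v)), prior)
        for v in s.variables)
    norm = log_score / (max(data.n_samples, 1) * len(s.variables))
    return log_score, norm


@dataclass
class EdgeAnnotation:
    """Score contribution and association sign of one arc.

    ``strength`` is the drop in network log-score when the arc is removed
    (non-negative when the arc improves the score); ``sign`` is '+' for
    positive ordinal association between parent and child states, '-' for
    inhibition.
    """

    strength: float
    sign: str


@dataclass
class NetworkModel:
    """A fitted network: structure, posterior-mean CPTs and scores.

    ``cpts[v]`` has shape (q_v, r_v) with rows indexed by the mixed-radix
    parent configuration (parents in canonical order) and rows summing to 1.
    """

    structure: DagStructure
    cpts: dict[str, np.ndarray]
    log_score: float
    normalized_score: float
    edge_annotations: dict[Arc, EdgeAnnotation] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.structure.variables),
            "arities": list(self.structure.arities),
            "arcs": sorted([list(a) for a in self.structure.arcs]),
            "cpts": {v: t.tolist() for v, t in self.cpts.items()},
            "log_score": self.log_score,
            "normalized_score": self.normalized_score,
            "edge_annotations": {
                f"{u}->{v}": {"strength": a.strength, "sign": a.sign}
                for (u, v), a in sorted(self.edge_annotations.items())},
        }

    @staticmethod
    def from_dict(d: dict) -> "NetworkModel":
        s = DagStructure(tuple(d["variables"]), tuple(d["arities"]),
                         frozenset(tuple(a) for a in d["arcs"]))
        ann = {}
        for key, a in d.get("edge_annotations", {}).items():
            u, v = key.split("->")
            ann[(u, v)] = EdgeAnnotation(a["strength"], a["sign"])
        return NetworkModel(s, {v: np.asarray(t) for v, t in d["cpts"].items()},
                            d["log_score"], d["normalized_score"], ann)


def fit_cpts(s: DagStructure, data: DiscreteDataset,
             prior: ScoreParams | None = None) -> NetworkModel:
    """Posterior-mean CPTs theta_ijk = (N_ijk + a_ijk)/(N_ij + a_ij)."""
    prior = prior or ScoreParams()
    cpts: dict[str, np.ndarray] = {}
    for v in s.variables:
        fc = family_counts(data, v, s.parents(v))
        a_ijk = prior.ess / (fc.q * fc.r)
        a_ij = prior.ess / fc.q
        theta = (fc.counts + a_ijk) / (fc.counts.sum(axis=1, keepdims=True) + a_ij)
        cpts[v] = theta
    log_score, norm = bde_network_score(s, data, prior)
    return NetworkModel(s, cpts, log_score, norm)


_ORDINAL = np.array([0.0, -1.0, 1.0])  # state code 0 -> 0, 1 (low) -> -1, 2 (high) -> +1


def _ordinal_codes(data: DiscreteDataset, v: str) -> np.ndarray:
    x = data.states.loc[v].to_numpy()
    if data.arities[v] == 2:  # condition variable: 0/1 already ordinal
        return x.astype(float)
    return _ORDINAL[x]


def annotate_edges(model: NetworkModel, data: DiscreteDataset,
                   prior: ScoreParams | None = None) -> NetworkModel:
    """Attach per-arc strength (score drop on removal) and sign annotations.

    Sign is the sign of the Pearson correlation between the ordinal-coded
    states of parent and child (low -> -1, no change -> 0, high -> +1;
    condition 0/1); '-' marks inhibition. A zero or undefined correlation
    is reported as '+'.
    """
    full, _ = bde_network_score(model.structure, data, prior)
    ann: dict[Arc, EdgeAnnotation] = {}
    for (u, v) in sorted(model.structure.arcs):
        reduced = model.structure.with_arcs(model.structure.arcs - {(u, v)})
        red_score, _ = bde_network_score(reduced, data, prior)
        strength = full - red_score
        xu, xv = _ordinal_codes(data, u), _ordinal_codes(data, v)
        if xu.std() == 0 or xv.std() == 0:
            sign = "+"
        else:
            corr = float(np.corrcoef(xu, xv)[0, 1])
            sign = "-" if corr < 0 else "+"
        ann[(u, v)] = EdgeAnnotation(strength, sign)
    return replace(model, edge_annotations=ann)
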