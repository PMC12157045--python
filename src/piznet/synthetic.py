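"""Ground-truth network and count-matrix simulator.

Emulates the study design the pipeline targets — two conditions
(wildtype / PiZ) with a handful of liver RNA-seq samples each — from a
known generative model, so every downstream stage can be tested against
a retained truth:

1. a random DAG over gene variables plus a parentless binary condition
   node (the genotype is an intervention, never a downstream effect; the
   structure learner is not told this),
2. random Dirichlet CPTs over the 3 gene states {1=low, 0=no change,
   2=high},
3. ancestral sampling of discrete states per sample,
4. negative-binomial counts whose per-gene mean is the baseline mu_g
   scaled by f^m with m = -1, 0, +1 for states low/none/high — a ladder
   symmetric on the log scale so z-score discretization can invert it.

The negative binomial is parameterized by mean mu and dispersion alpha
with variance mu + alpha*mu^2; alpha -> 0 degenerates to Poisson.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, KeyNotFoundError
from .model import DagStructure, validate_dag
from .preprocess import CONDITION_VAR, CountMatrix, DiscreteDataset

#: exponent of the fold ladder per state code: state 0 -> f^0, 1 -> f^-1, 2 -> f^+1
_STATE_EXPONENT = np.array([0, -1, 1])


@dataclass
class CountParams:
    """Per-gene NB count-generation parameters."""

    baseline: dict[str, float]  # mu_g > 0
    fold: float                 # f > 1
    dispersion: float           # alpha > 0 (or ~0 for Poisson)

    def __post_init__(self) -> None:
        if any(mu <= 0 for mu in self.baseline.values()):
            raise InvalidArgumentError("baseline means must be > 0")
        if self.fold <= 1:
            raise InvalidArgumentError("fold factor must be > 1")
        if self.dispersion < 0:
            raise InvalidArgumentError("dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and check a synthetic dataset."""

    dag: DagStructure
    cpts: dict[str, np.ndarray]
    count_params: CountParams
    seed: int

    def to_dict(self) -> dict:
        return {
            "variables": list(self.dag.variables),
            "arities": list(self.dag.arities),
            "arcs": sorted([list(a) for a in self.dag.arcs]),
            "cpts": {v: t.tolist() for v, t in self.cpts.items()},
            "count_params": {
                "baseline": self.count_params.baseline,
                "fold": self.count_params.fold,
                "dispersion": self.count_params.dispersion,
            },
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "SyntheticTruth":
        dag = DagStructure(tuple(d["variables"]), tuple(d["arities"]),
                           frozenset(tuple(a) for a in d["arcs"]))
        cp = d["count_params"]
        return SyntheticTruth(
            dag, {v: np.asarray(t) for v, t in d["cpts"].items()},
            CountParams(dict(cp["baseline"]), cp["fold"], cp["dispersion"]),
            int(d["seed"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @staticmethod
    def from_json(s: str) -> "SyntheticTruth":
        return SyntheticTruth.from_dict(json.loads(s))


def _gene_names(n_genes: int) -> list[str]:
    return [f"g{i + 1:03d}" for i in range(n_genes)]


def sample_ground_truth_dag(n_genes: int, max_parents: int = 3,
                            edge_prob: float = 0.05, seed: int = 0) -> DagStructure:
    """Random DAG over ``n_genes`` gene variables plus the condition node.

    A random permutation of the genes fixes a topological order with the
    condition node first; each candidate arc from an earlier node into a
    gene is kept with probability ``edge_prob``, thinned uniformly at
    random to respect the per-gene in-degree cap. The condition node has
    no parents.
    """
    if n_genes < 1:
        raise InvalidArgumentError("n_genes must be >= 1")
    if not 0 <= edge_prob <= 1:
        raise InvalidArgumentError("edge_prob must be in [0, 1]")
    if max_parents < 0:
        raise InvalidArgumentError("max_parents must be >= 0")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    order = [CONDITION_VAR] + [genes[i] for i in rng.permutation(n_genes)]
    arcs: set[tuple[str, str]] = set()
    for pos in range(1, len(order)):
        child = order[pos]
        candidates = [order[k] for k in range(pos)
                      if rng.random() < edge_prob]
        if len(candidates) > max_parents:
            pick = rng.choice(len(candidates), size=max_parents, replace=False)
            candidates = [candidates[i] for i in sorted(pick)]
        arcs.update((p, child) for p in candidates)
    variables = tuple(genes) + (CONDITION_VAR,)
    arities = tuple([3] * n_genes + [2])
    dag = DagStructure(variables, arities, frozenset(arcs))
    assert validate_dag(dag) is None
    return dag


#: default Dirichlet weights per gene-state code (0=no change, 1=low, 2=high):
#: most genes show no change in most samples; deviations are minority states.
BASELINE_STATE_WEIGHTS = (4.0, 0.4, 0.4)


def sample_cpts(dag: DagStructure, concentration: float = 1.0, seed: int = 0,
                state_weights: tuple[float, ...] | None = None,
                ) -> dict[str, np.ndarray]:
    """Dirichlet CPT rows for every variable and parent configuration.

    By default rows are symmetric Dirichlet(``concentration``). When
    ``state_weights`` is given, 3-state gene rows use those per-state
    Dirichlet weights instead (binary condition rows stay symmetric) —
    used by :func:`make_truth` to emulate the baseline-heavy state mix of
    real expression data.
    """
    if concentration <= 0:
        raise InvalidArgumentError("concentration must be > 0")
    if validate_dag(dag) is not None:
        raise InvalidArgumentError("dag must be acyclic")
    rng = np.random.default_rng(seed)
    cpts: dict[str, np.ndarray] = {}
    for v in dag.variables:
        r = dag.arity(v)
        q = int(np.prod([dag.arity(p) for p in dag.parents(v)])) or 1
        if state_weights is not None and r == len(state_weights):
            alpha = np.asarray(state_weights, dtype=float)
        else:
            alpha = np.full(r, concentration)
        cpts[v] = rng.dirichlet(alpha, size=q)
    return cpts


def sample_discrete_states(truth: SyntheticTruth, n_per_condition: int,
                           seed: int = 0) -> DiscreteDataset:
    """Ancestral sampling in topological order, condition fixed by design.

    The condition variable is clamped to 0 for the first ``n_per_condition``
    samples (wildtype) and 1 for the rest (PiZ), mirroring a balanced
    two-group design.
    """
    if n_per_condition < 1:
        raise InvalidArgumentError("n_per_condition must be >= 1")
    import networkx as nx

    rng = np.random.default_rng(seed)
    n = 2 * n_per_condition
    samples = [f"WT{i + 1}" for i in range(n_per_condition)] + \
              [f"PiZ{i + 1}" for i in range(n_per_condition)]
    states: dict[str, np.ndarray] = {
        CONDITION_VAR: np.repeat([0, 1], n_per_condition).astype(np.int8)}
    for v in nx.topological_sort(truth.dag.to_networkx()):
        if v == CONDITION_VAR:
            continue
        parents = truth.dag.parents(v)
        r = truth.dag.arity(v)
        cpt = truth.cpts[v]
        if parents:
            p_arities = tuple(truth.dag.arity(p) for p in parents)
            rows = np.stack([states[p] for p in parents])
            j = np.ravel_multi_index(rows, p_arities)
        else:
            j = np.zeros(n, dtype=np.intp)
        u = rng.random(n)
        cum = np.cumsum(cpt[j], axis=1)
        states[v] = (u[:, None] > cum[:, :-1]).sum(axis=1).astype(np.int8)
        assert states[v].max() < r
    table = pd.DataFrame(
        np.stack([states[v] for v in truth.dag.variables]),
        index=list(truth.dag.variables), columns=samples)
    arities = dict(zip(truth.dag.variables, truth.dag.arities))
    return DiscreteDataset(table, arities)


def states_to_counts(states: DiscreteDataset, count_params: CountParams,
                     seed: int = 0) -> CountMatrix:
    """Draw NB counts with mean mu_g * f^m per gene/sample from discrete states.

    Dispersion below 1e-8 switches to the Poisson limit. The condition row
    of ``states`` becomes the sample condition labels.
    """
    rng = np.random.default_rng(seed)
    genes = [v for v in states.variables if v != CONDITION_VAR]
    missing = [g for g in genes if g not in count_params.baseline]
    if missing:
        raise KeyNotFoundError(f"genes without count parameters: {missing}")
    f = count_params.fold
    alpha = count_params.dispersion
    rows = []
    for g in genes:
        m = _STATE_EXPONENT[states.states.loc[g].to_numpy()]
        mean = count_params.baseline[g] * (f ** m).astype(float)
        if alpha < 1e-8:
            rows.append(rng.poisson(mean))
        else:
            size = 1.0 / alpha  # NB "number of failures" parameter
            p = size / (size + mean)
            rows.append(rng.negative_binomial(size, p))
    counts = pd.DataFrame(np.stack(rows), index=genes,
                          columns=states.states.columns)
    condition = pd.Series(states.states.loc[CONDITION_VAR].to_numpy(),
                          index=states.states.columns)
    return CountMatrix(counts, condition)


def make_truth(n_genes: int, max_parents: int = 3, edge_prob: float = 0.05,
               concentration: float = 1.0, fold: float = 4.0,
               dispersion: float = 0.1, mean_range: tuple[float, float] = (20.0, 2000.0),
               state_weights: tuple[float, ...] | None = BASELINE_STATE_WEIGHTS,
               seed: int = 0) -> SyntheticTruth:
    """Sample a complete generative model (DAG, CPTs, count parameters).

    Baseline means are log-uniform over ``mean_range`` so genes straddle
    the low-count filter threshold; gene CPT rows default to the
    baseline-heavy state mix (pass ``state_weights=None`` for symmetric
    Dirichlet rows).
    """
    dag = sample_ground_truth_dag(n_genes, max_parents, edge_prob, seed)
    cpts = sample_cpts(dag, concentration, seed + 1, state_weights=state_weights)
    rng = np.random.default_rng(seed + 2)
    lo, hi = mean_range
    mus = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    baseline = dict(zip(_gene_names(n_genes), mus.astype(float)))
    return SyntheticTruth(dag, cpts, CountParams(baseline, fold, dispersion), seed)


def make_piz_like_dataset(seed: int = 0, n_genes: int = 215,
                          n_per_condition: int = 5,
                          ) -> tuple[CountMatrix, SyntheticTruth]:
    """Convenience preset mirroring the study design: 215 genes, 5 + 5 livers.

    Defaults: max_parents=3, edge_prob=0.01 (sparse regulatory structure,
    about one parent per gene on average), fold=4, dispersion=0.1.
    """
    truth = make_truth(n_genes, max_parents=3, edge_prob=0.01,
                       fold=4.0, dispersion=0.1, seed=seed)
    states = sample_discrete_states(truth, n_per_condition, seed=seed + 3)
    counts = states_to_counts(states, truth.count_params, seed=seed + 4)
    return counts, truth
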