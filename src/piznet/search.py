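"""Simulated-annealing maximization of the BDe score.

The search protocol mirrors a BANJO-style schedule, with deterministic
move-evaluation budgets standing in for wall-clock runtime: each round
runs three independent annealing searches; the round champion (best
normalized score, ties to the lowest search index) seeds the next round,
which doubles the budget (B, 2B, 4B, ...); the protocol stops when the
champion's relative improvement over the previous round is no greater
than 15% (or the round cap is hit).

Moves are add/delete/reverse of a single arc, drawn uniformly from the
currently legal set (acyclicity plus an optional in-degree cap). The
Metropolis rule always accepts score increases and accepts a decrease
delta with probability exp(delta/T) under geometric cooling; the
best-ever structure is returned, not the final one. Scores are updated
incrementally: a single-arc move changes only the affected families.

An exhaustive enumeration over all DAGs (<= 5 variables) provides an
independent optimum for validating the annealer.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .blanket import second_degree_mb
from .errors import InvalidArgumentError, KeyNotFoundError
from .model import (DagStructure, NetworkModel, ScoreParams, annotate_edges,
                    fit_cpts)
from .preprocess import DiscreteDataset

log = logging.getLogger("piznet")


@dataclass
class SearchConfig:
    """Knobs of the annealing protocol.

    ``budget`` counts move evaluations per search (the deterministic
    stand-in for the wall-clock hours of the original schedule).
    ``initial_temperature=None`` auto-tunes T0 as the standard deviation
    of 100 random-move score deltas from the start structure.
    """

    budget: int = 20000
    n_searches_per_round: int = 3
    improvement_threshold: float = 0.15
    max_rounds: int = 6
    initial_temperature: float | None = None
    cooling_rate: float = 0.999
    seed: int = 0
    max_parents: int | None = None
    ess: float = 1.0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise InvalidArgumentError("budget must be >= 1")
        if not 0 < self.cooling_rate < 1:
            raise InvalidArgumentError("cooling_rate must be in (0, 1)")
        if self.improvement_threshold < 0:
            raise InvalidArgumentError("improvement_threshold must be >= 0")
        if self.n_searches_per_round < 1:
            raise InvalidArgumentError("n_searches_per_round must be >= 1")

    def prior(self) -> ScoreParams:
        return ScoreParams(self.ess)


@dataclass
class SearchRecord:
    seed: int
    log_score: float
    normalized_score: float


@dataclass
class RoundRecord:
    index: int          # 1-based
    budget: int
    searches: list[SearchRecord]
    champion_index: int  # index into searches
    champion_log: float
    champion_norm: float
    improvement: float | None  # vs previous round champion; None for round 1
    stopped: bool

    def to_dict(self) -> dict:
        return {
            "index": self.index, "budget": self.budget,
            "searches": [vars(s) for s in self.searches],
            "champion_index": self.champion_index,
            "champion_log": self.champion_log,
            "champion_norm": self.champion_norm,
            "improvement": self.improvement, "stopped": self.stopped,
        }


@dataclass
class SearchTrace:
    rounds: list[RoundRecord] = field(default_factory=list)
    stopped_reason: str = ""

    def to_dict(self) -> dict:
        return {"rounds": [r.to_dict() for r in self.rounds],
                "stopped_reason": self.stopped_reason}


# ---------------------------------------------------------------------------
# internal index-based scoring machinery
# ---------------------------------------------------------------------------

class _Scorer:
    """Cached BDe family scores over an integer state matrix."""

    def __init__(self, data: DiscreteDataset, ess: float):
        self.X = data.states.to_numpy()
        self.arities = np.array([data.arities[v] for v in data.variables])
        self.ess = float(ess)
        self._cache: dict[tuple, float] = {}

    def family(self, node: int, parents: tuple[int, ...]) -> float:
        # parent configurations with no observations contribute exactly 0
        # to the BDe score, so only the <= n_samples observed configurations
        # are tabulated (q itself can be astronomically large)
        key = (node, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        r = int(self.arities[node])
        x = self.X[node]
        if parents:
            q = 1
            for p in parents:
                q *= int(self.arities[p])
            _, inv = np.unique(self.X[list(parents)], axis=1,
                               return_inverse=True)
            m = int(inv.max()) + 1 if inv.size else 0
        else:
            q = 1
            inv = np.zeros(x.shape[0], dtype=np.intp)
            m = 1
        n = np.zeros((m, r), dtype=np.int64)
        np.add.at(n, (inv, x), 1)
        a_ijk = self.ess / (q * r)
        a_ij = self.ess / q
        n_ij = n.sum(axis=1)
        score = float(np.sum(gammaln(a_ij) - gammaln(a_ij + n_ij))
                      + np.sum(gammaln(a_ijk + n) - gammaln(a_ijk)))
        self._cache[key] = score
        return score

    def network(self, adj: np.ndarray) -> float:
        return sum(self.family(v, _parents_of(adj, v))
                   for v in range(adj.shape[0]))


def _parents_of(adj: np.ndarray, v: int) -> tuple[int, ...]:
    return tuple(np.flatnonzero(adj[:, v]))


def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean transitive closure (paths of length >= 1) via repeated squaring."""
    r = adj.astype(np.int8)
    while True:
        nxt = ((r + r @ r) > 0).astype(np.int8)
        if np.array_equal(nxt, r):
            return r.astype(bool)
        r = nxt


def _has_path(adj: np.ndarray, src: int, dst: int) -> bool:
    """DFS path test on a small adjacency matrix."""
    stack = [src]
    seen = set()
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        if u in seen:
            continue
        seen.add(u)
        stack.extend(np.flatnonzero(adj[u]).tolist())
    return False


_ADD, _DEL, _REV = 0, 1, 2


def _legal_moves(adj: np.ndarray, max_parents: int | None) -> list[tuple[int, int, int]]:
    """All single-arc moves preserving acyclicity and the in-degree cap.

    Enumeration order is deterministic: adds by (u, v), then deletes,
    then reverses.
    """
    n = adj.shape[0]
    reach = _closure(adj)
    indeg = adj.sum(axis=0)
    cap = np.inf if max_parents is None else max_parents
    can_add = ~adj & ~adj.T & ~reach.T & (indeg[None, :] < cap)
    np.fill_diagonal(can_add, False)
    moves = [(_ADD, int(u), int(v)) for u, v in np.argwhere(can_add)]
    arcs = np.argwhere(adj)
    moves.extend((_DEL, int(u), int(v)) for u, v in arcs)
    for u, v in arcs:
        if indeg[u] >= cap:
            continue
        adj[u, v] = False
        cyclic = _has_path(adj, int(u), int(v))
        adj[u, v] = True
        if not cyclic:
            moves.append((_REV, int(u), int(v)))
    return moves


def _move_delta(adj: np.ndarray, move: tuple[int, int, int], scorer: _Scorer) -> float:
    kind, u, v = move
    pv = _parents_of(adj, v)
    if kind == _ADD:
        new_pv = tuple(sorted(pv + (u,)))
        return scorer.family(v, new_pv) - scorer.family(v, pv)
    if kind == _DEL:
        new_pv = tuple(p for p in pv if p != u)
        return scorer.family(v, new_pv) - scorer.family(v, pv)
    pu = _parents_of(adj, u)
    return (scorer.family(v, tuple(p for p in pv if p != u))
            - scorer.family(v, pv)
            + scorer.family(u, tuple(sorted(pu + (v,))))
            - scorer.family(u, pu))


def _apply_move(adj: np.ndarray, move: tuple[int, int, int]) -> None:
    kind, u, v = move
    if kind == _ADD:
        adj[u, v] = True
    elif kind == _DEL:
        adj[u, v] = False
    else:
        adj[u, v] = False
        adj[v, u] = True


def _to_adj(s: DagStructure, variables: tuple[str, ...]) -> np.ndarray:
    idx = {v: i for i, v in enumerate(variables)}
    adj = np.zeros((len(variables), len(variables)), dtype=bool)
    for u, v in s.arcs:
        adj[idx[u], idx[v]] = True
    return adj


def _to_structure(adj: np.ndarray, data: DiscreteDataset) -> DagStructure:
    vs = tuple(data.variables)
    arcs = frozenset((vs[u], vs[v]) for u, v in np.argwhere(adj))
    return DagStructure(vs, tuple(data.arities[v] for v in vs), arcs)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def propose_move(s: DagStructure, rng: np.random.Generator,
                 max_parents: int | None = None) -> DagStructure | None:
    """One uniformly chosen legal add/delete/reverse; ``None`` if no move is legal."""
    vs = tuple(s.variables)
    adj = _to_adj(s, vs)
    moves = _legal_moves(adj, max_parents)
    if not moves:
        return None
    move = moves[int(rng.integers(len(moves)))]
    _apply_move(adj, move)
    arcs = frozenset((vs[u], vs[v]) for u, v in np.argwhere(adj))
    return replace(s, arcs=arcs)


def anneal(data: DiscreteDataset, cfg: SearchConfig, start: DagStructure,
           ) -> tuple[DagStructure, tuple[float, float]]:
    """Single simulated-annealing search; returns the best-ever structure.

    Identical (data, cfg, start) gives an identical result: all randomness
    comes from ``cfg.seed``.
    """
    if set(start.variables) != set(data.variables):
        raise InvalidArgumentError("start structure must cover the data variables")
    rng = np.random.default_rng(cfg.seed)
    scorer = _Scorer(data, cfg.ess)
    adj = _to_adj(start, tuple(data.variables))
    score = scorer.network(adj)
    best_adj, best_score = adj.copy(), score

    temp = cfg.initial_temperature
    if temp is None:
        moves = _legal_moves(adj, cfg.max_parents)
        if moves:
            picks = rng.integers(len(moves), size=100)
            deltas = [_move_delta(adj, moves[int(i)], scorer) for i in picks]
            temp = float(np.std(deltas))
        if not temp:
            temp = 1.0

    moves: list | None = None  # recomputed only after an accepted move
    for _ in range(cfg.budget):
        if moves is None:
            moves = _legal_moves(adj, cfg.max_parents)
        if not moves:
            break
        move = moves[int(rng.integers(len(moves)))]
        delta = _move_delta(adj, move, scorer)
        if delta >= 0 or rng.random() < np.exp(delta / temp):
            _apply_move(adj, move)
            score += delta
            moves = None
            if score > best_score:
                best_score = score
                best_adj = adj.copy()
        temp *= cfg.cooling_rate

    norm = best_score / (data.n_samples * len(data.variables))
    return _to_structure(best_adj, data), (best_score, norm)


def _derive_seed(seed: int, round_index: int, search_index: int) -> int:
    return (seed * 100003 + round_index * 1009 + search_index) % (2 ** 31)


def run_round(data: DiscreteDataset, cfg: SearchConfig, start: DagStructure,
              round_index: int = 1,
              ) -> tuple[DagStructure, tuple[float, float], list[SearchRecord]]:
    """``n_searches_per_round`` independent anneals from ``start``.

    Returns the champion by normalized score (ties to the lowest search
    index) plus the per-search records; per-search seeds derive
    deterministically from ``cfg.seed`` and the round index.
    """
    records: list[SearchRecord] = []
    best = None
    for i in range(cfg.n_searches_per_round):
        seed_i = _derive_seed(cfg.seed, round_index, i)
        struct, (log_s, norm_s) = anneal(data, replace(cfg, seed=seed_i), start)
        records.append(SearchRecord(seed_i, log_s, norm_s))
        if best is None or norm_s > best[1][1]:
            best = (struct, (log_s, norm_s), i)
    struct, scores, champ_idx = best
    return struct, scores, records


def relative_improvement(s_prev: float, s_new: float) -> float:
    """(s_new - s_prev) / |s_prev|; positive when the score improved.

    Scores are negative log likelihoods-of-data, so "improvement" means
    moving toward zero.
    """
    denom = abs(s_prev) if s_prev != 0 else 1.0
    return (s_new - s_prev) / denom


def run_protocol(data: DiscreteDataset, cfg: SearchConfig,
                 round_runner=None) -> tuple[NetworkModel, SearchTrace]:
    """Multi-round doubling protocol; returns the fitted, annotated champion.

    Round 1 starts from the empty graph at ``cfg.budget``; every later
    round doubles the budget and starts from the latest champion. From
    round 2 on, the run stops when the champion's relative improvement is
    no greater than ``cfg.improvement_threshold``.
    """
    if cfg.max_rounds < 2:
        raise InvalidArgumentError("max_rounds must be >= 2")
    runner = round_runner or run_round
    start = DagStructure.empty(data)
    budget = cfg.budget
    trace = SearchTrace()
    champion = None
    prev_norm = None
    for r in range(1, cfg.max_rounds + 1):
        struct, (log_s, norm_s), records = runner(
            data, replace(cfg, budget=budget), start, round_index=r)
        improvement = None if r == 1 else relative_improvement(prev_norm, norm_s)
        stop = improvement is not None and improvement <= cfg.improvement_threshold
        champ_idx = max(range(len(records)),
                        key=lambda i: (records[i].normalized_score, -i)) if records else 0
        trace.rounds.append(RoundRecord(
            r, budget, records, champ_idx, log_s, norm_s, improvement, stop))
        log.info("round %d: budget=%d champion norm=%.6f improvement=%s",
                 r, budget, norm_s, improvement)
        champion, prev_norm = struct, norm_s
        if stop:
            trace.stopped_reason = (
                f"improvement {improvement:.4f} <= {cfg.improvement_threshold}")
            break
        budget *= 2
        start = struct
    else:
        trace.stopped_reason = f"max_rounds {cfg.max_rounds} reached"
    model = annotate_edges(fit_cpts(champion, data, cfg.prior()), data, cfg.prior())
    return model, trace


# ---------------------------------------------------------------------------
# exhaustive oracle (<= 5 variables)
# ---------------------------------------------------------------------------

def exhaustive_search(data: DiscreteDataset, prior: ScoreParams | None = None,
                      max_parents: int | None = None,
                      ) -> tuple[DagStructure, tuple[float, float], list]:
    """Enumerate ALL DAGs over the data's variables and return a global maximizer.

    Refuses more than 5 variables (29,281 DAGs at 5). Also returns the full
    (arcs, log_score) table for inspection.
    """
    n = len(data.variables)
    if n > 5:
        raise InvalidArgumentError(
            f"exhaustive search limited to 5 variables, got {n}")
    prior = prior or ScoreParams()
    scorer = _Scorer(data, prior.ess)
    vs = tuple(data.variables)
    pairs = list(itertools.combinations(range(n), 2))
    best = None
    table = []
    for assign in itertools.product((0, 1, 2), repeat=len(pairs)):
        adj = np.zeros((n, n), dtype=bool)
        for (a, b), state in zip(pairs, assign):
            if state == 1:
                adj[a, b] = True
            elif state == 2:
                adj[b, a] = True
        if _closure(adj).diagonal().any():
            continue
        if max_parents is not None and adj.sum(axis=0).max(initial=0) > max_parents:
            continue
        score = scorer.network(adj)
        table.append((frozenset((vs[u], vs[v]) for u, v in np.argwhere(adj)), score))
        if best is None or score > best[1]:
            best = (adj.copy(), score)
    adj, score = best
    norm = score / (data.n_samples * n)
    return _to_structure(adj, data), (score, norm), table


# ---------------------------------------------------------------------------
# second-pass refinement
# ---------------------------------------------------------------------------

def refine_and_research(data: DiscreteDataset, first_pass: NetworkModel,
                        target: str, genes_of_interest, cfg: SearchConfig,
                        ) -> tuple[DiscreteDataset, NetworkModel, SearchTrace]:
    """Reduce to the target's second-degree Markov blanket (plus genes of
    interest) and re-run the search protocol on the reduced dataset."""
    if target not in data.states.index:
        raise KeyNotFoundError(f"target {target!r} not in data")
    mb2 = second_degree_mb(first_pass.structure, target)
    keep = set(mb2) | (set(genes_of_interest) & set(data.variables)) | {target}
    reduced = data.subset(keep)
    log.info("refine: %d -> %d variables around %s",
             len(data.variables), len(reduced.variables), target)
    if len(reduced.variables) == 1:
        model = annotate_edges(
            fit_cpts(DagStructure.empty(reduced), reduced, cfg.prior()),
            reduced, cfg.prior())
        return reduced, model, SearchTrace(stopped_reason="single variable")
    model, trace = run_protocol(reduced, cfg)
    return reduced, model, trace
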