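"""Count-matrix preprocessing: low-count filtering, median-of-ratios
normalization, z-score standardization and 3-state discretization.

The stages run in a fixed order (filter -> normalize -> fold change /
gene selection -> z-score -> discretize) and turn a raw RNA-seq count
matrix into the discrete dataset consumed by the network-learning
stages: per gene a state in {1 = low, 0 = no change, 2 = high} per
sample, plus a binary condition variable (wildtype = 0, PiZ = 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError, KeyNotFoundError

log = logging.getLogger("piznet")

#: state codes used throughout: low expression, no change, high expression
STATE_LOW, STATE_NONE, STATE_HIGH = 1, 0, 2

#: canonical name of the binary condition variable
CONDITION_VAR = "PiZ"

#: accepted spellings of condition labels -> {0, 1}
_CONDITION_CODES = {
    "wildtype": 0, "wt": 0, "control": 0, "0": 0,
    "piz": 1, "mutant": 1, "1": 1,
}


def _encode_condition(condition: pd.Series) -> pd.Series:
    """Map condition labels (strings or 0/1) onto int8 codes 0=wildtype, 1=PiZ."""
    def code(v) -> int:
        s = str(v).strip().lower()
        if s not in _CONDITION_CODES:
            raise InvalidArgumentError(
                f"unrecognized condition label {v!r}; expected wildtype/PiZ or 0/1")
        return _CONDITION_CODES[s]

    return condition.map(code).astype(np.int8)


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample expression table with condition labels.

    Parameters
    ----------
    counts
        DataFrame with gene IDs as index and sample IDs as columns; values
        must be non-negative integers.
    condition
        Per-sample condition, indexed by sample ID; labels are coerced to
        ``0`` (wildtype) / ``1`` (PiZ).
    """

    counts: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise InvalidArgumentError(f"duplicate gene IDs: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise InvalidArgumentError(f"duplicate sample IDs: {dupes}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise InvalidArgumentError("counts must be numeric")
        if np.any(vals < 0) or np.any(vals != np.floor(vals)):
            raise InvalidArgumentError("counts must be non-negative integers")
        missing = [s for s in self.counts.columns if s not in self.condition.index]
        if missing:
            raise InvalidArgumentError(f"samples without condition label: {missing}")
        self.condition = _encode_condition(self.condition.loc[self.counts.columns])

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DiscretizationParams:
    """Thresholds for 3-state z-score discretization.

    z < ``z_low`` -> state 1 (low); ``z_low`` <= z <= ``z_high`` -> state 0
    (no change); z > ``z_high`` -> state 2 (high). Both boundaries map to
    state 0.
    """

    z_low: float = -1.0
    z_high: float = 1.0

    def __post_init__(self) -> None:
        if not self.z_low < self.z_high:
            raise InvalidArgumentError("z_low must be < z_high")


@dataclass
class DiscreteDataset:
    """Discrete variable x sample table: the input to all network operations.

    Gene variables take states {1, 0, 2} (arity 3); the condition variable
    ``PiZ`` takes {0, 1} (arity 2).
    """

    states: pd.DataFrame  # variables x samples, small ints
    arities: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.states.index.duplicated().any():
            raise InvalidArgumentError("duplicate variable names")
        if not self.arities:
            self.arities = {
                v: (2 if v == CONDITION_VAR else 3) for v in self.states.index
            }
        self.states = self.states.astype(np.int8)
        if self.states.shape[1]:  # empty (0-sample) tables are legal
            for v in self.states.index:
                r = self.arities[v]
                row = self.states.loc[v].to_numpy()
                if row.min() < 0 or row.max() >= r:
                    raise InvalidArgumentError(
                        f"variable {v!r} has states outside 0..{r - 1}")

    @property
    def variables(self) -> list[str]:
        return list(self.states.index)

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]

    def subset(self, variables) -> "DiscreteDataset":
        """Restrict to ``variables`` (kept in this dataset's order)."""
        missing = [v for v in variables if v not in self.states.index]
        if missing:
            raise KeyNotFoundError(f"unknown variables: {missing}")
        keep = [v for v in self.states.index if v in set(variables)]
        return DiscreteDataset(
            self.states.loc[keep].copy(),
            {v: self.arities[v] for v in keep},
        )


# ---------------------------------------------------------------------------
# stage 1: low-count filter
# ---------------------------------------------------------------------------

def filter_low_counts(m: CountMatrix, min_count: int = 10,
                      min_samples: int = 5) -> CountMatrix:
    """Remove genes whose count is below ``min_count`` in >= ``min_samples`` samples.

    A gene with counts exactly ``min_count`` is kept (the rule is strict
    "less than"). Sample set and gene order are unchanged.
    """
    if min_count < 0 or min_samples < 1:
        raise InvalidArgumentError("min_count must be >= 0 and min_samples >= 1")
    if m.counts.empty:
        raise InvalidArgumentError("empty count matrix")
    low = (m.counts < min_count).sum(axis=1)
    keep = low < min_samples
    out = CountMatrix(m.counts.loc[keep].copy(), m.condition.copy())
    log.info("filter_low_counts: %d -> %d genes", len(keep), int(keep.sum()))
    return out


# ---------------------------------------------------------------------------
# stage 2: median-of-ratios size factors and normalization
# ---------------------------------------------------------------------------

def size_factors_median_of_ratios(m: CountMatrix) -> pd.Series:
    """Per-sample scale factors: median over reference genes of count/geomean.

    Reference genes are those with a strictly positive geometric mean across
    samples (i.e. no zero count). Ties in the median (even number of
    reference genes) take the midpoint of the two central ratios.
    """
    counts = m.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise DegenerateInputError(
            "no gene with strictly positive counts in every sample")
    logc = np.log(counts[ref])
    geomean = np.exp(logc.mean(axis=1))
    ratios = counts[ref] / geomean[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def normalize(m: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    f = np.asarray(factors.loc[m.counts.columns], dtype=float)
    if np.any(f <= 0):
        raise InvalidArgumentError("size factors must be strictly positive")
    return m.counts / f


# ---------------------------------------------------------------------------
# stage 3: fold change and gene selection
# ---------------------------------------------------------------------------

def log2_fold_change(normalized: pd.DataFrame, condition: pd.Series,
                     pseudocount: float = 1.0, shrink: bool = False) -> pd.Series:
    """Per-gene log2 fold change, PiZ over wildtype.

    lfc_g = log2((mean_PiZ + pseudocount) / (mean_WT + pseudocount)).
    With ``shrink=True`` the value is moderated multiplicatively by
    n_eff/(n_eff + 1), n_eff the harmonic-mean group size — a lightweight
    stand-in for Bayesian shrinkage estimators that pulls small-sample fold
    changes toward zero.
    """
    cond = _encode_condition(condition.loc[normalized.columns])
    n1 = int((cond == 0).sum())
    n2 = int((cond == 1).sum())
    if n1 == 0 or n2 == 0:
        raise InvalidArgumentError("both conditions must be present")
    mean_wt = normalized.loc[:, cond[cond == 0].index].mean(axis=1)
    mean_piz = normalized.loc[:, cond[cond == 1].index].mean(axis=1)
    lfc = np.log2((mean_piz + pseudocount) / (mean_wt + pseudocount))
    if shrink:
        n_eff = 2.0 * n1 * n2 / (n1 + n2)
        lfc = lfc * (n_eff / (n_eff + 1.0))
    return pd.Series(lfc, index=normalized.index, name="log2_fold_change")


def select_genes(lfc: pd.Series, cutoff: float = 2.0,
                 genes_of_interest=()) -> list[str]:
    """Genes with |lfc| strictly greater than ``cutoff``, plus genes of interest.

    Order follows the input gene order. Genes of interest absent from the
    (filtered) universe are warned about, never fatal.
    """
    interest = list(genes_of_interest)
    absent = [g for g in interest if g not in lfc.index]
    if absent:
        log.warning("genes of interest absent after filtering: %s", absent)
    chosen = set(lfc.index[lfc.abs() > cutoff]) | (set(interest) & set(lfc.index))
    return [g for g in lfc.index if g in chosen]


# ---------------------------------------------------------------------------
# stage 4: z-scores and discretization
# ---------------------------------------------------------------------------

def zscore_standardize(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across all samples pooled (sample sd, n-1 denominator).

    Zero-variance genes yield all-zero rows (state "no change" downstream)
    with a logged warning rather than an error, so constant genes of
    interest stay in the table.
    """
    if normalized.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 samples for z-scores")
    mean = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=1)
    # genes constant up to floating-point noise (e.g. after dividing by
    # size factors that are 1 +- eps) must not have that noise blown up
    # to order-1 z-scores: treat sd below ~1e-10 of the signal as zero
    flat = sd <= 1e-10 * (mean.abs() + 1)
    if flat.any():
        log.warning("zero-variance genes set to z=0: %s",
                    list(normalized.index[flat]))
    sd[flat] = np.inf  # flat rows -> z = 0 exactly
    return normalized.sub(mean, axis=0).div(sd, axis=0)


def discretize(z: pd.DataFrame, params: DiscretizationParams | None = None,
               condition: pd.Series | None = None) -> DiscreteDataset:
    """Threshold z-scores into states {1, 0, 2}; append the PiZ condition row.

    z < z_low -> 1 (low); z_low <= z <= z_high -> 0; z > z_high -> 2. When
    ``condition`` is given, a binary ``PiZ`` variable (wildtype 0, PiZ 1)
    is appended as the last row.
    """
    p = params or DiscretizationParams()
    vals = z.to_numpy(dtype=float)
    states = np.zeros(vals.shape, dtype=np.int8)
    states[vals < p.z_low] = STATE_LOW
    states[vals > p.z_high] = STATE_HIGH
    table = pd.DataFrame(states, index=z.index, columns=z.columns)
    arities = {g: 3 for g in z.index}
    if condition is not None:
        cond = _encode_condition(condition.loc[z.columns])
        table.loc[CONDITION_VAR] = cond.to_numpy()
        arities[CONDITION_VAR] = 2
    return DiscreteDataset(table, arities)


# ---------------------------------------------------------------------------
# full preprocessing pipeline
# ---------------------------------------------------------------------------

def preprocess_counts(m: CountMatrix, genes_of_interest=(), min_count: int = 10,
                      min_samples: int = 5, lfc_cutoff: float = 2.0,
                      shrink: bool = True,
                      params: DiscretizationParams | None = None,
                      log_transform: bool = True,
                      ) -> tuple[DiscreteDataset, list[str], pd.Series]:
    """Run filter -> normalize -> select -> z-score -> discretize in order.

    Z-scores are computed on log2(normalized + 1) by default: expression
    fold changes are multiplicative, so standardizing on the log scale is
    what makes the low/no-change/high windows symmetric around a gene's
    baseline (set ``log_transform=False`` to standardize linear values).

    Returns the discrete dataset restricted to the selected genes (plus the
    PiZ condition variable), the selected gene list and the per-gene fold
    changes. Re-running on an already-discretized table is rejected.
    """
    if m.counts.to_numpy().max(initial=0) <= 2:
        raise InvalidArgumentError(
            "input looks already discretized (all counts <= 2); "
            "preprocess_counts expects raw counts")
    filtered = filter_low_counts(m, min_count=min_count, min_samples=min_samples)
    factors = size_factors_median_of_ratios(filtered)
    norm = normalize(filtered, factors)
    lfc = log2_fold_change(norm, filtered.condition, shrink=shrink)
    selected = select_genes(lfc, cutoff=lfc_cutoff,
                            genes_of_interest=genes_of_interest)
    expr = np.log2(norm.loc[selected] + 1) if log_transform else norm.loc[selected]
    z = zscore_standardize(expr)
    data = discretize(z, params, condition=filtered.condition)
    log.info("preprocess: %d genes selected, %d samples", len(selected),
             data.n_samples)
    return data, selected, lfc
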