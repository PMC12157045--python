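# Methods

## Model

A Bayesian network over discrete expression states: a DAG whose nodes are
gene variables with states {1 = low, 0 = no change, 2 = high} plus a
binary condition node `PiZ` (wildtype 0, mutant 1), and one conditional
probability table (CPT) per node given its parents. The Markov condition
supplies the independence semantics: a node is independent of every
non-descendant given its parents. Arcs express statistical co-regulation,
not established causal direction; the per-arc sign annotation ("inhibition"
when negative) is the sign of the Pearson correlation between
ordinal-coded states of parent and child (low → −1, none → 0, high → +1),
and the per-arc strength is the drop in network score when the arc is
removed. Both annotations are descriptive conventions: the underlying
score is indifferent within a Markov equivalence class, so individual arc
directions should be read as "potential direction" only.

## Preprocessing

Stages run in a fixed order on a counts × samples matrix:

1. **Low-count filter** — drop genes with counts < `min_count` (10) in
   `min_samples` (5) or more samples; the boundary count of exactly 10 is
   kept.
2. **Median-of-ratios normalization** — per-sample factor = median over
   reference genes (all counts strictly positive) of count/geometric mean.
   Even reference-gene counts take the midpoint of the central ratios.
   Note the estimator is homogeneous only up to a global rescaling:
   multiplying one sample by c multiplies factor *ratios* by c (the
   geometric means absorb c^(1/n)).
3. **Selection** — per-gene log2 fold change of condition means with
   pseudocount 1; optional multiplicative moderation n_eff/(n_eff+1),
   n_eff the harmonic-mean group size, standing in for Bayesian
   shrinkage estimators. Genes with |lfc| strictly > 2 are selected, plus
   the genes-of-interest list (selection by fold change, not p-value).
4. **Standardization** — per-gene z-scores of log2(normalized + 1) with
   the sample (n−1) standard deviation, pooled across both conditions.
   The log transform matters: expression effects are multiplicative, so
   only on the log scale are "low" and "high" symmetric deviations from a
   gene's baseline; z-scoring linear counts lets the high tail dominate
   the variance and the low state becomes unrecoverable. Genes whose
   standard deviation is below ~1e−10 of their mean are treated as
   constant (all states 0) rather than amplifying floating-point noise.
5. **Discretization** — z < −1 → 1 (low), −1 ≤ z ≤ 1 → 0, z > 1 → 2;
   both boundaries inclusive to "no change". A consequence worth knowing:
   a perfectly clean two-valued gene split 50/50 by condition has
   |z| = sqrt((n−1)/n) < 1 and lands entirely in "no change"; real data
   escape this via within-group noise.

Re-running the pipeline on an already-discretized table is rejected.

## Scoring and search

BDe marginal likelihood with a uniform structure prior; pseudo-counts
α_ijk = ESS/(q_i·r_i) with ESS defaulting to 1 (configurable). CPTs are
posterior means (N_ijk + α_ijk)/(N_ij + α_ij). The "normalized score" is
log score / (n_samples · n_variables); only relative comparisons of it
are used (the stopping rule), so any fixed positive normalization is
equivalent.

Search is simulated annealing over single-arc moves (add, delete,
reverse), drawn uniformly from the currently legal set (acyclicity plus
an optional in-degree cap). Acceptance is Metropolis: improvements
always, a deterioration Δ < 0 with probability exp(Δ/T); T cools
geometrically (default rate 0.999 per evaluation) from an initial
temperature auto-tuned to the standard deviation of 100 random-move
score deltas. Deterministic move-evaluation budgets replace wall-clock
runtimes so runs are exactly reproducible; the round structure —
three independent searches per round, champion by normalized score (ties
to the lowest search index), next round doubles the budget (B, 2B, 4B, …)
seeded from the champion, stop when relative improvement ≤ 15% — is
preserved. Round 1 starts from the empty graph. Improvement is
(s_new − s_prev)/|s_prev| on normalized scores. Scores are cached per
(node, parent set) and updated incrementally: a single-arc move rescores
only the affected families, and only parent configurations that are
actually observed are tabulated (unobserved configurations contribute
exactly zero to the score, so the cost is bounded by the sample count
even when the nominal configuration count 3^#parents is astronomical).

An exhaustive enumerator over all DAGs (refusing > 5 variables; 25 DAGs
at 3 nodes, 29,281 at 5) provides the independent global optimum used to
validate the annealer.

The two-pass design mirrors the study protocol: learn on all selected
genes, restrict to the target's second-degree Markov blanket plus the
genes of interest, and learn again on the reduced set.

## Blankets and inference

First-degree Markov blanket: parents ∪ children ∪ parents-of-children,
excluding the target (the target never appears inside its own blanket).
Second-degree: union with each member's first-degree blanket. Member
roles (parent/child/spouse/second-degree) are reported because the
neighborhoods are read biologically.

Queries are exact: variable elimination with a greedy min-fill ordering,
validated against brute-force joint summation. Evidence clamping is
observational conditioning (GeNIe-style evidence, not an intervention).
Clamping evidence of probability zero raises a dedicated error. The
k-gene combination analysis enumerates all C(n,k)·3^k assignments over a
candidate set (by default the first-degree blanket) and ranks them by
P(states | condition), with P(condition | states) reported alongside —
the conditioning direction was ambiguous in principle; conditioning on
the genotype matches the clamping semantics of the scenario simulations.
Ties rank lexicographically. "Minimal necessary set" is implemented as
the smallest k whose top assignment exceeds a configurable probability
threshold (default 0.5).

## Synthetic data generator

Emulates a two-condition bulk RNA-seq design (default 5 + 5 samples,
215 genes) from a known generative model so recovery is measurable:

- **Structure** — random DAG with the condition node as a root (the
  genotype is an intervention, never a downstream effect; the learner is
  not told this). Default edge probability 0.01 at 215 genes (~1 parent
  per gene), in-degree cap 3.
- **CPTs** — Dirichlet rows. Gene rows default to weights
  (α_none, α_low, α_high) = (4.0, 0.4, 0.4), i.e. E[P(no change)] ≈ 0.83:
  in real tissue most genes sit at baseline in most samples and
  deviations are the minority. This matters structurally: if a deviant
  state is modal for a gene, per-gene z-centering maps the majority state
  to "no change" and recovery of that gene's states is impossible for any
  threshold — a property of z-score discretization itself, not of noise.
  Symmetric Dirichlet rows remain available (`state_weights=None`).
- **Counts** — negative binomial with mean μ_g·f^m (m = −1, 0, +1 for
  low/none/high) and variance μ + αμ²; default fold f = 4 and dispersion
  α = 0.1 (typical bulk RNA-seq); α < 1e−8 switches to the Poisson
  limit. Baselines are log-uniform in [20, 2000] so genes straddle the
  low-count filter. The fold ladder is symmetric on the log scale, which
  is what the log-scale z-standardization inverts.

What it does **not** emulate: library-size confounding beyond per-sample
scale factors, gene-length effects, batch structure, or outlier samples.
Passing recovery tests therefore show the pipeline inverts its own
generative assumptions at realistic noise, not that GEO-scale data would
discretize equally cleanly.

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled-down problems chosen
to exercise every stage densely: 2–10-variable networks against
closed-form/enumeration oracles; annealer validation on 3-variable
datasets (n = 200) at 5,000 evaluations per search; recovery on a
20-gene truth at fold 8, dispersion 0.05, at the study size (5+5) and a
50+50 power check; and a 60-gene two-pass pipeline run. Score
comparisons use absolute tolerance 1e−9 (inference likewise); CPT row
sums are enforced to 1e−12. When the low-count filter removes genes from
a synthetic dataset, the true DAG is compared via its induced subgraph
on the surviving variables.

## Known limitations

- Arc-level conclusions are only identified up to Markov equivalence; no
  bootstrap or model averaging is provided.
- The shrinkage moderation is a deliberately simple stand-in; exact
  gene lists from a DESeq2/apeglm selection can differ near the cutoff.
- Exact inference is practical to roughly 25–30 variables with the
  default elimination heuristic; no sampling fallback exists.
- Wall-clock-to-budget correspondence is not calibrated; budgets are a
  reproducibility device, and search quality at a given budget depends
  on variable count.
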