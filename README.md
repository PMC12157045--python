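# piznet

Discrete Bayesian-network analysis of gene co-regulation in alpha-1
antitrypsin deficiency (AATD). The PiZ mouse expresses the human Z mutant
of SERPINA1, whose misfolded product accumulates in the hepatocyte ER;
`piznet` asks which genes — zinc transporters (ZIP/ZnT families,
metallothioneins) and unfolded-protein-response (UPR) genes in particular —
are co-regulated with that condition, by learning a Bayesian network over
discretized liver RNA-seq expression and reading gene neighborhoods and
exact conditional probabilities off the learned graph.

It is a library plus a small CLI for bioinformaticians who want the whole
chain — counts to discrete states to network to probability queries —
reproducible and testable, including a synthetic-data generator that
emulates the 5 PiZ vs 5 wildtype liver design with a known ground truth.

## Method

**Preprocessing.** Genes with counts < 10 in five or more samples are
removed; samples are normalized with median-of-ratios size factors
(s_j = median_g k_gj / (prod_j' k_gj')^(1/m)); genes with |log2 fold
change| > 2 (PiZ over wildtype, pseudocount 1, optional shrinkage
moderation) plus a user-supplied genes-of-interest list are selected;
log2 normalized expression is standardized per gene to z-scores and
discretized into three states: low (z < −1 → 1), no change
(−1 ≤ z ≤ 1 → 0), high (z > 1 → 2). The binary condition variable `PiZ`
(wildtype 0, mutant 1) joins the table.

**Scoring.** Structures are scored with the Bayesian Dirichlet equivalent
(BDe) marginal likelihood under a uniform prior. With N_ijk the count of
child state k under parent configuration j of node i, and pseudo-counts
α_ijk = ESS/(q_i·r_i):

    score(G) = Σ_i Σ_j [ lnΓ(α_ij) − lnΓ(α_ij + N_ij) ]
                   + Σ_i Σ_jk [ lnΓ(α_ijk + N_ijk) − lnΓ(α_ijk) ]

which is decomposable and assigns equal scores to Markov-equivalent DAGs.

**Search.** Simulated annealing over add/delete/reverse arc moves
(Metropolis acceptance, geometric cooling), organized in rounds of three
independent searches. The round champion seeds the next round at double
the evaluation budget; the protocol stops when the champion's relative
improvement in normalized score is ≤ 15%. An exhaustive enumeration over
all DAGs (≤ 5 variables) serves as an independent optimum oracle.

**Blankets and queries.** The first-degree Markov blanket of `PiZ`
(parents, children, co-parents) and its second-degree extension define
the gene neighborhoods of interest; the second pass of the pipeline
re-learns the network on the second-degree blanket plus the genes of
interest. Exact inference (variable elimination) supports GeNIe-style
evidence clamping (e.g. `PiZ=1, Slc39a7=2`) and ranks the most probable
two- and three-gene state combinations under each condition.

## Worked example

```python
import piznet as pz

counts, truth = pz.make_piz_like_dataset(seed=7, n_genes=60)
goi = tuple(list(truth.count_params.baseline)[:8])
cfg = pz.PipelineConfig(budget=1200, max_rounds=3, seed=7, lfc_cutoff=1.0,
                        genes_of_interest=goi)
res = pz.run_full_pipeline(cfg, counts)
print("selected genes:", len(res.selected_genes))
print("final normalized score:", round(res.final_model.normalized_score, 4))
print("MB(PiZ):", sorted(res.blanket.first_degree))
top = res.combinations[0].ranked[0]
print("top 2-gene combination under PiZ=1:", top.assignment,
      "p=%.3f" % top.p_states_given_condition)
```

prints

```
selected genes: 12
final normalized score: -0.7093
MB(PiZ): ['g006', 'g007', 'g008', 'g046', 'g057']
top 2-gene combination under PiZ=1: {'g007': 0, 'g057': 0} p=0.748
```

Twelve of the sixty synthetic genes pass the fold-change/interest
selection; the learned network places five genes in the first-degree
blanket of the condition node, and the most probable joint state of the
top gene pair given `PiZ=1` has conditional probability 0.748. The same
stages are available as CLI subcommands (`piznet simulate | preprocess |
learn | blanket | query | combos | run-all`).

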