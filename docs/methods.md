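# Methods

This note records the model implemented by `tumortyper`, the assumptions it
makes, the defaults of every tunable parameter, what the synthetic generator
does and does not emulate, and the numerical choices that make results
reproducible bit for bit.

## Problem statement and input model

A tumor is represented by a binary gene-level copy-number amplification
profile of its founding clone. The package treats three input layers:

- **Scores** — continuous per-gene amplification scores (e.g. from segmented
  copy-number calls). `binarize(scores, threshold=0.3)` calls a gene
  amplified iff its score is *strictly* greater than 0.3. Non-finite scores
  are an error (reported with gene and sample), not silently dropped.
- **Calls** — the resulting 0/1 matrix, genes × samples.
- **Clone mask** — a 0/1 matrix of the same shape with 1 where an
  amplification is assigned to the founding clone. `apply_clone_mask` is an
  elementwise AND; by default a mask that does not cover every sample in the
  call matrix is an error (`drop_unmasked_samples=True` opts into dropping
  the uncovered samples instead). The mask can only remove calls, never add
  them.

Assumptions: amplification status is meaningful at gene resolution; the
founding-clone mask is provided by an upstream clonality tool; cancer types
are mutually exclusive labels; every type has at least 3 samples so a
stratified split is possible.

## Data splitting

`split_dataset` produces a stratified train/validation/test partition,
default proportions (0.6, 0.2, 0.2). Per-type quota are computed by
largest-remainder rounding (floor each share, distribute the remaining slots
to the largest fractional parts, ties to the earlier split), so the per-type
counts always sum exactly to the type's size and each split's total matches
the global quota to within rounding. Sampling within a type is a seeded
permutation; the split is a deterministic function of (labels, proportions,
seed).

## Layer 1 — pairwise hallmark ensembles

### Differentially amplified genes (DAGs)

For a pair of types (a, b) with n_a and n_b training samples, each gene's
amplified counts are compared by a **two-sided Fisher's exact test**. The
significance threshold adapts to cohort size
(`SignificancePolicy(size_cutoff=200, p_small=0.01, p_mixed=0.005,
p_large=0.001)`): 0.01 when both cohorts have fewer than 200 samples, 0.005
when exactly one does, 0.001 when both have at least 200. A cohort of
exactly 200 counts as large. The rationale is the usual multiple-testing
one: larger cohorts give the test more resolution, so a stricter cutoff
keeps the selected gene lists comparable in quality across pairs of very
different sizes.

Significant genes are grouped by hallmark GO term and ranked within each
term by

    rank_score = max(f_a, f_b) * |f_a - f_b|

where f is the amplification frequency in each cohort — the first factor is
the amplification *degree* (how common the event is at all), the second the
*difference* (how discriminative it is). Ties break lexicographically by
gene name (stable mergesort). Each term keeps at most `top_n=100` genes
(30 is the tested alternative for small cohorts). A gene annotated to
several terms appears in each; terms with no significant gene are recorded
as empty and later abstain.

### Hallmark annotation

Six cancer hallmarks are modelled: apoptosis, cell adhesion, cell cycle,
cell proliferation, phosphorylation, immune response. The default
annotation carries 12 GO terms (two per hallmark); annotations are read and
written as GMT or JSON. The package takes the term → gene mapping as given;
it does not resolve the GO graph itself.

### Boosting

Each non-empty (pair, term) gene list trains one **discrete AdaBoost**
ensemble of depth-1 decision stumps
(`BoostConfig(n_rounds=50, subsample_fraction=0.5, learning_rate=1.0)`).
Because the features are binary, the only stump threshold is 0.5 and a stump
is (gene, polarity). Each round fits its stump on a uniform subsample
without replacement of half the training samples (weights renormalised on
the subsample), then updates the weights of *all* samples. Weighted error is
clipped to [1e-10, 1 − 1e-10] before alpha = ½ · lr · ln((1 − ε)/ε); rounds
are kept even when ε ≥ 0.5 (alpha then ≤ 0), matching the fixed-round
contract. Stump selection breaks ties deterministically: all polarity +1
stumps are preferred over polarity −1, then the lowest gene index. The
decision score is the signed alpha sum; a tied score predicts the
lexicographically smaller type name.

Each ensemble gets its own seed derived as
`sha256(master_seed|type_a|type_b|term_id) mod 2^31`, so the bank is
invariant to training order and any single model can be re-fit in isolation.

The full bank holds G · K(K−1)/2 entries (G = 12 terms), e.g. **1836**
models for K = 18 types. Empty entries are serialised explicitly; model
banks round-trip through JSON bit-exactly (float lists via repr).

## Layer 2 — vote vectors and centroids

Scoring a sample against every model of pair (i, j) yields V[i][j] votes
for type i and V[j][i] = m_ij − V[i][j] for type j, where m_ij ≤ 12 is the
number of non-abstaining terms for that pair. The **vote vector** is the
row mean: votes for type i divided by its K − 1 comparisons. Genes a model
expects but the sample lacks are treated as not amplified (logged once).

Per-type **centroids** are the unshrunken per-class means of the training
vote vectors (shrinkage Δ = 0). A sample is ranked against all centroids by
Pearson correlation (Spearman available); the top-k types (default k = 3)
form the candidate set. Evaluation: a sample is assigned its true type if
that type is in the candidate set, else the rank-1 type; per-type
**accuracy** is true assignments / all assignments to that type (precision)
and **power** is true assignments / true samples of that type (recall);
macro averages are unweighted means over types.

## Layer 3 — leading patterns

For each reference type, the K candidate types become points in the space of
that type's training samples' vote profiles, and **k-medoids** clustering
looks for a compact "leading" structure. k is screened over (3, 4, 5, 6)
ascending; a clustering is accepted when the cluster containing the
reference type (the *up-pattern*) has at most 5 members and the farthest
cluster from it (the *bottom-pattern*) has at most 3. If no k qualifies,
the k = 6 clusters are truncated to those caps by mean vote (keep the
highest-vote members of the up cluster, the lowest of the bottom cluster).
If fewer than 3 distinct profiles exist, a rank-by-mean-vote fallback
defines the patterns directly.

Prediction mode `leading_pattern` scores candidate c by **weighted Pearson
correlation** (weighted means and covariances) between the sample's vote
vector and c's centroid, with weight 3 on c's up-pattern types, 0.1 on its
bottom-pattern types, and 1 elsewhere (`PatternConfig(w_up=3, w_bottom=0.1)`).
`screen_weights` evaluates the grid w_up ∈ {2, 3, 4, 5} ×
w_bottom ∈ {0.1, 0.2, 0.3} **on the validation split only**, picking the
pair maximising macro power, ties broken by macro accuracy then grid order.
With unit weights the weighted predictor reduces exactly to the plain
centroid predictor — both run through the same weighted-correlation code
path, so the reduction is bit-identical, not merely close.

### k-medoids

Distances are Euclidean. For C(n, k) ≤ 20,000 candidate medoid sets (which
covers every pattern-derivation call, since n = K ≤ 18 types) the optimum is
found by exhaustive enumeration, ties going to the lexicographically
smallest index set with a 1e-12 cost margin. Larger instances use PAM
(BUILD then best-improving single-swap SWAP, lowest-index tie-breaks). The
enumeration fast path exists because PAM's single-swap neighbourhood has
genuine local optima even at n = 5, k = 2; exact clustering makes the
derived patterns a deterministic function of the data alone.

## Synthetic generator

`generate(SyntheticConfig(...))` emulates a typed amplification cohort:

- Each type owns `genes_per_signature=20` signature genes out of
  `n_genes=400`; each gene × sample call is an independent Bernoulli draw —
  probability `p_signature=0.8` on the sample's own signature,
  `p_background=0.05` elsewhere.
- `confusable_groups` makes listed types share `share_frac=0.5` of their
  signature genes, creating realistic type confusion.
- Scores are 0.5 · calls (so every call sits strictly above the 0.3
  threshold and `binarize` reproduces the calls exactly).
- The clone mask marks floor(`subclone_frac=0.2` · #calls) uniformly chosen
  amplified calls as sub-clonal.
- The annotation has `n_go_terms=12` terms cycling the six hallmarks; each
  signature gene joins each term with probability 0.5, plus background
  genes.

What it does **not** emulate: segment-level correlation between neighbouring
genes, per-sample purity/ploidy noise, type-specific background rates,
deletions, or realistic cohort-size imbalance. It exists to exercise and
validate the pipeline, not to mimic any real cohort. Setting
`p_background=0`, `subclone_frac=0` gives the noiseless limit used in
testing.

## Numerical choices

- **Fisher's exact test** is computed in-package by enumerating the
  hypergeometric support with log-factorials (`scipy.special.gammaln`),
  summing tables whose probability is ≤ observed · (1 + 1e-7); the relative
  epsilon absorbs log-space rounding in the standard "as extreme" rule.
  Degenerate margins return p = 1. Results are memoised
  (`lru_cache`, 10^6 entries) since counts repeat heavily across genes. The
  implementation is tested exhaustively against a `math.comb` brute force
  and property-tested against `scipy.stats.fisher_exact`.
- **Determinism**: every stochastic step (splits, subsampling, generator,
  medoid seeding) is driven by explicit seeds; derived seeds are
  sha256-based and < 2^31; all results are reproducible across runs and
  platforms with the same dependency versions.
- **Constant vote vectors** (zero variance) cannot be correlated; they rank
  with score −inf under a `RuntimeWarning` rather than raising, so one
  degenerate sample cannot abort a batch.
- Ranking ties anywhere (scores, stumps, medoids, gene lists) break by name
  or index, never by dict order.

## Limitations

- The method only uses amplifications; deletions, SNVs and expression are
  out of scope.
- Gene lists depend on the supplied GO annotation; a poor annotation starves
  the per-term ensembles.
- The adaptive significance policy is a heuristic, not an FDR control.
- Pattern weights are screened on a single validation split; with few
  samples per type the screen is noisy and ties are common.
- All empirical numbers in the README and examples come from the synthetic
  generator; performance on real cohorts will depend on profiling noise,
  clonality-call quality and cohort composition.
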