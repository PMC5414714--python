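# tumortyper

Predicting a tumor's cancer type from the copy-number amplifications of its
founding clone.

Circulating tumor cells and cell-free DNA carry the genomic changes of the
tumor's founding clone — the most recent common ancestor cell, whose copy-number
variants (CNVs) are present in every cancer cell. Amplifications in particular
give strong signals at low sequencing depth, which makes a founding-clone
amplification profile a realistic non-invasive readout. `tumortyper` answers
the question such a readout poses: *given a binary gene-level amplification
profile, which cancer type is this?* It reports a small candidate set (top
1–3 types) so a clinician can restrict follow-up to a few organ sites.

## The method

The classifier has three layers, trained on a cohort of typed tumor profiles
(gene × sample binary matrix, 1 = amplified; gene-level scores above 0.3 are
called amplified, and a founding-clone mask removes sub-clonal calls):

1. **Pairwise hallmark ensembles.** For every pair of cancer types (a, b),
   the differentially amplified genes (DAGs) are found by a two-sided
   Fisher's exact test on per-gene amplified counts, with a sample-size
   adaptive threshold (p < 0.01 when both cohorts have < 200 samples,
   p < 0.005 when one does, p < 0.001 when neither). Significant genes are
   grouped into 12 hallmark-associated GO terms (apoptosis, cell adhesion,
   cell cycle, cell proliferation, phosphorylation, immune response — two
   terms each), ranked within each term by
   *amplification degree × amplification difference*
   (max(f_a, f_b) · |f_a − f_b|) and truncated to the top 100. Each
   (pair, term) gene set trains one discrete AdaBoost ensemble of decision
   stumps with per-round subsampling, giving 12 · C(K, 2) binary models for
   K types (1836 for K = 18).

2. **Vote-vector centroids.** A sample is pushed through all models: for
   each pair (i, j), V[i][j] of the 12 models vote type i and
   V[j][i] = 12 − V[i][j] vote type j (terms with no significant genes
   abstain). Averaging row i over its K − 1 comparisons yields the K-entry
   vote vector. Per-type means of training vote vectors form the K × K
   centroid matrix. A new sample is ranked by Pearson correlation of its
   vote vector with each centroid; the top-3 candidate types are the
   prediction. Per-type **accuracy** = true predictions / all predictions as
   that type and **power** = true predictions / true samples of that type,
   where a sample counts as correct if its true type is in the candidate set.

3. **Leading-pattern weighting.** For each type, k-medoids clustering of the
   candidate types (as points in the type's vote-profile space) identifies a
   leading *up-pattern* (≤ 5 most-similar types, weight 3) and *bottom-pattern*
   (≤ 3 least-similar, weight 0.1). Candidate c is then scored by *weighted*
   Pearson correlation under c's weight vector, which sharpens discrimination
   between confusable types.

No public tumor data ships with the package; a synthetic generator
(`tumortyper.generate`) draws binary amplification cohorts with type-specific
signatures, shared-signature "confusable" groups, and a founding-clone mask,
so every stage is testable end to end.

## Worked example

```python
import tumortyper as tt

ds = tt.generate(tt.SyntheticConfig(n_types=8, samples_per_type=60, seed=3))
calls = tt.prepare_calls(scores=ds.scores, mask=ds.mask)
model, split = tt.train_pipeline(calls, ds.labels, ds.annotation, tt.RunConfig(seed=3))
test = split.index[split == "test"]
preds = tt.predict_pipeline(model, calls.loc[:, test], mode="centroid", k=3)
rep = tt.evaluate_predictions(preds, ds.labels, k=3)
print(rep.macro_accuracy, rep.macro_power)
```

Running `python examples/03_centroid_prediction.py` (the same computation)
prints:

```
top-1: macro accuracy 0.990, macro power 0.990
top-3: macro accuracy 0.990, macro power 0.990
```

i.e. with eight well-separated synthetic types, correlating a test sample's
vote vector against the training centroids recovers the type at rank 1 for
all but one test sample (95 of 96). The other scripts in
`examples/` walk through dataset simulation, DAG selection and vote matrices,
and leading-pattern weighting with a confusable type group.

A thin CLI mirrors the pipeline for shell use:

```bash
tumortyper simulate --n-types 8 --samples-per-type 60 --out-dir data/
tumortyper train --scores data/scores.tsv --mask data/clone_mask.tsv \
    --labels data/labels.tsv --annotation data/annotation.json --out-dir model/
tumortyper predict --model-dir model/ --scores data/scores.tsv \
    --mask data/clone_mask.tsv --out preds.tsv
tumortyper evaluate --predictions preds.tsv --labels data/labels.tsv
```

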