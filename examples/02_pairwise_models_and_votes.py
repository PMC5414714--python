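"""Differentially amplified genes, pairwise ensembles, and vote matrices.

For one pair of cancer types: select the significant differentially
amplified genes per hallmark GO term, train the per-term boosting
ensembles, and inspect a sample's pairwise vote matrix.
"""

import tumortyper as tt

ds = tt.generate(tt.SyntheticConfig(n_types=4, samples_per_type=40, seed=2))

pair = ("T01", "T02")
selected = tt.select_dags(ds.calls, ds.labels, pair, ds.annotation)
print(f"significant DAGs per GO term for pair {pair}:")
for term, genes in selected.items():
    print(f"  {term}: {len(genes)} genes (top: {genes[:3]})")

bank = tt.build_model_bank(ds.calls, ds.labels, ds.annotation,
                           boost=tt.BoostConfig(seed=2))
print(f"\nmodel bank: {len(bank)} (pair, term) entries "
      f"= {ds.annotation.n_terms} terms x C({len(bank.types)},2) pairs")

sample = ds.calls.iloc[:, 0]  # a T01 sample
V, m = tt.vote_matrix(sample, bank)
print(f"\nvote matrix for sample {ds.calls.columns[0]} (row type gets the votes):")
print(V.astype(int))
vec = tt.vote_vector(V)
print("\nvote vector (mean votes per comparison; highest should be T01):")
print(vec.round(2).sort_values(ascending=False))
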