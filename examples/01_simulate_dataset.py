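"""Generate a synthetic founding-clone amplification dataset.

Eight cancer types, 60 samples each: every type amplifies its own 20
signature genes with probability 0.8 over a 5% background, and a clone mask
marks 20% of the amplified calls as sub-clonal.
"""

import tumortyper as tt

config = tt.SyntheticConfig(n_types=8, samples_per_type=60, seed=1)
ds = tt.generate(config)

calls = tt.prepare_calls(scores=ds.scores, mask=ds.mask)

print(f"genes x samples: {ds.calls.shape[0]} x {ds.calls.shape[1]}")
print(f"types: {sorted(ds.labels.unique())}")
print(f"amplified calls: {int(ds.calls.to_numpy().sum())} "
      f"({ds.n_subclonal} marked sub-clonal and removed by the clone mask)")
own = ds.calls.loc[ds.signatures['T01'], ds.labels.index[ds.labels == 'T01']]
print(f"T01 signature frequency in its own samples: {own.to_numpy().mean():.3f} "
      "(close to p_signature = 0.8)")
print(f"GO terms in the annotation: {ds.annotation.n_terms} "
      f"across {len(set(t.hallmark for t in ds.annotation.terms))} hallmarks")
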