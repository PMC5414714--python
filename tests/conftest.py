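import numpy as np
import pandas as pd
import pytest

import tumortyper as tt


@pytest.fixture(scope="session")
def small_dataset() -> tt.SyntheticDataset:
    """4 types x 16 samples, enough to exercise every stage quickly."""
    return tt.generate(
        tt.SyntheticConfig(
            n_types=4,
            samples_per_type=16,
            n_genes=150,
            genes_per_signature=10,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A trained model (with split) on the small dataset."""
    calls = tt.prepare_calls(scores=small_dataset.scores, mask=small_dataset.mask)
    model, split = tt.train_pipeline(
        calls, small_dataset.labels, small_dataset.annotation, tt.RunConfig(seed=7)
    )
    return model, split, calls


@pytest.fixture()
def toy_annotation() -> tt.HallmarkAnnotation:
    return tt.make_annotation(
        {"GO:1": ["g1", "g2", "g3", "g4"], "GO:2": ["g2", "g5"]}
    )


@pytest.fixture()
def toy_calls_labels():
    """Two types, 10 samples each; g1 discriminates strongly."""
    genes = [f"g{i}" for i in range(1, 6)]
    samples = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
    calls = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    calls.loc["g1", [f"A{i}" for i in range(9)]] = 1  # 0.9 vs 0.1
    calls.loc["g1", "B0"] = 1
    for g in ["g2", "g3", "g4", "g5"]:
        calls.loc[g, [f"A{i}" for i in range(5)]] = 1  # 0.5 vs 0.5
        calls.loc[g, [f"B{i}" for i in range(5)]] = 1
    labels = pd.Series(["A"] * 10 + ["B"] * 10, index=samples)
    return calls, labels
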