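"""Copy-number profiles: I/O, binarization, clone masking, and splits.

Matrices are pandas DataFrames with gene identifiers as the index and sample
identifiers as the columns (the gene-level score matrix convention: first
column gene ID, header row sample IDs, tab-separated).  Labels are a pandas
Series mapping sample -> cancer type; split assignments are a Series mapping
sample -> partition name.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARTITIONS = ("train", "validation", "test")

# ---------------------------------------------------------------------------
# TSV I/O


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV matrix (first column gene ID, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df)
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read sample <TAB> cancer_type (with or without a header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="cancer_type")
    if labels.index.duplicated().any():
        dups = labels.index[labels.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample identifiers in labels: {dups}")
    return labels


def write_labels_tsv(labels: pd.Series, path: str | Path) -> None:
    labels.rename("cancer_type").rename_axis("sample_id").to_csv(path, sep="\t")


def read_split_tsv(path: str | Path) -> pd.Series:
    s = read_labels_tsv(path)
    return s.rename("partition")


def write_split_tsv(split: pd.Series, path: str | Path) -> None:
    split.rename("partition").rename_axis("sample_id").to_csv(path, sep="\t")


def _check_unique(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        raise ValueError(
            f"duplicate gene identifiers: {df.index[df.index.duplicated()].tolist()}"
        )
    if df.columns.duplicated().any():
        raise ValueError(
            f"duplicate sample identifiers: {df.columns[df.columns.duplicated()].tolist()}"
        )


# ---------------------------------------------------------------------------
# Binarization and clone masking


def binarize(scores: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Call a gene amplified (1) when its score is strictly above ``threshold``.

    The default 0.3 is the conventional gene-level score cut for amplification;
    the inequality is strict, so a score exactly at the threshold is
    non-amplified.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = scores.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        gi, si = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-finite score for gene {scores.index[gi]!r}, "
            f"sample {scores.columns[si]!r}"
        )
    return pd.DataFrame(
        (values > threshold).astype(np.int8), index=scores.index, columns=scores.columns
    )


def apply_clone_mask(
    calls: pd.DataFrame,
    mask: pd.DataFrame,
    *,
    drop_unmasked_samples: bool = False,
) -> pd.DataFrame:
    """Retain only amplification calls whose segment belongs to the founding clone.

    ``mask`` is a binary gene x sample matrix with 1 where the amplified
    segment is clonal.  The output is the elementwise AND of calls and mask,
    so a call can only be removed, never created.

    By default gene or sample set mismatches raise with the symmetric
    difference.  With ``drop_unmasked_samples=True``, samples absent from the
    mask are dropped with a warning (samples present only in the mask are
    ignored); gene sets must still match exactly.
    """
    gene_diff = set(calls.index).symmetric_difference(mask.index)
    if gene_diff:
        raise ValueError(f"gene sets differ between calls and mask: {sorted(gene_diff)}")
    sample_diff = set(calls.columns).symmetric_difference(mask.columns)
    if sample_diff:
        missing = sorted(set(calls.columns) - set(mask.columns))
        if drop_unmasked_samples:
            if missing:
                logger.warning(
                    "dropping %d samples lacking a clone-mask column: %s",
                    len(missing), missing,
                )
            calls = calls.drop(columns=missing)
        else:
            raise ValueError(
                f"sample sets differ between calls and mask: {sorted(sample_diff)}"
            )
    mask = mask.reindex(index=calls.index, columns=calls.columns)
    out = calls.to_numpy(dtype=np.int8) & mask.to_numpy(dtype=np.int8)
    return pd.DataFrame(out, index=calls.index, columns=calls.columns)


# ---------------------------------------------------------------------------
# Stratified splitting


def _largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion n into integer parts by largest-remainder rounding.

    Ties in the fractional remainder are broken by partition order, so the
    result is deterministic and each part differs from p*n by less than 1.
    """
    quotas = [p * n for p in proportions]
    base = [int(math.floor(q)) for q in quotas]
    short = n - sum(base)
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - base[i]), i)
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def split_dataset(
    labels: pd.Series,
    proportions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    partitions: Sequence[str] = PARTITIONS,
) -> pd.Series:
    """Stratified train/validation/test split, deterministic given ``seed``.

    Within every cancer type the partition sizes are the largest-remainder
    rounding of the proportions, so each part differs from the exact quota by
    less than one sample.
    """
    if len(proportions) != len(partitions):
        raise ValueError("proportions and partitions must have equal length")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {sum(proportions)!r}")
    counts = labels.value_counts()
    too_small = counts[counts < 3]
    if len(too_small):
        raise ValueError(
            f"every cancer type needs >=3 samples; too few for: "
            f"{sorted(too_small.index.tolist())}"
        )
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for ctype in sorted(labels.unique()):
        samples = sorted(labels.index[labels == ctype])
        order = rng.permutation(len(samples))
        sizes = _largest_remainder(len(samples), proportions)
        start = 0
        for part, size in zip(partitions, sizes):
            for k in order[start : start + size]:
                assignment[samples[k]] = part
            start += size
    split = pd.Series(assignment, name="partition").reindex(labels.index)
    split.attrs.update({"proportions": tuple(proportions), "seed": seed})
    return split
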