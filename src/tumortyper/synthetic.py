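"""Synthetic founding-clone amplification datasets.

Emulates the statistical structure the classifier assumes: each cancer type
has a characteristic set of frequently amplified signature genes (amplified
with probability ``p_signature`` in its own samples) over a low shared
background rate; designated confusable type groups share a fraction of their
signature genes, which makes their vote profiles overlap the way clinically
similar tumor types do; a clone mask marks a fraction of amplification calls
as sub-clonal.  Scores are emitted as {0.0, 0.5}, so thresholding at the
conventional 0.3 cut reproduces the generated calls exactly.

Genes are independent Bernoulli draws — there is no within-chromosome
segment correlation — which is sufficient to exercise every algorithmic
stage but does not model the spatial structure of real copy-number data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import HALLMARKS, GoTerm, HallmarkAnnotation


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the generator.

    confusable_groups lists tuples of type names (e.g. ``(("T01", "T02",
    "T03"),)``) whose members share ``share_frac`` of their signature genes.
    subclone_frac is the fraction of amplified calls marked sub-clonal (zeroed
    in the clone mask).
    """

    n_types: int = 8
    samples_per_type: int = 60
    n_genes: int = 400
    genes_per_signature: int = 20
    p_signature: float = 0.8
    p_background: float = 0.05
    confusable_groups: tuple[tuple[str, ...], ...] = ()
    share_frac: float = 0.5
    n_go_terms: int = 12
    subclone_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_background < self.p_signature <= 1):
            raise ValueError("need 0 <= p_background < p_signature <= 1")
        if not (0 <= self.subclone_frac < 1):
            raise ValueError("subclone_frac must be in [0, 1)")
        if not (0 <= self.share_frac <= 1):
            raise ValueError("share_frac must be in [0, 1]")

    @property
    def type_names(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_types)]


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus ground truth for testing."""

    scores: pd.DataFrame  # gene x sample, {0.0, 0.5}
    calls: pd.DataFrame  # gene x sample, {0, 1} (pre-mask)
    mask: pd.DataFrame  # gene x sample clone mask
    labels: pd.Series  # sample -> type
    annotation: HallmarkAnnotation
    signatures: dict[str, list[str]] = field(default_factory=dict)
    n_subclonal: int = 0


def _assign_signatures(config: SyntheticConfig) -> dict[str, list[str]]:
    """Allocate signature genes; confusable group members share a block."""
    types = config.type_names
    for group in config.confusable_groups:
        unknown = set(group) - set(types)
        if unknown:
            raise ValueError(f"confusable group names not in type set: {sorted(unknown)}")
    gps = config.genes_per_signature
    n_shared = round(config.share_frac * gps)
    grouped = {t for g in config.confusable_groups for t in g}
    needed = sum(
        len(g) * (gps - n_shared) + n_shared for g in config.confusable_groups
    ) + (config.n_types - len(grouped)) * gps
    if needed > config.n_genes:
        raise ValueError(
            f"signatures need {needed} genes but only {config.n_genes} available"
        )
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = gene_names[cursor : cursor + n]
        cursor += n
        return block

    signatures: dict[str, list[str]] = {}
    for group in config.confusable_groups:
        shared = take(n_shared)
        for t in group:
            signatures[t] = shared + take(gps - n_shared)
    for t in types:
        if t not in signatures:
            signatures[t] = take(gps)
    return signatures


def _build_annotation(
    config: SyntheticConfig,
    signatures: dict[str, list[str]],
    gene_names: list[str],
    rng: np.random.Generator,
) -> HallmarkAnnotation:
    """Assign signature blocks plus random background genes to GO terms.

    Each signature gene joins each term with probability 1/2, so genes
    commonly belong to several terms and every term carries discriminating
    genes for (almost) every type.
    """
    sig_genes = sorted({g for genes in signatures.values() for g in genes})
    background = [g for g in gene_names if g not in set(sig_genes)]
    n_bg = max(5, config.n_genes // 20)
    terms = []
    for j in range(config.n_go_terms):
        keep = [g for g in sig_genes if rng.random() < 0.5]
        if not keep:  # guarantee a non-empty discriminating core
            keep = [sig_genes[int(rng.integers(len(sig_genes)))]]
        extras = list(rng.choice(background, size=min(n_bg, len(background)), replace=False))
        terms.append(
            GoTerm(
                term_id=f"GO:{j + 1:07d}",
                hallmark=HALLMARKS[j % len(HALLMARKS)],
                genes=tuple(sorted(set(keep) | set(extras))),
            )
        )
    return HallmarkAnnotation(tuple(terms))


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Draw a complete synthetic dataset, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    types = config.type_names
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    signatures = _assign_signatures(config)
    sample_names = [
        f"{t}_S{i + 1:03d}" for t in types for i in range(config.samples_per_type)
    ]
    labels = pd.Series(
        [t for t in types for _ in range(config.samples_per_type)],
        index=sample_names,
        name="cancer_type",
    )

    gene_pos = {g: i for i, g in enumerate(gene_names)}
    P = np.full((config.n_genes, len(sample_names)), config.p_background)
    for j, s in enumerate(sample_names):
        rows = [gene_pos[g] for g in signatures[labels[s]]]
        P[rows, j] = config.p_signature
    calls = (rng.random(P.shape) < P).astype(np.int8)

    mask = np.ones_like(calls)
    ones = np.argwhere(calls == 1)
    n_sub = int(np.floor(config.subclone_frac * len(ones)))
    if n_sub:
        chosen = ones[rng.choice(len(ones), size=n_sub, replace=False)]
        mask[chosen[:, 0], chosen[:, 1]] = 0

    annotation = _build_annotation(config, signatures, gene_names, rng)
    idx = pd.Index(gene_names, name="gene")
    return SyntheticDataset(
        scores=pd.DataFrame(calls * 0.5, index=idx, columns=sample_names),
        calls=pd.DataFrame(calls, index=idx, columns=sample_names),
        mask=pd.DataFrame(mask, index=idx, columns=sample_names),
        labels=labels,
        annotation=annotation,
        signatures=signatures,
        n_subclonal=n_sub,
    )
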