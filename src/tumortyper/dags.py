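"""Differentially amplified genes (DAGs) between cancer-type pairs.

For every pair of cancer types, each gene's amplification counts in the two
types form a 2x2 table tested with Fisher's exact test (two-sided).  The
significance threshold adapts to the pair's sample sizes: small cohorts get a
loose threshold so enough discriminating genes survive, large cohorts a
strict one.  Significant genes are grouped by hallmark GO term, ranked by
amplification degree x amplification difference, and truncated to the top N
per term.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .annotation import HallmarkAnnotation


@dataclass(frozen=True)
class SignificancePolicy:
    """Sample-size-adaptive Fisher p-value thresholds.

    size_cutoff
        Cohort size separating "small" from "large" types; a cohort of
        exactly this size counts as large.
    p_small / p_mixed / p_large
        Thresholds when both cohorts are small, one is small, or both large.
    """

    size_cutoff: int = 200
    p_small: float = 0.01
    p_mixed: float = 0.005
    p_large: float = 0.001

    def __post_init__(self) -> None:
        if not (self.p_small >= self.p_mixed >= self.p_large > 0):
            raise ValueError("thresholds must satisfy p_small >= p_mixed >= p_large > 0")


@dataclass(frozen=True)
class SelectionConfig:
    """How many top-ranked genes to keep per GO term (100 or, alternatively, 30)."""

    top_n: int = 100

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def significance_threshold(
    n_a: int, n_b: int, policy: SignificancePolicy = SignificancePolicy()
) -> float:
    """Pick the Fisher threshold for a pair from its two cohort sizes."""
    if n_a < 1 or n_b < 1:
        raise ValueError("cohort sizes must be >= 1")
    small = (n_a < policy.size_cutoff) + (n_b < policy.size_cutoff)
    return (policy.p_large, policy.p_mixed, policy.p_small)[small]


# Relative tolerance for "as or less probable" table inclusion; matches the
# convention of common Fisher implementations so near-equal point
# probabilities (from float rounding of exactly tied tables) are included.
_REL_EPS = 1e-7


@lru_cache(maxsize=1_000_000)
def dag_test(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p-value for amplified counts in two cohorts.

    The 2x2 table is [[count_a, n_a-count_a], [count_b, n_b-count_b]].  The
    p-value sums the hypergeometric point probabilities of every table with
    the same margins that is no more probable than the observed one.
    Degenerate tables (a margin of zero) return 1.
    """
    for c, n in ((count_a, n_a), (count_b, n_b)):
        if not (0 <= c <= n):
            raise ValueError(f"count {c} outside [0, {n}]")
    total = count_a + count_b
    pop = n_a + n_b
    lo = max(0, total - n_b)
    hi = min(total, n_a)
    if lo == hi:
        return 1.0
    support = np.arange(lo, hi + 1)
    logpmf = (
        _lchoose(total, support)
        + _lchoose(pop - total, n_a - support)
        - _lchoose(pop, n_a)
    )
    pmf = np.exp(logpmf)
    observed = pmf[count_a - lo]
    p = float(pmf[pmf <= observed * (1 + _REL_EPS)].sum())
    return min(p, 1.0)


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rank_score(freq_a: float, freq_b: float) -> float:
    """Amplification degree x amplification difference.

    Degree is the larger of the two type-wise frequencies, so the score
    rewards genes that are both highly amplified in at least one type and
    strongly differential between the two.
    """
    if not (0 <= freq_a <= 1 and 0 <= freq_b <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    return max(freq_a, freq_b) * abs(freq_a - freq_b)


def pair_dag_table(
    calls: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    annotation: HallmarkAnnotation,
    policy: SignificancePolicy = SignificancePolicy(),
) -> pd.DataFrame:
    """Per-gene amplification statistics for one cancer-type pair.

    Only genes appearing in the annotation (and in the matrix) are tested.
    Returns a DataFrame indexed by gene with columns count_a, count_b, n_a,
    n_b, freq_a, freq_b, p_value, rank_score, significant.
    """
    type_a, type_b = pair
    samples_a = labels.index[labels == type_a]
    samples_b = labels.index[labels == type_b]
    samples_a = [s for s in samples_a if s in calls.columns]
    samples_b = [s for s in samples_b if s in calls.columns]
    if not samples_a or not samples_b:
        raise ValueError(f"pair {pair} has a type with no samples in the matrix")
    genes = [g for g in annotation.all_genes() if g in calls.index]
    n_a, n_b = len(samples_a), len(samples_b)
    sub_a = calls.loc[genes, samples_a].to_numpy()
    sub_b = calls.loc[genes, samples_b].to_numpy()
    count_a = sub_a.sum(axis=1).astype(int)
    count_b = sub_b.sum(axis=1).astype(int)
    pvals = np.array(
        [dag_test(int(ca), n_a, int(cb), n_b) for ca, cb in zip(count_a, count_b)]
    )
    freq_a = count_a / n_a
    freq_b = count_b / n_b
    scores = np.maximum(freq_a, freq_b) * np.abs(freq_a - freq_b)
    threshold = significance_threshold(n_a, n_b, policy)
    return pd.DataFrame(
        {
            "count_a": count_a,
            "count_b": count_b,
            "n_a": n_a,
            "n_b": n_b,
            "freq_a": freq_a,
            "freq_b": freq_b,
            "p_value": pvals,
            "rank_score": scores,
            "significant": pvals < threshold,
        },
        index=pd.Index(genes, name="gene"),
    )


def select_dags(
    calls: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    annotation: HallmarkAnnotation,
    policy: SignificancePolicy = SignificancePolicy(),
    config: SelectionConfig = SelectionConfig(),
) -> dict[str, list[str]]:
    """Per GO term, the top-N significant DAGs for one cancer-type pair.

    Within each term, significant genes are ordered by rank_score descending
    (ties by gene identifier) and truncated to ``config.top_n``.  A gene
    annotated to several terms appears in each.  Terms with no significant
    gene map to an empty list.
    """
    table = pair_dag_table(calls, labels, pair, annotation, policy)
    sig = table[table["significant"]]
    ordered = sig.sort_values(
        ["rank_score", "gene"], ascending=[False, True], kind="mergesort"
    ).index.tolist()
    out: dict[str, list[str]] = {}
    for term in annotation.terms:
        term_genes = set(term.genes)
        out[term.term_id] = [g for g in ordered if g in term_genes][: config.top_n]
    return out


def dag_report(
    calls: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    annotation: HallmarkAnnotation,
    policy: SignificancePolicy = SignificancePolicy(),
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Long-format report (one row per gene x term) mirroring select_dags."""
    table = pair_dag_table(calls, labels, pair, annotation, policy)
    selected = select_dags(calls, labels, pair, annotation, policy, config)
    rows = []
    for term in annotation.terms:
        chosen = set(selected[term.term_id])
        for g in term.genes:
            if g not in table.index:
                continue
            rec = table.loc[g]
            rows.append(
                {
                    "gene": g,
                    "term_id": term.term_id,
                    "freq_a": rec["freq_a"],
                    "freq_b": rec["freq_b"],
                    "p_value": rec["p_value"],
                    "rank_score": rec["rank_score"],
                    "selected": int(g in chosen),
                }
            )
    return pd.DataFrame(rows)
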