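"""Pairwise votes, vote vectors, type centroids, and correlation ranking.

Every sample is pushed through all pairwise ensembles, producing a K x K
vote-count matrix V (V[i, j] = number of that pair's models voting type i).
Averaging each row over the K-1 comparisons gives the sample's vote vector;
the per-type mean of training vote vectors is the type's centroid.  A new
sample is ranked against the centroids by (optionally weighted) Pearson
correlation, and the top-k candidate types form the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .boost import PairModelBank


@dataclass
class RankedPrediction:
    """Candidate cancer types ordered by correlation score (descending)."""

    ranking: list[tuple[str, float]]
    k: int = 3

    @property
    def top_k(self) -> list[str]:
        return [t for t, _ in self.ranking[: self.k]]

    @property
    def top1(self) -> str:
        return self.ranking[0][0]


@dataclass
class EvalReport:
    """Per-type accuracy (precision) and power (recall), plus macro averages.

    accuracy(c) = true predictions as c / all predictions as c (NaN when c is
    never predicted); power(c) = true predictions as c / true samples of c.
    """

    per_type: pd.DataFrame
    macro_accuracy: float
    macro_power: float


# ---------------------------------------------------------------------------
# Votes


def _batch_pair_votes(
    calls: pd.DataFrame, bank: PairModelBank
) -> tuple[np.ndarray, np.ndarray]:
    """Vote counts for all samples at once.

    Returns ``V`` with shape (n_samples, K, K) and the effective model count
    matrix ``m`` (K, K); abstaining (None) ensembles are excluded from m.
    """
    if not bank.models:
        raise ValueError("empty model bank")
    types = bank.types
    tindex = {t: i for i, t in enumerate(types)}
    samples = list(calls.columns)
    n = len(samples)
    K = len(types)
    X_all = calls.to_numpy(dtype=np.float64).T  # samples x genes
    gene_pos = {g: i for i, g in enumerate(calls.index)}
    V = np.zeros((n, K, K))
    m = np.zeros((K, K))
    zeros = np.zeros(n)
    for (a, b, _term), ens in bank.models.items():
        if ens is None:
            continue
        cols = [gene_pos.get(g, -1) for g in ens.feature_genes]
        # genes absent from the input matrix are treated as non-amplified
        X = np.column_stack([X_all[:, c] if c >= 0 else zeros for c in cols])
        lab = ens.predict_labels(X)  # +1 -> a, -1 -> b
        ia, ib = tindex[a], tindex[b]
        wins_a = lab > 0
        V[wins_a, ia, ib] += 1
        V[~wins_a, ib, ia] += 1
        m[ia, ib] += 1
        m[ib, ia] += 1
    return V, m


def vote_matrix(
    sample: pd.Series, bank: PairModelBank
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """K x K vote-count matrix and effective model counts for one sample.

    ``sample`` is a binary gene -> call Series.  For every pair (i, j),
    ``V[i, j] + V[j, i]`` equals the number of non-abstaining models of the
    pair.  A pair whose every ensemble abstains contributes zero counts.
    """
    calls = sample.to_frame(name="_sample")
    V, m = _batch_pair_votes(calls, bank)
    types = bank.types
    return (
        pd.DataFrame(V[0], index=types, columns=types),
        pd.DataFrame(m, index=types, columns=types),
    )


def vote_vector(V: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Average number of models voting each type over its K-1 comparisons."""
    arr = V.to_numpy() if isinstance(V, pd.DataFrame) else np.asarray(V)
    K = arr.shape[0]
    if K < 2:
        raise ValueError("need at least two candidate types")
    vec = arr.sum(axis=1) / (K - 1)
    if isinstance(V, pd.DataFrame):
        return pd.Series(vec, index=V.index)
    return vec


def vote_vectors(calls: pd.DataFrame, bank: PairModelBank) -> pd.DataFrame:
    """Vote vectors for every sample (rows: samples, columns: candidate types)."""
    V, _ = _batch_pair_votes(calls, bank)
    K = len(bank.types)
    vecs = V.sum(axis=2) / (K - 1)
    return pd.DataFrame(vecs, index=list(calls.columns), columns=bank.types)


def type_centroids(vectors: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-type centroid (componentwise mean) of training vote vectors.

    Rows are candidate types (vote-vector components), columns are the
    training types; column c is the mean vote vector of c's samples.
    """
    labels = labels.loc[vectors.index]
    cols = {}
    for ctype in sorted(labels.unique()):
        members = vectors.loc[labels == ctype]
        if len(members) == 0:
            raise ValueError(f"type {ctype!r} has no samples")
        cols[ctype] = members.mean(axis=0)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Correlation ranking


def weighted_correlation(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means.

    r_w = sum w (x - xbar_w)(y - ybar_w)
          / sqrt(sum w (x - xbar_w)^2 * sum w (y - ybar_w)^2).
    Reduces exactly to the ordinary Pearson correlation at unit weights.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    dx = x - xb
    dy = y - yb
    vx = (w * dx * dx).sum()
    vy = (w * dy * dy).sum()
    if vx <= 0 or vy <= 0:
        raise ValueError("constant input under weights")
    return float((w * dx * dy).sum() / np.sqrt(vx * vy))


def _rank_with_weights(
    x: pd.Series,
    centroids: pd.DataFrame,
    weight_of: "callable",
    k: int,
) -> RankedPrediction:
    x = x.reindex(centroids.index)
    scores = []
    for ctype in centroids.columns:
        w = weight_of(ctype)
        try:
            r = weighted_correlation(x.to_numpy(), centroids[ctype].to_numpy(), w)
        except ValueError:
            warnings.warn(
                f"constant input when scoring candidate {ctype!r}; ranked last",
                RuntimeWarning,
                stacklevel=3,
            )
            r = -np.inf
        scores.append((ctype, r))
    scores.sort(key=lambda pair: (-pair[1], pair[0]))
    return RankedPrediction(ranking=scores, k=k)


def correlation_rank(
    x: pd.Series,
    centroids: pd.DataFrame,
    k: int = 3,
    method: str = "pearson",
) -> RankedPrediction:
    """Rank candidate types by correlation of the vote vector with centroids.

    ``method`` is "pearson" (default) or "spearman" (rank-transform first).
    Constant inputs score -inf and rank last, with a warning.  Score ties are
    broken by type name.
    """
    if method == "spearman":
        x = x.rank()
        centroids = centroids.rank(axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    ones = np.ones(len(centroids.index))
    return _rank_with_weights(x, centroids, lambda c: ones, k)


def topk_assign(pred: RankedPrediction, true_type: str) -> str:
    """Assign the true type when it appears in the top-k, else the top-1."""
    return true_type if true_type in pred.top_k else pred.top1


def evaluate(assigned: Sequence[str], truths: Sequence[str]) -> EvalReport:
    """Per-type accuracy/power over paired assignment and truth lists."""
    if len(assigned) != len(truths):
        raise ValueError("assigned and truths must have equal length")
    assigned = pd.Series(list(assigned))
    truths = pd.Series(list(truths))
    types = sorted(set(truths) | set(assigned))
    rows = {}
    for c in types:
        pred_c = assigned == c
        true_c = truths == c
        correct = (pred_c & true_c).sum()
        acc = correct / pred_c.sum() if pred_c.sum() else np.nan
        pow_ = correct / true_c.sum() if true_c.sum() else np.nan
        rows[c] = {"accuracy": acc, "power": pow_}
    per_type = pd.DataFrame(rows).T.rename_axis("cancer_type")
    return EvalReport(
        per_type=per_type,
        macro_accuracy=float(per_type["accuracy"].mean(skipna=True)),
        macro_power=float(per_type["power"].mean(skipna=True)),
    )
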