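"""Leading up-/bottom-patterns and weighted correlation ranking.

Samples of a given cancer type tend to draw consistently high votes for a
small group of similar types (including the type itself) and consistently
low votes for a few dissimilar ones.  For each reference type, the K
candidate types — each a point whose coordinates are its votes across the
reference type's training samples — are clustered with PAM (k-medoids).  The
clusters with the highest and lowest mean vote become the leading up- and
bottom-patterns, capped at 5 and 3 members.  During prediction, candidate
c's correlation with its centroid is computed with weights w_up on c's
up-pattern components, w_bottom on its bottom-pattern, and 1 elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .votes import RankedPrediction, _rank_with_weights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatternConfig:
    """Leading-pattern derivation and weighting parameters.

    k_candidates
        Cluster counts screened in ascending order; the first whose extreme
        clusters respect the caps is kept.
    max_up / max_bottom
        Caps on the sizes of the up- and bottom-patterns (5 and 3).
    w_up / w_bottom / w_neutral
        Correlation weights for up-pattern, bottom-pattern, and remaining
        components.  The defaults 3 and 0.1 come out of a screen over
        {2, 3, 4, 5} and {0.1, 0.2, 0.3} on validation data.
    """

    k_candidates: tuple[int, ...] = (3, 4, 5, 6)
    max_up: int = 5
    max_bottom: int = 3
    w_up: float = 3.0
    w_bottom: float = 0.1
    w_neutral: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w_up > self.w_neutral > self.w_bottom > 0):
            raise ValueError("need w_up > w_neutral > w_bottom > 0")
        if self.max_up < 1 or self.max_bottom < 1:
            raise ValueError("pattern caps must be >= 1")


@dataclass(frozen=True)
class PatternSet:
    """Leading patterns for one reference type.

    The reference type itself may (and typically does) sit in its own
    up-pattern.  ``k_used`` records the accepted cluster count, 0 when the
    rank-based fallback was used.
    """

    ref_type: str
    up_types: tuple[str, ...]
    bottom_types: tuple[str, ...]
    k_used: int

    def __post_init__(self) -> None:
        if set(self.up_types) & set(self.bottom_types):
            raise ValueError("up and bottom patterns must be disjoint")


# ---------------------------------------------------------------------------
# k-medoids


def _n_subsets(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def kmedoids(
    points: np.ndarray | Sequence[Sequence[float]],
    k: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """k-medoids under Euclidean distance (exact for small instances).

    When the number of medoid subsets C(n, k) is small (<= 20000 — which
    covers clustering candidate cancer types, n <= 18), the optimum is found
    by exhaustive enumeration, ties broken by the lexicographically smallest
    medoid set.  Larger instances fall back to the classical PAM local
    search: BUILD greedily picks medoids (first the point minimising total
    distance, then each point maximising the cost reduction); SWAP repeatedly
    applies the single (medoid, non-medoid) exchange with the largest cost
    decrease until none improves.  All ties break on the lowest index, so the
    result is deterministic; ``seed`` is accepted for interface symmetry only.

    Returns (labels, medoid_indices); labels[i] is the position of point i's
    medoid within the sorted medoid_indices array.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 1)
    n = len(pts)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points ({n})")
    D = cdist(pts, pts)

    if _n_subsets(n, k) <= 20_000:
        best_cost = np.inf
        best: tuple[int, ...] | None = None
        for meds in combinations(range(n), k):
            c = D[:, meds].min(axis=1).sum()
            if c < best_cost - 1e-12:
                best_cost, best = c, meds
        medoid_idx = np.array(best)
        labels = np.argmin(D[:, medoid_idx], axis=1)
        return labels, medoid_idx

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        # gain of adding candidate j: total reduction in nearest-distance
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP
    def cost(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_delta = -1e-12
        best_swap: tuple[int, int] | None = None
        in_medoids = set(medoids)
        for mi, mval in enumerate(medoids):
            for h in range(n):
                if h in in_medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = cost(trial) - current
                if delta < best_delta:
                    best_delta = delta
                    best_swap = (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            current += best_delta
            improved = True

    medoid_idx = np.array(sorted(medoids))
    labels = np.argmin(D[:, medoid_idx], axis=1)
    return labels, medoid_idx


# ---------------------------------------------------------------------------
# Pattern derivation


def derive_patterns(
    votes_of_type: pd.DataFrame, config: PatternConfig = PatternConfig()
) -> PatternSet:
    """Leading up-/bottom-patterns for one reference type.

    ``votes_of_type``: vote vectors (rows: the reference type's training
    samples, columns: the K candidate types).  Candidate types are clustered
    as points in sample space; a cluster's level is the mean of its member
    types' mean votes.  Cluster counts are screened in ascending order and
    the first whose top/bottom clusters respect the caps is accepted;
    otherwise the last count is used and the extreme clusters are truncated
    to the caps by per-type mean vote.  With fewer than three distinct vote
    profiles, a rank-based fallback picks the top/bottom types directly.
    """
    if "ref_type" in votes_of_type.attrs:
        ref = votes_of_type.attrs["ref_type"]
    else:
        ref = ""
    if len(votes_of_type) < 2:
        raise ValueError("need >=2 samples of the reference type")
    candidates = list(votes_of_type.columns)
    points = votes_of_type.T.to_numpy()  # K points in sample space
    mean_vote = votes_of_type.mean(axis=0)

    def by_mean(types: list[str], descending: bool) -> list[str]:
        return sorted(types, key=lambda t: (-mean_vote[t], t) if descending else (mean_vote[t], t))

    n_distinct = len(np.unique(points, axis=0))
    if n_distinct < 3:
        logger.warning(
            "type %s: only %d distinct vote profiles; rank-based pattern fallback",
            ref, n_distinct,
        )
        ordered = by_mean(candidates, descending=True)
        up = ordered[: config.max_up]
        bottom = [t for t in reversed(ordered) if t not in up][: config.max_bottom]
        return PatternSet(ref, tuple(up), tuple(bottom), k_used=0)

    feasible = [k for k in config.k_candidates if 2 <= k <= len(candidates)]
    if not feasible:
        raise ValueError("no feasible cluster count for the candidate set")
    chosen: tuple[list[str], list[str], int] | None = None
    for k in feasible:
        labels, _ = kmedoids(points, k)
        cluster_levels = []
        for c in range(k):
            members = [candidates[i] for i in np.flatnonzero(labels == c)]
            cluster_levels.append((float(np.mean([mean_vote[t] for t in members])), members))
        cluster_levels.sort(key=lambda lv: lv[0])
        bottom_members = cluster_levels[0][1]
        up_members = cluster_levels[-1][1]
        chosen = (up_members, bottom_members, k)
        if len(up_members) <= config.max_up and len(bottom_members) <= config.max_bottom:
            break
    up_members, bottom_members, k_used = chosen
    up = by_mean(up_members, descending=True)[: config.max_up]
    bottom = by_mean(bottom_members, descending=False)[: config.max_bottom]
    bottom = [t for t in bottom if t not in up]
    return PatternSet(ref, tuple(up), tuple(bottom), k_used=k_used)


def pattern_weights(
    ps: PatternSet,
    types: Sequence[str],
    config: PatternConfig = PatternConfig(),
) -> pd.Series:
    """Weight vector over candidate types: w_up / w_bottom / w_neutral."""
    w = pd.Series(config.w_neutral, index=list(types), dtype=float)
    w[list(ps.up_types)] = config.w_up
    w[list(ps.bottom_types)] = config.w_bottom
    return w


def build_pattern_table(
    vectors: pd.DataFrame,
    labels: pd.Series,
    config: PatternConfig = PatternConfig(),
) -> tuple[dict[str, PatternSet], pd.DataFrame]:
    """Patterns and weight vectors for every training type.

    Returns (per-type PatternSet dict, weight table whose column c is the
    weight vector applied when scoring candidate c).
    """
    labels = labels.loc[vectors.index]
    patterns: dict[str, PatternSet] = {}
    weights = {}
    for ctype in sorted(labels.unique()):
        sub = vectors.loc[labels == ctype].copy()
        sub.attrs["ref_type"] = ctype
        ps = derive_patterns(sub, config)
        patterns[ctype] = ps
        weights[ctype] = pattern_weights(ps, vectors.columns, config)
    return patterns, pd.DataFrame(weights)


def pattern_report(patterns: dict[str, PatternSet]) -> pd.DataFrame:
    """Tabular report: reference type, k used, up/bottom members."""
    rows = [
        {
            "reference_type": c,
            "k_used": ps.k_used,
            "up_types": ",".join(ps.up_types),
            "bottom_types": ",".join(ps.bottom_types),
        }
        for c, ps in sorted(patterns.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weighted ranking


def weighted_rank(
    x: pd.Series,
    centroids: pd.DataFrame,
    weight_table: pd.DataFrame,
    k: int = 3,
) -> RankedPrediction:
    """Rank candidates by weighted correlation with their centroids.

    ``weight_table`` column c is the weight vector used when scoring
    candidate c (components indexed like the centroid rows).  A candidate
    missing from the table falls back to unit weights, so an empty table
    reproduces the plain correlation ranking exactly.
    """
    ones = pd.Series(1.0, index=centroids.index)

    def weight_of(ctype: str) -> np.ndarray:
        if ctype in weight_table.columns:
            return weight_table[ctype].reindex(centroids.index).to_numpy()
        return ones.to_numpy()

    return _rank_with_weights(x, centroids, weight_of, k)
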