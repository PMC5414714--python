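"""Pairwise boosting ensembles on binary amplification features.

One ensemble is trained per (cancer-type pair, GO term) on that term's
selected differentially amplified genes.  The learner is discrete AdaBoost
over depth-1 decision stumps; because the features are 0/1 amplification
calls, every stump reduces to a "is gene g amplified?" test with a polarity.
A stochastic element is added by fitting each round's stump on a uniform
random subsample of the training set drawn without replacement.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import HallmarkAnnotation
from .dags import SelectionConfig, SignificancePolicy, select_dags

logger = logging.getLogger(__name__)

_EPS_CLIP = 1e-10


@dataclass(frozen=True)
class BoostConfig:
    """Boosting hyper-parameters.

    n_rounds
        Boosting iterations (stumps in the ensemble).
    subsample_fraction
        Fraction of the training set (without replacement) each round's
        stump is fitted on; 1.0 recovers deterministic AdaBoost.
    stump_depth
        Kept at 1: on binary features deeper trees add nothing a pair of
        stumps cannot express.
    learning_rate
        Multiplier on the stump weights.
    """

    n_rounds: int = 50
    subsample_fraction: float = 0.5
    stump_depth: int = 1
    learning_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.stump_depth != 1:
            raise ValueError("only depth-1 stumps are supported")


@dataclass
class BoostEnsemble:
    """A fitted stump ensemble for one (type pair, GO term).

    ``polarity[t] = +1`` means round t's stump votes for ``pair[0]`` when the
    gene at ``gene_index[t]`` is amplified; ``alpha`` are the stump weights.
    The stump threshold is fixed at 0.5 (binary features).
    """

    pair: tuple[str, str]
    term_id: str
    feature_genes: list[str]
    gene_index: np.ndarray  # (n_rounds,) int
    polarity: np.ndarray  # (n_rounds,) int8, +-1
    alpha: np.ndarray  # (n_rounds,) float
    trained_on: int

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Weighted stump sum for samples x feature-genes matrix ``X``.

        Positive scores favour ``pair[0]``, negative ``pair[1]``.
        """
        signed = self.alpha * self.polarity
        # stump output is polarity * (2*x - 1)
        return 2.0 * (X[:, self.gene_index] @ signed.reshape(-1, 1)).ravel() - signed.sum()

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        """+1 (pair[0]) / -1 (pair[1]) per sample; a tied score goes to the
        lexicographically smaller type name."""
        scores = self.decision_scores(X)
        first_smaller = self.pair[0] <= self.pair[1]
        tie = 1 if first_smaller else -1
        out = np.where(scores > 0, 1, np.where(scores < 0, -1, tie))
        return out.astype(np.int8)


def fit_boost(
    features: pd.DataFrame | np.ndarray,
    labels: Iterable[int],
    config: BoostConfig = BoostConfig(),
    *,
    pair: tuple[str, str] = ("A", "B"),
    term_id: str = "",
    feature_genes: list[str] | None = None,
) -> BoostEnsemble:
    """Fit discrete AdaBoost with per-round subsampling on binary features.

    ``labels`` are +1/-1 (or 1/0) with +1 meaning ``pair[0]``.  Each round
    draws ceil(subsample_fraction * n) samples uniformly without replacement,
    picks the stump (gene, polarity) minimising the weighted error on the
    subsample, weights it by 0.5 * learning_rate * ln((1 - eps) / eps) with
    eps clipped to [1e-10, 1 - 1e-10], and reweights the full training set.
    Deterministic given ``config.seed``.
    """
    if isinstance(features, pd.DataFrame):
        feature_genes = list(features.columns)
        X = features.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        if feature_genes is None:
            feature_genes = [f"g{i}" for i in range(X.shape[1])]
    y = np.asarray(list(labels))
    y = np.where(y > 0, 1.0, -1.0)
    n, g = X.shape
    if n == 0 or g == 0:
        raise ValueError("empty training matrix")
    if len(y) != n:
        raise ValueError("labels length does not match sample count")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate pair training set: single-class input")

    rng = np.random.default_rng(config.seed)
    m = math.ceil(config.subsample_fraction * n)
    w = np.full(n, 1.0 / n)
    gene_index = np.empty(config.n_rounds, dtype=np.int64)
    polarity = np.empty(config.n_rounds, dtype=np.int8)
    alpha = np.empty(config.n_rounds, dtype=np.float64)

    pos = (y > 0).astype(np.float64)
    for t in range(config.n_rounds):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        ws = w[idx]
        W = ws.sum()
        Xs = X[idx]
        # weighted error of the polarity=+1 stump for every gene at once:
        # it errs on positives that are 0 and negatives that are 1
        err_plus = (ws * (1 - pos[idx])) @ Xs + (ws * pos[idx]) @ (1 - Xs)
        err_minus = W - err_plus
        # ties break to polarity +1, then the lowest gene index; the tolerance
        # absorbs the one-ulp asymmetry of err_minus = W - err_plus at an
        # exact tie (weighted error W/2)
        bp = int(np.argmin(err_plus))
        bm = int(np.argmin(err_minus))
        if err_minus[bm] < err_plus[bp] - 1e-12 * W:
            gi, pol, err = bm, -1, err_minus[bm]
        else:
            gi, pol, err = bp, 1, err_plus[bp]
        eps = min(max(err / W, _EPS_CLIP), 1 - _EPS_CLIP)
        a = 0.5 * config.learning_rate * math.log((1 - eps) / eps)
        gene_index[t], polarity[t], alpha[t] = gi, pol, a
        h = pol * (2.0 * X[:, gi] - 1.0)
        w = w * np.exp(-a * y * h)
        w = w / w.sum()

    return BoostEnsemble(
        pair=tuple(pair),
        term_id=term_id,
        feature_genes=list(feature_genes),
        gene_index=gene_index,
        polarity=polarity,
        alpha=alpha,
        trained_on=n,
    )


def predict_vote(
    ensemble: BoostEnsemble, sample: Mapping[str, int] | pd.Series
) -> str:
    """Vote one of the ensemble's two types for a single sample.

    Genes absent from the sample are treated as non-amplified (logged).
    """
    if isinstance(sample, pd.Series):
        sample = sample.to_dict()
    missing = [g for g in ensemble.feature_genes if g not in sample]
    if missing:
        logger.debug(
            "pair %s term %s: %d feature genes missing from sample, treated as 0",
            ensemble.pair, ensemble.term_id, len(missing),
        )
    x = np.array(
        [[float(sample.get(g, 0)) for g in ensemble.feature_genes]]
    )
    lab = int(ensemble.predict_labels(x)[0])
    return ensemble.pair[0] if lab > 0 else ensemble.pair[1]


@dataclass
class PairModelBank:
    """All fitted ensembles, indexed by (unordered type pair, GO term).

    A ``None`` entry marks a term with no significant genes for that pair:
    its models abstain instead of casting uninformative votes.
    """

    types: list[str]
    term_ids: list[str]
    models: dict[tuple[str, str, str], BoostEnsemble | None] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.models)

    def pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.types, 2))

    def get(self, type_a: str, type_b: str, term_id: str) -> BoostEnsemble | None:
        a, b = sorted((type_a, type_b))
        return self.models[(a, b, term_id)]

    # -- JSON serialization (bit-exact float round trip via repr) -----------

    def to_dict(self) -> dict:
        entries = {}
        for (a, b, term), ens in self.models.items():
            key = f"{a}\t{b}\t{term}"
            if ens is None:
                entries[key] = None
            else:
                entries[key] = {
                    "feature_genes": ens.feature_genes,
                    "gene_index": ens.gene_index.tolist(),
                    "polarity": ens.polarity.tolist(),
                    "alpha": ens.alpha.tolist(),
                    "trained_on": ens.trained_on,
                }
        return {"types": self.types, "term_ids": self.term_ids, "models": entries}

    @classmethod
    def from_dict(cls, raw: dict) -> "PairModelBank":
        bank = cls(types=list(raw["types"]), term_ids=list(raw["term_ids"]))
        for key, rec in raw["models"].items():
            a, b, term = key.split("\t")
            if rec is None:
                bank.models[(a, b, term)] = None
            else:
                bank.models[(a, b, term)] = BoostEnsemble(
                    pair=(a, b),
                    term_id=term,
                    feature_genes=list(rec["feature_genes"]),
                    gene_index=np.array(rec["gene_index"], dtype=np.int64),
                    polarity=np.array(rec["polarity"], dtype=np.int8),
                    alpha=np.array(rec["alpha"], dtype=np.float64),
                    trained_on=int(rec["trained_on"]),
                )
        return bank

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PairModelBank":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _derived_seed(master_seed: int, a: str, b: str, term: str) -> int:
    """Stable per-(pair, term) seed independent of iteration order."""
    digest = hashlib.sha256(f"{master_seed}|{a}|{b}|{term}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def build_model_bank(
    calls: pd.DataFrame,
    labels: pd.Series,
    annotation: HallmarkAnnotation,
    policy: SignificancePolicy = SignificancePolicy(),
    selection: SelectionConfig = SelectionConfig(),
    boost: BoostConfig = BoostConfig(),
    types: list[str] | None = None,
) -> PairModelBank:
    """Train one ensemble per (unordered type pair, GO term) on training calls.

    ``calls`` is the binary gene x sample training matrix; ``labels`` maps its
    samples to cancer types.  The bank holds exactly
    ``n_terms * K*(K-1)/2`` entries, ``None`` where a term had no significant
    genes for a pair.
    """
    labels = labels.loc[[s for s in labels.index if s in calls.columns]]
    if types is None:
        types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least two cancer types")
    bank = PairModelBank(types=list(types), term_ids=list(annotation.term_ids))
    for a, b in combinations(types, 2):
        try:
            per_term = select_dags(calls, labels, (a, b), annotation, policy, selection)
            samples = labels.index[(labels == a) | (labels == b)]
            y = np.where(labels.loc[samples] == a, 1, -1)
            sub = calls.loc[:, samples]
            for term_id in annotation.term_ids:
                genes = per_term[term_id]
                if not genes:
                    bank.models[(a, b, term_id)] = None
                    continue
                X = sub.loc[genes].to_numpy().T
                cfg = BoostConfig(
                    n_rounds=boost.n_rounds,
                    subsample_fraction=boost.subsample_fraction,
                    stump_depth=boost.stump_depth,
                    learning_rate=boost.learning_rate,
                    seed=_derived_seed(boost.seed, a, b, term_id),
                )
                bank.models[(a, b, term_id)] = fit_boost(
                    X, y, cfg, pair=(a, b), term_id=term_id, feature_genes=genes
                )
        except ValueError as exc:
            raise ValueError(f"pair ({a}, {b}): {exc}") from exc
    return bank
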