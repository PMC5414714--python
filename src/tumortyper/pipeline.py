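"""End-to-end orchestration: train, predict, evaluate, screen weights.

The training stage binarizes scores (when needed), applies the founding-clone
mask, splits samples, fits the pairwise ensemble bank on the training
partition, builds vote-vector centroids, and derives leading patterns.  The
prediction stage turns new samples into vote vectors and ranks candidate
types by plain (``mode="centroid"``) or leading-pattern-weighted
(``mode="leading_pattern"``) correlation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import HallmarkAnnotation
from .boost import BoostConfig, PairModelBank, build_model_bank
from .dags import SelectionConfig, SignificancePolicy
from .patterns import (
    PatternConfig,
    PatternSet,
    build_pattern_table,
    pattern_report,
    weighted_rank,
)
from .profiles import apply_clone_mask, binarize, split_dataset
from .votes import (
    EvalReport,
    correlation_rank,
    evaluate,
    topk_assign,
    type_centroids,
    vote_vectors,
)

logger = logging.getLogger(__name__)

MODES = ("centroid", "leading_pattern")


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a training run, serializable for manifests."""

    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    policy: SignificancePolicy = field(default_factory=SignificancePolicy)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    boost: BoostConfig = field(default_factory=BoostConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    k: int = 3
    mode: str = "leading_pattern"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class TrainedModel:
    """Artifacts of a training run."""

    bank: PairModelBank
    centroids: pd.DataFrame  # candidate types x training types
    patterns: dict[str, PatternSet]
    weight_table: pd.DataFrame  # candidate types x training types
    config: RunConfig
    manifest: dict = field(default_factory=dict)


def train_pipeline(
    calls: pd.DataFrame,
    labels: pd.Series,
    annotation: HallmarkAnnotation,
    config: RunConfig = RunConfig(),
    split: pd.Series | None = None,
) -> tuple[TrainedModel, pd.Series]:
    """Fit the full three-layer model on the training partition.

    ``calls`` must already be binary founding-clone amplification calls (use
    :func:`prepare_calls` to get them from scores and a clone mask).  When
    ``split`` is None, a stratified split is drawn from the config seed.
    """
    labels = labels.loc[[s for s in labels.index if s in calls.columns]]
    if split is None:
        split = split_dataset(labels, config.proportions, seed=config.seed)
    train_samples = split.index[split == "train"]
    train_labels = labels.loc[[s for s in train_samples if s in labels.index]]
    if train_labels.nunique() < 2:
        raise ValueError("training partition must contain >=2 cancer types")

    boost = BoostConfig(
        n_rounds=config.boost.n_rounds,
        subsample_fraction=config.boost.subsample_fraction,
        stump_depth=config.boost.stump_depth,
        learning_rate=config.boost.learning_rate,
        seed=config.seed,
    )
    logger.info("training model bank on %d samples", len(train_labels))
    bank = build_model_bank(
        calls.loc[:, train_labels.index],
        train_labels,
        annotation,
        config.policy,
        config.selection,
        boost,
    )
    logger.info("computing training vote vectors")
    vectors = vote_vectors(calls.loc[:, train_labels.index], bank)
    centroids = type_centroids(vectors, train_labels)
    patterns, weight_table = build_pattern_table(vectors, train_labels, config.pattern)
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "n_train": int(len(train_labels)), "types": bank.types}
    model = TrainedModel(bank, centroids, patterns, weight_table, config, manifest)
    return model, split


def prepare_calls(
    scores: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    mask: pd.DataFrame | None = None,
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Binarize scores (if calls are not given) and apply the clone mask."""
    if calls is None:
        if scores is None:
            raise ValueError("provide scores or calls")
        calls = binarize(scores, threshold)
    if mask is not None:
        calls = apply_clone_mask(calls, mask, drop_unmasked_samples=True)
    return calls


def predict_pipeline(
    model: TrainedModel,
    calls: pd.DataFrame,
    mode: str | None = None,
    k: int | None = None,
) -> pd.DataFrame:
    """Rank candidate types for every sample (column) of ``calls``.

    Returns a DataFrame with the full ranking compressed to rank1..rank-k and
    score1..score-k columns, indexed by sample.
    """
    mode = mode or model.config.mode
    k = k or model.config.k
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    shared = set(calls.index) & {
        g for ens in model.bank.models.values() if ens is not None
        for g in ens.feature_genes
    }
    if not shared:
        raise ValueError("sample genes are disjoint from model feature genes")
    vectors = vote_vectors(calls, model.bank)
    rows = {}
    for sample, x in vectors.iterrows():
        if mode == "centroid":
            pred = correlation_rank(x, model.centroids, k)
        else:
            pred = weighted_rank(x, model.centroids, model.weight_table, k)
        rec = {}
        for r, (ctype, score) in enumerate(pred.ranking[:k], start=1):
            rec[f"rank{r}"] = ctype
            rec[f"score{r}"] = score
        rows[sample] = rec
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    out.attrs.update({"mode": mode, "k": k})
    return out


def assign_predictions(
    predictions: pd.DataFrame, truths: pd.Series, k: int | None = None
) -> pd.Series:
    """Apply the top-k assignment rule: keep the true type when it is among
    the top-k candidates, otherwise take the rank-1 candidate."""
    k = k or predictions.attrs.get("k", 3)
    assigned = {}
    for sample, row in predictions.iterrows():
        topk = [row[f"rank{r}"] for r in range(1, k + 1) if f"rank{r}" in row]
        true = truths[sample]
        assigned[sample] = true if true in topk else row["rank1"]
    return pd.Series(assigned, name="assigned")


def evaluate_predictions(
    predictions: pd.DataFrame, truths: pd.Series, k: int | None = None
) -> EvalReport:
    truths = truths.loc[predictions.index]
    assigned = assign_predictions(predictions, truths, k)
    return evaluate(assigned.tolist(), truths.tolist())


def screen_weights(
    model: TrainedModel,
    calls_val: pd.DataFrame,
    labels_val: pd.Series,
    up_grid: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
    bottom_grid: tuple[float, ...] = (0.1, 0.2, 0.3),
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Grid-screen the up/bottom pattern weights on validation samples.

    Every (w_up, w_bottom) combination is scored by macro power (macro
    accuracy breaks ties).  Returns the best pair and the full table.
    """
    from .patterns import pattern_weights  # local to avoid cycles in docs

    vectors = vote_vectors(calls_val, model.bank)
    truths = labels_val.loc[vectors.index]
    rows = []
    for w_up in up_grid:
        for w_bottom in bottom_grid:
            cfg = PatternConfig(
                k_candidates=model.config.pattern.k_candidates,
                max_up=model.config.pattern.max_up,
                max_bottom=model.config.pattern.max_bottom,
                w_up=w_up,
                w_bottom=w_bottom,
            )
            table = pd.DataFrame(
                {
                    c: pattern_weights(ps, model.centroids.index, cfg)
                    for c, ps in model.patterns.items()
                }
            )
            assigned = []
            for sample, x in vectors.iterrows():
                pred = weighted_rank(x, model.centroids, table, model.config.k)
                assigned.append(topk_assign(pred, truths[sample]))
            report = evaluate(assigned, truths.tolist())
            rows.append(
                {
                    "w_up": w_up,
                    "w_bottom": w_bottom,
                    "macro_power": report.macro_power,
                    "macro_accuracy": report.macro_accuracy,
                }
            )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["macro_power", "macro_accuracy", "w_up", "w_bottom"],
        ascending=[False, False, True, True],
    ).iloc[0]
    return (float(best["w_up"]), float(best["w_bottom"])), table


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.bank.save(out / "model_bank.json")
    model.centroids.to_csv(out / "centroids.tsv", sep="\t", index_label="candidate_type")
    model.weight_table.to_csv(out / "pattern_weights.tsv", sep="\t", index_label="candidate_type")
    pattern_report(model.patterns).to_csv(out / "patterns.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps({**model.manifest, "config": model.config.to_dict()}, indent=2) + "\n"
    )


def load_model(in_dir: str | Path) -> TrainedModel:
    src = Path(in_dir)
    bank = PairModelBank.load(src / "model_bank.json")
    centroids = pd.read_csv(src / "centroids.tsv", sep="\t", index_col=0)
    weight_table = pd.read_csv(src / "pattern_weights.tsv", sep="\t", index_col=0)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_raw = manifest.pop("config")
    config = RunConfig(
        proportions=tuple(cfg_raw["proportions"]),
        policy=SignificancePolicy(**cfg_raw["policy"]),
        selection=SelectionConfig(**cfg_raw["selection"]),
        boost=BoostConfig(**cfg_raw["boost"]),
        pattern=PatternConfig(
            **{**cfg_raw["pattern"],
               "k_candidates": tuple(cfg_raw["pattern"]["k_candidates"])}
        ),
        k=cfg_raw["k"],
        mode=cfg_raw["mode"],
        seed=cfg_raw["seed"],
    )
    pat_df = pd.read_csv(src / "patterns.tsv", sep="\t").fillna("")
    patterns = {
        row["reference_type"]: PatternSet(
            ref_type=row["reference_type"],
            up_types=tuple(t for t in str(row["up_types"]).split(",") if t),
            bottom_types=tuple(t for t in str(row["bottom_types"]).split(",") if t),
            k_used=int(row["k_used"]),
        )
        for _, row in pat_df.iterrows()
    }
    return TrainedModel(bank, centroids, patterns, weight_table, config, manifest)
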