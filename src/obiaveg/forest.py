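"""Bagged gain-ratio-tree forest with positive-class-aware feature weighting.

A classical random forest (bootstrap resampling, per-tree random feature
subsets, majority vote) built from the pruned gain-ratio trees of
:mod:`obiaveg.tree_c50`, with one twist aimed at strong class imbalance:
per-tree feature subsets are drawn *without replacement* from a weighted
distribution that up-weights features useful for separating the positive
(minority) class one-vs-rest, while a uniform floor keeps every feature
— including those only useful for the negative class — permanently
sampleable.

With mixing weight ``lambda_weight = 0`` the sampler is uniform and the
model reduces exactly to a plain random forest of gain-ratio trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureTable
from .tree_c50 import (
    C50Tree,
    TreeConfig,
    best_split,
    grow_tree,
    predict_tree_batch,
    prune_tree,
)

__all__ = [
    "ForestConfig",
    "ForestModel",
    "compute_feature_weights",
    "sample_features",
    "bootstrap_sample",
    "train_forest",
    "predict_forest",
    "oob_score",
    "feature_importance",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``m_features`` defaults to ``ceil(sqrt(F))`` at train time (10 for
    the standard 85-feature table).  ``lambda_weight`` mixes uniform
    feature sampling (0) with purely score-proportional sampling (1);
    ``positive_class`` names the minority class the scores target.
    """

    n_trees: int = 100
    m_features: int | None = None
    positive_class: str | None = None
    lambda_weight: float = 0.5
    bootstrap: bool = True
    prune: bool = True
    tree_config: TreeConfig = field(default_factory=TreeConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValueError("lambda_weight must lie in [0, 1]")


@dataclass
class ForestModel:
    trees: list[C50Tree]
    feature_subsets: list[list[str]]
    inbag_indices: list[np.ndarray]
    feature_weights: dict[str, float]
    feature_names: list[str]
    classes: tuple[str, ...]
    config: ForestConfig

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "format": "obiaveg-forest/1",
            "config": {
                "n_trees": cfg.n_trees,
                "m_features": cfg.m_features,
                "positive_class": cfg.positive_class,
                "lambda_weight": cfg.lambda_weight,
                "bootstrap": cfg.bootstrap,
                "prune": cfg.prune,
                "seed": cfg.seed,
                "tree_config": {
                    "min_split": cfg.tree_config.min_split,
                    "min_leaf": cfg.tree_config.min_leaf,
                    "min_gain": cfg.tree_config.min_gain,
                    "max_depth": cfg.tree_config.max_depth,
                    "prune_confidence": cfg.tree_config.prune_confidence,
                },
            },
            "classes": list(self.classes),
            "feature_names": self.feature_names,
            "feature_weights": self.feature_weights,
            "feature_subsets": self.feature_subsets,
            "inbag_indices": [idx.tolist() for idx in self.inbag_indices],
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        cfg = d["config"]
        tc = cfg.get("tree_config", {})
        config = ForestConfig(
            n_trees=cfg["n_trees"],
            m_features=cfg.get("m_features"),
            positive_class=cfg.get("positive_class"),
            lambda_weight=cfg.get("lambda_weight", 0.5),
            bootstrap=cfg.get("bootstrap", True),
            prune=cfg.get("prune", True),
            tree_config=TreeConfig(
                min_split=tc.get("min_split", 2),
                min_leaf=tc.get("min_leaf", 1),
                min_gain=tc.get("min_gain", 1e-6),
                max_depth=tc.get("max_depth"),
                prune_confidence=tc.get("prune_confidence", 0.25),
            ),
            seed=cfg.get("seed", 0),
        )
        return cls(
            trees=[C50Tree.from_dict(t) for t in d["trees"]],
            feature_subsets=[list(s) for s in d["feature_subsets"]],
            inbag_indices=[np.asarray(i, dtype=np.int64) for i in d["inbag_indices"]],
            feature_weights=dict(d["feature_weights"]),
            feature_names=list(d["feature_names"]),
            classes=tuple(d["classes"]),
            config=config,
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ForestModel":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Feature weighting and sampling
# ---------------------------------------------------------------------------

def compute_feature_weights(
    table: FeatureTable, positive_class: str, lambda_weight: float
) -> dict[str, float]:
    """Per-feature sampling probabilities.

    Each feature is scored by its best single-split gain ratio on the
    one-vs-rest problem (positive class against everything else); the
    sampling weight is the mixture
    ``(1 - lambda) / F + lambda * score / sum(scores)`` (uniform when all
    scores vanish).  The uniform floor ``(1 - lambda)/F`` keeps every
    weight strictly positive, so features useful only for the negative
    class are never starved out of the ensemble.
    """
    labels = table.labels
    if labels is None:
        raise ValueError("a labeled table is required")
    if positive_class not in set(labels):
        raise ValueError(f"positive class {positive_class!r} absent from the labels")
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValueError("lambda_weight must lie in [0, 1]")
    y = (labels == positive_class).astype(np.int64)
    X = table.X
    names = table.feature_names
    scores = np.zeros(len(names))
    for j, name in enumerate(names):
        cand = best_split(X[:, [j]], y, [name])
        if cand is not None:
            scores[j] = cand.gain_ratio
    f = len(names)
    if scores.sum() > 0:
        weights = (1.0 - lambda_weight) / f + lambda_weight * scores / scores.sum()
    else:
        weights = np.full(f, 1.0 / f)
    return {name: float(w) for name, w in zip(names, weights)}


def sample_features(
    weights: dict[str, float] | Sequence[float],
    m: int,
    rng: np.random.Generator,
    feature_names: Sequence[str] | None = None,
) -> list[str]:
    """Weighted sampling without replacement: sequential draw from the
    renormalised remainder.  Deterministic under a fixed rng state."""
    if isinstance(weights, dict):
        feature_names = list(weights.keys())
        w = np.asarray([weights[n] for n in feature_names], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if feature_names is None:
            feature_names = [str(i) for i in range(len(w))]
    if m > len(w):
        raise ValueError(f"cannot draw {m} features from {len(w)}")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    remaining = list(range(len(w)))
    chosen: list[int] = []
    for _ in range(m):
        sub = w[remaining]
        p = sub / sub.sum()
        pick = int(rng.choice(len(remaining), p=p))
        chosen.append(remaining.pop(pick))
    return [feature_names[i] for i in chosen]


def bootstrap_sample(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """n draws with replacement plus the out-of-bag complement."""
    if n < 1:
        raise ValueError("n must be >= 1")
    inbag = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), inbag)
    return inbag, oob


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_forest(table: FeatureTable, config: ForestConfig = ForestConfig()) -> ForestModel:
    """Grow (and by default prune) ``n_trees`` gain-ratio trees, each on
    its own bootstrap sample restricted to its weighted feature subset.

    Feature weights are computed once on the full training table.  The
    per-tree RNG substream is derived from ``(seed, tree index)``, so the
    model is fully determined by ``(seed, config, table)``.
    """
    labels = table.labels
    if labels is None:
        raise ValueError("a labeled table is required")
    classes = tuple(sorted({str(v) for v in labels}))
    if len(classes) < 2:
        raise ValueError(
            f"single-class training table (only {classes[0]!r}); at least two classes required"
        )
    names = table.feature_names
    n, f = table.n_objects, len(names)
    m = config.m_features if config.m_features is not None else int(np.ceil(np.sqrt(f)))
    if not 1 <= m <= f:
        raise ValueError(f"m_features must lie in [1, {f}]")

    if config.lambda_weight > 0 and config.positive_class is not None:
        weights = compute_feature_weights(table, config.positive_class, config.lambda_weight)
    else:
        weights = {name: 1.0 / f for name in names}

    X = table.X
    col = {name: j for j, name in enumerate(names)}
    trees: list[C50Tree] = []
    subsets: list[list[str]] = []
    inbags: list[np.ndarray] = []
    for t in range(config.n_trees):
        rng = np.random.default_rng([config.seed, t])
        subset = sample_features(weights, m, rng)
        if config.bootstrap:
            inbag, _ = bootstrap_sample(n, rng)
        else:
            inbag = np.arange(n)
        cols = [col[s] for s in subset]
        tree = grow_tree(
            X[np.ix_(inbag, cols)],
            labels[inbag],
            subset,
            config.tree_config,
            classes=classes,
        )
        if config.prune:
            tree = prune_tree(tree)
        trees.append(tree)
        subsets.append(list(subset))
        inbags.append(np.asarray(inbag, dtype=np.int64))
    return ForestModel(
        trees=trees,
        feature_subsets=subsets,
        inbag_indices=inbags,
        feature_weights=weights,
        feature_names=list(names),
        classes=classes,
        config=config,
    )


# ---------------------------------------------------------------------------
# Prediction and diagnostics
# ---------------------------------------------------------------------------

def _tree_votes(model: ForestModel, X: np.ndarray, feature_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-tree hard votes (trees x rows) and summed leaf probabilities
    (rows x classes)."""
    n = X.shape[0]
    votes = np.empty((len(model.trees), n), dtype=np.int64)
    prob_sum = np.zeros((n, len(model.classes)))
    for t, tree in enumerate(model.trees):
        probs = predict_tree_batch(tree, X, feature_names)
        votes[t] = np.argmax(probs, axis=1)
        prob_sum += probs
    return votes, prob_sum


def _majority(vote_counts: np.ndarray, prob_sum: np.ndarray) -> np.ndarray:
    """Row-wise winner: most votes, ties by higher summed leaf
    probability, then lowest (lexicographically first) class index."""
    n, k = vote_counts.shape
    winner = np.empty(n, dtype=np.int64)
    for i in range(n):
        top = vote_counts[i].max()
        tied = np.nonzero(vote_counts[i] == top)[0]
        if tied.size == 1:
            winner[i] = tied[0]
        else:
            best_p = prob_sum[i, tied].max()
            tied2 = tied[prob_sum[i, tied] >= best_p - 1e-12]
            winner[i] = tied2[0]
    return winner


def predict_forest(
    model: ForestModel, table: FeatureTable | np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and per-class vote fractions (rows x classes)."""
    if isinstance(table, FeatureTable):
        X = table.X
        feature_names = table.feature_names
    else:
        X = np.asarray(table, dtype=float)
        if feature_names is None:
            raise ValueError("feature_names are required with a bare array")
    votes, prob_sum = _tree_votes(model, X, feature_names)
    k = len(model.classes)
    vote_counts = np.stack([(votes == c).sum(axis=0) for c in range(k)], axis=1)
    fractions = vote_counts / len(model.trees)
    winner = _majority(vote_counts, prob_sum)
    labels = np.asarray(model.classes)[winner]
    return labels, fractions


def oob_score(model: ForestModel, table: FeatureTable) -> dict:
    """Out-of-bag accuracy: each row is predicted only by trees whose
    bootstrap sample excluded it.

    Returns overall and per-class OOB accuracy (per-class recall), the
    OOB predictions, and the count of rows never out of bag (excluded).
    """
    if not model.config.bootstrap:
        raise ValueError("OOB scoring requires a bootstrap-trained model")
    labels = table.labels
    if labels is None:
        raise ValueError("a labeled table is required")
    X = table.X
    names = table.feature_names
    n = X.shape[0]
    k = len(model.classes)
    vote_counts = np.zeros((n, k), dtype=np.int64)
    prob_sum = np.zeros((n, k))
    for tree, inbag in zip(model.trees, model.inbag_indices):
        oob_rows = np.setdiff1d(np.arange(n), inbag)
        if oob_rows.size == 0:
            continue
        probs = predict_tree_batch(tree, X[oob_rows], names)
        hard = np.argmax(probs, axis=1)
        vote_counts[oob_rows, hard] += 1
        prob_sum[oob_rows] += probs
    covered = vote_counts.sum(axis=1) > 0
    n_excluded = int(n - covered.sum())
    winner = _majority(vote_counts[covered], prob_sum[covered])
    pred = np.asarray(model.classes)[winner]
    truth = np.asarray([str(v) for v in labels])[covered]
    overall = float((pred == truth).mean()) if truth.size else float("nan")
    per_class: dict[str, float] = {}
    for c in model.classes:
        sel = truth == c
        per_class[c] = float((pred[sel] == c).mean()) if sel.any() else float("nan")
    oob_pred = np.full(n, None, dtype=object)
    oob_pred[covered] = pred
    return {
        "overall": overall,
        "per_class": per_class,
        "n_excluded": n_excluded,
        "predictions": oob_pred,
    }


def feature_importance(model: ForestModel) -> dict[str, float]:
    """Gain-weighted split importance.

    Sums ``info_gain * (node samples / root samples)`` over every
    internal node of every tree, per feature, normalised to total 1.
    Features never split on score 0.
    """
    scores = {name: 0.0 for name in model.feature_names}

    def walk(node, root_n: float) -> None:
        if node.is_leaf:
            return
        scores[node.split.feature_name] += node.split.info_gain * (node.n / root_n)
        walk(node.left, root_n)
        walk(node.right, root_n)

    for tree in model.trees:
        walk(tree.root, float(tree.root.n))
    total = sum(scores.values())
    if total > 0:
        scores = {name: s / total for name, s in scores.items()}
    return scores
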