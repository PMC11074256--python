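"""Gain-ratio decision-tree induction (C4.5/C5.0 family), from scratch.

Entropy, information gain and split information are in bits.  Splits are
binary on numeric features (``value <= threshold`` goes left), candidate
thresholds are midpoints between consecutive distinct sorted values, and
the selected split maximises the gain ratio among candidates whose
information gain is at least the mean gain of all positive-gain
candidates — the classic guard against the gain ratio's bias toward
near-trivial splits.  Generalisation is handled by bottom-up pessimistic
pruning with an upper binomial confidence bound on training error.

Ties on gain ratio are broken deterministically: lower feature index in
the supplied feature order, then lower threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

__all__ = [
    "SplitCandidate",
    "TreeConfig",
    "TreeNode",
    "C50Tree",
    "entropy",
    "info_gain",
    "split_info",
    "best_split",
    "grow_tree",
    "prune_tree",
    "predict_tree",
    "pessimistic_errors",
]


# ---------------------------------------------------------------------------
# Impurity primitives
# ---------------------------------------------------------------------------

def entropy(class_counts: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy of a class-count vector, in bits."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a non-empty 1-D vector")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("class counts must not all be zero")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def info_gain(
    parent_counts: Sequence[int] | np.ndarray,
    children_counts: Sequence[Sequence[int]] | np.ndarray,
) -> float:
    """Information gain of a partition: parent entropy minus the
    size-weighted mean of child entropies.  Non-negative."""
    parent = np.asarray(parent_counts, dtype=float)
    children = [np.asarray(c, dtype=float) for c in children_counts]
    if not children:
        raise ValueError("at least one child is required")
    summed = np.sum(children, axis=0)
    if summed.shape != parent.shape or not np.allclose(summed, parent):
        raise ValueError("children counts must sum to the parent counts")
    n = parent.sum()
    weighted = sum((c.sum() / n) * entropy(c) for c in children if c.sum() > 0)
    return float(entropy(parent) - weighted)


def split_info(children_sizes: Sequence[int] | np.ndarray) -> float:
    """Entropy of the partition's size distribution (gain-ratio denominator)."""
    sizes = np.asarray(children_sizes, dtype=float)
    if sizes.size < 2:
        raise ValueError("a split needs at least two children")
    if np.any(sizes <= 0):
        raise ValueError("children sizes must be positive")
    p = sizes / sizes.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitCandidate:
    """A binary threshold split; rows with ``value <= threshold`` go left."""

    feature_name: str
    threshold: float
    info_gain: float
    split_info: float
    gain_ratio: float


@dataclass(frozen=True)
class TreeConfig:
    """Stopping and pruning controls.

    ``min_leaf`` defaults to 2 (the classic C4.5 minimum branch size):
    pure singleton leaves carry a pessimistic bound of only 0.75 errors
    each, so a fringe of them is never worth collapsing and pessimistic
    pruning loses all traction on noise — requiring 2 items per leaf
    restores it.  Set ``min_leaf=1`` to grow to full purity.
    """

    min_split: int = 2
    min_leaf: int = 2
    min_gain: float = 1e-6
    max_depth: int | None = None
    prune_confidence: float = 0.25

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0.0 < self.prune_confidence <= 0.5:
            raise ValueError("prune_confidence must lie in (0, 0.5]")


def _class_entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Entropy (bits) of each row of a 2-D count matrix; 0 for empty rows."""
    totals = counts.sum(axis=1, keepdims=True)
    safe_tot = np.where(totals > 0, totals, 1.0)
    p = counts / safe_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=1)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    config: TreeConfig = TreeConfig(),
) -> SplitCandidate | None:
    """Exhaustive threshold search over every feature.

    Returns the gain-ratio-maximising candidate under the mean-gain guard,
    or ``None`` when no candidate reaches ``config.min_gain`` bits of gain.
    ``y`` is an integer class-index vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("at least one feature is required")
    n, n_feat = X.shape
    if len(feature_names) != n_feat:
        raise ValueError("feature_names length must match the column count")
    n_classes = int(y.max()) + 1 if y.size else 0
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    parent_entropy = entropy(parent_counts)

    feat_idx_all: list[np.ndarray] = []
    thr_all: list[np.ndarray] = []
    gain_all: list[np.ndarray] = []
    sinfo_all: list[np.ndarray] = []

    for j in range(n_feat):
        order = np.argsort(X[:, j], kind="stable")
        xv = X[order, j]
        ys = y[order]
        # cumulative one-hot class counts after each row
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        boundary = np.nonzero(xv[:-1] < xv[1:])[0]  # split after position i
        if boundary.size == 0:
            continue
        n_left = boundary + 1
        n_right = n - n_left
        ok = (n_left >= config.min_leaf) & (n_right >= config.min_leaf)
        boundary = boundary[ok]
        if boundary.size == 0:
            continue
        n_left = n_left[ok].astype(float)
        n_right = n_right[ok].astype(float)
        left = cum[boundary]
        right = parent_counts[None, :] - left
        h_left = _class_entropy_rows(left)
        h_right = _class_entropy_rows(right)
        gain = parent_entropy - (n_left / n) * h_left - (n_right / n) * h_right
        pl = n_left / n
        pr = n_right / n
        sinfo = -(pl * np.log2(pl) + pr * np.log2(pr))
        thr = (xv[boundary] + xv[boundary + 1]) / 2.0
        feat_idx_all.append(np.full(boundary.size, j))
        thr_all.append(thr)
        gain_all.append(gain)
        sinfo_all.append(sinfo)

    if not gain_all:
        return None
    feat_idx = np.concatenate(feat_idx_all)
    thr = np.concatenate(thr_all)
    gain = np.concatenate(gain_all)
    sinfo = np.concatenate(sinfo_all)

    if gain.max() < config.min_gain:
        return None
    positive = gain > 0
    mean_gain = gain[positive].mean()
    eligible = (gain >= mean_gain) & (gain >= config.min_gain)
    ratio = np.where(eligible, gain / sinfo, -np.inf)

    # argmax with deterministic tie-break: candidates are ordered by
    # (feature index, threshold) already; np.argmax returns the first max
    best = int(np.argmax(ratio))
    return SplitCandidate(
        feature_name=str(feature_names[feat_idx[best]]),
        threshold=float(thr[best]),
        info_gain=float(gain[best]),
        split_info=float(sinfo[best]),
        gain_ratio=float(ratio[best]),
    )


# ---------------------------------------------------------------------------
# Tree structure, growth, pruning, prediction
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    class_counts: np.ndarray
    depth: int
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())

    def node_count(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.node_count() + self.right.node_count()


@dataclass
class C50Tree:
    """A grown (optionally pruned) gain-ratio tree.

    ``classes`` fixes the class order used by every count vector and
    probability vector in the tree.
    """

    root: TreeNode
    classes: tuple[str, ...]
    config: TreeConfig = field(default_factory=TreeConfig)

    def node_count(self) -> int:
        return self.root.node_count()

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            d: dict = {"class_counts": [int(c) for c in node.class_counts], "depth": node.depth}
            if not node.is_leaf:
                d["split"] = {
                    "feature_name": node.split.feature_name,
                    "threshold": node.split.threshold,
                    "info_gain": node.split.info_gain,
                    "split_info": node.split.split_info,
                    "gain_ratio": node.split.gain_ratio,
                }
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        return {
            "classes": list(self.classes),
            "config": {
                "min_split": self.config.min_split,
                "min_leaf": self.config.min_leaf,
                "min_gain": self.config.min_gain,
                "max_depth": self.config.max_depth,
                "prune_confidence": self.config.prune_confidence,
            },
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "C50Tree":
        def build(nd: dict) -> TreeNode:
            node = TreeNode(
                class_counts=np.asarray(nd["class_counts"], dtype=np.int64),
                depth=int(nd["depth"]),
            )
            if "split" in nd:
                s = nd["split"]
                node.split = SplitCandidate(
                    feature_name=s["feature_name"],
                    threshold=float(s["threshold"]),
                    info_gain=float(s["info_gain"]),
                    split_info=float(s["split_info"]),
                    gain_ratio=float(s["gain_ratio"]),
                )
                node.left = build(nd["left"])
                node.right = build(nd["right"])
            return node

        cfg = d.get("config", {})
        return cls(
            root=build(d["root"]),
            classes=tuple(d["classes"]),
            config=TreeConfig(
                min_split=cfg.get("min_split", 2),
                min_leaf=cfg.get("min_leaf", 1),
                min_gain=cfg.get("min_gain", 1e-6),
                max_depth=cfg.get("max_depth"),
                prune_confidence=cfg.get("prune_confidence", 0.25),
            ),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "C50Tree":
        return cls.from_dict(json.loads(s))


def grow_tree(
    X: np.ndarray,
    y_labels: Sequence[str] | np.ndarray,
    feature_names: Sequence[str],
    config: TreeConfig = TreeConfig(),
    classes: Sequence[str] | None = None,
) -> C50Tree:
    """Recursive partitioning until purity, ``min_split``, ``max_depth``
    or no admissible split.  Leaves store class counts."""
    X = np.asarray(X, dtype=float)
    y_labels = np.asarray(y_labels)
    if X.shape[0] < 1:
        raise ValueError("a labeled table with at least one row is required")
    if y_labels.shape[0] != X.shape[0]:
        raise ValueError("labels must align with rows")
    if classes is None:
        classes = sorted({str(v) for v in y_labels})
    classes = tuple(str(c) for c in classes)
    class_idx = {c: i for i, c in enumerate(classes)}
    try:
        y = np.asarray([class_idx[str(v)] for v in y_labels], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"label {exc} not in the declared class set") from exc
    names = [str(f) for f in feature_names]

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[rows], minlength=len(classes))
        node = TreeNode(class_counts=counts, depth=depth)
        if (
            np.count_nonzero(counts) <= 1
            or rows.size < config.min_split
            or (config.max_depth is not None and depth >= config.max_depth)
        ):
            return node
        cand = best_split(X[rows], y[rows], names, config)
        if cand is None:
            return node
        j = names.index(cand.feature_name)
        go_left = X[rows, j] <= cand.threshold
        node.split = cand
        node.left = build(rows[go_left], depth + 1)
        node.right = build(rows[~go_left], depth + 1)
        return node

    root = build(np.arange(X.shape[0]), 0)
    return C50Tree(root=root, classes=classes, config=config)


def _pessimistic_upper(errors: float, n: float, confidence: float) -> float:
    """Clopper–Pearson upper bound on the true error rate given ``errors``
    misclassifications out of ``n``, at one-sided level ``confidence``."""
    if n <= 0:
        return 1.0
    if errors >= n:
        return 1.0
    return float(beta_dist.ppf(1.0 - confidence, errors + 1.0, n - errors))


def pessimistic_errors(node: TreeNode, confidence: float) -> float:
    """Summed pessimistic error count over the leaves of a subtree."""
    if node.is_leaf:
        n = node.n
        errors = n - int(node.class_counts.max())
        return n * _pessimistic_upper(errors, n, confidence)
    return pessimistic_errors(node.left, confidence) + pessimistic_errors(
        node.right, confidence
    )


def prune_tree(tree: C50Tree, config: TreeConfig | None = None) -> C50Tree:
    """Bottom-up pessimistic pruning (subtree replacement).

    A subtree collapses to a leaf whenever the leaf's pessimistic error
    count is no worse than the subtree's summed leaf bounds; the node
    count never increases and the total pessimistic training-error bound
    never increases.  Returns a new tree; the input is untouched.
    """
    cfg = config or tree.config
    conf = cfg.prune_confidence

    def prune(node: TreeNode) -> tuple[TreeNode, float]:
        if node.is_leaf:
            return node, pessimistic_errors(node, conf)
        left, err_left = prune(node.left)
        right, err_right = prune(node.right)
        subtree_err = err_left + err_right
        n = node.n
        leaf_errors = n - int(node.class_counts.max())
        leaf_err = n * _pessimistic_upper(leaf_errors, n, conf)
        if leaf_err <= subtree_err:
            return TreeNode(class_counts=node.class_counts.copy(), depth=node.depth), leaf_err
        new = TreeNode(
            class_counts=node.class_counts.copy(),
            depth=node.depth,
            split=node.split,
            left=left,
            right=right,
        )
        return new, subtree_err

    root, _ = prune(tree.root)
    return C50Tree(root=root, classes=tree.classes, config=cfg)


def predict_tree(
    tree: C50Tree, row: Mapping[str, float]
) -> tuple[str, dict[str, float]]:
    """Route one row down the tree.

    Returns the majority label of the reached leaf and the leaf's
    class-count-normalised probabilities.  A feature used by the tree but
    absent from the row is an error.
    """
    node = tree.root
    while not node.is_leaf:
        name = node.split.feature_name
        if name not in row:
            raise KeyError(f"row is missing feature {name!r}")
        node = node.left if row[name] <= node.split.threshold else node.right
    counts = node.class_counts.astype(float)
    probs = counts / counts.sum()
    label = tree.classes[int(np.argmax(counts))]
    return label, {c: float(p) for c, p in zip(tree.classes, probs)}


def predict_tree_batch(
    tree: C50Tree, X: np.ndarray, feature_names: Sequence[str]
) -> np.ndarray:
    """Leaf probability matrix (rows x classes) for an array of rows.

    ``feature_names`` gives the column order of ``X``; every feature the
    tree splits on must be present.
    """
    X = np.asarray(X, dtype=float)
    col = {str(f): i for i, f in enumerate(feature_names)}
    out = np.empty((X.shape[0], len(tree.classes)))

    def descend(node: TreeNode, rows: np.ndarray) -> None:
        if rows.size == 0:
            return
        if node.is_leaf:
            counts = node.class_counts.astype(float)
            out[rows] = counts / counts.sum()
            return
        name = node.split.feature_name
        if name not in col:
            raise KeyError(f"rows are missing feature {name!r}")
        go_left = X[rows, col[name]] <= node.split.threshold
        descend(node.left, rows[go_left])
        descend(node.right, rows[~go_left])

    descend(tree.root, np.arange(X.shape[0]))
    return out
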