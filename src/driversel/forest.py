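"""From-scratch CART trees and a bagged random forest over the 10 predictors.

The trees are deliberately introspectable — every node exposes its split
feature, threshold and cached class distribution — because the transfer
operators rewrite them (snip clades, move thresholds) after training.  A
library forest would not expose enough structure for that, so the ensemble
is implemented here.

Conventions (fixed; serialization depends on them):

* classes ordered (OG, TSG, PG);
* routing: feature value <= threshold goes left, > goes right;
* split choice: maximum count-weighted Gini decrease among ``m_features``
  randomly drawn candidate features, candidate thresholds at midpoints of
  consecutive sorted unique values; ties break toward the lowest feature
  index, then the lowest threshold;
* leaf prediction is the leaf's training class distribution (not a hard
  vote), giving graded per-gene probabilities;
* rows are put in a canonical sort order before bagging, so training is
  invariant to input row order for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger("driversel")

CLASSES = ("OG", "TSG", "PG")
N_CLASSES = 3

VARIANT_SOURCE = "T_h"
VARIANT_PRUNE = "T_prune"
VARIANT_SHIFT = "T_shift"

KIND_SOURCE = "RF"
KIND_ADAPTED = "RF_mouse"


class UndefinedImpurityError(ValueError):
    """Gini impurity of an empty node is undefined."""


def gini(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 − Σ (c_k / total)² of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise UndefinedImpurityError("gini of an empty node is undefined")
    p = counts / total
    return float(1.0 - (p * p).sum())


@dataclass
class Node:
    """Tree node; a leaf has ``feature is None``.

    Every node — internal or leaf — caches the class distribution and count
    of the training rows that reached it, so a snipped internal node can
    become a leaf without retraining.
    """

    feature: int | None
    threshold: float | None
    left: "Node | None"
    right: "Node | None"
    dist: np.ndarray  # proportions over CLASSES, sums to 1
    n: int

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def copy(self) -> "Node":
        return Node(
            feature=self.feature,
            threshold=self.threshold,
            left=self.left.copy() if self.left else None,
            right=self.right.copy() if self.right else None,
            dist=self.dist.copy(),
            n=self.n,
        )

    def as_leaf(self) -> "Node":
        return Node(feature=None, threshold=None, left=None, right=None,
                    dist=self.dist.copy(), n=self.n)

    def structurally_equal(self, other: "Node") -> bool:
        if self.is_leaf != other.is_leaf or self.n != other.n:
            return False
        if not np.allclose(self.dist, other.dist):
            return False
        if self.is_leaf:
            return True
        return (
            self.feature == other.feature
            and self.threshold == other.threshold
            and self.left.structurally_equal(other.left)
            and self.right.structurally_equal(other.right)
        )


@dataclass
class DecisionTree:
    """A bifurcating CART tree tagged with its variant (T_h/T_prune/T_shift)."""

    root: Node
    variant: str = VARIANT_SOURCE

    def predict_row(self, x: np.ndarray) -> np.ndarray:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.dist

    def nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def internal_nodes(self) -> Iterator[Node]:
        return (n for n in self.nodes() if not n.is_leaf)

    def n_nodes(self) -> int:
        return sum(1 for _ in self.nodes())

    def structurally_equal(self, other: "DecisionTree") -> bool:
        return self.variant == other.variant and self.root.structurally_equal(other.root)


@dataclass
class TrainConfig:
    """Forest hyperparameters.

    200 trees is the ensemble size of the source model; ``m_features``
    defaults to ⌊√10⌋ = 3 candidate features per split.
    """

    n_trees: int = 200
    m_features: int = 3
    min_leaf: int = 2
    bootstrap: bool = True
    seed: int = 0


@dataclass
class Forest:
    """An ordered tree ensemble: RF (source) or RF_mouse (adapted)."""

    trees: list[DecisionTree]
    kind: str = KIND_SOURCE
    config: TrainConfig | None = None
    standardization: "object | None" = None  # StandardizationParams, optional
    oob_indices: list[np.ndarray] | None = None  # per-tree out-of-bag rows

    def structurally_equal(self, other: "Forest") -> bool:
        return (
            self.kind == other.kind
            and len(self.trees) == len(other.trees)
            and all(a.structurally_equal(b) for a, b in zip(self.trees, other.trees))
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=N_CLASSES).astype(float)


def _best_split_on_feature(
    v: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best (impurity decrease, threshold) on one feature, or None.

    Vectorized scan over all midpoints of consecutive sorted unique values.
    Among equal decreases the lowest threshold wins (argmax takes the first
    maximum and thresholds ascend).
    """
    n = v.shape[0]
    order = np.argsort(v, kind="mergesort")
    vs = v[order]
    ys = y[order]
    onehot = np.zeros((n, N_CLASSES))
    onehot[np.arange(n), ys] = 1.0
    left_counts = np.cumsum(onehot, axis=0)
    total = left_counts[-1]

    cut = np.nonzero(vs[:-1] < vs[1:])[0]  # split after index i
    cut = cut[(cut + 1 >= min_leaf) & (n - cut - 1 >= min_leaf)]
    if cut.size == 0:
        return None
    nl = (cut + 1).astype(float)
    nr = n - nl
    lc = left_counts[cut]
    rc = total - lc
    gini_l = 1.0 - ((lc / nl[:, None]) ** 2).sum(axis=1)
    gini_r = 1.0 - ((rc / nr[:, None]) ** 2).sum(axis=1)
    parent = 1.0 - ((total / n) ** 2).sum()
    dec = parent - (nl * gini_l + nr * gini_r) / n
    best = int(np.argmax(dec))
    thr = 0.5 * (vs[cut[best]] + vs[cut[best] + 1])
    return float(dec[best]), float(thr)


def _grow(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> Node:
    counts = _class_counts(y[idx])
    n = idx.shape[0]
    node_dist = counts / counts.sum()
    if n < 2 * config.min_leaf or np.count_nonzero(counts) < 2:
        return Node(None, None, None, None, node_dist, n)

    n_feat = X.shape[1]
    m = min(config.m_features, n_feat)
    cand = np.sort(rng.choice(n_feat, size=m, replace=False))
    best: tuple[float, int, float] | None = None  # (dec, feature, threshold)
    for f in cand:
        res = _best_split_on_feature(X[idx, f], y[idx], config.min_leaf)
        if res is None:
            continue
        dec, thr = res
        if best is None or dec > best[0] + 1e-15:
            best = (dec, int(f), thr)
    if best is None or best[0] <= 1e-15:
        return Node(None, None, None, None, node_dist, n)

    _, f, thr = best
    mask = X[idx, f] <= thr
    left = _grow(X, y, idx[mask], config, rng)
    right = _grow(X, y, idx[~mask], config, rng)
    return Node(f, thr, left, right, node_dist, n)


def train_tree(
    X: np.ndarray, y: np.ndarray, config: TrainConfig, rng: np.random.Generator
) -> DecisionTree:
    """Grow one CART tree by greedy Gini-decrease splitting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] == 1:
        logger.info("degenerate input (1 sample): single-leaf tree")
    return DecisionTree(root=_grow(X, y, np.arange(X.shape[0]), config, rng))


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lexicographic row order over (features, label): makes training
    invariant to the order rows arrive in."""
    keys = [y] + [X[:, j] for j in range(X.shape[1] - 1, -1, -1)]
    return np.lexsort(keys)


def train_forest(X: np.ndarray, y: np.ndarray, config: TrainConfig) -> Forest:
    """Bag ``config.n_trees`` trees on bootstrap resamples (same size as the
    input, with replacement), deterministically seeded from ``config.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] < 2 or np.unique(y).size < 2:
        raise ValueError("forest training needs >= 2 samples and >= 2 classes")
    order = _canonical_order(X, y)
    Xc, yc = X[order], y[order]
    n = Xc.shape[0]
    rng = np.random.default_rng(config.seed)
    trees: list[DecisionTree] = []
    oob: list[np.ndarray] = []
    for _ in range(config.n_trees):
        if config.bootstrap:
            boot = rng.integers(0, n, size=n)
        else:
            boot = np.arange(n)
        tree = train_tree(Xc[boot], yc[boot], config, rng)
        trees.append(tree)
        oob.append(order[np.setdiff1d(np.arange(n), boot)])
    return Forest(trees=trees, kind=KIND_SOURCE, config=config, oob_indices=oob)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_proba(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Class probabilities: mean over trees of the reached leaf distribution."""
    if not forest.trees:
        raise ValueError("empty forest")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains undefined entries")
    out = np.zeros((X.shape[0], N_CLASSES))
    for tree in forest.trees:
        stack: list[tuple[Node, np.ndarray]] = [(tree.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node.is_leaf:
                out[idx] += node.dist
            else:
                mask = X[idx, node.feature] <= node.threshold
                stack.append((node.left, idx[mask]))
                stack.append((node.right, idx[~mask]))
    return out / len(forest.trees)


def oob_accuracy(forest: Forest, X: np.ndarray, y: np.ndarray) -> float:
    """Out-of-bag accuracy from the bootstrap bookkeeping kept at training."""
    if forest.oob_indices is None:
        raise ValueError("forest carries no out-of-bag bookkeeping (loaded model?)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    votes = np.zeros((X.shape[0], N_CLASSES))
    for tree, oob in zip(forest.trees, forest.oob_indices):
        for i in oob:
            votes[i] += tree.predict_row(X[i])
    covered = votes.sum(axis=1) > 0
    pred = votes[covered].argmax(axis=1)
    return float((pred == y[covered]).mean())
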