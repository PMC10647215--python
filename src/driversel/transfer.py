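"""Transductive transfer of a source-domain forest to an unlabeled target.

Genes of the same class are assumed to cluster in predictor space even when
labels are unknown, so the mean pairwise Euclidean distance D among target
genes routed to a node is used as an unsupervised stand-in for the
supervised splitting index.  Two operators adapt each source tree:

* structure reduction (T_prune): traverse top-down; at an internal node
  with routed target genes, compute D_i for the node and D_a, D_b for its
  children — if the split fails to reduce the distance (D_i < D_a and
  D_i < D_b) the clade below is snipped, and the node becomes a leaf
  carrying its cached source-training class distribution;
* threshold shifting (T_shift): topology and split features unchanged; at
  each internal node the threshold moves to the candidate (original value
  plus midpoints of consecutive sorted unique target values of the split
  feature) minimizing the sum of pairwise gene distances within the two
  child nodes, ties broken toward the original value.  The objective is the
  pair *sum* S_a + S_b, not the sum of the two mean distances: the mean
  variant is degenerate — it is minimized by slicing a single extreme gene
  off an otherwise coherent cluster (D_a ≈ D_parent, D_b = 0), which
  collapses routing.  Minimizing S_a + S_b instead maximizes the summed
  distance across children, placing thresholds at cluster boundaries.

Each source tree yields one pruned and one shifted variant; the adapted
ensemble therefore has exactly twice the source tree count.

All distances are computed on z-scored features (source-domain center and
scale) — raw-scale Euclidean distance would be dominated by the unbounded
summit mutation count.  A node with fewer than two routed genes has an
undefined D, treated as 0 (a singleton is a maximally tight cluster), so a
snip is never triggered merely by an empty child.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .features import FEATURE_NAMES, feature_array
from .forest import (
    KIND_ADAPTED,
    KIND_SOURCE,
    VARIANT_PRUNE,
    VARIANT_SHIFT,
    DecisionTree,
    Forest,
    Node,
    gini,
)

logger = logging.getLogger("driversel")

DEFAULT_MIN_TARGET = 20


class InsufficientTargetError(ValueError):
    """No target genes to adapt on; reuse a previously adapted model instead."""


@dataclass
class StandardizationParams:
    """Per-feature center/scale learned on the source domain and applied
    unchanged to the target (same affine map on both sides)."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "StandardizationParams":
        X = np.asarray(X, dtype=float)
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        constant = scale == 0
        if constant.any():
            logger.warning(
                "constant feature(s) at indices %s: scale set to 1",
                np.nonzero(constant)[0].tolist(),
            )
            scale = np.where(constant, 1.0, scale)
        return cls(center=center, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale


def standardize(features: pd.DataFrame | np.ndarray, params: StandardizationParams) -> np.ndarray:
    """Feature matrix → standardized array in canonical feature order."""
    if isinstance(features, pd.DataFrame):
        arr = feature_array(features)
    else:
        arr = np.asarray(features, dtype=float)
    if arr.shape[1] != params.center.shape[0]:
        raise ValueError(
            f"feature matrix has {arr.shape[1]} columns, params expect "
            f"{params.center.shape[0]} ({len(FEATURE_NAMES)} canonical features)"
        )
    return params.transform(arr)


def pairwise_mean_distance(rows: np.ndarray) -> float | None:
    """Mean Euclidean distance over all unordered pairs; None if < 2 rows."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[0] < 2:
        return None
    return float(pdist(rows).mean())


def _d_or_zero(rows: np.ndarray) -> float:
    d = pairwise_mean_distance(rows)
    return 0.0 if d is None else d


def _distance_matrix(targets: np.ndarray) -> np.ndarray:
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[0] == 0:
        return np.zeros((0, 0))
    return squareform(pdist(targets))


def _mean_d_subset(dmat: np.ndarray, idx: np.ndarray) -> float:
    """Mean pairwise distance of a row subset; 0 when < 2 rows (undefined)."""
    k = idx.shape[0]
    if k < 2:
        return 0.0
    return float(dmat[np.ix_(idx, idx)].sum()) / (k * (k - 1))


def route_targets(tree: DecisionTree, targets: np.ndarray) -> dict[int, np.ndarray]:
    """Route target rows down the tree; returns node-id → row indices.

    Every gene lands in exactly one leaf and appears on every node of its
    root-to-leaf path.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    out: dict[int, np.ndarray] = {}
    stack = [(tree.root, np.arange(targets.shape[0]))]
    while stack:
        node, idx = stack.pop()
        out[id(node)] = idx
        if not node.is_leaf:
            mask = targets[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
    return out


# ---------------------------------------------------------------------------
# Structure reduction
# ---------------------------------------------------------------------------


def _prune(node: Node, targets: np.ndarray, dmat: np.ndarray, idx: np.ndarray) -> Node:
    if node.is_leaf or idx.shape[0] < 2:
        # too few routed genes to judge the split: leave the subtree as-is
        return node.copy()
    d_i = _mean_d_subset(dmat, idx)
    mask = targets[idx, node.feature] <= node.threshold
    ia, ib = idx[mask], idx[~mask]
    d_a = _mean_d_subset(dmat, ia)
    d_b = _mean_d_subset(dmat, ib)
    if d_i < d_a and d_i < d_b:
        return node.as_leaf()
    return Node(
        feature=node.feature,
        threshold=node.threshold,
        left=_prune(node.left, targets, dmat, ia),
        right=_prune(node.right, targets, dmat, ib),
        dist=node.dist.copy(),
        n=node.n,
    )


def prune_tree(
    tree: DecisionTree, targets: np.ndarray, _dmat: np.ndarray | None = None
) -> DecisionTree:
    """Structure reduction: snip clades whose split fails to tighten the
    target-gene clusters; snipped nodes predict their cached source-training
    distribution."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    dmat = _distance_matrix(targets) if _dmat is None else _dmat
    root = _prune(tree.root, targets, dmat, np.arange(targets.shape[0]))
    return DecisionTree(root=root, variant=VARIANT_PRUNE)


# ---------------------------------------------------------------------------
# Threshold shifting
# ---------------------------------------------------------------------------


def _candidate_totals(
    dmat: np.ndarray, idx: np.ndarray, vals: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For one node: within-child pair-sum totals S_a + S_b at every prefix.

    Returns (prefix_sizes, midpoint_thresholds, totals) where prefix k means
    the k smallest feature values go left.  Computed incrementally: moving
    one gene from the right child to the left child updates both pair sums
    in O(n) via the precomputed distance matrix.
    """
    order = np.argsort(vals, kind="mergesort")
    sidx = idx[order]
    vs = vals[order]
    sub = dmat[np.ix_(sidx, sidx)]
    k = sidx.shape[0]
    add_left = np.array([sub[j, :j].sum() for j in range(k)])
    drop_right = np.array([sub[j, j + 1 :].sum() for j in range(k)])
    s_left = np.concatenate(([0.0], np.cumsum(add_left)))        # after moving j genes
    s_right = sub.sum() / 2.0 - np.cumsum(np.concatenate(([0.0], drop_right)))
    totals = s_left + s_right
    boundaries = np.nonzero(vs[:-1] < vs[1:])[0]  # split after position j
    prefix = boundaries + 1
    thresholds = 0.5 * (vs[boundaries] + vs[boundaries + 1])
    return prefix, thresholds, totals


def _shift(node: Node, targets: np.ndarray, dmat: np.ndarray, idx: np.ndarray) -> Node:
    if node.is_leaf:
        return node.copy()
    t0 = float(node.threshold)
    new_t = t0
    if idx.shape[0] >= 2:
        vals = targets[idx, node.feature]
        prefix, thresholds, totals = _candidate_totals(dmat, idx, vals)
        vs_sorted = np.sort(vals, kind="mergesort")
        j0 = int(np.searchsorted(vs_sorted, t0, side="right"))
        best = (float(totals[j0]), 0.0, t0)  # (total, |c−t0|, c)
        for j, c in zip(prefix, thresholds):
            key = (float(totals[j]), abs(float(c) - t0), float(c))
            if key < best:
                best = key
        new_t = best[2]
    mask = targets[idx, node.feature] <= new_t
    return Node(
        feature=node.feature,
        threshold=new_t,
        left=_shift(node.left, targets, dmat, idx[mask]),
        right=_shift(node.right, targets, dmat, idx[~mask]),
        dist=node.dist.copy(),
        n=node.n,
    )


def shift_thresholds(
    tree: DecisionTree, targets: np.ndarray, _dmat: np.ndarray | None = None
) -> DecisionTree:
    """Threshold shifting: same topology and split features, thresholds
    re-optimized to minimize the summed within-child pairwise distances
    (the pair sum S_a + S_b; see the module docstring for why the sum of
    the two mean distances is not used)."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    dmat = _distance_matrix(targets) if _dmat is None else _dmat
    root = _shift(tree.root, targets, dmat, np.arange(targets.shape[0]))
    return DecisionTree(root=root, variant=VARIANT_SHIFT)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def build_rf_mouse(
    source: Forest, targets: np.ndarray, min_target: int = DEFAULT_MIN_TARGET
) -> Forest:
    """Adapt a source RF: one pruned + one shifted variant per source tree.

    Refuses an empty target matrix (small datasets should reuse an already
    adapted model); warns below ``min_target`` genes.
    """
    if source.kind != KIND_SOURCE:
        raise ValueError(f"adaptation expects a source forest (kind {KIND_SOURCE}), got {source.kind}")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.size == 0 or targets.shape[0] == 0:
        raise InsufficientTargetError(
            "insufficient target data: no target genes to adapt on"
        )
    if targets.shape[0] < min_target:
        logger.warning(
            "only %d target genes (< %d): adaptation may be unstable; "
            "consider reusing a previously adapted model",
            targets.shape[0],
            min_target,
        )
    dmat = _distance_matrix(targets)
    pruned = [prune_tree(t, targets, _dmat=dmat) for t in source.trees]
    shifted = [shift_thresholds(t, targets, _dmat=dmat) for t in source.trees]
    return Forest(
        trees=pruned + shifted,
        kind=KIND_ADAPTED,
        config=source.config,
        standardization=source.standardization,
    )


# ---------------------------------------------------------------------------
# Split diagnostics (distance vs. impurity)
# ---------------------------------------------------------------------------


def node_split_stats(tree: DecisionTree, rows: np.ndarray, y: np.ndarray | None = None) -> list[dict]:
    """Per-split distance statistics on a set of routed rows.

    For every internal node reached by >= 2 rows, reports the node distance
    D_i, child distances D_a/D_b (None when undefined), row count and — when
    labels are given — the node's Gini impurity.  Used to check that node
    splitting tightens clusters and that within-node distance tracks the
    supervised splitting index.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    routing = route_targets(tree, rows)
    stats: list[dict] = []
    for node in tree.internal_nodes():
        idx = routing[id(node)]
        if idx.shape[0] < 2:
            continue
        mask = rows[idx, node.feature] <= node.threshold
        ia, ib = idx[mask], idx[~mask]
        rec = {
            "n": int(idx.shape[0]),
            "n_a": int(ia.shape[0]),
            "n_b": int(ib.shape[0]),
            "D_i": pairwise_mean_distance(rows[idx]),
            "D_a": pairwise_mean_distance(rows[ia]),
            "D_b": pairwise_mean_distance(rows[ib]),
        }
        if y is not None:
            rec["gini"] = gini(np.bincount(np.asarray(y)[idx], minlength=3))
        stats.append(rec)
    return stats


def split_reduction_fraction(stats: list[dict]) -> float:
    """Fraction of splits that reduce the mean pairwise distance in a child.

    A split counts as reducing when at least one child's mean pairwise
    distance falls below the parent's (an undefined child distance counts
    as 0): exactly the complement of the structure-reduction snip rule
    D_i < D_a and D_i < D_b."""
    if not stats:
        raise ValueError("no splits to evaluate")
    good = 0
    for s in stats:
        d_a = 0.0 if s["D_a"] is None else s["D_a"]
        d_b = 0.0 if s["D_b"] is None else s["D_b"]
        if not (s["D_i"] < d_a and s["D_i"] < d_b):
            good += 1
    return good / len(stats)
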