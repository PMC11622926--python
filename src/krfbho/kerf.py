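"""Kernel random forest (KeRF): randomized trees read as a kernel smoother.

A random forest can be rewritten as a local averaging estimator: the
prediction at a query point x is the average over trees of the mean training
response inside the tree cell containing x. Equivalently it is a kernel
smoother whose kernel at (x, x_i) is the co-occupancy frequency of tree
leaves. This module fits such a forest with explicit leaf membership lists
so the kernel form is directly computable, ranks features by how often they
are chosen at split nodes, and optionally lifts the inputs through a random
Fourier feature (RFF) map approximating the Gaussian (RBF) kernel
exp(-gamma * ||x - y||^2).

Trees are grown on bootstrap resamples. At each node, ceil(sqrt(d)) random
candidate features are drawn, each with one uniform random threshold inside
the node's value range, and the candidate with the lowest weighted Gini
impurity is used. Growth stops at ``max_depth`` or when a per-tree leaf
budget tau_n (default ceil(sqrt(n))) is reached.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from collections import deque
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .preprocessing import FeatureTable

__all__ = [
    "KerfParams",
    "KerfTree",
    "KerfForest",
    "ImportanceRanking",
    "rff_transform",
    "fit_kerf",
    "fit_kerf_matrix",
    "kerf_predict",
    "feature_importances",
    "rank_and_filter",
    "forest_to_json",
    "forest_from_json",
]


@dataclass
class KerfParams:
    """Forest hyperparameters.

    ``leaf_target`` is the per-tree leaf budget tau_n; ``None`` means
    ceil(sqrt(n)) at fit time. ``rff_dims`` = 0 disables the Fourier map.
    ``empty_cell`` chooses how a tree whose cell holds no training row
    contributes to a prediction: ``"zero"`` contributes 0, ``"skip"``
    drops the tree and renormalizes.
    """

    n_trees: int = 100
    max_depth: int = 10
    leaf_target: Optional[int] = None
    rff_dims: int = 0
    gamma: float = 1.0
    seed: int = 0
    empty_cell: str = "zero"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if self.rff_dims < 0:
            raise ValidationError("rff_dims must be >= 0")
        if self.empty_cell not in ("zero", "skip"):
            raise ValidationError("empty_cell must be 'zero' or 'skip'")


@dataclass
class KerfTree:
    """One randomized tree stored as parallel node arrays.

    ``feature[i] == -1`` marks node i as a leaf. ``leaf_rows`` maps each leaf
    node id to the ORIGINAL training-row indices routed into its cell, so the
    kernel weights are computable after fitting on a bootstrap resample.
    """

    feature: list[int]
    threshold: list[float]
    left: list[int]
    right: list[int]
    leaf_rows: dict[int, np.ndarray]

    def leaf_for(self, x: np.ndarray) -> int:
        node = 0
        while self.feature[node] != -1:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.left[node]
            else:
                node = self.right[node]
        return node

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for every row of X (vectorized routing)."""
        n = X.shape[0]
        out = np.zeros(n, dtype=int)
        stack = [(0, np.arange(n))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] == -1:
                out[idx] = node
                continue
            go_left = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((self.left[node], idx[go_left]))
            stack.append((self.right[node], idx[~go_left]))
        return out

    @property
    def n_internal(self) -> int:
        return sum(1 for f in self.feature if f != -1)


@dataclass
class KerfForest:
    """A fitted forest: trees, the training responses, and the parameters."""

    trees: list[KerfTree]
    responses: np.ndarray
    params: KerfParams
    n_features: int
    rff_projection: Optional[tuple[np.ndarray, np.ndarray]] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"query has {X.shape[1]} features, forest expects {self.n_features}"
            )
        if self.rff_projection is not None:
            X = _apply_rff(X, *self.rff_projection)
        total = np.zeros(X.shape[0])
        count = np.zeros(X.shape[0])
        for tree in self.trees:
            leaves = tree.apply(X)
            for leaf in np.unique(leaves):
                rows = tree.leaf_rows.get(int(leaf), np.empty(0, dtype=int))
                sel = leaves == leaf
                if rows.size:
                    total[sel] += self.responses[rows].mean()
                    count[sel] += 1
                elif self.params.empty_cell == "zero":
                    count[sel] += 1  # empty cell contributes 0 to the average
        if self.params.empty_cell == "zero":
            return total / len(self.trees)
        safe = np.maximum(count, 1)
        return total / safe


@dataclass
class ImportanceRanking:
    """Split-frequency feature importances and the induced rank order."""

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        if sorted(self.order.tolist()) != list(range(len(self.scores))):
            raise ValidationError("order must be a permutation of feature indices")


# ---------------------------------------------------------------------------
# random Fourier features


def _apply_rff(X: np.ndarray, omega: np.ndarray, phase: np.ndarray) -> np.ndarray:
    return math.sqrt(2.0 / omega.shape[1]) * np.cos(X @ omega + phase)


def rff_transform(
    X: np.ndarray, rff_dims: int, gamma: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Random Fourier feature map for the RBF kernel exp(-gamma ||x-y||^2).

    Returns sqrt(2/D) * cos(omega^T x + b) with omega ~ N(0, 2*gamma) i.i.d.
    and b ~ Uniform[0, 2*pi); inner products of the transformed rows
    approximate the kernel. Deterministic for a fixed seed.
    """
    if rff_dims < 1:
        raise ValidationError("rff_dims must be >= 1")
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    omega, phase = _draw_rff(X.shape[1], rff_dims, gamma, seed)
    return _apply_rff(X, omega, phase)


def _draw_rff(
    d: int, rff_dims: int, gamma: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    omega = rng.normal(0.0, math.sqrt(2.0 * gamma), size=(d, rff_dims))
    phase = rng.uniform(0.0, 2.0 * math.pi, size=rff_dims)
    return omega, phase


# ---------------------------------------------------------------------------
# fitting


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _build_tree(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    max_depth: int,
    leaf_target: int,
) -> KerfTree:
    n, d = X.shape
    boot = rng.integers(0, n, size=n)
    m_try = max(1, math.ceil(math.sqrt(d)))

    feature = [-1]
    threshold = [math.nan]
    left = [-1]
    right = [-1]
    depth = [0]
    node_boot: dict[int, np.ndarray] = {0: boot}

    queue: deque[int] = deque([0])
    n_leaves = 1
    while queue and n_leaves < leaf_target:
        nid = queue.popleft()
        rows = node_boot[nid]
        if depth[nid] >= max_depth or rows.size < 2:
            continue
        Xn, yn = X[rows], y[rows]
        best = None  # (impurity, feature, threshold, left_mask)
        cand_feats = rng.choice(d, size=min(m_try, d), replace=False)
        for f in cand_feats:
            col = Xn[:, f]
            lo, hi = col.min(), col.max()
            thr = rng.uniform(lo, hi)
            mask = col <= thr
            n_left = int(mask.sum())
            if n_left == 0 or n_left == rows.size:
                continue
            imp = (
                n_left * _gini(yn[mask]) + (rows.size - n_left) * _gini(yn[~mask])
            ) / rows.size
            if best is None or imp < best[0]:
                best = (imp, int(f), float(thr), mask)
        if best is None:
            continue
        _, f, thr, mask = best
        lid, rid = len(feature), len(feature) + 1
        feature[nid] = f
        threshold[nid] = thr
        left[nid] = lid
        right[nid] = rid
        for child, child_rows in ((lid, rows[mask]), (rid, rows[~mask])):
            feature.append(-1)
            threshold.append(math.nan)
            left.append(-1)
            right.append(-1)
            depth.append(depth[nid] + 1)
            node_boot[child] = child_rows
            queue.append(child)
        del node_boot[nid]
        n_leaves += 1

    tree = KerfTree(feature, threshold, left, right, {})
    # record leaf membership of the ORIGINAL rows (not the bootstrap sample)
    assigned = tree.apply(X)
    tree.leaf_rows = {
        int(leaf): np.flatnonzero(assigned == leaf) for leaf in np.unique(assigned)
    }
    return tree


def fit_kerf_matrix(X: np.ndarray, y: np.ndarray, params: KerfParams) -> KerfForest:
    """Fit a forest on a raw feature matrix and binary response vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if d == 0:
        raise ValidationError("cannot fit a forest with zero features")
    if n < 2:
        raise ValidationError("need at least 2 training samples")
    if y.shape != (n,):
        raise ValidationError("response length must equal n_samples")

    rff_projection = None
    X_fit = X
    if params.rff_dims > 0:
        rff_projection = _draw_rff(d, params.rff_dims, params.gamma, params.seed)
        X_fit = _apply_rff(X, *rff_projection)

    leaf_target = params.leaf_target or max(2, math.ceil(math.sqrt(n)))
    rng = np.random.default_rng(params.seed)
    trees = [
        _build_tree(X_fit, y, np.random.default_rng(rng.integers(0, 2**31)),
                    params.max_depth, leaf_target)
        for _ in range(params.n_trees)
    ]
    return KerfForest(trees, y, params, d, rff_projection)


def fit_kerf(data: FeatureTable, params: KerfParams) -> KerfForest:
    """Fit a forest on a FeatureTable with a binary target."""
    if data.target is None:
        raise ValidationError("fit_kerf requires a table with a target")
    if np.isnan(data.values).any():
        raise ValidationError("fit_kerf requires a complete table (impute first)")
    return fit_kerf_matrix(data.values, data.target, params)


def kerf_predict(forest: KerfForest, query: np.ndarray) -> float:
    """Kernel-forest prediction at one query point.

    Average over trees of the mean training response in the cell containing
    the query; a tree with an empty cell contributes per
    ``params.empty_cell``.
    """
    query = np.asarray(query, dtype=float).ravel()
    if query.shape[0] != forest.n_features:
        raise ValidationError(
            f"query has {query.shape[0]} features, forest expects "
            f"{forest.n_features}"
        )
    return float(forest.predict(query[None, :])[0])


def feature_importances(forest: KerfForest) -> ImportanceRanking:
    """Split-frequency importances: share of internal nodes using each feature.

    Scores sum to 1 whenever any split exists; a forest with no internal node
    gets all-zero scores and the identity ranking. Ranking is descending with
    ties broken by lower feature index. For an RFF-fitted forest the scores
    are over the transformed coordinates.
    """
    d = (
        forest.params.rff_dims
        if forest.rff_projection is not None
        else forest.n_features
    )
    counts = np.zeros(d)
    for tree in forest.trees:
        for f in tree.feature:
            if f != -1:
                counts[f] += 1
    total = counts.sum()
    scores = counts / total if total > 0 else counts
    order = np.lexsort((np.arange(d), -scores))
    return ImportanceRanking(scores, order)


def rank_and_filter(data: FeatureTable, params: KerfParams, keep: int) -> list[int]:
    """Return the top-``keep`` original feature indices by split frequency.

    Importances are always computed on the original feature columns (a forest
    fitted without the RFF map), so the returned indices refer to the input
    table even when ``params.rff_dims`` > 0.
    """
    if not (1 <= keep <= data.n_features):
        raise ValidationError("keep must be in [1, n_features]")
    raw_params = KerfParams(
        n_trees=params.n_trees,
        max_depth=params.max_depth,
        leaf_target=params.leaf_target,
        rff_dims=0,
        gamma=params.gamma,
        seed=params.seed,
        empty_cell=params.empty_cell,
    )
    ranking = feature_importances(fit_kerf(data, raw_params))
    return ranking.order[:keep].tolist()


# ---------------------------------------------------------------------------
# JSON serialization (documented structure for fixture-based tests)


def forest_to_json(forest: KerfForest) -> str:
    payload = {
        "params": {
            "n_trees": forest.params.n_trees,
            "max_depth": forest.params.max_depth,
            "leaf_target": forest.params.leaf_target,
            "rff_dims": forest.params.rff_dims,
            "gamma": forest.params.gamma,
            "seed": forest.params.seed,
            "empty_cell": forest.params.empty_cell,
        },
        "n_features": forest.n_features,
        "responses": forest.responses.tolist(),
        "rff_projection": (
            None
            if forest.rff_projection is None
            else [forest.rff_projection[0].tolist(), forest.rff_projection[1].tolist()]
        ),
        "trees": [
            {
                "feature": t.feature,
                "threshold": [None if math.isnan(v) else v for v in t.threshold],
                "left": t.left,
                "right": t.right,
                "leaf_rows": {str(k): v.tolist() for k, v in t.leaf_rows.items()},
            }
            for t in forest.trees
        ],
    }
    return json.dumps(payload)


def forest_from_json(text: str) -> KerfForest:
    payload = json.loads(text)
    params = KerfParams(**payload["params"])
    trees = [
        KerfTree(
            t["feature"],
            [math.nan if v is None else v for v in t["threshold"]],
            t["left"],
            t["right"],
            {int(k): np.asarray(v, dtype=int) for k, v in t["leaf_rows"].items()},
        )
        for t in payload["trees"]
    ]
    proj = payload["rff_projection"]
    rff_projection = (
        None if proj is None else (np.asarray(proj[0]), np.asarray(proj[1]))
    )
    return KerfForest(
        trees,
        np.asarray(payload["responses"], dtype=float),
        params,
        payload["n_features"],
        rff_projection,
    )
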