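"""Seed-deterministic random-forest regressor used by the missForest-style imputer.

Trees use variance-reduction (SSE) splits evaluated vectorised across the
candidate features of a node; equal-gain splits resolve to the lowest
candidate feature index, then the lowest threshold, so results are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

_MIN_GAIN = 1e-12  # below this a split is considered no better than none


class _Node:
    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self, value: float):
        self.feature = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.value = value

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _best_split(X: np.ndarray, y: np.ndarray, features: np.ndarray, min_leaf: int):
    """Best (feature, threshold) by SSE reduction over the given features.

    Returns None when no admissible split improves on the parent node.
    """
    n = len(y)
    if n < 2 * min_leaf:
        return None
    sub = X[:, features]  # n x f
    order = np.argsort(sub, axis=0, kind="stable")  # n x f
    y_ord = y[order]  # n x f, y sorted per feature
    x_ord = np.take_along_axis(sub, order, axis=0)

    csum = np.cumsum(y_ord, axis=0)
    total = csum[-1]
    k = np.arange(1, n)[:, None]  # left sizes for split after position k-1
    left_sum = csum[:-1]
    right_sum = total[None, :] - left_sum
    # SSE_parent - SSE_children = sum_left^2/n_left + sum_right^2/n_right - total^2/n
    gain = left_sum**2 / k + right_sum**2 / (n - k) - (total**2 / n)[None, :]

    valid = (x_ord[:-1] < x_ord[1:]) & (k >= min_leaf) & ((n - k) >= min_leaf)
    gain = np.where(valid, gain, -np.inf)
    if not np.isfinite(gain).any() or gain.max() <= _MIN_GAIN:
        return None
    # lowest feature index first, then lowest split position, on ties
    best = np.unravel_index(np.argmax(gain.T), gain.T.shape)
    f_local, pos = int(best[0]), int(best[1])
    feature = int(features[f_local])
    threshold = 0.5 * (x_ord[pos, f_local] + x_ord[pos + 1, f_local])
    return feature, float(threshold)


def _grow(X, y, features_fn, min_leaf, rng) -> _Node:
    node = _Node(float(y.mean()))
    split = _best_split(X, y, features_fn(rng), min_leaf)
    if split is None:
        return node
    feature, threshold = split
    mask = X[:, feature] <= threshold
    node.feature = feature
    node.threshold = threshold
    node.left = _grow(X[mask], y[mask], features_fn, min_leaf, rng)
    node.right = _grow(X[~mask], y[~mask], features_fn, min_leaf, rng)
    return node


def _predict_node(node: _Node, X: np.ndarray, out: np.ndarray, idx: np.ndarray):
    if node.is_leaf:
        out[idx] = node.value
        return
    mask = X[idx, node.feature] <= node.threshold
    _predict_node(node.left, X, out, idx[mask])
    _predict_node(node.right, X, out, idx[~mask])


class RandomForestRegressor:
    """Bagged regression trees with random feature subsets per node."""

    def __init__(
        self,
        n_trees: int = 100,
        max_features: int | None = None,
        min_leaf: int = 5,
        seed=0,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_leaf = min_leaf
        self.seed = seed
        self._trees: list[_Node] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        mtry = self.max_features or max(1, -(-p // 3))
        mtry = min(mtry, p)

        def features_fn(rng):
            # sorted so ties in gain resolve to the lowest feature index
            return np.sort(rng.choice(p, size=mtry, replace=False))

        rng = np.random.default_rng(self.seed)
        self._trees = []
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            self._trees.append(_grow(X[boot], y[boot], features_fn, self.min_leaf, rng))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        buf = np.empty(len(X))
        idx = np.arange(len(X))
        for tree in self._trees:
            _predict_node(tree, X, buf, idx)
            out += buf
        return out / len(self._trees)
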