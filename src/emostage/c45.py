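"""A C4.5-style decision tree with per-node class distributions.

Splits are binary thresholds on numeric features chosen by information
gain ratio; thresholds sit at midpoints between sorted class-distinct
values. Every node stores a Laplace-smoothed class distribution (+1 per
class), so no stored distribution is degenerate. Pruning is the
pessimistic (error-based) scheme with the C4.5 default confidence 0.25.

The tree exposes the path-probability decision rule: a sample is walked
from the root to a leaf, the stored class distributions of every node on
the path are summed per class and the sums normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .recording import DomainError


@dataclass
class TreeNode:
    distribution: np.ndarray            # smoothed P(class), sums to 1
    counts: np.ndarray                  # raw training counts per class
    feature: int | None = None          # split feature (column), None = leaf
    threshold: float | None = None      # go left if x[feature] <= threshold
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_text(self, depth: int = 0) -> str:
        pad = "  " * depth
        dist = "[" + ", ".join(f"{p:.4f}" for p in self.distribution) + "]"
        if self.is_leaf:
            return f"{pad}leaf dist={dist}\n"
        return (f"{pad}x[{self.feature}] <= {self.threshold:.6g} dist={dist}\n"
                + self.left.to_text(depth + 1) + self.right.to_text(depth + 1))


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _pessimistic_errors(counts: np.ndarray, confidence: float) -> float:
    """Predicted error count at a leaf under the C4.5 upper confidence bound."""
    n = counts.sum()
    if n == 0:
        return 0.0
    e = n - counts.max()
    # upper confidence limit of the binomial error rate
    if e >= n:
        return float(n)
    ub = stats.beta.ppf(1.0 - confidence, e + 1, n - e)
    return float(n * ub)


class C45Tree:
    """Gain-ratio decision tree over numeric features.

    Parameters
    ----------
    min_leaf : smallest admissible child size (default 2).
    confidence : pessimistic-pruning confidence factor (C4.5 default 0.25);
        ``None`` disables pruning.
    max_depth : safety cap on recursion depth.
    """

    def __init__(self, min_leaf: int = 2, confidence: float | None = 0.25,
                 max_depth: int = 25):
        self.min_leaf = min_leaf
        self.confidence = confidence
        self.max_depth = max_depth
        self.root: TreeNode | None = None
        self.classes_: np.ndarray | None = None

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "C45Tree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[0] == 0:
            raise DomainError("X must be non-empty 2-D with one label per row")
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self.root = self._build(X, codes, depth=0)
        if self.confidence is not None:
            self._prune(self.root)
        return self

    def _node(self, codes: np.ndarray) -> TreeNode:
        counts = np.bincount(codes, minlength=self.classes_.size).astype(float)
        smoothed = counts + 1.0
        return TreeNode(distribution=smoothed / smoothed.sum(), counts=counts)

    def _build(self, X: np.ndarray, codes: np.ndarray, depth: int) -> TreeNode:
        node = self._node(codes)
        n = codes.size
        if (depth >= self.max_depth or n < 2 * self.min_leaf
                or np.unique(codes).size < 2):
            return node
        feat, thr = self._best_split(X, codes)
        if feat is None:
            return node
        go_left = X[:, feat] <= thr
        node.feature, node.threshold = feat, thr
        node.left = self._build(X[go_left], codes[go_left], depth + 1)
        node.right = self._build(X[~go_left], codes[~go_left], depth + 1)
        return node

    def _best_split(self, X: np.ndarray, codes: np.ndarray):
        n, n_feat = X.shape
        k = self.classes_.size
        parent_counts = np.bincount(codes, minlength=k).astype(float)
        h_parent = _entropy(parent_counts)
        best = (None, None, 0.0)   # feature, threshold, gain ratio
        onehot = np.eye(k)[codes]
        for f in range(n_feat):
            order = np.argsort(X[:, f], kind="stable")
            xs = X[order, f]
            cum = np.cumsum(onehot[order], axis=0)       # (n, k)
            # candidate cut after position i (left size i+1)
            valid = (xs[1:] > xs[:-1])
            sizes = np.arange(1, n)
            valid &= (sizes >= self.min_leaf) & (n - sizes >= self.min_leaf)
            if not np.any(valid):
                continue
            idx = np.nonzero(valid)[0]
            left = cum[idx]
            right = parent_counts[None, :] - left
            nl = left.sum(axis=1)
            nr = n - nl
            with np.errstate(divide="ignore", invalid="ignore"):
                pl = left / nl[:, None]
                pr = right / nr[:, None]
                hl = -np.nansum(np.where(pl > 0, pl * np.log2(pl), 0.0), axis=1)
                hr = -np.nansum(np.where(pr > 0, pr * np.log2(pr), 0.0), axis=1)
            gain = h_parent - (nl * hl + nr * hr) / n
            frac = nl / n
            split_info = -(frac * np.log2(frac) + (1 - frac) * np.log2(1 - frac))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where((gain > 1e-12) & (split_info > 0),
                                 gain / split_info, 0.0)
            j = int(np.argmax(ratio))
            if ratio[j] > best[2]:
                cut = idx[j]
                thr = 0.5 * (xs[cut] + xs[cut + 1])
                best = (f, float(thr), float(ratio[j]))
        return best[0], best[1]

    def _prune(self, node: TreeNode) -> float:
        """Bottom-up pessimistic pruning; returns predicted errors of subtree."""
        if node.is_leaf:
            return _pessimistic_errors(node.counts, self.confidence)
        subtree_err = self._prune(node.left) + self._prune(node.right)
        leaf_err = _pessimistic_errors(node.counts, self.confidence)
        if leaf_err <= subtree_err:
            node.feature = node.threshold = None
            node.left = node.right = None
            return leaf_err
        return subtree_err

    # -- prediction ---------------------------------------------------------

    def _path(self, x: np.ndarray):
        node = self.root
        while True:
            yield node
            if node.is_leaf:
                return
            node = node.left if x[node.feature] <= node.threshold else node.right

    def path_probability(self, x: np.ndarray) -> np.ndarray:
        """Root-to-leaf summed node distributions, normalized to 1."""
        if self.root is None:
            raise RuntimeError("tree is not fitted")
        sums = np.zeros(self.classes_.size)
        for node in self._path(np.asarray(x, dtype=float)):
            sums += node.distribution
        return sums / sums.sum()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.vstack([self.path_probability(row) for row in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def to_text(self) -> str:
        """Serialize the tree as indented text (feature, threshold, distribution)."""
        return self.root.to_text() if self.root is not None else "(unfitted)\n"
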