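"""From-scratch CART classifier: Gini split search, constrained growth,
and maximum-depth selection by stratified cross-validation.

The estimator follows the recursive-partitioning conventions of classic CART:

* splits minimise the weighted Gini impurity of the two children;
* ordinal predictors split at thresholds midway between consecutive observed
  values (``value < threshold`` goes left); nominal predictors with at most
  8 levels split on every binary partition of their categories;
* ``minsplit`` is the minimum node size eligible for splitting and
  ``minbucket`` the minimum size of any child; the two constraints are
  checked independently;
* depth is the only pruning parameter.  When ``max_depth`` is None it is
  selected by stratified K-fold cross-validation over ``max_depth_grid``
  (mean held-out accuracy, ties broken toward the shallowest depth).

There are no surrogate splits, no cost-complexity pruning, and no priors:
rows with missing predictor values are rejected at prediction time.

Tie-breaking is fully deterministic — largest gain, then lowest predictor
index (column order), then lowest threshold / first category subset — because
downstream rule counting requires reproducible trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "gini_impurity",
    "split_gain",
    "best_split",
    "SplitCandidate",
    "TreeNode",
    "CartClassifier",
    "select_max_depth",
    "variable_importance",
    "audit_tree",
]

_EPS = 1e-12
_MAX_NOMINAL_LEVELS = 8


def gini_impurity(class_counts: Sequence[float] | np.ndarray) -> float:
    """Gini impurity 1 - sum(p_c^2) of a node's class-count vector."""
    c = np.asarray(class_counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValueError("class_counts must be a nonempty 1-d vector")
    if np.any(c < 0):
        raise ValueError("class counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one class count must be positive")
    p = c / total
    return float(1.0 - p @ p)


def split_gain(parent_counts, left_counts, right_counts) -> float:
    """Weighted Gini decrease G(parent) - nL/n G(left) - nR/n G(right)."""
    p = np.asarray(parent_counts, dtype=float)
    l = np.asarray(left_counts, dtype=float)
    r = np.asarray(right_counts, dtype=float)
    if p.shape != l.shape or p.shape != r.shape or not np.array_equal(l + r, p):
        raise ValueError("left + right counts must equal parent counts elementwise")
    n_l, n_r = l.sum(), r.sum()
    if n_l <= 0 or n_r <= 0:
        raise ValueError("a split may not produce an empty child")
    n = p.sum()
    return float(gini_impurity(p) - n_l / n * gini_impurity(l) - n_r / n * gini_impurity(r))


@dataclass(frozen=True)
class SplitCandidate:
    """One binary split: ordinal threshold or nominal category subset."""

    feature: str
    kind: str  # "ordinal" | "nominal"
    gain: float
    threshold: float | None = None          # ordinal: left iff value < threshold
    left_categories: tuple[str, ...] | None = None  # nominal: left iff value in set

    def describe(self) -> str:
        if self.kind == "ordinal":
            return f"{self.feature} < {self.threshold:g}"
        cats = ",".join(self.left_categories or ())
        return f"{self.feature} in {{{cats}}}"


@dataclass
class TreeNode:
    """A fitted tree node holding per-class counts and an optional split."""

    counts: np.ndarray
    depth: int
    split: SplitCandidate | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def majority_code(self) -> int:
        """Majority class index; ties resolve to the highest (most severe)
        class under the estimator's sorted class ordering."""
        c = self.counts
        return int(c.size - 1 - np.argmax(c[::-1]))

    @property
    def proba(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class _Feature:
    name: str
    kind: str                      # "ordinal" | "nominal"
    values: np.ndarray             # float values (ordinal) or int codes (nominal)
    categories: tuple[str, ...] | None = None


def _encode_features(X: pd.DataFrame, nominal_features: Sequence[str] | None) -> list[_Feature]:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    feats: list[_Feature] = []
    declared = set(nominal_features or ())
    for name in X.columns:
        col = X[name]
        is_nominal = (name in declared or col.dtype == object or col.dtype == bool
                      or isinstance(col.dtype, pd.CategoricalDtype))
        if is_nominal:
            cats = tuple(sorted(map(str, pd.unique(col.dropna().astype(str)))))
            if len(cats) > _MAX_NOMINAL_LEVELS:
                raise ValueError(
                    f"nominal predictor {name!r} has {len(cats)} levels; at most "
                    f"{_MAX_NOMINAL_LEVELS} are supported")
            lookup = {c: i for i, c in enumerate(cats)}
            raw = col.astype(str).to_numpy()
            if col.isna().any():
                raise ValueError(f"predictor {name!r} contains missing values")
            codes = np.array([lookup[v] for v in raw], dtype=np.int64)
            feats.append(_Feature(str(name), "nominal", codes, cats))
        else:
            vals = col.to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"predictor {name!r} contains missing values")
            feats.append(_Feature(str(name), "ordinal", vals))
    return feats


def _best_ordinal(x, y, idx, parent_counts, minbucket):
    """Best legal threshold for one ordinal feature, or None."""
    xv = x[idx]
    xu, inv = np.unique(xv, return_inverse=True)
    if xu.size < 2:
        return None
    k = parent_counts.size
    counts = np.zeros((xu.size, k))
    np.add.at(counts, (inv, y[idx]), 1.0)
    cum_l = np.cumsum(counts, axis=0)[:-1]
    n = parent_counts.sum()
    n_l = cum_l.sum(axis=1)
    n_r = n - n_l
    legal = (n_l >= minbucket) & (n_r >= minbucket)
    if not legal.any():
        return None
    cum_r = parent_counts[None, :] - cum_l
    safe_l = np.where(n_l > 0, n_l, 1.0)
    safe_r = np.where(n_r > 0, n_r, 1.0)
    g_l = 1.0 - (cum_l ** 2).sum(axis=1) / safe_l ** 2
    g_r = 1.0 - (cum_r ** 2).sum(axis=1) / safe_r ** 2
    g_p = 1.0 - (parent_counts ** 2).sum() / n ** 2
    gain = g_p - (n_l / n) * g_l - (n_r / n) * g_r
    gain[~legal] = -np.inf
    i = int(np.argmax(gain))  # first maximum -> lowest threshold on ties
    if gain[i] <= _EPS:
        return None
    return float(gain[i]), float((xu[i] + xu[i + 1]) / 2)


def _best_nominal(codes, y, idx, parent_counts, minbucket, n_levels):
    """Best legal binary category partition for one nominal feature."""
    k = parent_counts.size
    level_counts = np.zeros((n_levels, k))
    np.add.at(level_counts, (codes[idx], y[idx]), 1.0)
    n = parent_counts.sum()
    g_p = 1.0 - (parent_counts ** 2).sum() / n ** 2
    best: tuple[float, int] | None = None
    # enumerate the 2^(L-1)-1 partitions: subsets containing level 0 (odd masks)
    for mask in range(1, (1 << n_levels) - 1, 2):
        sel = [(mask >> lvl) & 1 == 1 for lvl in range(n_levels)]
        left = level_counts[np.asarray(sel)].sum(axis=0)
        n_l = left.sum()
        n_r = n - n_l
        if n_l < minbucket or n_r < minbucket:
            continue
        right = parent_counts - left
        gain = g_p - (n_l / n) * (1.0 - (left ** 2).sum() / n_l ** 2) \
                   - (n_r / n) * (1.0 - (right ** 2).sum() / n_r ** 2)
        if best is None or gain > best[0]:
            best = (float(gain), mask)
    if best is None or best[0] <= _EPS:
        return None
    return best


def _node_best_split(feats, y, idx, parent_counts, minbucket) -> SplitCandidate | None:
    best: SplitCandidate | None = None
    for f in feats:
        if f.kind == "ordinal":
            res = _best_ordinal(f.values, y, idx, parent_counts, minbucket)
            if res is None:
                continue
            gain, threshold = res
            cand = SplitCandidate(f.name, "ordinal", gain, threshold=threshold)
        else:
            res = _best_nominal(f.values, y, idx, parent_counts, minbucket,
                                len(f.categories or ()))
            if res is None:
                continue
            gain, mask = res
            cats = tuple(c for lvl, c in enumerate(f.categories or ())
                         if (mask >> lvl) & 1)
            cand = SplitCandidate(f.name, "nominal", gain, left_categories=cats)
        if best is None or cand.gain > best.gain:  # strict: earlier feature wins ties
            best = cand
    return best


def _left_mask(feature: _Feature, cand: SplitCandidate, idx: np.ndarray) -> np.ndarray:
    if cand.kind == "ordinal":
        return feature.values[idx] < cand.threshold
    left_codes = {i for i, c in enumerate(feature.categories or ())
                  if c in (cand.left_categories or ())}
    return np.isin(feature.values[idx], list(left_codes))


class CartClassifier(ClassifierMixin, BaseEstimator):
    """CART classifier with Gini splits and depth-only pruning.

    Parameters
    ----------
    minsplit : int, default=20
        Minimum number of observations a node must hold to be eligible for
        splitting.
    minbucket : int, default=7
        Minimum number of observations in any terminal node.
    max_depth : int or None, default=None
        Fixed maximum depth, or None to select it by cross-validation.
    max_depth_grid : tuple of int, default=(1, ..., 8)
        Candidate depths examined when ``max_depth`` is None.
    cv : int, default=10
        Number of stratified folds used for depth selection.
    scale_to_n : bool, default=False
        When True, ``minsplit``/``minbucket`` are interpreted as values quoted
        for a reference training size ``reference_n`` and rescaled
        proportionally to the actual training size.
    reference_n : int, default=14410
        Reference training size for ``scale_to_n``.
    nominal_features : sequence of str or None
        Columns to treat as nominal regardless of dtype.  Object, boolean and
        categorical columns are always nominal.
    random_state : int or None
        Seeds the fold assignment of the depth-selection CV.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; probability columns follow this order.  Leaf-label
        ties resolve toward the *last* class (the most severe level under the
        canonical severity token ordering).
    tree_ : TreeNode
        Root of the fitted tree.
    max_depth_ : int
        Depth actually used (CV-selected when ``max_depth`` is None).
    feature_importances_ : ndarray
        Per-feature sum of n * gain over the internal nodes splitting on that
        feature (raw, unnormalised; zeros for unused features).
    """

    def __init__(self, *, minsplit: int = 20, minbucket: int = 7,
                 max_depth: int | None = None,
                 max_depth_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
                 cv: int = 10, scale_to_n: bool = False, reference_n: int = 14410,
                 nominal_features: Sequence[str] | None = None,
                 random_state: int | None = None):
        self.minsplit = minsplit
        self.minbucket = minbucket
        self.max_depth = max_depth
        self.max_depth_grid = max_depth_grid
        self.cv = cv
        self.scale_to_n = scale_to_n
        self.reference_n = reference_n
        self.nominal_features = nominal_features
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y) -> "CartClassifier":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        else:
            X = pd.DataFrame(np.asarray(X),
                             columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("cannot fit a tree on an empty training table")
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")

        self._feats = _encode_features(X, self.nominal_features)
        self.n_features_in_ = len(self._feats)
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        self.n_samples_ = len(y)

        if self.minbucket < 1 or self.minsplit < 2:
            raise ValueError("require minbucket >= 1 and minsplit >= 2")
        if self.scale_to_n:
            ratio = self.n_samples_ / self.reference_n
            self.minsplit_effective_ = max(2, round(self.minsplit * ratio))
            self.minbucket_effective_ = max(1, round(self.minbucket * ratio))
        else:
            self.minsplit_effective_ = self.minsplit
            self.minbucket_effective_ = self.minbucket

        grid = tuple(sorted(self.max_depth_grid))
        if self.max_depth is not None:
            if self.max_depth < 1:
                raise ValueError("max_depth must be >= 1")
            self.max_depth_ = int(self.max_depth)
            self.cv_accuracy_ = None
        else:
            self.max_depth_, self.cv_accuracy_ = self._select_depth(y_codes, grid)

        importances = np.zeros(self.n_features_in_)
        self.tree_ = self._grow(y_codes, np.arange(self.n_samples_), 0,
                                self.max_depth_, importances)
        self.feature_importances_ = importances
        return self

    def _grow(self, y_codes, idx, depth, max_depth, importances=None) -> TreeNode:
        counts = np.bincount(y_codes[idx], minlength=len(self.classes_)).astype(float)
        node = TreeNode(counts=counts, depth=depth)
        if (depth >= max_depth or idx.size < self.minsplit_effective_
                or np.count_nonzero(counts) <= 1):
            return node
        cand = _node_best_split(self._feats, y_codes, idx, counts,
                                self.minbucket_effective_)
        if cand is None:
            return node
        feature = next(f for f in self._feats if f.name == cand.feature)
        mask = _left_mask(feature, cand, idx)
        node.split = cand
        if importances is not None:
            f_idx = int(np.flatnonzero(self.feature_names_in_ == cand.feature)[0])
            importances[f_idx] += idx.size * cand.gain
        node.left = self._grow(y_codes, idx[mask], depth + 1, max_depth, importances)
        node.right = self._grow(y_codes, idx[~mask], depth + 1, max_depth, importances)
        return node

    # -------------------------------------------------- depth selection (CV)

    def _select_depth(self, y_codes, grid) -> tuple[int, np.ndarray]:
        n = y_codes.size
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        if n < self.cv:
            raise ValueError(f"need at least cv={self.cv} rows for depth selection, got {n}")
        rng = np.random.default_rng(self.random_state)
        fold = np.empty(n, dtype=np.int64)
        for c in range(len(self.classes_)):
            ci = np.flatnonzero(y_codes == c)
            perm = rng.permutation(ci)
            fold[perm] = np.arange(perm.size) % self.cv

        # pooled held-out accuracy: total correct over all folds, well defined
        # even when a fold is empty or misses a class
        depth_cap = max(grid)
        correct = np.zeros(len(grid))
        for f in range(self.cv):
            test = fold == f
            train_idx = np.flatnonzero(~test)
            test_idx = np.flatnonzero(test)
            if test_idx.size == 0 or train_idx.size == 0:
                continue
            tree = self._grow(y_codes, train_idx, 0, depth_cap)
            for d_i, d in enumerate(grid):
                pred = self._route_codes(tree, test_idx, depth_cap=d)
                correct[d_i] += np.sum(pred == y_codes[test_idx])
        acc = correct / n
        return int(grid[int(np.argmax(acc))]), acc

    # -------------------------------------------------------------- predict

    def _route_codes(self, tree: TreeNode, idx: np.ndarray, depth_cap: int | None = None,
                     proba_out: np.ndarray | None = None) -> np.ndarray:
        out = np.empty(idx.size, dtype=np.int64)
        stack = [(tree, np.arange(idx.size))]
        while stack:
            node, pos = stack.pop()
            if node.is_leaf or (depth_cap is not None and node.depth >= depth_cap):
                out[pos] = node.majority_code
                if proba_out is not None:
                    proba_out[pos] = node.proba
                continue
            feature = next(f for f in self._feats if f.name == node.split.feature)
            mask = _left_mask(feature, node.split, idx[pos])
            stack.append((node.left, pos[mask]))
            stack.append((node.right, pos[~mask]))
        return out

    def _encode_predict(self, X) -> list[_Feature]:
        """Encode a prediction table against the training feature layout."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=list(self.feature_names_in_))
        missing = [n for n in self.feature_names_in_ if n not in X.columns]
        if missing:
            raise ValueError(f"prediction table is missing predictors: {missing}")
        feats: list[_Feature] = []
        for f in self._feats:
            col = X[f.name]
            if col.isna().any():
                raise ValueError(f"predictor {f.name!r} contains missing values "
                                 "(no surrogate splits)")
            if f.kind == "ordinal":
                feats.append(_Feature(f.name, "ordinal", col.to_numpy(dtype=float)))
            else:
                lookup = {c: i for i, c in enumerate(f.categories or ())}
                raw = col.astype(str).to_numpy()
                unknown = sorted({v for v in raw if v not in lookup})
                if unknown:
                    raise ValueError(f"predictor {f.name!r} has unseen categories: {unknown}")
                feats.append(_Feature(f.name, "nominal",
                                      np.array([lookup[v] for v in raw], dtype=np.int64),
                                      f.categories))
        return feats

    def predict_proba(self, X) -> np.ndarray:
        feats = self._encode_predict(X)
        saved, self._feats = self._feats, feats
        try:
            n = feats[0].values.size
            proba = np.empty((n, len(self.classes_)))
            self._route_codes(self.tree_, np.arange(n), proba_out=proba)
        finally:
            self._feats = saved
        return proba

    def predict(self, X) -> np.ndarray:
        feats = self._encode_predict(X)
        saved, self._feats = self._feats, feats
        try:
            n = feats[0].values.size
            codes = self._route_codes(self.tree_, np.arange(n))
        finally:
            self._feats = saved
        return self.classes_[codes]

    def variable_importance(self) -> dict[str, float]:
        """Raw per-predictor importance (sum of n * gain over its splits)."""
        return {str(name): float(v)
                for name, v in zip(self.feature_names_in_, self.feature_importances_)}


def best_split(X, y, *, minbucket: int = 1,
               nominal_features: Sequence[str] | None = None) -> SplitCandidate | None:
    """Exhaustive best Gini split of a single node (module-level convenience).

    Returns None when no candidate satisfies ``minbucket`` on both sides or
    every legal candidate has zero gain.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X),
                         columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    feats = _encode_features(X, nominal_features)
    _, y_codes = np.unique(np.asarray(y), return_inverse=True)
    counts = np.bincount(y_codes).astype(float)
    return _node_best_split(feats, y_codes, np.arange(len(y_codes)), counts, minbucket)


def select_max_depth(X, y, **params) -> int:
    """Cross-validated depth choice without keeping the fitted tree."""
    clf = CartClassifier(max_depth=None, **params).fit(X, y)
    return clf.max_depth_


def variable_importance(clf: CartClassifier) -> dict[str, float]:
    return clf.variable_importance()


def audit_tree(clf: CartClassifier) -> None:
    """Structural audit: count conservation, size constraints, depth bound.

    Raises AssertionError on any violation; used liberally by the test suite
    on every fitted tree.
    """
    root = clf.tree_
    assert root.n == clf.n_samples_, "root counts must equal the training size"
    leaf_total = 0
    stack = [root]
    while stack:
        node = stack.pop()
        assert node.depth <= clf.max_depth_, "node exceeds the selected max depth"
        if node.is_leaf:
            if node is not root:  # an unsplit root may legitimately be small
                assert node.n >= clf.minbucket_effective_, "leaf smaller than minbucket"
            leaf_total += node.n
        else:
            assert node.n >= clf.minsplit_effective_, "split node smaller than minsplit"
            assert node.left is not None and node.right is not None
            assert np.array_equal(node.left.counts + node.right.counts, node.counts), \
                "child counts must sum to parent counts"
            stack.extend((node.left, node.right))
    assert leaf_total == clf.n_samples_, "leaf counts must sum to the training size"
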