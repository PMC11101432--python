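"""Greedy binary recursive partitioning (CART) with Gini splits.

Implemented in-house so the threshold-reporting convention is fully
controlled: each internal split is reported as the smallest observed
feature value on the >= side of the split, which maps midpoint splits such
as 5.5 onto the observed-scale integers (6, 20, 60) that the shipped
classification rule uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CARTNode:
    """One node of a fitted tree.

    ``threshold`` is the split midpoint; cases with ``feature`` value
    >= threshold go right.  ``right_min`` is the smallest observed feature
    value on the right side among the training cases at this node (the
    reported cut-off).
    """

    counts: dict[str, int]
    prediction: str
    depth: int
    feature: Optional[str] = None
    threshold: Optional[float] = None
    right_min: Optional[float] = None
    left: Optional["CARTNode"] = None
    right: Optional["CARTNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class CARTTree:
    """Fitted classification tree."""

    root: CARTNode
    feature_names: list[str]
    classes: list[str]
    max_depth: int
    cp: float
    root_error: int = 0

    def predict_one(self, x: dict[str, float]) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.right if x[node.feature] >= node.threshold else node.left
        return node.prediction

    def predict(self, features: pd.DataFrame) -> pd.Series:
        cols = {name: features[name].to_numpy(dtype=float) for name in self.feature_names}
        out = [
            self.predict_one({name: cols[name][i] for name in self.feature_names})
            for i in range(len(features))
        ]
        return pd.Series(out, index=features.index, name="prediction")

    def resubstitution_error(self, features: pd.DataFrame, labels: pd.Series) -> int:
        return int((self.predict(features).to_numpy() != labels.to_numpy()).sum())

    def depth(self) -> int:
        def _d(node: CARTNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def to_dict(self) -> dict:
        def _node(node: CARTNode) -> dict:
            d = {
                "counts": node.counts,
                "prediction": node.prediction,
                "depth": node.depth,
            }
            if not node.is_leaf:
                d.update(
                    feature=node.feature,
                    threshold=node.threshold,
                    right_min=node.right_min,
                    left=_node(node.left),
                    right=_node(node.right),
                )
            return d

        return {
            "feature_names": self.feature_names,
            "classes": self.classes,
            "max_depth": self.max_depth,
            "cp": self.cp,
            "root_error": self.root_error,
            "root": _node(self.root),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CARTTree":
        def _node(nd: dict) -> CARTNode:
            node = CARTNode(
                counts=nd["counts"], prediction=nd["prediction"], depth=nd["depth"]
            )
            if "feature" in nd:
                node.feature = nd["feature"]
                node.threshold = nd["threshold"]
                node.right_min = nd["right_min"]
                node.left = _node(nd["left"])
                node.right = _node(nd["right"])
            return node

        return cls(
            root=_node(d["root"]),
            feature_names=list(d["feature_names"]),
            classes=list(d["classes"]),
            max_depth=d["max_depth"],
            cp=d["cp"],
            root_error=d["root_error"],
        )

    @classmethod
    def from_json(cls, path) -> "CARTTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _misclassified(counts: np.ndarray) -> int:
    return int(counts.sum() - counts.max())


def _class_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes)


def _best_split(
    X: np.ndarray, y: np.ndarray, n_classes: int, feature_names: list[str]
) -> Optional[tuple[int, float, float, np.ndarray]]:
    """Best Gini split over all features and midpoint candidates.

    Returns (feature index, threshold, gini decrease, right mask) or None if
    no feature admits a split.  Ties in Gini decrease are broken by feature
    name and then by lower threshold, for determinism.
    """
    n = len(y)
    parent_gini = _gini(_class_counts(y, n_classes))
    best = None
    best_key = None
    order_by_name = sorted(range(X.shape[1]), key=lambda j: feature_names[j])
    for j in order_by_name:
        xs = X[:, j]
        values = np.unique(xs)
        if len(values) < 2:
            continue
        thresholds = (values[:-1] + values[1:]) / 2.0
        for t in thresholds:
            right = xs >= t
            nr = int(right.sum())
            nl = n - nr
            cr = _class_counts(y[right], n_classes)
            cl = _class_counts(y[~right], n_classes)
            decrease = parent_gini - (nl * _gini(cl) + nr * _gini(cr)) / n
            key = (-decrease, feature_names[j], t)
            if best_key is None or key < best_key:
                best_key = key
                best = (j, float(t), float(decrease), right)
    return best


def cart_fit(
    features: pd.DataFrame,
    labels: pd.Series,
    max_depth: int = 5,
    cp: float = 0.0001,
) -> CARTTree:
    """Fit a classification tree by greedy Gini partitioning.

    Splits are midpoints between consecutive observed feature values.  A
    node is split only if the best split reduces resubstitution
    misclassification error by at least ``cp`` times the root error
    (and the depth limit is not exceeded and the node is impure).
    Class predictions at ties are the lexicographically first majority
    class, for determinism.
    """
    if features.isna().any().any() or labels.isna().any():
        raise ValueError("features and labels must not contain missing values")
    feature_names = list(features.columns)
    classes = sorted(pd.unique(labels))
    class_index = {c: i for i, c in enumerate(classes)}
    X = features.to_numpy(dtype=float)
    y = np.array([class_index[v] for v in labels], dtype=int)
    n_classes = len(classes)

    root_counts = _class_counts(y, n_classes)
    root_error = _misclassified(root_counts)
    # literal acceptance rule: keep a split iff error improvement >= cp * root
    # error; with cp=0 zero-improvement (but impurity-reducing) splits stay,
    # which is what exhaustive-depth oracle comparisons need
    min_improve = cp * root_error

    def _majority(counts: np.ndarray) -> str:
        return classes[int(np.argmax(counts))]

    def _grow(X_node: np.ndarray, y_node: np.ndarray, depth: int) -> CARTNode:
        counts = _class_counts(y_node, n_classes)
        node = CARTNode(
            counts={classes[i]: int(counts[i]) for i in range(n_classes)},
            prediction=_majority(counts),
            depth=depth,
        )
        if depth >= max_depth or _gini(counts) == 0.0:
            return node
        split = _best_split(X_node, y_node, n_classes, feature_names)
        if split is None or split[2] <= 0.0:
            return node
        j, t, _, right = split
        err_before = _misclassified(counts)
        err_after = _misclassified(
            _class_counts(y_node[right], n_classes)
        ) + _misclassified(_class_counts(y_node[~right], n_classes))
        if err_before - err_after < min_improve:
            return node
        node.feature = feature_names[j]
        node.threshold = t
        node.right_min = float(X_node[right, j].min())
        node.left = _grow(X_node[~right], y_node[~right], depth + 1)
        node.right = _grow(X_node[right], y_node[right], depth + 1)
        return node

    root = _grow(X, y, 0)
    return CARTTree(
        root=root,
        feature_names=feature_names,
        classes=classes,
        max_depth=max_depth,
        cp=cp,
        root_error=root_error,
    )


def report_thresholds(tree: CARTTree) -> dict[str, list[float]]:
    """Per-feature sorted, deduplicated cut-offs of a fitted tree.

    Each internal split reports the smallest observed value on its >= side,
    so a midpoint split between 5 and 6 is reported as 6.
    """
    if tree.root is None:
        raise ValueError("tree is not fitted")
    out: dict[str, set[float]] = {}

    def _walk(node: CARTNode) -> None:
        if node.is_leaf:
            return
        out.setdefault(node.feature, set()).add(node.right_min)
        _walk(node.left)
        _walk(node.right)

    _walk(tree.root)
    return {f: sorted(v) for f, v in sorted(out.items())}
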