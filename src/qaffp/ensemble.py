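"""Balanced random forest for imbalanced active/inactive classification.

Each tree is grown on a bootstrap that draws an equal number of samples (with
replacement) from each class — the size of the smaller class — so the
majority class is undersampled per tree.  Trees use the GINI criterion and
sqrt(n_features) candidate features per split, the usual classification-forest
defaults; 100 trees unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier


@dataclass
class BalancedRandomForestClassifier:
    """Random forest with per-tree class-balanced bootstraps (binary)."""

    n_estimators: int = 100
    random_state: int = 0
    max_features: str = "sqrt"

    classes_: np.ndarray = field(init=False, default=None)
    estimators_: list = field(init=False, default_factory=list)
    #: per-tree (class0_count, class1_count) of the bootstrap actually drawn
    tree_sample_counts_: list = field(init=False, default_factory=list)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForestClassifier":
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected exactly 2 classes, got {list(self.classes_)}")
        idx_by_class = [np.flatnonzero(y == c) for c in self.classes_]
        n_draw = min(len(idx) for idx in idx_by_class)
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        self.tree_sample_counts_ = []
        for t in range(self.n_estimators):
            boot = np.concatenate(
                [rng.choice(idx, size=n_draw, replace=True) for idx in idx_by_class]
            )
            tree = DecisionTreeClassifier(
                criterion="gini",
                max_features=self.max_features,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[boot], y[boot])
            counts = tuple(int((y[boot] == c).sum()) for c in self.classes_)
            self.tree_sample_counts_.append(counts)
            self.estimators_.append(tree)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.estimators_:
            raise ValueError("classifier is not fitted")
        X = np.asarray(X)
        proba = np.zeros((len(X), len(self.classes_)))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            # align the tree's class order with self.classes_
            for j, c in enumerate(tree.classes_):
                proba[:, np.searchsorted(self.classes_, c)] += p[:, j]
        return proba / len(self.estimators_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
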