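"""Bagged CART trees: the pathway classifier.

The classifier of record is a random forest with *mtry equal to the
number of features* — every split considers all features, so the
ensemble is exactly bagging over CART trees.  The predictivity designs
fit thousands of such forests on ~80-subject matrices; scikit-learn's
``RandomForestClassifier`` spends milliseconds of per-tree Python
overhead there, so this module drives scikit-learn's Cython tree
builder directly.  If those internals are unavailable the class falls
back to looping ``DecisionTreeClassifier``, which is identical but
slower.  Predictions soft-vote (average leaf class distributions),
matching scikit-learn's forest voting.
"""

from __future__ import annotations

import numpy as np

try:  # fast path: sklearn's Cython tree internals
    from sklearn.tree._criterion import Gini as _Gini
    from sklearn.tree._splitter import BestSplitter as _BestSplitter
    from sklearn.tree._tree import DepthFirstTreeBuilder as _Builder
    from sklearn.tree._tree import Tree as _Tree

    _HAVE_FAST_TREES = True
except Exception:  # pragma: no cover - exercised only on API drift
    _HAVE_FAST_TREES = False

from sklearn.tree import DecisionTreeClassifier

_MAX_DEPTH = 2**31 - 1


class BaggedTreeClassifier:
    """Bootstrap-aggregated CART trees with all-feature splits.

    Parameters
    ----------
    n_trees
        Ensemble size (the library default elsewhere is 1000).
    random_state
        Seed controlling bootstraps and split tie-breaking; the fit is
        deterministic given the seed.
    """

    def __init__(self, n_trees: int = 1000, random_state: int | None = None):
        self.n_trees = int(n_trees)
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreeClassifier":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        self._trees = []
        if _HAVE_FAST_TREES:
            y2 = np.ascontiguousarray(y_enc, dtype=np.float64).reshape(-1, 1)
            n_classes = np.array([k], dtype=np.intp)
            for _ in range(self.n_trees):
                w = np.bincount(rng.integers(0, n, n), minlength=n).astype(np.float64)
                crit = _Gini(1, n_classes)
                splitter = _BestSplitter(
                    crit, p, 1, 0.0,
                    np.random.RandomState(int(rng.integers(2**31))), None)
                tree = _Tree(p, n_classes, 1)
                _Builder(splitter, 2, 1, 0.0, _MAX_DEPTH, 0.0).build(tree, X, y2, w, None)
                self._trees.append(tree)
        else:
            for _ in range(self.n_trees):
                w = np.bincount(rng.integers(0, n, n), minlength=n).astype(np.float64)
                t = DecisionTreeClassifier(random_state=int(rng.integers(2**31)))
                t.fit(X, y_enc, sample_weight=w, check_input=False)
                self._trees.append(t)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        k = len(self.classes_)
        acc = np.zeros((X.shape[0], k))
        for tree in self._trees:
            if _HAVE_FAST_TREES:
                leaf = tree.predict(X).reshape(X.shape[0], k)
                total = leaf.sum(axis=1, keepdims=True)
                total[total == 0] = 1.0
                acc += leaf / total
            else:
                acc += tree.predict_proba(X)
        return acc / len(self._trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
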