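"""Classification-tree model family for Bayesian averaging.

A tree is parameterised by its split nodes -- position in the binary tree,
splitting feature, and threshold rule drawn from the observed values of that
feature -- and by per-leaf class counts over the training data.  Leaves carry
a Dirichlet(1,...,1) prior over class probabilities, giving each leaf the
closed-form Dirichlet-multinomial marginal likelihood

    p(counts) = Gamma(C) * prod_c Gamma(n_c + 1) / Gamma(n + C)

and the posterior-mean class probabilities (n_c + 1) / (n + C).  The routing
convention is ``x[feature] <= rule`` goes left; a record exactly at the rule
goes left.
"""

from __future__ import annotations

import json
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln


class Dataset:
    """Training data plus the per-feature candidate rule sets.

    Parameters
    ----------
    X : ndarray (n, m)
        Feature matrix; no missing values allowed.
    y : array-like (n,)
        Class labels; any hashable values, at least two distinct, every
        class present.  Stored internally as indices 0..C-1 against the
        sorted ``classes`` array.
    """

    def __init__(self, X: np.ndarray, y: Sequence) -> None:
        X = np.ascontiguousarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-d, got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains missing or non-finite values")
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X rows")
        self.classes, self.y = np.unique(y, return_inverse=True)
        if self.classes.size < 2:
            raise ValueError("need at least 2 classes")
        self.X = X
        self.n, self.m = X.shape
        self.n_classes = int(self.classes.size)
        #: sorted unique observed values per feature (the candidate rules)
        self.levels: list[np.ndarray] = [np.unique(X[:, j]) for j in range(self.m)]
        #: features with at least two observed values, i.e. splittable at all
        self.splittable = np.array(
            [j for j in range(self.m) if self.levels[j].size >= 2], dtype=int
        )

    def class_counts(self, idx: np.ndarray) -> np.ndarray:
        return np.bincount(self.y[idx], minlength=self.n_classes)


def leaf_log_marginal(counts: np.ndarray) -> float:
    """Log Dirichlet-multinomial marginal of one leaf under a unit prior."""
    counts = np.asarray(counts)
    c = counts.size
    return float(
        gammaln(c) + gammaln(counts + 1.0).sum() - gammaln(counts.sum() + c)
    )


class Node:
    """One tree node.  Leaves have ``feature is None``.

    ``idx`` (training row indices reaching the node) is carried during
    sampling and dropped by :meth:`DecisionTree.strip` for storage;
    ``counts`` (class counts of those rows) is always kept.
    """

    __slots__ = ("feature", "rule", "left", "right", "idx", "counts", "_loglik")

    def __init__(self, feature=None, rule=None, left=None, right=None,
                 idx=None, counts=None):
        self.feature = feature
        self.rule = rule
        self.left = left
        self.right = right
        self.idx = idx
        self.counts = counts
        self._loglik = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def loglik(self) -> float:
        if self._loglik is None:
            self._loglik = leaf_log_marginal(self.counts)
        return self._loglik


class DecisionTree:
    """Binary classification tree with count-bearing leaves."""

    def __init__(self, root: Node, n_classes: int):
        self.root = root
        self.n_classes = int(n_classes)

    # -- structure ---------------------------------------------------------

    def _iter(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                if node.left is None or node.right is None:
                    raise ValueError("malformed tree: split node with a dangling child")
                stack.append(node.right)
                stack.append(node.left)

    def leaves(self) -> list[Node]:
        return [n for n in self._iter() if n.is_leaf]

    def split_nodes(self) -> list[Node]:
        return [n for n in self._iter() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def split_features(self) -> np.ndarray:
        """Sorted unique feature indices used by the tree's split nodes."""
        return np.unique([n.feature for n in self.split_nodes()]).astype(int)

    # -- probability -------------------------------------------------------

    def log_marginal_likelihood(self, p_min: int | None = None) -> float:
        """Sum of per-leaf log Dirichlet-multinomial marginals.

        With ``p_min`` given, a leaf holding fewer than ``p_min`` records is
        an invalid state and raises.
        """
        total = 0.0
        for leaf in self.leaves():
            if p_min is not None and int(leaf.counts.sum()) < p_min:
                raise ValueError(
                    f"leaf with {int(leaf.counts.sum())} records violates "
                    f"p_min={p_min}"
                )
            total += leaf.loglik
        return total

    def route(self, x: np.ndarray) -> Node:
        """Leaf reached by one feature vector (<= goes left)."""
        x = np.asarray(x, dtype=np.float64)
        node = self.root
        while not node.is_leaf:
            if node.left is None or node.right is None:
                raise ValueError("malformed tree: split node with a dangling child")
            node = node.left if x[node.feature] <= node.rule else node.right
        return node

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean leaf probabilities (n_c+1)/(n+C), row-wise."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty((X.shape[0], self.n_classes))
        self._fill_proba(self.root, np.arange(X.shape[0]), X, out)
        return out

    def _fill_proba(self, node: Node, rows: np.ndarray, X: np.ndarray,
                    out: np.ndarray) -> None:
        if node.is_leaf:
            c = node.counts
            out[rows] = (c + 1.0) / (c.sum() + self.n_classes)
            return
        if node.left is None or node.right is None:
            raise ValueError("malformed tree: split node with a dangling child")
        go_left = X[rows, node.feature] <= node.rule
        self._fill_proba(node.left, rows[go_left], X, out)
        self._fill_proba(node.right, rows[~go_left], X, out)

    # -- copies / serialization -------------------------------------------

    def strip(self) -> "DecisionTree":
        """Copy without training-row indices (counts kept); for storage."""

        def cp(node: Node) -> Node:
            new = Node(node.feature, node.rule, counts=node.counts)
            new._loglik = node._loglik
            if not node.is_leaf:
                new.left = cp(node.left)
                new.right = cp(node.right)
            return new

        return DecisionTree(cp(self.root), self.n_classes)

    def to_dict(self) -> dict:
        def enc(node: Node) -> dict:
            if node.is_leaf:
                return {"counts": [int(c) for c in node.counts]}
            return {
                "feature": int(node.feature),
                "rule": float(node.rule),
                "left": enc(node.left),
                "right": enc(node.right),
                "counts": [int(c) for c in node.counts],
            }

        return {"n_classes": self.n_classes, "root": enc(self.root)}

    @classmethod
    def from_dict(cls, doc: dict) -> "DecisionTree":
        def dec(d: dict) -> Node:
            counts = np.asarray(d["counts"], dtype=np.int64)
            if "feature" not in d:
                return Node(counts=counts)
            return Node(int(d["feature"]), float(d["rule"]),
                        dec(d["left"]), dec(d["right"]), counts=counts)

        return cls(dec(doc["root"]), int(doc["n_classes"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# -- module-level operation wrappers --------------------------------------

def route(tree: DecisionTree, x: np.ndarray) -> Node:
    return tree.route(x)


def log_marginal_likelihood(tree: DecisionTree, dataset: Dataset | None = None,
                            p_min: int | None = None) -> float:
    return tree.log_marginal_likelihood(p_min=p_min)


def predict_proba(tree: DecisionTree, x: np.ndarray) -> np.ndarray:
    return tree.predict_proba(x)


def draw_split(dataset: Dataset, rng: np.random.Generator):
    """Draw (feature, rule) from the split prior.

    The feature is uniform over the attributes admitting a split (at least
    two observed values); the rule is uniform over the observed values of
    that feature.  Returns None when no feature admits a split.
    """
    if dataset.splittable.size == 0:
        return None
    j = int(dataset.splittable[rng.integers(dataset.splittable.size)])
    lv = dataset.levels[j]
    return j, float(lv[rng.integers(lv.size)])


def make_leaf(dataset: Dataset, idx: np.ndarray) -> Node:
    return Node(idx=idx, counts=dataset.class_counts(idx))


def single_leaf_tree(dataset: Dataset) -> DecisionTree:
    return DecisionTree(make_leaf(dataset, np.arange(dataset.n)), dataset.n_classes)


# -- greedy induction (single-tree baseline) -------------------------------

def _gini_score(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return -float(n * (1.0 - (p * p).sum()))


def _best_split(dataset: Dataset, idx: np.ndarray, p_min: int,
                criterion: str) -> tuple[int, float, float] | None:
    """Best (feature, rule, gain) over all candidate splits of one node.

    Gain is the increase in the summed leaf score (log marginal likelihood,
    or negative weighted Gini impurity) over leaving the node unsplit.
    Ties break to the lowest feature index, then the lowest rule.
    """
    y = dataset.y[idx]
    parent_counts = np.bincount(y, minlength=dataset.n_classes)
    if criterion == "bayes":
        parent = leaf_log_marginal(parent_counts)
    elif criterion == "gini":
        parent = _gini_score(parent_counts)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = None
    n = idx.size
    for j in range(dataset.m):
        x = dataset.X[idx, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # cumulative class counts after each sorted record
        onehot = np.zeros((n, dataset.n_classes))
        onehot[np.arange(n), ys] = 1.0
        cum = np.cumsum(onehot, axis=0)
        vals = np.unique(xs)[:-1]  # splitting at the max leaves right empty
        if vals.size == 0:
            continue
        left_n = np.searchsorted(xs, vals, side="right")
        ok = (left_n >= p_min) & (n - left_n >= p_min)
        if not ok.any():
            continue
        vals, left_n = vals[ok], left_n[ok]
        lc = cum[left_n - 1]
        rc = parent_counts - lc
        if criterion == "bayes":
            score = (
                gammaln(lc + 1.0).sum(axis=1) - gammaln(left_n + dataset.n_classes)
                + gammaln(rc + 1.0).sum(axis=1)
                - gammaln(n - left_n + dataset.n_classes)
                + 2 * gammaln(dataset.n_classes)
            )
        else:
            ln, rn = left_n, n - left_n
            score = -(
                ln * (1.0 - ((lc / ln[:, None]) ** 2).sum(axis=1))
                + rn * (1.0 - ((rc / rn[:, None]) ** 2).sum(axis=1))
            )
        i = int(np.argmax(score))
        gain = float(score[i] - parent)
        if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
            best = (j, float(vals[i]), gain)
    return best


def grow_greedy_tree(dataset: Dataset, p_min: int = 6,
                     criterion: str = "bayes") -> DecisionTree:
    """Deterministic top-down greedy tree respecting the leaf-size floor."""

    def grow(idx: np.ndarray) -> Node:
        found = None
        if idx.size >= 2 * p_min:
            found = _best_split(dataset, idx, p_min, criterion)
        if found is None:
            return make_leaf(dataset, idx)
        j, rule, _ = found
        go_left = dataset.X[idx, j] <= rule
        node = Node(j, rule, grow(idx[go_left]), grow(idx[~go_left]),
                    idx=idx, counts=dataset.class_counts(idx))
        return node

    return DecisionTree(grow(np.arange(dataset.n)), dataset.n_classes)
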