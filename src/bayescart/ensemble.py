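"""Posterior tree ensembles: model averaging, feature usage, refinement.

The predictive distribution is approximated by the unweighted mean of the
per-tree leaf probabilities over the N sampled trees (Bayesian model
averaging).  Posterior feature importance is the split-node usage
frequency: the fraction of all split nodes in the ensemble that test a
given feature.  Features whose frequency falls strictly below a threshold
T are *weak*; the refinement strategy discards every tree containing a
split on any weak feature, which sharpens the ensemble without re-running
the sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .tree import DecisionTree


@dataclass(frozen=True)
class WeakSet:
    """Features with posterior usage frequency strictly below ``threshold``.

    ``indices`` are 0-based feature indices.  Weak sets are nested in the
    threshold: T <= T' implies WeakSet(T) is a subset of WeakSet(T').
    """

    threshold: float
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)


class Ensemble:
    """Ordered collection of posterior tree samples.

    Parameters
    ----------
    trees : list of DecisionTree
    n_features : int
        Dimensionality m of the feature space the trees split on.
    classes : array-like
        Original class labels, sorted; per-tree counts index into these.
    provenance : dict, optional
        Sampler config / seed record; carried through serialization.
    """

    def __init__(self, trees: Sequence[DecisionTree], n_features: int,
                 classes: Sequence, provenance: dict | None = None) -> None:
        trees = list(trees)
        if not trees:
            raise ValueError("an ensemble needs at least one tree")
        self.trees = trees
        self.n_features = int(n_features)
        self.classes = np.asarray(classes)
        self.provenance = provenance or {}

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[DecisionTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> DecisionTree:
        return self.trees[i]

    @property
    def n_classes(self) -> int:
        return int(self.classes.size)

    # -- prediction --------------------------------------------------------

    def proba_stack(self, X: np.ndarray) -> np.ndarray:
        """Per-tree class probabilities, shape (N, n_records, C)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.stack([t.predict_proba(X) for t in self.trees])

    def bma_predict(self, X: np.ndarray) -> np.ndarray:
        """Model-averaged class distribution per record; rows sum to 1."""
        return self.proba_stack(X).mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class labels (ties break to the lowest class index)."""
        return self.classes[np.argmax(self.bma_predict(X), axis=1)]

    # -- posterior feature usage -------------------------------------------

    def feature_usage(self) -> np.ndarray:
        """Split-node usage frequency per feature; sums to 1.

        Raises when the ensemble contains no split node at all (the
        denominator is undefined).
        """
        counts = np.zeros(self.n_features)
        for tree in self.trees:
            for node in tree.split_nodes():
                counts[node.feature] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError("ensemble has no split nodes; usage undefined")
        return counts / total

    def weak_set(self, threshold: float) -> WeakSet:
        freq = self.feature_usage()
        idx = tuple(int(j) for j in np.nonzero(freq < threshold)[0])
        return WeakSet(float(threshold), idx)

    def refine(self, weak: "WeakSet | Sequence[int]") -> "Ensemble":
        """Ensemble keeping only the trees that use no weak feature.

        Order is preserved and the original is untouched.  Raises when no
        tree survives (threshold too large), reporting the survivor count.
        """
        weak_idx = set(weak.indices if isinstance(weak, WeakSet) else
                       (int(j) for j in weak))
        kept = [
            t for t in self.trees
            if not weak_idx.intersection(t.split_features().tolist())
        ]
        if not kept:
            raise ValueError(
                "refinement left 0 surviving trees; the weak-feature "
                "threshold is too large for this ensemble"
            )
        return Ensemble(kept, self.n_features, self.classes,
                        dict(self.provenance, refined_against=sorted(weak_idx)))

    # -- uncertainty and accuracy ------------------------------------------

    def entropy(self, X_test: np.ndarray) -> float:
        """Total base-2 Shannon entropy of the averaged predictions.

        Summed over the test records; bounded by n_test * log2(C).
        """
        P = self.bma_predict(X_test)
        if P.shape[0] == 0:
            raise ValueError("empty test set")
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(P > 0, -P * np.log2(P), 0.0)
        return float(h.sum())

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "classes": [c.item() if hasattr(c, "item") else c
                        for c in self.classes],
            "provenance": _jsonable(self.provenance),
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Ensemble":
        return cls(
            [DecisionTree.from_dict(t) for t in doc["trees"]],
            n_features=doc["n_features"],
            classes=doc["classes"],
            provenance=doc.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "Ensemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# -- module-level operation wrappers ---------------------------------------

def bma_predict(ensemble: Ensemble, x: np.ndarray) -> np.ndarray:
    return ensemble.bma_predict(x)


def feature_usage(ensemble: Ensemble) -> np.ndarray:
    return ensemble.feature_usage()


def refine(ensemble: Ensemble, weak: WeakSet | Sequence[int]) -> Ensemble:
    return ensemble.refine(weak)


def ensemble_entropy(ensemble: Ensemble, X_test: np.ndarray) -> float:
    return ensemble.entropy(X_test)


def match_accuracy(predictions: Sequence, labels: Sequence,
                   tolerance_weeks: int = 0) -> float:
    """Percentage of predictions within ``tolerance_weeks`` of the truth.

    Classes are ordinal week indices; tolerance 0 is the exact match.
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(labels, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {true.shape} labels"
        )
    if tolerance_weeks < 0:
        raise ValueError("tolerance must be non-negative")
    return float(100.0 * np.mean(np.abs(pred - true) <= tolerance_weeks))
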