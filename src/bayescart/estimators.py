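"""Scikit-learn-style estimators wrapping the sampler and the greedy tree.

``BayesianTreeClassifier`` runs one reversible-jump chain at ``fit`` time
and predicts by model averaging over the collected trees; the fitted
posterior feature-usage frequencies and a ``refined`` view (trees using
weak features discarded) are exposed on the fitted object.
``GreedyTreeClassifier`` is the deterministic single-tree baseline grown
with the same marginal-likelihood split criterion and leaf-size floor.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .sampler import ChainConfig, run_chain
from .tree import Dataset, grow_greedy_tree


class BayesianTreeClassifier(ClassifierMixin, BaseEstimator):
    """Bayesian classification by MCMC averaging over decision trees.

    Parameters mirror :class:`~bayescart.sampler.ChainConfig`; see there for
    the full-scale defaults.  ``random_state`` seeds the single chain.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray
        Sorted class labels.
    ensemble_ : Ensemble
        Collected post-burn-in trees.
    feature_usage_ : ndarray of shape (n_features,)
        Posterior split-node usage frequency per feature.
    diagnostics_ : ChainDiagnostics
        Acceptance rates and traces.
    """

    def __init__(self, burn_in: int = 200_000, post_burn_in: int = 10_000,
                 thin: int = 7, p_min: int = 6,
                 move_probs: tuple = (0.15, 0.15, 0.10, 0.60),
                 proposal_scale: float = 1.0, s_max: int | None = None,
                 random_state: int | None = None):
        self.burn_in = burn_in
        self.post_burn_in = post_burn_in
        self.thin = thin
        self.p_min = p_min
        self.move_probs = move_probs
        self.proposal_scale = proposal_scale
        self.s_max = s_max
        self.random_state = random_state

    def _config(self) -> ChainConfig:
        return ChainConfig(
            burn_in=self.burn_in, post_burn_in=self.post_burn_in,
            thin=self.thin, p_min=self.p_min,
            move_probs=tuple(self.move_probs),
            proposal_scale=self.proposal_scale, s_max=self.s_max,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        ds = Dataset(X, y)
        self.ensemble_, self.diagnostics_ = run_chain(ds, self._config())
        self.classes_ = ds.classes
        self.n_features_in_ = ds.m
        try:
            self.feature_usage_ = self.ensemble_.feature_usage()
        except ValueError:  # all-leaf ensemble (un-splittable data)
            self.feature_usage_ = np.zeros(ds.m)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "ensemble_")
        X = check_array(X)
        return self.ensemble_.bma_predict(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def refined(self, threshold: float) -> "BayesianTreeClassifier":
        """Fitted copy whose ensemble drops trees using weak features.

        Weak features are those with usage frequency strictly below
        ``threshold`` in this estimator's ensemble; ``threshold=0`` returns
        an identical ensemble.  Raises if no tree would survive.
        """
        check_is_fitted(self, "ensemble_")
        new = copy.deepcopy(self)
        new.ensemble_ = self.ensemble_.refine(self.ensemble_.weak_set(threshold))
        return new


class GreedyTreeClassifier(ClassifierMixin, BaseEstimator):
    """Deterministic single decision tree (baseline).

    Splits are chosen top-down to maximise the gain of the same
    Dirichlet-multinomial marginal likelihood used by the sampler
    (``criterion="bayes"``) or the weighted Gini impurity decrease
    (``criterion="gini"``), subject to every leaf holding at least
    ``p_min`` training records.
    """

    def __init__(self, p_min: int = 6, criterion: str = "bayes"):
        self.p_min = p_min
        self.criterion = criterion

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        ds = Dataset(X, y)
        self.tree_ = grow_greedy_tree(ds, p_min=self.p_min,
                                      criterion=self.criterion)
        self.classes_ = ds.classes
        self.n_features_in_ = ds.m
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "tree_")
        X = check_array(X)
        return self.tree_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
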