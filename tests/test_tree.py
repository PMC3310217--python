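import math

import numpy as np
import pytest

import bayescart as bc
from bayescart.tree import (Dataset, DecisionTree, Node, grow_greedy_tree,
                            leaf_log_marginal, make_leaf, single_leaf_tree)

from _oracles import leaf_marginal_quad_2class, leaf_marginal_quad_3class


def two_class_dataset(x, y):
    return Dataset(np.asarray(x, float).reshape(-1, 1), np.asarray(y))


def stump(ds, feature, rule):
    idx = np.arange(ds.n)
    go = ds.X[:, feature] <= rule
    root = Node(feature, rule, make_leaf(ds, idx[go]), make_leaf(ds, idx[~go]),
                idx=idx, counts=ds.class_counts(idx))
    return DecisionTree(root, ds.n_classes)


class TestRoute:
    def test_single_leaf_routes_everything_to_root(self):
        ds = two_class_dataset([0.1, 0.9], [0, 1])
        tree = single_leaf_tree(ds)
        for v in (-5.0, 0.0, 7.0):
            assert tree.route([v]) is tree.root

    def test_one_split_routing_and_boundary(self):
        ds = two_class_dataset([0.4, 0.5, 0.6], [0, 0, 1])
        tree = stump(ds, 0, 0.5)
        assert tree.route([0.4]) is tree.root.left
        assert tree.route([0.6]) is tree.root.right
        # boundary: <= goes left
        assert tree.route([0.5]) is tree.root.left

    def test_malformed_tree_raises(self):
        node = Node(0, 0.5, left=Node(counts=np.array([1, 0])), right=None)
        tree = DecisionTree(node, 2)
        with pytest.raises(ValueError, match="dangling"):
            tree.route([0.0])


class TestLogMarginalLikelihood:
    def test_empty_leaf_is_log_one(self):
        assert leaf_log_marginal(np.array([0, 0])) == pytest.approx(0.0)

    def test_counts_1_1_is_beta_2_2(self):
        # uniform prior: integral of p(1-p) dp = 1/6
        assert leaf_log_marginal(np.array([1, 1])) == pytest.approx(
            math.log(1 / 6), abs=1e-12)

    def test_counts_3_0_is_quarter(self):
        # integral of p^3 dp = 1/4
        assert leaf_log_marginal(np.array([3, 0])) == pytest.approx(
            math.log(1 / 4), abs=1e-12)

    def test_matches_quad_oracle_all_two_class_counts_to_n8(self):
        for n in range(0, 9):
            for a in range(n + 1):
                expect = math.log(leaf_marginal_quad_2class(a, n - a))
                assert leaf_log_marginal(np.array([a, n - a])) == pytest.approx(
                    expect, abs=1e-10)

    def test_matches_quad_oracle_three_class_cases(self):
        for counts in [(0, 0, 0), (1, 1, 1), (3, 2, 0), (5, 1, 2)]:
            expect = math.log(leaf_marginal_quad_3class(*counts))
            assert leaf_log_marginal(np.array(counts)) == pytest.approx(
                expect, abs=1e-8)

    def test_split_tree_sums_leaf_marginals(self):
        ds = two_class_dataset([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        tree = stump(ds, 0, 0.5)
        expect = 2 * math.log(leaf_marginal_quad_2class(2, 0))
        assert tree.log_marginal_likelihood() == pytest.approx(expect, abs=1e-10)

    def test_splitting_pure_leaf_never_helps(self):
        """Partitioning single-class records cannot raise the marginal."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(2, 12)
            split = rng.integers(1, n)
            whole = leaf_log_marginal(np.array([n, 0]))
            parts = (leaf_log_marginal(np.array([split, 0]))
                     + leaf_log_marginal(np.array([n - split, 0])))
            assert parts <= whole + 1e-12

    def test_p_min_violation_is_invalid_state(self):
        ds = two_class_dataset([0.1, 0.9], [0, 1])
        tree = stump(ds, 0, 0.5)  # leaves of size 1
        with pytest.raises(ValueError, match="p_min"):
            tree.log_marginal_likelihood(p_min=6)


class TestPredictProba:
    def test_empty_leaf_is_uniform_prior_mean(self):
        tree = DecisionTree(Node(counts=np.zeros(6, dtype=int)), 6)
        np.testing.assert_allclose(tree.predict_proba([[0.0]]),
                                   np.full((1, 6), 1 / 6))

    def test_counts_3_1_posterior_mean(self):
        tree = DecisionTree(Node(counts=np.array([3, 1])), 2)
        np.testing.assert_allclose(tree.predict_proba([[0.0]]),
                                   [[2 / 3, 1 / 3]])

    def test_rows_sum_to_one(self):
        ds = two_class_dataset([0.1, 0.2, 0.8, 0.9], [0, 1, 0, 1])
        tree = stump(ds, 0, 0.5)
        P = tree.predict_proba(np.linspace(0, 1, 7).reshape(-1, 1))
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert (P > 0).all()

    def test_invariant_to_training_record_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = (X[:, 0] > 0).astype(int)
        perm = rng.permutation(40)
        t1 = grow_greedy_tree(Dataset(X, y), p_min=5)
        t2 = grow_greedy_tree(Dataset(X[perm], y[perm]), p_min=5)
        grid = rng.normal(size=(25, 2))
        np.testing.assert_allclose(t1.predict_proba(grid),
                                   t2.predict_proba(grid))


class TestDrawSplit:
    def test_degenerate_single_value_feature(self):
        ds = Dataset(np.full((4, 1), 0.2), [0, 1, 0, 1])
        assert bc.draw_split(ds, np.random.default_rng(0)) is None

    def test_feature_frequencies_uniform(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        ds = Dataset(X, rng.integers(0, 2, 30))
        draws = [bc.draw_split(ds, rng)[0] for _ in range(10_000)]
        freq = np.mean(np.asarray(draws) == 0)
        sigma = math.sqrt(0.25 / 10_000)
        assert abs(freq - 0.5) <= 3 * sigma

    def test_rule_always_among_observed_values(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 3))
        ds = Dataset(X, rng.integers(0, 2, 15))
        for _ in range(200):
            j, rule = bc.draw_split(ds, rng)
            assert rule in ds.levels[j]


class TestSerialization:
    def test_round_trip_preserves_predictions(self):
        ds = two_class_dataset([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        tree = stump(ds, 0, 0.5)
        clone = DecisionTree.from_dict(tree.to_dict())
        grid = np.linspace(-1, 2, 9).reshape(-1, 1)
        np.testing.assert_allclose(clone.predict_proba(grid),
                                   tree.predict_proba(grid))
        assert clone.log_marginal_likelihood() == pytest.approx(
            tree.log_marginal_likelihood())


class TestGreedyTree:
    def test_perfect_one_feature_split_found(self):
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(2, 3, 10)])
        y = np.repeat([0, 1], 10)
        ds = two_class_dataset(x, y)
        tree = grow_greedy_tree(ds, p_min=6)
        assert tree.n_leaves == 2
        assert tree.root.rule == pytest.approx(1.0)  # class boundary

    def test_exhaustive_rule_search_agrees(self):
        """The chosen split maximises the leaf-marginal gain over every
        observed rule, checked by brute force."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = (x > 0.3).astype(int)
        ds = two_class_dataset(x, y)
        tree = grow_greedy_tree(ds, p_min=6)
        best = -np.inf
        best_rule = None
        for rule in ds.levels[0][:-1]:
            left = y[x <= rule]
            right = y[x > rule]
            if len(left) < 6 or len(right) < 6:
                continue
            score = (leaf_log_marginal(np.bincount(left, minlength=2))
                     + leaf_log_marginal(np.bincount(right, minlength=2)))
            if score > best:
                best, best_rule = score, rule
        assert tree.root.rule == pytest.approx(best_rule)

    def test_pure_leaves_are_not_split_further(self):
        """Once a leaf is single-class there is no marginal gain, so the
        greedy tree stops: perfectly separated data yields exactly 2 leaves
        even though deeper splits would still satisfy p_min."""
        x = np.concatenate([np.linspace(0, 1, 30), np.linspace(2, 3, 30)])
        y = np.repeat([0, 1], 30)
        tree = grow_greedy_tree(two_class_dataset(x, y), p_min=6)
        assert tree.n_leaves == 2

    def test_every_leaf_respects_p_min(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        tree = grow_greedy_tree(Dataset(X, y), p_min=6)
        assert min(int(l.counts.sum()) for l in tree.leaves()) >= 6

    def test_small_n_returns_single_leaf(self):
        ds = two_class_dataset([0.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])
        tree = grow_greedy_tree(ds, p_min=6)
        assert tree.n_leaves == 1
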