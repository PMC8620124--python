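"""CART growing, pruning, prediction and rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import best_bipartition_gini, best_bipartition_sse
from ethnosurvey.drivers import (
    TreeParams,
    fit_classification_tree,
    fit_regression_tree,
    predict_tree,
    prune_tree,
    tree_to_text,
)


def _leaf_shares(tree):
    return [lf.n_share for lf in tree.leaves()]


class TestClassificationTree:
    def test_perfect_binary_feature_gives_pure_depth_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.choice(["a", "b"], size=100)})
        y = np.where(X["f"] == "a", "yes", "no")
        tree = fit_classification_tree(X, y)
        assert tree.n_leaves() == 2
        assert all(lf.probability == 1.0 for lf in tree.leaves())

    def test_constant_labels_give_single_leaf(self):
        X = pd.DataFrame({"f": ["a", "b"] * 20})
        tree = fit_classification_tree(X, ["yes"] * 40)
        assert tree.is_leaf
        assert tree.prediction == "yes"
        assert tree.probability == 1.0

    def test_split_isolates_outlying_category(self):
        rng = np.random.default_rng(1)
        rates = {"a": 0.9, "b": 0.1, "c": 0.8}
        levels = rng.choice(list(rates), size=600)
        y = np.where(rng.random(600) < [rates[l] for l in levels], "yes", "no")
        X = pd.DataFrame({"f": levels})
        tree = fit_classification_tree(X, y)
        split = tree.split
        left = (split.left_levels if "b" in split.left_levels
                else split.all_levels - split.left_levels)
        assert left == {"b"}

    @pytest.mark.parametrize("seed", range(4))
    def test_chosen_split_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))  # up to 8 categories
        levels = [f"lv{i}" for i in range(k)]
        draw = rng.choice(levels, size=400)
        rates = dict(zip(levels, rng.random(k)))
        y = np.where(rng.random(400) < [rates[l] for l in draw], 1, 0)
        X = pd.DataFrame({"f": draw})
        tree = fit_classification_tree(
            X, np.where(y == 1, "yes", "no"),
            TreeParams(min_split=2, min_bucket=1, complexity=0.0, max_depth=1))
        y_by_level = {lv: y[draw == lv] for lv in levels}
        oracle_gain, oracle_left = best_bipartition_gini(levels, y_by_level)
        if tree.is_leaf:
            assert oracle_gain <= 1e-9
            return
        got = tree.split.left_levels
        assert got in (oracle_left, frozenset(levels) - oracle_left)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            fit_classification_tree(pd.DataFrame(index=range(30)), ["y"] * 30)

    def test_more_than_two_classes_rejected(self):
        X = pd.DataFrame({"f": ["a"] * 30})
        with pytest.raises(ValueError, match="binary"):
            fit_classification_tree(X, ["x", "y", "z"] * 10)


class TestRegressionTree:
    def test_noise_free_two_level_leaf_means_exact(self):
        X = pd.DataFrame({"schooling": ["university"] * 40 + ["none"] * 60})
        y = np.where(X["schooling"] == "university", 1.8, 0.2)
        tree = fit_regression_tree(X, y)
        assert tree.n_leaves() == 2
        assert sorted(float(lf.prediction) for lf in tree.leaves()) == \
            pytest.approx([0.2, 1.8])

    def test_constant_response_single_leaf(self):
        X = pd.DataFrame({"f": ["a", "b"] * 20})
        tree = fit_regression_tree(X, [0.43] * 40)
        assert tree.is_leaf
        assert float(tree.prediction) == pytest.approx(0.43)

    def test_first_split_prefers_larger_ss_reduction(self):
        # additive two-factor response; f1 carries 4x the effect of f2
        rng = np.random.default_rng(3)
        n = 400
        f1 = rng.choice(["a", "b"], size=n)
        f2 = rng.choice(["u", "v"], size=n)
        y = 2.0 * (f1 == "b") + 0.5 * (f2 == "v") + rng.normal(0, 0.1, n)
        X = pd.DataFrame({"f1": f1, "f2": f2})
        tree = fit_regression_tree(X, y)
        assert tree.split.feature == "f1"
        # gain of the chosen split equals the exhaustive scan's optimum
        y_by = {lv: y[f1 == lv] for lv in ("a", "b")}
        gain, _ = best_bipartition_sse(["a", "b"], y_by)
        alt = {lv: y[f2 == lv] for lv in ("u", "v")}
        gain2, _ = best_bipartition_sse(["u", "v"], alt)
        assert gain > gain2

    @pytest.mark.parametrize("seed", range(4))
    def test_split_matches_exhaustive_sse_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        k = int(rng.integers(3, 9))
        levels = [f"lv{i}" for i in range(k)]
        draw = rng.choice(levels, size=300)
        means = dict(zip(levels, rng.normal(0, 2, k)))
        y = np.array([means[l] for l in draw]) + rng.normal(0, 0.5, 300)
        tree = fit_regression_tree(
            pd.DataFrame({"f": draw}), y,
            TreeParams(min_split=2, min_bucket=1, complexity=0.0, max_depth=1))
        oracle_gain, oracle_left = best_bipartition_sse(
            levels, {lv: y[draw == lv] for lv in levels})
        got = tree.split.left_levels
        assert got in (oracle_left, frozenset(levels) - oracle_left)


class TestPruning:
    @pytest.fixture
    def structured(self):
        rng = np.random.default_rng(5)
        n = 500
        sch = rng.choice(["university", "none", "primary"], size=n)
        y = np.select([sch == "university", sch == "none"], [1.8, 0.2], 0.4) \
            + rng.normal(0, 0.05, n)
        return pd.DataFrame({"schooling": sch}), y

    def test_zero_complexity_leaves_tree_unchanged(self, structured):
        X, y = structured
        tree = fit_regression_tree(X, y)
        pruned = prune_tree(tree, X, y, TreeParams(complexity=0.0))
        assert pruned.n_leaves() == tree.n_leaves()

    def test_infinite_complexity_collapses_to_root(self, structured):
        X, y = structured
        tree = fit_regression_tree(X, y)
        pruned = prune_tree(tree, X, y, TreeParams(complexity=math.inf))
        assert pruned.is_leaf

    def test_true_structure_survives_default_pruning(self, structured):
        X, y = structured
        tree = fit_regression_tree(X, y)
        pruned = prune_tree(tree, X, y, TreeParams(seed=1))
        assert pruned.n_leaves() == 3

    def test_noise_only_outcome_prunes_to_root(self):
        pruned_to_root = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"g": rng.choice(list("abcd"), size=500)})
            y = rng.normal(size=500)
            tree = fit_regression_tree(X, y)
            pruned = prune_tree(tree, X, y, TreeParams(seed=seed))
            pruned_to_root += pruned.is_leaf
        assert pruned_to_root >= 9

    def test_training_risk_non_increasing_in_tree_size(self, structured):
        from ethnosurvey.drivers import _alpha_sequence
        X, y = structured
        tree = fit_regression_tree(X, y, TreeParams(complexity=0.001))
        seq = _alpha_sequence(tree)
        risks = [t.subtree_risk() for _, t in seq]
        sizes = [t.n_leaves() for _, t in seq]
        assert sizes == sorted(sizes, reverse=True)
        assert risks == sorted(risks)  # smaller trees fit no better


class TestPredictAndRender:
    def test_training_predictions_reproduce_leaf_means(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"f": rng.choice(["a", "b", "c"], size=200)})
        y = np.select([X["f"] == "a", X["f"] == "b"], [1.0, 2.0], 5.0) \
            + rng.normal(0, 0.1, 200)
        tree = fit_regression_tree(X, y)
        preds = predict_tree(tree, X)
        leaf_means = {round(float(lf.prediction), 10) for lf in tree.leaves()}
        assert {round(float(p), 10) for p in preds} <= leaf_means

    def test_every_row_reaches_exactly_one_leaf(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"f": rng.choice(["a", "b"], size=100),
                          "x": rng.normal(size=100)})
        y = np.where(X["f"] == "a", "yes", "no")
        tree = fit_classification_tree(X, y)
        assert sum(_leaf_shares(tree)) == pytest.approx(1.0)
        assert len(predict_tree(tree, X)) == 100

    def test_unseen_level_routed_to_majority_with_warning(self):
        X = pd.DataFrame({"f": ["a"] * 70 + ["b"] * 30})
        y = ["yes"] * 70 + ["no"] * 30
        tree = fit_classification_tree(
            X, y, TreeParams(min_split=2, min_bucket=1, complexity=0.0))
        with pytest.warns(UserWarning, match="unseen"):
            pred = predict_tree(tree, pd.DataFrame({"f": ["zz"]}))
        assert pred[0] == "yes"  # majority side held the 70 'a' rows

    def test_text_rendering_of_depth_one_tree(self):
        X = pd.DataFrame({"f": ["a"] * 50 + ["b"] * 50})
        y = ["yes"] * 50 + ["no"] * 50
        tree = fit_classification_tree(X, y)
        text = tree_to_text(tree)
        lines = text.splitlines()
        assert len(lines) == 3
        assert "100.0% of obs" in lines[0]
        assert sum(ch.n_share for ch in tree.children) == pytest.approx(
            tree.n_share)

    def test_min_bucket_constraint_validated(self):
        with pytest.raises(ValueError, match="min_bucket"):
            TreeParams(min_split=10, min_bucket=20).validate()
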