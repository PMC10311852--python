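"""Importance ranking, surrogate distillation, pruning, rule tracing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blgpa import (
    fit_surrogate,
    post_prune,
    rank_feature_importance,
    trace_decision,
    train_model,
)
from blgpa.explainability import (
    DegenerateTargetError,
    SurrogateTree,
    TreeNode,
    tree_to_dict,
)

UNRESTRICTED = {"max_depth": [None], "min_samples_leaf": [1]}


@pytest.fixture(scope="module")
def toy():
    """One decisive feature among noise; forest learns a single-split rule."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(300, 12))
    y = (X[:, 4] > 0.2).astype(int)
    forest = train_model(X, y, n_trees=50, seed=0)
    names = [f"f{i}" for i in range(12)]
    return forest, X, y, names


class TestImportance:
    def test_decisive_feature_ranks_first(self, toy):
        forest, X, y, names = toy
        ranked = rank_feature_importance(forest, names)
        assert ranked[0][0] == "f4"

    def test_constant_feature_importance_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        X[:, 2] = 0.0
        y = (X[:, 0] > 0).astype(int)
        forest = train_model(X, y, n_trees=30, seed=0)
        ranked = dict(rank_feature_importance(forest, ["a", "b", "const", "d"]))
        assert ranked["const"] == 0.0

    def test_importances_sum_to_one(self, toy):
        forest, _, _, names = toy
        assert sum(v for _, v in rank_feature_importance(forest, names)) == pytest.approx(1.0)

    def test_unfitted_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(RuntimeError):
            rank_feature_importance(RandomForestClassifier(), ["a"])


class TestFitSurrogate:
    def test_single_split_forest_recovered_at_depth_one(self, toy):
        forest, X, _, names = toy
        tree = fit_surrogate(forest, X, names, seed=0, holdout_fraction=0.25)
        assert tree.fidelity["accuracy"] >= 0.95
        # grid search should not need depth > 2 for a one-feature rule
        assert tree.depth <= 2

    def test_unrestricted_tree_memorizes_training_pool(self, toy):
        forest, X, _, names = toy
        tree = fit_surrogate(
            forest, X, names, seed=0, param_grid=UNRESTRICTED, holdout_fraction=0.0
        )
        assert tree.fidelity == {"accuracy": 1.0, "f1": 1.0}

    def test_degenerate_forest_rejected(self):
        X = np.ones((30, 3))
        y = np.array([0, 1] * 15)
        forest = train_model(X, y, n_trees=10, seed=0)
        pred = forest.predict(X)
        if len(np.unique(pred)) < 2:
            with pytest.raises(DegenerateTargetError):
                fit_surrogate(forest, X, ["a", "b", "c"], seed=0)
        else:
            pytest.skip("forest not degenerate on constant features")

    def test_leaf_counts_sum_to_training_size(self, toy):
        forest, X, _, names = toy
        tree = fit_surrogate(
            forest, X, names, seed=0, param_grid=UNRESTRICTED, holdout_fraction=0.0
        )
        def leaf_total(node):
            if node.is_leaf:
                return sum(node.counts)
            return leaf_total(node.left) + leaf_total(node.right)
        assert leaf_total(tree.root) == X.shape[0]


class TestPostPrune:
    def test_floor_zero_prunes_to_single_leaf(self, toy):
        forest, X, _, names = toy
        tree = fit_surrogate(
            forest, X, names, seed=0, param_grid=UNRESTRICTED, holdout_fraction=0.0
        )
        pruned = post_prune(tree, X, forest.predict(X), fidelity_floor=0.0)
        assert pruned.depth == 0 and pruned.root.is_leaf

    def test_floor_one_on_memorizing_tree_unchanged(self, toy):
        forest, X, _, names = toy
        tree = fit_surrogate(
            forest, X, names, seed=0, param_grid=UNRESTRICTED, holdout_fraction=0.0
        )
        pruned = post_prune(tree, X, forest.predict(X), fidelity_floor=1.0)
        assert pruned.depth == tree.depth
        assert pruned.fidelity["accuracy"] == 1.0

    def test_unattainable_floor_flags_and_returns_unpruned(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)
        forest = train_model(X, y, n_trees=10, seed=0)
        tree = fit_surrogate(
            forest, X, [f"f{i}" for i in range(4)], seed=0,
            param_grid={"max_depth": [1], "min_samples_leaf": [1]},
            holdout_fraction=0.0,
        )
        pruned = post_prune(tree, X, y_reference=1 - forest.predict(X), fidelity_floor=0.999)
        assert pruned.floor_unattained
        assert pruned.depth == tree.depth

    def test_monotone_depth_and_fidelity_over_random_runs(self):
        """Depth never grows and accuracy fidelity stays above the floor."""
        rng = np.random.default_rng(3)
        for run in range(50):
            X = rng.normal(size=(120, 6))
            w = rng.normal(size=6)
            y = (X @ w > 0).astype(int)
            if len(np.unique(y)) < 2:
                continue
            forest = train_model(X, y, n_trees=10, seed=run)
            tree = fit_surrogate(
                forest, X, [f"f{i}" for i in range(6)], seed=run,
                param_grid=UNRESTRICTED, holdout_fraction=0.0,
            )
            floor = 0.9
            pruned = post_prune(tree, X, forest.predict(X), fidelity_floor=floor)
            assert pruned.depth <= tree.depth
            assert pruned.fidelity["accuracy"] >= floor
            assert pruned.fidelity["accuracy"] <= tree.fidelity["accuracy"]


class TestTrace:
    def _format_fixture_tree(self):
        """Synthetic two-split tree mirroring the published example rule's
        shape and thresholds; used purely as a rendering fixture."""
        leaf_pos = TreeNode(counts=(41, 800))
        leaf_mid = TreeNode(counts=(120, 30))
        leaf_neg = TreeNode(counts=(900, 50))
        inner = TreeNode(feature=1, threshold=8.5, left=leaf_mid, right=leaf_pos)
        root = TreeNode(feature=0, threshold=49.5, left=leaf_neg, right=inner)
        return SurrogateTree(root=root, feature_names=["rel1_TREATS", "PATH2"])

    def test_rule_renders_verbatim(self):
        tree = self._format_fixture_tree()
        rule = trace_decision(tree, np.array([60.0, 10.0]))
        assert rule.render() == (
            "IF rel1_TREATS > 49.5 AND PATH2 > 8.5 THEN Interaction (800/841)"
        )

    def test_depth_one_tree_single_condition(self):
        root = TreeNode(
            feature=0, threshold=1.5,
            left=TreeNode(counts=(10, 0)), right=TreeNode(counts=(0, 10)),
        )
        tree = SurrogateTree(root=root, feature_names=["x"])
        rule = trace_decision(tree, np.array([0.0]))
        assert rule.conditions == [("x", "<=", 1.5)]
        assert rule.label == "No interaction"

    def test_same_leaf_same_rule(self):
        tree = self._format_fixture_tree()
        r1 = trace_decision(tree, np.array([50.0, 9.0]))
        r2 = trace_decision(tree, np.array([99.0, 99.0]))
        assert r1 == r2

    def test_layout_mismatch_rejected(self):
        tree = self._format_fixture_tree()
        with pytest.raises(ValueError):
            trace_decision(tree, np.zeros(3))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_trace_agrees_with_tree_prediction(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        if len(np.unique(y)) < 2:
            return
        forest = train_model(X, y, n_trees=5, seed=0)
        tree = fit_surrogate(
            forest, X, [f"f{i}" for i in range(5)], seed=0,
            param_grid=UNRESTRICTED, holdout_fraction=0.0,
        )
        probe = rng.normal(size=(20, 5))
        for x in probe:
            assert trace_decision(tree, x).predicted_class == tree.predict_one(x)


def test_tree_to_dict_round_trips_structure(toy):
    forest, X, _, names = toy
    tree = fit_surrogate(forest, X, names, seed=0, holdout_fraction=0.25)
    d = tree_to_dict(tree.root, tree.feature_names)
    def depth(node):
        if node["leaf"]:
            return 0
        return 1 + max(depth(node["left"]), depth(node["right"]))
    assert depth(d) == tree.depth
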