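"""Featurization, sampling regimes, training and cross-validation."""

import numpy as np
import pytest

from blgpa import (
    SamplingConfig,
    SELayout,
    cross_validate,
    feature_names,
    featurize_pair,
    sample_dataset,
    select_features,
    select_top_chains,
    train_model,
)
from blgpa.path_ranking import ChainList, ChainScore, mine_chains
from blgpa.synthetic_kg import fig3_chainlist


def _padded_chainlist(n=100):
    """Fig. 3 chains at ranks 0 and 5, padded with dummies to n entries."""
    base = list(fig3_chainlist())
    extra = [
        ChainScore((f"FILLER_{i}",), 0.1 - i * 1e-4, 0.0) for i in range(n - len(base))
    ]
    return ChainList(base + extra)


class TestFeaturize:
    def test_default_vector_length_586(self, fig3):
        graph, (drug, gene), _ = fig3
        vec = featurize_pair(graph, drug, gene, _padded_chainlist(), SELayout(3))
        assert vec.shape == (586,)

    def test_disconnected_pair_is_zero(self):
        from blgpa import KnowledgeGraph, Predication

        graph = KnowledgeGraph(
            [
                Predication("d1", "phsu", "TREATS", "c1", "dsyn", "p1"),
                Predication("d2", "phsu", "TREATS", "g1", "gngm", "p2"),
            ]
        )
        vec = featurize_pair(graph, "d1", "g1", _padded_chainlist(), SELayout(3))
        assert vec.shape == (586,) and vec.sum() == 0

    def test_fig3_nonzeros_exactly_expected(self, fig3):
        graph, (drug, gene), manifest = fig3
        layout = SELayout(3)
        chains = _padded_chainlist()
        vec = featurize_pair(graph, drug, gene, chains, layout)
        names = feature_names(layout, chains)
        nonzero = {names[i]: int(v) for i, v in enumerate(vec) if v}
        expected = dict(manifest["expected_se_nonzero"])
        expected.update(manifest["expected_pr_nonzero"])
        assert nonzero == expected

    def test_no_pr_ablation_shrinks_by_chain_count(self, fig3):
        graph, (drug, gene), _ = fig3
        chains = _padded_chainlist()
        full = featurize_pair(graph, drug, gene, chains, SELayout(3))
        se_only = featurize_pair(graph, drug, gene, chains, SELayout(3), include_pr=False)
        assert full.shape[0] - se_only.shape[0] == len(chains)


class TestSampling:
    PAIRS = [(f"d{i}", "g", 1) for i in range(100)] + [
        (f"d{i}", "g", 0) for i in range(100, 5500)
    ]

    def test_balanced_draws_equal_classes(self):
        selected, desc = sample_dataset(self.PAIRS, SamplingConfig(seed=1))
        labels = [y for _, _, y in selected]
        assert labels.count(1) == 100 and labels.count(0) == 100
        assert desc["inner_subsample"] is False

    def test_ratio_1_10_keeps_imbalance(self):
        selected, desc = sample_dataset(
            self.PAIRS, SamplingConfig(regime="ratio_1_10", seed=1)
        )
        labels = [y for _, _, y in selected]
        assert labels.count(0) == 10 * labels.count(1)
        assert desc["inner_subsample"] is True

    def test_fixed_seed_reproduces_selection(self):
        a, _ = sample_dataset(self.PAIRS, SamplingConfig(seed=5))
        b, _ = sample_dataset(self.PAIRS, SamplingConfig(seed=5))
        assert a == b

    def test_insufficient_negatives_rejected(self):
        pairs = [("d", "g", 1)] * 5 + [("e", "h", 0)] * 3
        with pytest.raises(ValueError):
            sample_dataset(pairs, SamplingConfig(regime="ratio_1_54", seed=0))


class TestTrainModel:
    def test_separable_features_memorized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] > 0).astype(int)
        forest = train_model(X, y, n_trees=20, seed=0)
        assert (forest.predict(X) == y).all()

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8))
        y = rng.integers(0, 2, size=60)
        p1 = train_model(X, y, seed=3).predict_proba(X)
        p2 = train_model(X, y, seed=3).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train_model(X, np.ones(10))


class TestCrossValidate:
    def test_folds_partition_and_disjoint(self, planted_report):
        folds = planted_report["folds"]
        assert len(folds) == 10
        assert sum(f["n_test"] for f in folds) == 400
        assert planted_report["leakage_audit"] == "passed"

    def test_macro_is_mean_of_folds(self, planted_report):
        for metric in ("precision", "recall", "f1"):
            vals = [f[metric] for f in planted_report["folds"]]
            assert planted_report["macro"][metric] == pytest.approx(np.mean(vals))
            assert 0.0 <= planted_report["macro"][metric] <= 1.0

    def test_planted_signal_beats_no_skill_baseline(self, planted_report):
        # balanced classes: always-positive prediction yields F1 = 2/3
        assert planted_report["macro"]["f1"] > 2 / 3 + 0.1

    def test_too_few_positives_rejected(self, planted):
        graph, pairs, _, _ = planted
        few = [p for p in pairs if p[2] == 0][:50] + [p for p in pairs if p[2] == 1][:5]
        with pytest.raises(ValueError):
            cross_validate(graph, few, SamplingConfig(seed=0))

    def test_ratio_regime_selects_inner_ratio(self, planted):
        graph, pairs, _, path_sets = planted
        pos = [p for p in pairs if p[2] == 1][:20]
        neg = [p for p in pairs if p[2] == 0]
        config = SamplingConfig(regime="ratio_1_10", candidate_ratios=(1, 5, 10), seed=2)
        report = cross_validate(
            graph, pos + neg, config, n_trees=20, n_folds=10, top_chains=20,
            path_sets=path_sets,
        )
        assert all(f["inner_ratio"] in (1, 5, 10) for f in report["folds"])
        labels = [f["n_test"] for f in report["folds"]]
        assert sum(labels) == 20 + 200


class TestSelectFeatures:
    def _fit(self, planted):
        graph, pairs, _, path_sets = planted
        labels = {(d, g): y for d, g, y in pairs}
        chains = select_top_chains(mine_chains(path_sets, labels), 100)
        layout = SELayout(3)
        X = np.vstack([
            featurize_pair(graph, d, g, chains, layout, path_set=path_sets[(d, g)])
            for d, g, _ in pairs
        ])
        y = np.array([y for _, _, y in pairs])
        return train_model(X, y, n_trees=50, seed=0), X, y

    def test_all_features_mask_changes_nothing(self, planted):
        forest, X, y = self._fit(planted)
        mask, refit, report = select_features(
            forest, X, y, top_k=X.shape[1], n_trees=50, seed=0
        )
        assert mask.all()
        assert report["selected_train_f1"] == pytest.approx(report["baseline_train_f1"])

    def test_constant_feature_exclusion_harmless(self, planted):
        forest, X, y = self._fit(planted)
        nonconstant = int((X.std(axis=0) > 0).sum())
        mask, _, report = select_features(forest, X, y, threshold=0.0, seed=0)
        assert mask.sum() <= nonconstant
        assert report["selected_train_f1"] >= report["baseline_train_f1"] - 0.02

    def test_informative_features_survive_top_40(self, planted):
        forest, X, y = self._fit(planted)
        mask, _, _ = select_features(forest, X, y, top_k=40, seed=0)
        layout = SELayout(3)
        names = layout.feature_names()
        kept = {names[i] for i in range(len(names)) if mask[i]}
        kept |= {f"PATH{i - len(names)}" for i in range(len(names), X.shape[1]) if mask[i]}
        # the planted chain's own features must be retained
        assert "PATH0" in kept
        assert {"rel1_INTERACTS_WITH", "rel2_TREATS", "rel3_AFFECTS"} <= kept

    def test_empty_mask_rejected(self, planted):
        forest, X, y = self._fit(planted)
        with pytest.raises(ValueError):
            select_features(forest, X, y, threshold=1.1, seed=0)
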