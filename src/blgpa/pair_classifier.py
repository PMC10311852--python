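"""Pair featurization, sampling regimes, forest training and evaluation.

A drug-gene pair is represented by the concatenation of its aggregated
semantic-encoding vector and its path-ranking vector: with the defaults
(path length 3, 127 types + 35 relations, top 100 chains) that is
3*162 + 100 = 586 features. Evaluation follows stratified 10-fold outer
cross-validation with positive-class precision/recall/F1 averaged across
folds; chain mining and, under imbalanced regimes, inner 5-fold selection
of the training negative:positive ratio happen strictly inside each
training fold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .kg_model import KnowledgeGraph
from .path_ranking import ChainList, mine_chains, pr_vector, select_top_chains
from .path_search import DEFAULT_PATH_CAP, PathSet, enumerate_paths
from .semantic_encoding import SELayout, encode_pair_paths

BALANCED = "balanced_1_1"
RATIO_1_10 = "ratio_1_10"
RATIO_1_54 = "ratio_1_54"
REGIMES = (BALANCED, RATIO_1_10, RATIO_1_54)
_REGIME_RATIO = {RATIO_1_10: 10, RATIO_1_54: 54}


@dataclass
class SamplingConfig:
    """Sampling regime, inner-CV settings and the master seed."""

    regime: str = BALANCED
    inner_cv_folds: int = 5
    candidate_ratios: Sequence[int] = (1, 2, 5, 10, 20, 54)
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")


def load_pairs(path) -> list[tuple[str, str, int]]:
    """Read a pairs CSV with header drug_id,gene_id,label."""
    pairs = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["drug_id", "gene_id", "label"]:
            raise ValueError(f"{path}: expected header drug_id,gene_id,label")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            pairs.append((row[0], row[1], int(row[2])))
    return pairs


def featurize_pair(
    graph: KnowledgeGraph,
    drug_id: str,
    gene_id: str,
    chains: ChainList,
    layout: SELayout,
    degree_cap: int | None = None,
    path_cap: int | None = DEFAULT_PATH_CAP,
    binary_se: bool = False,
    substring_match: bool = False,
    include_pr: bool = True,
    path_set: PathSet | None = None,
) -> np.ndarray:
    """SE (+) PR feature vector for one pair; all-zero when disconnected."""
    if path_set is None:
        path_set = enumerate_paths(
            graph, drug_id, gene_id, layout.max_len, degree_cap, path_cap
        )
    se = encode_pair_paths(graph, path_set, layout, binary_se).values
    if not include_pr:
        return se
    pr = pr_vector(path_set, chains, substring_match)
    return np.concatenate([se, pr])


def feature_names(layout: SELayout, chains: ChainList | None) -> list[str]:
    names = layout.feature_names()
    if chains is not None:
        names += chains.names()
    return names


def sample_dataset(
    pairs: Sequence[tuple[str, str, int]],
    config: SamplingConfig,
) -> tuple[list[tuple[str, str, int]], dict]:
    """Apply the regime's negative sampling to the labeled pair list.

    Balanced: all positives plus an equal-size uniform negative sample.
    Ratio regimes: all positives plus ratio * n_pos negatives — the test
    folds keep this imbalance, while the training pools are marked for
    inner-CV ratio subsampling.
    """
    rng = np.random.default_rng(config.seed)
    positives = [p for p in pairs if p[2] == 1]
    negatives = [p for p in pairs if p[2] == 0]
    if not positives or not negatives:
        raise ValueError("both classes must be present")
    ratio = _REGIME_RATIO.get(config.regime, 1)
    n_neg = ratio * len(positives)
    if n_neg > len(negatives):
        raise ValueError(
            f"regime {config.regime} needs {n_neg} negatives, only {len(negatives)} available"
        )
    chosen = rng.choice(len(negatives), size=n_neg, replace=False)
    selected = positives + [negatives[i] for i in sorted(chosen.tolist())]
    descriptor = {
        "regime": config.regime,
        "n_pos": len(positives),
        "n_neg": n_neg,
        "inner_subsample": config.regime != BALANCED,
    }
    return selected, descriptor


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    class_weight=None,
) -> RandomForestClassifier:
    """Random forest with the library defaults and n_trees estimators."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, class_weight=class_weight
    )
    forest.fit(X, y)
    return forest


def _positive_metrics(y_true, y_pred) -> dict[str, float]:
    return {
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }


def _subsample_to_ratio(train_idx, y, ratio, rng) -> np.ndarray:
    """Keep all positives and at most ratio * n_pos negatives of train_idx."""
    pos = [i for i in train_idx if y[i] == 1]
    neg = [i for i in train_idx if y[i] == 0]
    keep = min(len(neg), ratio * len(pos))
    chosen = rng.choice(len(neg), size=keep, replace=False)
    return np.array(pos + [neg[i] for i in sorted(chosen.tolist())])


def _select_ratio(
    X, y, train_idx, config: SamplingConfig, n_trees, class_weight, threshold, seed
) -> int:
    """Inner k-fold CV over candidate training ratios, maximising mean F1."""
    y_train = y[train_idx]
    n_pos = int(y_train.sum())
    n_neg = len(y_train) - n_pos
    feasible = [r for r in config.candidate_ratios if r * n_pos * (1 - 1 / config.inner_cv_folds) <= n_neg]
    if not feasible:
        feasible = [max(config.candidate_ratios)]
    rng = np.random.default_rng(seed)
    inner = StratifiedKFold(
        n_splits=config.inner_cv_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    best_ratio, best_f1 = feasible[0], -1.0
    for ratio in feasible:
        scores = []
        for inner_tr, inner_val in inner.split(X[train_idx], y_train):
            tr_idx = _subsample_to_ratio(train_idx[inner_tr], y, ratio, rng)
            if len(np.unique(y[tr_idx])) < 2:
                continue
            forest = train_model(
                X[tr_idx], y[tr_idx], n_trees, int(rng.integers(2**31)), class_weight
            )
            proba = forest.predict_proba(X[train_idx[inner_val]])[:, 1]
            scores.append(f1_score(y[train_idx[inner_val]], proba >= threshold, zero_division=0))
        mean = float(np.mean(scores)) if scores else -1.0
        if mean > best_f1:
            best_ratio, best_f1 = ratio, mean
    return best_ratio


def cross_validate(
    graph: KnowledgeGraph,
    pairs: Sequence[tuple[str, str, int]],
    config: SamplingConfig,
    max_len: int = 3,
    top_chains: int = 100,
    n_trees: int = 100,
    degree_cap: int | None = None,
    path_cap: int | None = DEFAULT_PATH_CAP,
    layout: SELayout | None = None,
    binary_se: bool = False,
    substring_match: bool = False,
    include_pr: bool = True,
    class_weight=None,
    threshold: float = 0.5,
    n_folds: int = 10,
    path_sets: Mapping[tuple[str, str], PathSet] | None = None,
) -> dict:
    """Stratified outer CV with per-fold chain mining and ratio selection.

    All randomness flows from config.seed, so identical configurations
    produce bit-identical reports. The report carries a leakage audit:
    chain mining and ratio selection are asserted to have seen only
    training-fold pairs.
    """
    layout = layout or SELayout(max_len)
    selected, descriptor = sample_dataset(pairs, config)
    if int(sum(p[2] for p in selected)) < n_folds:
        raise ValueError(f"need at least {n_folds} positives for {n_folds}-fold CV")
    keys = [(d, g) for d, g, _ in selected]
    y = np.array([lab for _, _, lab in selected])

    if path_sets is None:
        path_sets = {
            (d, g): enumerate_paths(graph, d, g, layout.max_len, degree_cap, path_cap)
            for d, g in keys
        }
    # SE features are label-free; compute once across folds
    se_matrix = np.vstack(
        [encode_pair_paths(graph, path_sets[k], layout, binary_se).values for k in keys]
    )

    rng = np.random.default_rng(config.seed)
    outer_seed = int(rng.integers(2**31))
    fold_seeds = rng.integers(0, 2**31, size=n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=outer_seed)

    folds = []
    audit: list[dict] = []
    for fold_no, (train_idx, test_idx) in enumerate(skf.split(se_matrix, y)):
        fold_seed = int(fold_seeds[fold_no])
        fold_rng = np.random.default_rng(fold_seed)
        train_keys = [keys[i] for i in train_idx]
        mining_sets = {k: path_sets[k] for k in train_keys}
        mining_labels = {k: int(y[i]) for k, i in zip(train_keys, train_idx)}
        chains = select_top_chains(mine_chains(mining_sets, mining_labels), top_chains)

        if include_pr:
            pr_matrix = np.vstack(
                [pr_vector(path_sets[k], chains, substring_match) for k in keys]
            )
            X = np.hstack([se_matrix, pr_matrix])
        else:
            X = se_matrix

        inner_ratio = None
        fit_idx = train_idx
        if descriptor["inner_subsample"]:
            inner_ratio = _select_ratio(
                X, y, train_idx, config, n_trees, class_weight, threshold,
                int(fold_rng.integers(2**31)),
            )
            fit_idx = _subsample_to_ratio(train_idx, y, inner_ratio, fold_rng)

        forest = train_model(
            X[fit_idx], y[fit_idx], n_trees, int(fold_rng.integers(2**31)), class_weight
        )
        proba = forest.predict_proba(X[test_idx])[:, 1]
        metrics = _positive_metrics(y[test_idx], proba >= threshold)
        metrics.update(
            fold=fold_no,
            inner_ratio=inner_ratio,
            n_train=int(len(fit_idx)),
            n_test=int(len(test_idx)),
        )
        folds.append(metrics)
        audit.append(
            {
                "test": {keys[i] for i in test_idx},
                "mined": set(mining_labels),
                "fitted": {keys[i] for i in fit_idx},
            }
        )

    # leakage audit: no test pair may have influenced mining or fitting
    for entry in audit:
        leaked = entry["test"] & (entry["mined"] | entry["fitted"])
        assert not leaked, f"leakage audit failed for pairs {sorted(leaked)[:3]}"

    macro = {
        m: float(np.mean([f[m] for f in folds])) for m in ("precision", "recall", "f1")
    }
    return {
        "config": {
            "regime": config.regime,
            "seed": config.seed,
            "max_len": layout.max_len,
            "top_chains": top_chains,
            "n_trees": n_trees,
            "n_folds": n_folds,
            "include_pr": include_pr,
            "binary_se": binary_se,
            "threshold": threshold,
        },
        "sampling": descriptor,
        "folds": folds,
        "macro": macro,
        "leakage_audit": "passed",
    }


def select_features(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    top_k: int | None = None,
    threshold: float | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, RandomForestClassifier, dict]:
    """Mask features by forest importance and refit on the masked matrix.

    Exactly one of top_k / threshold selects the mask. Returns the boolean
    mask, the refit forest, and training-set F1 of both models.
    """
    if (top_k is None) == (threshold is None):
        raise ValueError("specify exactly one of top_k or threshold")
    importances = forest.feature_importances_
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        order = np.argsort(-importances, kind="stable")
        mask = np.zeros(len(importances), dtype=bool)
        mask[order[:top_k]] = True
    else:
        mask = importances > threshold
    if not mask.any():
        raise ValueError("feature mask is empty")
    refit = train_model(X[:, mask], y, n_trees, seed)
    report = {
        "n_selected": int(mask.sum()),
        "baseline_train_f1": float(f1_score(y, forest.predict(X), zero_division=0)),
        "selected_train_f1": float(f1_score(y, refit.predict(X[:, mask]), zero_division=0)),
    }
    return mask, refit, report
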