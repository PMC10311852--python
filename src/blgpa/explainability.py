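"""Explaining forest predictions: importances, surrogate tree, rules.

The forest is distilled into a single decision tree trained on the
forest's *predicted labels*; its fidelity (accuracy and positive-class F1
against the forest) quantifies how well the tree stands in for the model.
An iterative post-pruning pass then collapses subtrees while fidelity
stays above a floor, shortening the root-to-leaf rules that explain
individual drug-gene pairs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

CLASS_LABELS = {0: "No interaction", 1: "Interaction"}

DEFAULT_PARAM_GRID = {
    "max_depth": [2, 3, 4, 6, 8, None],
    "min_samples_leaf": [1, 5, 10, 20],
}


class DegenerateTargetError(ValueError):
    """The forest predicts a single class everywhere; nothing to distill."""


@dataclass
class TreeNode:
    """One node of the surrogate; feature < 0 marks a leaf."""

    feature: int = -1
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    counts: tuple[int, int] = (0, 0)  # training samples per class routed here

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0

    @property
    def predicted_class(self) -> int:
        # tie goes to the negative class, deterministically
        return int(self.counts[1] > self.counts[0])

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


@dataclass
class SurrogateTree:
    """A decision tree over the named features, imitating the forest."""

    root: TreeNode
    feature_names: list[str]
    fidelity: dict = field(default_factory=dict)
    floor_unattained: bool = False

    @property
    def depth(self) -> int:
        return self.root.depth()

    def predict_one(self, x) -> int:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.predicted_class

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        return np.array([self.predict_one(row) for row in X])

    def n_training_samples(self) -> int:
        return int(sum(self.root.counts))


@dataclass
class Rule:
    """A root-to-leaf decision path rendered as a conjunctive rule."""

    conditions: list[tuple[str, str, float]]  # (feature name, '>' or '<=', threshold)
    predicted_class: int
    majority: int
    total: int

    @property
    def label(self) -> str:
        return CLASS_LABELS[self.predicted_class]

    def render(self) -> str:
        if self.conditions:
            body = " AND ".join(f"{n} {op} {t:g}" for n, op, t in self.conditions)
        else:
            body = "TRUE"
        return f"IF {body} THEN {self.label} ({self.majority}/{self.total})"


def rank_feature_importance(
    forest, feature_names: list[str]
) -> list[tuple[str, float]]:
    """All features with impurity-based importances, sorted descending."""
    if not hasattr(forest, "feature_importances_"):
        raise RuntimeError("model is not fitted")
    imps = forest.feature_importances_
    if len(imps) != len(feature_names):
        raise ValueError("feature name list does not match the model")
    ranked = sorted(zip(feature_names, imps), key=lambda t: (-t[1], t[0]))
    return [(n, float(v)) for n, v in ranked]


def _sklearn_to_nodes(clf: DecisionTreeClassifier, X, y) -> TreeNode:
    """Convert a fitted sklearn tree, recomputing per-node class counts by
    routing (X, y) through the structure (robust to sklearn's internal
    value conventions)."""
    t = clf.tree_
    indicator = clf.decision_path(X)
    y = np.asarray(y)
    counts = np.zeros((t.node_count, 2), dtype=np.int64)
    for cls in (0, 1):
        col = np.asarray(indicator[y == cls].sum(axis=0)).ravel()
        counts[:, cls] = col

    def build(i: int) -> TreeNode:
        if t.children_left[i] == -1:
            return TreeNode(counts=(int(counts[i, 0]), int(counts[i, 1])))
        return TreeNode(
            feature=int(t.feature[i]),
            threshold=float(t.threshold[i]),
            left=build(t.children_left[i]),
            right=build(t.children_right[i]),
            counts=(int(counts[i, 0]), int(counts[i, 1])),
        )

    return build(0)


def surrogate_fidelity(tree: SurrogateTree, X, y_reference) -> dict:
    """Accuracy and positive-class F1 of the tree against reference labels."""
    pred = tree.predict(X)
    return {
        "accuracy": float(accuracy_score(y_reference, pred)),
        "f1": float(f1_score(y_reference, pred, zero_division=0)),
    }


def fit_surrogate(
    forest,
    X: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    param_grid: dict | None = None,
    holdout_fraction: float = 0.25,
    cv: int = 5,
) -> SurrogateTree:
    """Distill the forest into a decision tree on its predicted labels.

    Hyperparameters (depth, leaf size) are chosen by cross-validated
    fidelity over ``param_grid`` (pre-pruning); pass ``{"max_depth":
    [None], "min_samples_leaf": [1]}`` for an unrestricted tree. Fidelity
    is reported on a held-out fraction, or on the training pool itself
    when ``holdout_fraction`` is 0.
    """
    X = np.asarray(X)
    y_forest = np.asarray(forest.predict(X))
    if len(np.unique(y_forest)) < 2:
        raise DegenerateTargetError("forest predicts a single class on this pool")
    if param_grid is None:
        param_grid = DEFAULT_PARAM_GRID

    if holdout_fraction > 0:
        X_fit, X_eval, y_fit, y_eval = train_test_split(
            X, y_forest, test_size=holdout_fraction, stratify=y_forest, random_state=seed
        )
    else:
        X_fit, X_eval, y_fit, y_eval = X, X, y_forest, y_forest

    base = DecisionTreeClassifier(random_state=seed)
    n_grid = sum(len(v) for v in param_grid.values())
    if n_grid > len(param_grid):  # a real grid: tune by cross-validated fidelity
        min_class = int(min(np.bincount(y_fit)))
        folds = max(2, min(cv, min_class))
        search = GridSearchCV(
            base,
            param_grid,
            scoring="accuracy",
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        )
        search.fit(X_fit, y_fit)
        clf = search.best_estimator_
    else:
        clf = base.set_params(**{k: v[0] for k, v in param_grid.items()})
        clf.fit(X_fit, y_fit)

    tree = SurrogateTree(
        root=_sklearn_to_nodes(clf, X_fit, y_fit), feature_names=list(feature_names)
    )
    tree.fidelity = surrogate_fidelity(tree, X_eval, y_eval)
    return tree


def post_prune(
    tree: SurrogateTree,
    X: np.ndarray,
    y_reference: np.ndarray,
    fidelity_floor: float = 0.95,
) -> SurrogateTree:
    """Iteratively collapse subtrees while accuracy fidelity stays >= floor.

    Each iteration collapses the internal node whose replacement by a
    majority leaf costs the least accuracy against ``y_reference``
    (typically the forest's predictions), subject to the floor; it stops
    when no collapse survives. If even the unpruned tree misses the floor,
    the tree is returned unchanged with ``floor_unattained`` set.
    """
    X = np.asarray(X)
    y_reference = np.asarray(y_reference)
    pruned = copy.deepcopy(tree)
    current = surrogate_fidelity(pruned, X, y_reference)
    if current["accuracy"] < fidelity_floor:
        pruned.floor_unattained = True
        pruned.fidelity = current
        return pruned

    def internal_nodes(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return []
        return [node] + internal_nodes(node.left) + internal_nodes(node.right)

    while True:
        best: tuple[float, int] | None = None
        candidates = internal_nodes(pruned.root)
        for idx, node in enumerate(candidates):
            saved = (node.feature, node.left, node.right)
            node.feature, node.left, node.right = -1, None, None
            acc = surrogate_fidelity(pruned, X, y_reference)["accuracy"]
            node.feature, node.left, node.right = saved
            if acc >= fidelity_floor and (best is None or acc > best[0]):
                best = (acc, idx)
        if best is None:
            break
        node = candidates[best[1]]
        node.feature, node.left, node.right = -1, None, None

    pruned.fidelity = surrogate_fidelity(pruned, X, y_reference)
    return pruned


def trace_decision(tree: SurrogateTree, x) -> Rule:
    """The conjunctive rule the tree applies to one feature vector."""
    x = np.asarray(x)
    if x.shape != (len(tree.feature_names),):
        raise ValueError(
            f"vector of length {x.shape} does not match layout of "
            f"{len(tree.feature_names)} features"
        )
    conditions: list[tuple[str, str, float]] = []
    node = tree.root
    while not node.is_leaf:
        name = tree.feature_names[node.feature]
        if x[node.feature] <= node.threshold:
            conditions.append((name, "<=", node.threshold))
            node = node.left
        else:
            conditions.append((name, ">", node.threshold))
            node = node.right
    majority = max(node.counts)
    return Rule(
        conditions=conditions,
        predicted_class=node.predicted_class,
        majority=int(majority),
        total=int(sum(node.counts)),
    )


def tree_to_dict(node: TreeNode, feature_names: list[str]) -> dict:
    """JSON-serializable form of a surrogate (sub)tree."""
    if node.is_leaf:
        return {
            "leaf": True,
            "class": node.predicted_class,
            "label": CLASS_LABELS[node.predicted_class],
            "counts": list(node.counts),
        }
    return {
        "leaf": False,
        "feature": feature_names[node.feature],
        "threshold": node.threshold,
        "counts": list(node.counts),
        "left": tree_to_dict(node.left, feature_names),
        "right": tree_to_dict(node.right, feature_names),
    }


def tree_to_dot(tree: SurrogateTree) -> str:
    """Graphviz dot rendering of the surrogate tree."""
    lines = ["digraph surrogate {", '  node [shape=box, fontname="Helvetica"];']
    counter = [0]

    def walk(node: TreeNode) -> int:
        my_id = counter[0]
        counter[0] += 1
        if node.is_leaf:
            lines.append(
                f'  n{my_id} [label="{CLASS_LABELS[node.predicted_class]}\\n'
                f'{max(node.counts)}/{sum(node.counts)}"];'
            )
        else:
            name = tree.feature_names[node.feature]
            lines.append(f'  n{my_id} [label="{name} <= {node.threshold:g}"];')
            left_id = walk(node.left)
            right_id = walk(node.right)
            lines.append(f'  n{my_id} -> n{left_id} [label="yes"];')
            lines.append(f'  n{my_id} -> n{right_id} [label="no"];')
        return my_id

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)
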