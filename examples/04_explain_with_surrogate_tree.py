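"""Distill the forest into a pruned decision tree and trace a rule.

Trains the forest on a synthetic benchmark, ranks its feature
importances, fits a surrogate tree on the forest's own predictions,
post-prunes it under a fidelity floor, and prints the human-readable
rule the tree applies to one drug-gene pair.
"""

import numpy as np

from blgpa import (
    SELayout,
    SyntheticConfig,
    enumerate_paths,
    feature_names,
    featurize_pair,
    fit_surrogate,
    generate_kg,
    mine_chains,
    post_prune,
    rank_feature_importance,
    select_top_chains,
    trace_decision,
    train_model,
)

graph, pairs, _ = generate_kg(SyntheticConfig(seed=42))
path_sets = {(d, g): enumerate_paths(graph, d, g, 3) for d, g, _ in pairs}
labels = {(d, g): y for d, g, y in pairs}
chains = select_top_chains(mine_chains(path_sets, labels), 100)
layout = SELayout(3)
X = np.vstack([
    featurize_pair(graph, d, g, chains, layout, path_set=path_sets[(d, g)])
    for d, g, _ in pairs
])
y = np.array([y for _, _, y in pairs])
forest = train_model(X, y, n_trees=100, seed=42)
names = feature_names(layout, chains)

print("top 5 forest feature importances:")
for name, imp in rank_feature_importance(forest, names)[:5]:
    print(f"  {name:>24}  {imp:.3f}")

tree = fit_surrogate(forest, X, names, seed=42, holdout_fraction=0.25)
print(f"\nsurrogate (pre-pruning grid search): depth {tree.depth}, held-out "
      f"fidelity accuracy {tree.fidelity['accuracy']:.3f} / F1 {tree.fidelity['f1']:.3f}")

pruned = post_prune(tree, X, forest.predict(X), fidelity_floor=0.9)
print(f"after post-pruning (floor 0.9): depth {pruned.depth}, "
      f"fidelity accuracy {pruned.fidelity['accuracy']:.3f}")

d, g, _ = pairs[0]
rule = trace_decision(pruned, X[0])
print(f"\nrule applied to ({d}, {g}):\n  {rule.render()}")
print("\nThe rule reads directly in graph terms: the pair is predicted to"
      "\ninteract when its path set realises the top-ranked relational chain.")
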