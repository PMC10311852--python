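"""Leakage-free cross-validated evaluation on a planted-signal benchmark.

Runs the full pipeline under stratified 10-fold cross-validation: chains
are re-mined inside every training fold, a 100-tree random forest is fit
on the concatenated SE (+) PR features, and positive-class precision,
recall and F1 are averaged across folds.
"""

import json

from blgpa import SamplingConfig, SyntheticConfig, cross_validate, generate_kg

graph, pairs, _ = generate_kg(SyntheticConfig(seed=42))
report = cross_validate(graph, pairs, SamplingConfig(regime="balanced_1_1", seed=42))

print("per-fold positive-class metrics:")
for fold in report["folds"]:
    print(f"  fold {fold['fold']}: P={fold['precision']:.3f} "
          f"R={fold['recall']:.3f} F1={fold['f1']:.3f}")
print("\nmacro averages:", json.dumps({k: round(v, 3) for k, v in report["macro"].items()}))
print("leakage audit:", report["leakage_audit"])
print(
    "\nThe macro-F1 tracks the generator's ceiling: with the planted chain in"
    "\n90% of positives and 10% of negatives, even the Bayes-optimal rule"
    "\n('predict interaction iff the chain is present') cannot exceed ~0.9."
)
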