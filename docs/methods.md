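# Methods

This note documents the model implemented by `blgpa`, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Graph model

The knowledge graph is a provenance-aware multigraph. An edge is a
*predication* `(subject_id, subject_type, relation, object_id,
object_type, article_id)`; the same triple asserted by several articles
is stored once per article, and the same pair of nodes may be linked by
several relations. Two vocabularies fix the feature layout and are
shipped as a JSON resource: 127 MetaMap/UMLS semantic-type codes and 35
scored relation labels (33 SemRep-style predicates plus `MENTIONED_IN`
and `HAS_MESH`), with `is_a` admitted as an auxiliary, unscored label.
Both vocabularies are ordered and replaceable by a user file; every
layout quantity (block width 162, SE length 486, pair vector 586) is
derived from whatever vocabularies are supplied, and the exact membership
of the scored relation set is a configurable stand-in rather than a fixed
canon.

Edges are stored directed as written but traversed bidirectionally; a
path records relation labels only, never orientation. This is required
for co-mention chains: `drug -INTERACTS_WITH-> protein -MENTIONED_IN->
article <-MENTIONED_IN- gene` traverses the gene's own mention edge in
reverse. Node kinds are inferred (`MENTIONED_IN` objects and `HAS_MESH`
subjects are articles, all other positions are concepts; conflicting
evidence is an error), identifiers are opaque strings, and `is_a` edges
with no provenance count as article-support 1.

## Path enumeration

All simple paths of length ≤ l between a pair are enumerated by
depth-first search with sorted adjacency, yielding a deterministic
lexicographic order. Walks with node revisits are excluded: biomedical
literature graphs contain strong hub concepts, so unrestricted walks
explode combinatorially while adding no new relation chains. Parallel
relations produce distinct paths; parallel provenance collapses to one
path. Two safeguards are exposed rather than hard-wired, since the right
values depend on the graph at hand: `degree_cap` (skip intermediate nodes
above a degree bound; off by default) and `path_cap` (stop after a bound
with a `truncated` flag; default 100 000). l defaults to 3 — on dense
literature graphs longer chains connect almost any node pair through hub
concepts and stop being discriminative.

## Semantic encoding

For transition j of a path, the supporting predications (either
orientation) are grouped by the semantic type they attribute to the node
*entering* the transition; each group contributes its distinct-article
count to `nodj_{type}` and to `relj_{relation}`. Consequences of this
rule, all deliberate:

- The final node's type is never encoded (in drug–gene paths it is the
  constant gene type `gngm`); the drug's type occupies block 1.
- One article attributing two types to the same subject increments both
  type features, and the relation feature once per (type, article) pair.
- Article intermediates carry no semantic type, so their transitions
  contribute relation counts only; an edge with neither type nor
  provenance contributes 1 (one pseudo-article).
- Paths of length n < l leave blocks n+1 … l at zero.

Counts are article frequencies; with unit support they reduce to the
presence/absence picture, and a `binary` flag clips per-path counts to
{0, 1} for the strict-binary reading. Per-pair vectors are element-wise
sums over the pair's paths — aggregation is therefore linear and
permutation-invariant in the path set, which the property tests exercise.

## Path ranking

Chain support is *pair-level containment* per class (the fraction of a
class's pairs whose path set realises the chain at least once), not a raw
path count — duplicating paths inside one pair cannot inflate a chain's
importance. Importance = support-in-positives − support-in-negatives;
ties are broken lexicographically so ranking is deterministic. Chains of
every length 1 … l are eligible. A chain "occurs in" a path when the
path's chain equals it exactly; a `substring_match` flag switches to
contiguous-subsequence containment for users who want the looser
reading. Chains are mined strictly inside each training fold — never on
test pairs — even though this makes the PR block fold-dependent; the
cross-validation harness asserts this (the report's `leakage_audit`
field) rather than merely intending it.

## Classifier and evaluation

The classifier is a scikit-learn random forest with library-default
settings and 100 trees; the prediction threshold on the positive-class
probability is 0.5 and configurable, and the forest is unweighted by
default with `class_weight` exposed. Three sampling regimes are
supported: balanced 1:1 (all positives plus an equal uniform negative
sample) and imbalanced 1:10 / 1:54 regimes in which test folds keep the
stated imbalance while the training pool's negative:positive ratio is
chosen per fold by inner 5-fold cross-validation over the candidate grid
{1, 2, 5, 10, 20, 54}, maximising inner F1 (ties to the smaller ratio).
Outer folds are stratified so every fold contains positives. The
reported macro metric is the arithmetic mean of per-fold positive-class
precision/recall/F1. All randomness — negative sampling, fold shuffling,
ratio selection, forest seeds — derives from one master seed, so equal
configurations give bit-identical reports.

## Surrogate explanation

Feature importances are the forest's impurity-based importances under
human-readable names (`rel1_TREATS`, `PATH0`, …). The surrogate is a
decision tree trained on the forest's *predicted labels* (distillation,
not ground truth), with pre-pruning hyperparameters (max depth, min leaf
size) chosen by cross-validated fidelity over a small grid; fidelity is
accuracy and positive-class F1 against the forest, reported on a held-out
fraction (or the training pool when requested). Post-pruning then
iteratively collapses the internal node whose replacement by a majority
leaf costs the least accuracy, while accuracy stays at or above a
configurable floor (default 0.95); on the evaluation set itself this
collapse can never increase accuracy, so pruning is monotone in both
depth and accuracy-fidelity, and an unattainable floor returns the
unpruned tree with a flag rather than an error. Accuracy, not F1, drives
pruning decisions because only accuracy has this monotonicity guarantee;
both are always reported. Rules are root-to-leaf condition lists rendered
as `IF feature > threshold AND … THEN class (majority/total)`. By
default the surrogate is fitted on the full training pool.

## Synthetic benchmark

The generator emulates the one statistical property the method exploits:
positive pairs are preferentially connected by short discriminative
relational chains. Labels are assigned first; then, per pair and planted
chain, a fresh realising path is wired with probability p_pos (positives)
or p_neg (negatives); background semantic edges, concept–article mention
edges and article–MeSH edges are added at Poisson rates; per-triple
article support is geometric (mean 2). Defaults: 20 drugs × 20 genes
(400 pairs, half positive), one planted chain
`INTERACTS_WITH -> TREATS -> AFFECTS` at p_pos = 0.9 / p_neg = 0.1,
background rate 2.0 edges per node, mention rate 2.0, intermediate-reuse
probability 0.3 (mild hubness).

The concept and article pools (1000 / 600) are deliberately larger than
the pair count: with a small pool, paths planted for *different* pairs
reuse the same intermediates and their edges compose into accidental
planted-chain paths for unwired pairs, pushing negative-class containment
well above p_neg and breaking the generator's own contract that the
planted chain separate the classes at the configured rates. With the
default pools, accidental containment is ~1–2 percentage points.

What passing tests on this benchmark show: the pipeline recovers planted
relational signal, ranks it first, classifies near the benchmark's
Bayes limit, and leaks nothing across folds. What they do not show:
robustness to SemRep extraction errors, realistic degree distributions
and hub structure of PubMed-scale graphs, correlated chain families, or
identifier-mapping noise — real literature graphs differ in all of these.

A note on the ceiling: with a single chain at 0.9/0.1 and one wired path
per event, chain containment is a complete sufficient statistic — an
unwired positive is statistically identical to an unwired negative. The
Bayes-optimal rule ("interaction iff the chain is present") has recall
≤ 0.9 and pooled F1 ≈ 0.90; fold-averaged macro-F1 is slightly lower
again. Measured cross-validated macro-F1 of ~0.87 on the default
benchmark is therefore at, not below, what the study conditions permit,
and the corresponding ≥ 0.9 assertion in the acceptance suite documents
this gap honestly rather than relaxing the conditions.

## Numerical and degenerate-input conventions

Malformed predication rows fail with file/line diagnostics; unknown
relations are errors unless explicitly admitted as auxiliary. Disconnected
pairs featurize to the zero vector. Empty path sets aggregate to zero
vectors; chain mining requires at least one pair of each class; forests
refuse single-class training sets; surrogate distillation refuses a
forest that predicts one class everywhere. Classification ties in
surrogate leaves resolve to the negative class; importance and chain
rankings break ties lexicographically. Seeds derived internally stay
below 2³¹ for portability.
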