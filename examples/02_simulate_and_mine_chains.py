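"""Generate a synthetic literature graph and mine relational chains.

The generator plants the chain INTERACTS_WITH -> TREATS -> AFFECTS into
90% of positive and 10% of negative drug-gene pairs against background
noise. Chain mining should recover it at rank 0 with an importance score
near 0.9 - 0.1 = 0.8.
"""

from blgpa import SyntheticConfig, enumerate_paths, generate_kg, mine_chains

config = SyntheticConfig(seed=42)
graph, pairs, manifest = generate_kg(config)
stats = graph.stats()
print(f"graph: {stats['nodes']} nodes, {stats['predications']} predications "
      f"({stats['articles']} article nodes)")
print(f"pairs: {sum(y for _, _, y in pairs)} positive / "
      f"{sum(1 - y for _, _, y in pairs)} negative")

path_sets = {(d, g): enumerate_paths(graph, d, g, max_len=3) for d, g, _ in pairs}
labels = {(d, g): y for d, g, y in pairs}
scores = mine_chains(path_sets, labels)

print("\ntop 5 relational chains (support in positives - support in negatives):")
print(f"{'rank':>4}  {'importance':>10}  {'freq_pos':>8}  {'freq_neg':>8}  chain")
for k, s in enumerate(scores[:5]):
    print(f"{k:>4}  {s.importance:>10.3f}  {s.freq_pos:>8.3f}  {s.freq_neg:>8.3f}  "
          + " -> ".join(s.chain))
print("\nThe planted chain separates the classes; everything below it is "
      "background noise with near-zero importance.")
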