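"""Path Ranking (PR) features: support-ranked relational chains.

A relational chain is the ordered relation-label sequence of a path, the
nodes discarded. Chains are mined from labeled training pairs: the support
of a chain in a class is the fraction of that class's pairs whose path set
contains at least one path with the chain, and the importance score is
support-in-positives minus support-in-negatives. The top M chains define a
fixed PR feature layout PATH0..PATH{M-1}; a pair's PR vector counts, per
ranked chain, how many of its paths realise that chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .path_search import Path, PathSet

logger = logging.getLogger(__name__)

RelationalChain = tuple[str, ...]


def chain_of(path: Path) -> RelationalChain:
    """The relation-label sequence of a path (node-blind)."""
    return tuple(path.relations)


@dataclass(frozen=True)
class ChainScore:
    chain: RelationalChain
    freq_pos: float
    freq_neg: float

    @property
    def importance(self) -> float:
        return self.freq_pos - self.freq_neg


class ChainList:
    """The ranked top-M chains; rank k is feature PATH{k}."""

    def __init__(self, scores: list[ChainScore]):
        self.scores = list(scores)
        self.rank = {s.chain: k for k, s in enumerate(self.scores)}
        if len(self.rank) != len(self.scores):
            raise ValueError("duplicate chains in chain list")

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def __getitem__(self, k: int) -> ChainScore:
        return self.scores[k]

    def name(self, k: int) -> str:
        return f"PATH{k}"

    def names(self) -> list[str]:
        return [self.name(k) for k in range(len(self.scores))]

    def chains(self) -> list[RelationalChain]:
        return [s.chain for s in self.scores]


def mine_chains(
    pair_path_sets: Mapping[tuple[str, str], PathSet],
    labels: Mapping[tuple[str, str], int],
    use_counts: bool = False,
) -> list[ChainScore]:
    """Score every relational chain observed in any pair's path set.

    Support is pair-level containment per class: duplicating a path inside
    one pair's set does not change the score. With ``use_counts`` supports
    are raw pair counts instead of fractions (importance then ranges over
    integers). Result is sorted by importance descending, ties broken
    lexicographically by chain labels.
    """
    pos_pairs = [p for p, y in labels.items() if y == 1]
    neg_pairs = [p for p, y in labels.items() if y == 0]
    if not pos_pairs or not neg_pairs:
        raise ValueError("chain mining needs at least one pair of each class")

    pos_count: dict[RelationalChain, int] = {}
    neg_count: dict[RelationalChain, int] = {}
    for pair, pset in pair_path_sets.items():
        if pair not in labels:
            continue
        chains = {chain_of(p) for p in pset}
        bucket = pos_count if labels[pair] == 1 else neg_count
        for c in chains:
            bucket[c] = bucket.get(c, 0) + 1

    pos_denom = 1 if use_counts else len(pos_pairs)
    neg_denom = 1 if use_counts else len(neg_pairs)
    all_chains = set(pos_count) | set(neg_count)
    scores = [
        ChainScore(
            chain=c,
            freq_pos=pos_count.get(c, 0) / pos_denom,
            freq_neg=neg_count.get(c, 0) / neg_denom,
        )
        for c in all_chains
    ]
    scores.sort(key=lambda s: (-s.importance, s.chain))
    return scores


def select_top_chains(scores: list[ChainScore], m: int) -> ChainList:
    """Keep the M most important chains (all, with a log note, if fewer)."""
    if m < 1:
        raise ValueError("M must be >= 1")
    ordered = sorted(scores, key=lambda s: (-s.importance, s.chain))
    if len(ordered) < m:
        logger.info(
            "only %d chains available for a top-%d list; PR layout shrinks", len(ordered), m
        )
    return ChainList(ordered[:m])


def _contains_subsequence(haystack: RelationalChain, needle: RelationalChain) -> bool:
    k = len(needle)
    return any(haystack[i : i + k] == needle for i in range(len(haystack) - k + 1))


def pr_vector(
    path_set: PathSet,
    chains: ChainList,
    substring_match: bool = False,
) -> np.ndarray:
    """PR vector: per ranked chain, the number of matching paths in the set.

    A path matches when its chain equals the ranked chain exactly; with
    ``substring_match`` a contiguous-subsequence occurrence also counts.
    """
    values = np.zeros(len(chains), dtype=np.int64)
    for path in path_set:
        pc = chain_of(path)
        if substring_match:
            for k, score in enumerate(chains):
                if _contains_subsequence(pc, score.chain):
                    values[k] += 1
        else:
            k = chains.rank.get(pc)
            if k is not None:
                values[k] += 1
    return values
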