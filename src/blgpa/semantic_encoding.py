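"""Positional Semantic Encoding (SE) features.

Every path position j (1-based) owns one block of T + R features, where T
is the semantic-type vocabulary size and R the scored relation vocabulary
size (162 with the default 127 + 35). ``nod{j}_{st}`` counts, over the
articles supporting transition j, how often the node *entering* that
transition carries semantic type st; ``rel{j}_{sr}`` counts the supporting
articles of relation sr at position j. The final node's type is never
encoded (in drug-gene paths it is always 'gngm'). Paths shorter than the
layout leave their trailing blocks at zero, and a pair's vector is the
element-wise sum over its paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kg_model import (
    KnowledgeGraph,
    RelationVocabulary,
    SemanticTypeVocabulary,
    default_vocabularies,
)
from .path_search import Path

logger = logging.getLogger(__name__)


class SELayout:
    """Fixed feature layout: l blocks of (types + scored relations)."""

    def __init__(
        self,
        max_len: int = 3,
        type_vocab: SemanticTypeVocabulary | None = None,
        rel_vocab: RelationVocabulary | None = None,
    ):
        if type_vocab is None or rel_vocab is None:
            default_types, default_rels = default_vocabularies()
            type_vocab = type_vocab or default_types
            rel_vocab = rel_vocab or default_rels
        if max_len < 1:
            raise ValueError("max_len must be >= 1")
        self.max_len = max_len
        self.type_vocab = type_vocab
        self.rel_vocab = rel_vocab
        self.n_types = len(type_vocab)
        self.n_relations = len(rel_vocab)
        self.block_width = self.n_types + self.n_relations
        self.total_len = max_len * self.block_width

    def nod_index(self, position: int, type_code: str) -> int:
        """Index of nod{position}_{type_code}; position is 1-based."""
        self._check_position(position)
        return (position - 1) * self.block_width + self.type_vocab.index[type_code]

    def rel_index(self, position: int, relation: str) -> int:
        """Index of rel{position}_{relation}; position is 1-based."""
        self._check_position(position)
        return (
            (position - 1) * self.block_width
            + self.n_types
            + self.rel_vocab.index[relation]
        )

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.max_len:
            raise IndexError(f"position {position} outside 1..{self.max_len}")

    def feature_names(self) -> list[str]:
        names = []
        for j in range(1, self.max_len + 1):
            names.extend(f"nod{j}_{st}" for st in self.type_vocab.codes)
            names.extend(f"rel{j}_{sr}" for sr in self.rel_vocab.scored)
        return names

    def compatible(self, other: "SELayout") -> bool:
        return (
            self.max_len == other.max_len
            and self.type_vocab.codes == other.type_vocab.codes
            and self.rel_vocab.scored == other.rel_vocab.scored
        )


@dataclass
class SEVector:
    values: np.ndarray
    layout: SELayout

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (self.layout.total_len,):
            raise ValueError("SE vector length does not match layout")
        if (self.values < 0).any():
            raise ValueError("SE counts must be non-negative")

    def __getitem__(self, name: str) -> int:
        """Value by feature name, e.g. vec['rel1_INTERACTS_WITH']."""
        prefix, _, code = name.partition("_")
        kind, pos = prefix[:3], int(prefix[3:])
        if kind == "nod":
            return int(self.values[self.layout.nod_index(pos, code)])
        if kind == "rel":
            return int(self.values[self.layout.rel_index(pos, code)])
        raise KeyError(name)


def encode_path(
    graph: KnowledgeGraph,
    path: Path,
    layout: SELayout,
    binary: bool = False,
) -> SEVector:
    """SE vector of one path.

    For transition j between u = node j-1 and v = node j, the supporting
    predications (either orientation) are grouped by the semantic type they
    attribute to u; each group contributes its distinct-article count to
    nod{j}_{type} and to rel{j}_{relation}. Untyped support (article nodes,
    ontology edges) contributes to the relation feature only. With
    ``binary=True`` the per-path counts are clipped to {0, 1}, matching the
    presence/absence reading of the encoding.
    """
    if path.n > layout.max_len:
        raise ValueError(f"path length {path.n} exceeds layout max_len {layout.max_len}")
    values = np.zeros(layout.total_len, dtype=np.int64)
    for j in range(1, path.n + 1):
        u, v = path.node_ids[j - 1], path.node_ids[j]
        rel = path.relations[j - 1]
        preds = graph.edge_predications(u, rel, v)
        if not preds:
            raise ValueError(f"edge ({u!r}, {rel!r}, {v!r}) absent from graph")
        typed_articles: dict[str, set[str]] = {}
        untyped_articles: set[str] = set()
        for p in preds:
            u_type = p.subject_type if p.subject_id == u else p.object_type
            if u_type:
                typed_articles.setdefault(u_type, set()).add(p.article_id)
            else:
                untyped_articles.add(p.article_id)
        rel_count = len(untyped_articles)
        for u_type, articles in typed_articles.items():
            rel_count += len(articles)
            if u_type in layout.type_vocab:
                values[layout.nod_index(j, u_type)] += len(articles)
            else:
                logger.warning("semantic type %r outside vocabulary; skipped", u_type)
        if rel in layout.rel_vocab:
            values[layout.rel_index(j, rel)] += rel_count
        else:
            logger.warning("relation %r outside scored vocabulary; skipped", rel)
    if binary:
        values = np.minimum(values, 1)
    return SEVector(values, layout)


def aggregate_se(vectors: list[SEVector], layout: SELayout | None = None) -> SEVector:
    """Element-wise sum of per-path SE vectors (zero vector for no paths)."""
    if not vectors:
        if layout is None:
            raise ValueError("layout required to aggregate an empty path set")
        return SEVector(np.zeros(layout.total_len, dtype=np.int64), layout)
    layout = layout or vectors[0].layout
    total = np.zeros(layout.total_len, dtype=np.int64)
    for vec in vectors:
        if not vec.layout.compatible(layout):
            raise ValueError("cannot aggregate SE vectors with mixed layouts")
        total += vec.values
    return SEVector(total, layout)


def encode_pair_paths(
    graph: KnowledgeGraph,
    paths,
    layout: SELayout,
    binary: bool = False,
) -> SEVector:
    """Aggregate SE vector over an iterable of paths (one drug-gene pair)."""
    return aggregate_se([encode_path(graph, p, layout, binary) for p in paths], layout)
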