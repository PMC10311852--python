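"""Data model and I/O for literature-derived knowledge graphs.

The graph is a provenance-aware multigraph: each edge is a *predication*,
a subject-relation-object triple extracted from one article (SemRep-style
semantic relations), or one of the auxiliary edge kinds MENTIONED_IN
(concept occurs in article), HAS_MESH (article is tagged with a MeSH
concept) and is_a (ontology taxonomy, no article provenance).

Edges are stored directed, as written, but exposed bidirectionally through
an ``orientation`` flag: downstream path features record only the relation
label, never the direction of traversal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources as importlib_resources
from pathlib import Path as FilePath
from typing import Iterable, Sequence

CONCEPT = "concept"
ARTICLE = "article"
FORWARD = "forward"
REVERSE = "reverse"

MENTIONED_IN = "MENTIONED_IN"
HAS_MESH = "HAS_MESH"
IS_A = "is_a"

TSV_COLUMNS = (
    "subject_id",
    "subject_type",
    "relation",
    "object_id",
    "object_type",
    "article_id",
)


class VocabularyError(ValueError):
    """A relation or semantic-type label is not in the configured vocabulary."""


class PredicationParseError(ValueError):
    """A predication file row is malformed."""


class GraphLookupError(KeyError):
    """A node id referenced by a query does not exist in the graph."""


class NodeKindConflictError(ValueError):
    """An id is used both as an article and as a concept."""


@dataclass(frozen=True)
class Predication:
    """One typed, article-attributed triple of the knowledge graph."""

    subject_id: str
    subject_type: str
    relation: str
    object_id: str
    object_type: str
    article_id: str

    def as_row(self) -> tuple[str, ...]:
        return (
            self.subject_id,
            self.subject_type,
            self.relation,
            self.object_id,
            self.object_type,
            self.article_id,
        )


class SemanticTypeVocabulary:
    """Ordered list of semantic-type codes; the order fixes the SE layout."""

    def __init__(self, codes: Sequence[str]):
        codes = tuple(codes)
        if len(set(codes)) != len(codes):
            raise VocabularyError("semantic type codes must be unique")
        self.codes = codes
        self.index = {c: i for i, c in enumerate(codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.index


class RelationVocabulary:
    """Ordered scored relation labels plus auxiliary graph-only labels.

    The *scored* labels are the ones eligible for semantic-encoding and
    path-ranking features; auxiliary labels (is_a by default) are admitted
    in the graph but carry no feature slot.
    """

    def __init__(self, scored: Sequence[str], auxiliary: Sequence[str] = ()):
        scored = tuple(scored)
        auxiliary = tuple(auxiliary)
        all_labels = scored + auxiliary
        if len(set(all_labels)) != len(all_labels):
            raise VocabularyError("relation labels must be unique")
        self.scored = scored
        self.auxiliary = auxiliary
        self.index = {r: i for i, r in enumerate(scored)}
        self._all = frozenset(all_labels)

    @property
    def all_labels(self) -> frozenset[str]:
        return self._all

    def __len__(self) -> int:
        return len(self.scored)

    def __contains__(self, label: str) -> bool:
        return label in self.index


def default_vocabularies() -> tuple[SemanticTypeVocabulary, RelationVocabulary]:
    """Load the bundled vocabularies (127 MetaMap types, 35 scored relations)."""
    ref = importlib_resources.files("blgpa.resources").joinpath("vocab.json")
    with ref.open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    return (
        SemanticTypeVocabulary(data["semantic_types"]),
        RelationVocabulary(data["relations"], data.get("auxiliary_relations", ())),
    )


def load_vocabularies(path: str | FilePath) -> tuple[SemanticTypeVocabulary, RelationVocabulary]:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return (
        SemanticTypeVocabulary(data["semantic_types"]),
        RelationVocabulary(data["relations"], data.get("auxiliary_relations", ())),
    )


class KnowledgeGraph:
    """Multigraph of concept and article nodes with per-article predications.

    Node kinds are inferred: any id appearing as a MENTIONED_IN object or a
    HAS_MESH subject is an article; every other position implies a concept.
    An id with conflicting evidence raises :class:`NodeKindConflictError`.
    """

    def __init__(
        self,
        predications: Iterable[Predication],
        rel_vocab: RelationVocabulary | None = None,
        allow_unknown_relations: bool = False,
    ):
        if rel_vocab is None:
            _, rel_vocab = default_vocabularies()
        self.rel_vocab = rel_vocab

        seen: set[tuple[str, ...]] = set()
        preds: list[Predication] = []
        for p in predications:
            if p.relation not in rel_vocab.all_labels and not allow_unknown_relations:
                raise VocabularyError(
                    f"unknown relation label {p.relation!r}; pass "
                    f"allow_unknown_relations=True to admit it as auxiliary"
                )
            key = p.as_row()
            if key in seen:
                continue
            seen.add(key)
            preds.append(p)
        self.predications: tuple[Predication, ...] = tuple(preds)

        article_ids: set[str] = set()
        concept_ids: set[str] = set()
        for p in self.predications:
            if p.relation == MENTIONED_IN:
                concept_ids.add(p.subject_id)
                article_ids.add(p.object_id)
            elif p.relation == HAS_MESH:
                article_ids.add(p.subject_id)
                concept_ids.add(p.object_id)
            else:
                concept_ids.add(p.subject_id)
                concept_ids.add(p.object_id)
        clash = article_ids & concept_ids
        if clash:
            raise NodeKindConflictError(
                f"ids used both as article and concept: {sorted(clash)[:5]}"
            )
        self.node_kinds: dict[str, str] = {}
        for nid in concept_ids:
            self.node_kinds[nid] = CONCEPT
        for nid in article_ids:
            self.node_kinds[nid] = ARTICLE

        # adjacency: node -> sorted distinct (relation, neighbor, orientation)
        adj: dict[str, set[tuple[str, str, str]]] = {n: set() for n in self.node_kinds}
        # edge index: (subject, relation, object) as stored -> predications
        edges: dict[tuple[str, str, str], list[Predication]] = {}
        for p in self.predications:
            adj[p.subject_id].add((p.relation, p.object_id, FORWARD))
            adj[p.object_id].add((p.relation, p.subject_id, REVERSE))
            edges.setdefault((p.subject_id, p.relation, p.object_id), []).append(p)
        self._adjacency = {n: tuple(sorted(v)) for n, v in adj.items()}
        self._edges = edges

    # -- basic queries ----------------------------------------------------

    @property
    def nodes(self) -> dict[str, str]:
        return self.node_kinds

    def has_node(self, node_id: str) -> bool:
        return node_id in self.node_kinds

    def _require(self, node_id: str) -> None:
        if node_id not in self.node_kinds:
            raise GraphLookupError(f"unknown node id {node_id!r}")

    def node_kind(self, node_id: str) -> str:
        self._require(node_id)
        return self.node_kinds[node_id]

    def neighbors(self, node_id: str) -> tuple[tuple[str, str, str], ...]:
        """Distinct (relation, neighbor, orientation) entries, sorted."""
        self._require(node_id)
        return self._adjacency[node_id]

    def degree(self, node_id: str) -> int:
        self._require(node_id)
        return len(self._adjacency[node_id])

    def edge_predications(self, u: str, relation: str, v: str) -> list[Predication]:
        """All predications realising relation between u and v, either orientation."""
        out = list(self._edges.get((u, relation, v), ()))
        if u != v:
            out += self._edges.get((v, relation, u), ())
        return out

    def triple_support(self, subject_id: str, relation: str, object_id: str) -> int:
        """Number of distinct articles asserting the triple (either orientation).

        Ontology edges with empty article_id count as one pseudo-article,
        so asserted provenance-free facts have support 1.
        """
        self._require(subject_id)
        self._require(object_id)
        arts = {p.article_id for p in self.edge_predications(subject_id, relation, object_id)}
        return len(arts)

    def stats(self) -> dict[str, int]:
        kinds = list(self.node_kinds.values())
        return {
            "nodes": len(self.node_kinds),
            "concepts": kinds.count(CONCEPT),
            "articles": kinds.count(ARTICLE),
            "predications": len(self.predications),
            "distinct_triples": len(self._edges),
            "provenance_articles": len(
                {p.article_id for p in self.predications if p.article_id}
            ),
        }


# -- file I/O -------------------------------------------------------------


def load_predications(
    path: str | FilePath,
    rel_vocab: RelationVocabulary | None = None,
    allow_unknown_relations: bool = False,
) -> KnowledgeGraph:
    """Read a predication TSV (header + 6 columns) into a KnowledgeGraph.

    Raises :class:`PredicationParseError` with the line number on malformed
    rows and :class:`VocabularyError` on relation labels outside the
    vocabulary (unless ``allow_unknown_relations``).
    """
    preds: list[Predication] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PredicationParseError(f"{path}: empty file") from None
        if tuple(header) != TSV_COLUMNS:
            raise PredicationParseError(
                f"{path}:1: expected header {list(TSV_COLUMNS)}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 6:
                raise PredicationParseError(
                    f"{path}:{lineno}: expected 6 columns, got {len(row)}"
                )
            preds.append(Predication(*row))
    return KnowledgeGraph(preds, rel_vocab, allow_unknown_relations)


def write_predications(graph: KnowledgeGraph, path: str | FilePath) -> None:
    """Write the graph's predication multiset as a TSV (stable row order)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for p in graph.predications:
            writer.writerow(p.as_row())
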