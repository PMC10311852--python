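"""Bounded enumeration of simple drug-to-gene paths.

Traversal is orientation-agnostic: a stored edge s-r->o can be walked in
either direction, and a path records only the relation labels. Article
nodes are admissible intermediates (MENTIONED_IN chains need them).
Hub mitigation is exposed as two optional caps: ``degree_cap`` skips
high-degree intermediate nodes, ``path_cap`` truncates enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .kg_model import KnowledgeGraph

logger = logging.getLogger(__name__)

DEFAULT_PATH_CAP = 100_000


@dataclass(frozen=True)
class Path:
    """A simple walk: n+1 node ids joined by n relation labels."""

    node_ids: tuple[str, ...]
    relations: tuple[str, ...]

    def __post_init__(self):
        if len(self.node_ids) != len(self.relations) + 1:
            raise ValueError("node/relation count mismatch")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("path must be simple (no repeated nodes)")

    @property
    def n(self) -> int:
        return len(self.relations)


@dataclass
class PathSet:
    """All enumerated paths for one drug-gene pair."""

    source: str
    target: str
    paths: list[Path] = field(default_factory=list)
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)


def enumerate_paths(
    graph: KnowledgeGraph,
    source: str,
    target: str,
    max_len: int,
    degree_cap: int | None = None,
    path_cap: int | None = DEFAULT_PATH_CAP,
) -> PathSet:
    """Depth-first enumeration of all simple paths of length <= max_len.

    Parallel edges with distinct relations yield distinct paths; parallel
    provenance (same endpoints and relation in several articles) collapses
    to one path. Output order is lexicographic by (node sequence, relation
    sequence).
    """
    if source == target:
        raise ValueError("source and target must differ")
    graph._require(source)
    graph._require(target)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    result = PathSet(source=source, target=target)

    def expand(node: str, nodes: list[str], rels: list[str]) -> bool:
        """Returns False when the path cap fired."""
        # distinct (relation, neighbor): orientations collapse
        steps = sorted({(nb, rel) for rel, nb, _ in graph.neighbors(node)})
        for nb, rel in steps:
            if nb == target:
                result.paths.append(
                    Path(tuple(nodes) + (nb,), tuple(rels) + (rel,))
                )
                if path_cap is not None and len(result.paths) >= path_cap:
                    result.truncated = True
                    return False
            elif len(rels) + 1 < max_len and nb not in nodes:
                if degree_cap is not None and graph.degree(nb) > degree_cap:
                    continue
                nodes.append(nb)
                rels.append(rel)
                ok = expand(nb, nodes, rels)
                nodes.pop()
                rels.pop()
                if not ok:
                    return False
        return True

    expand(source, [source], [])
    if result.truncated:
        logger.warning(
            "path enumeration for (%s, %s) truncated at %d paths", source, target, path_cap
        )
    result.paths.sort(key=lambda p: (p.node_ids, p.relations))
    return result
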