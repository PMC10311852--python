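"""Shared fixtures: the worked-example graph, random multigraphs, and the
planted-signal synthetic benchmark (session-scoped; several tests share it)."""

from itertools import permutations, product

import pytest

from blgpa import (
    KnowledgeGraph,
    Predication,
    RelationVocabulary,
    SamplingConfig,
    SyntheticConfig,
    cross_validate,
    enumerate_paths,
    generate_kg,
)
from blgpa.path_search import Path, PathSet
from blgpa.synthetic_kg import fig3_fixture


@pytest.fixture(scope="session")
def fig3():
    """(graph, (drug, gene), manifest) of the deterministic worked example."""
    return fig3_fixture()


@pytest.fixture(scope="session")
def planted():
    """Default planted-chain benchmark: 200/200 pairs, p_pos=0.9 / p_neg=0.1."""
    config = SyntheticConfig(seed=0)
    graph, pairs, manifest = generate_kg(config)
    path_sets = {
        (d, g): enumerate_paths(graph, d, g, 3) for d, g, _ in pairs
    }
    return graph, pairs, manifest, path_sets


@pytest.fixture(scope="session")
def planted_report(planted):
    """One 10-fold cross-validated evaluation of the planted benchmark."""
    graph, pairs, _, path_sets = planted
    return cross_validate(
        graph, pairs, SamplingConfig(seed=0), path_sets=path_sets
    )


# -- independent oracles ---------------------------------------------------


def relations_between(graph: KnowledgeGraph, u: str, v: str) -> set[str]:
    return {rel for rel, nb, _ in graph.neighbors(u) if nb == v}


def brute_force_paths(graph: KnowledgeGraph, source, target, max_len) -> PathSet:
    """Exhaustive oracle: all node sequences, filtered to valid simple paths."""
    others = sorted(n for n in graph.nodes if n not in (source, target))
    found = []
    for length in range(1, max_len + 1):
        for mids in permutations(others, length - 1):
            seq = (source,) + mids + (target,)
            options = [
                sorted(relations_between(graph, a, b)) for a, b in zip(seq, seq[1:])
            ]
            if any(not opts for opts in options):
                continue
            for rels in product(*options):
                found.append(Path(seq, tuple(rels)))
    found.sort(key=lambda p: (p.node_ids, p.relations))
    return PathSet(source=source, target=target, paths=found)


@pytest.fixture(scope="session")
def tiny_vocab():
    return RelationVocabulary(["r", "s", "t"])


def random_graph(rng, tiny_vocab, n_nodes=None, n_edges=None) -> KnowledgeGraph:
    """Random directed relation-multigraph on <= 12 nodes (no article nodes)."""
    n = n_nodes or int(rng.integers(4, 13))
    nodes = [f"n{i}" for i in range(n)]
    m = n_edges or int(rng.integers(n, 3 * n))
    preds = []
    for _ in range(m):
        u, v = rng.choice(n, size=2, replace=False)
        rel = ["r", "s", "t"][int(rng.integers(3))]
        preds.append(
            Predication(nodes[u], "aapp", rel, nodes[v], "dsyn", f"p{int(rng.integers(4))}")
        )
    return KnowledgeGraph(preds, tiny_vocab)
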