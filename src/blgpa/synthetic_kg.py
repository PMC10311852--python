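"""Synthetic literature-style knowledge graphs with planted chain signal.

The generator emulates the statistical structure the path-analysis method
exploits in real literature graphs: positive drug-gene pairs are
preferentially connected by short planted relational chains (for example
INTERACTS_WITH -> TREATS -> AFFECTS) against a background of random
semantic predications and concept-article mention edges. Labels are
assigned before wiring, so the ground-truth manifest records exactly which
planted paths exist for which pair.

Also ships the deterministic worked-example fixture: a drug and a gene
joined by exactly two length-3 paths, one purely semantic and one running
through an article via mention edges.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .kg_model import (
    HAS_MESH,
    MENTIONED_IN,
    KnowledgeGraph,
    Predication,
    RelationVocabulary,
    default_vocabularies,
)
from .path_ranking import ChainList, ChainScore, RelationalChain

DRUG_TYPE = "phsu"
GENE_TYPE = "gngm"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic benchmark.

    ``planted_chains`` entries are (relations, p_pos, p_neg): per pair and
    per chain, the class-conditional probability that a fresh path
    realising the chain is wired in. ``article_support_mean`` is the mean
    of the geometric distribution over per-triple distinct-article counts.
    ``intermediate_reuse`` is the probability that a planted path reuses an
    existing concept instead of minting a new intermediate, which creates
    mild hubness.
    """

    n_drugs: int = 20
    n_genes: int = 20
    n_concepts: int = 1000
    n_articles: int = 600
    planted_chains: Sequence[tuple[RelationalChain, float, float]] = (
        (("INTERACTS_WITH", "TREATS", "AFFECTS"), 0.9, 0.1),
    )
    background_edge_rate: float = 2.0
    mention_rate: float = 2.0
    has_mesh_rate: float = 0.5
    article_support_mean: float = 2.0
    pos_fraction: float = 0.5
    intermediate_reuse: float = 0.3
    concept_types: Sequence[str] = ("dsyn", "neop", "aapp", "topp", "celf", "patf")
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_genes, self.n_concepts) < 1:
            raise ValueError("node counts must be positive")
        if self.n_articles < 1 and (self.mention_rate > 0 or self.has_mesh_rate > 0):
            raise ValueError("mention/HAS_MESH noise requires at least one article")
        for chain, p_pos, p_neg in self.planted_chains:
            if not (0.0 <= p_pos <= 1.0 and 0.0 <= p_neg <= 1.0):
                raise ValueError(f"chain probabilities outside [0,1] for {chain}")
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ValueError("pos_fraction outside [0,1]")
        if not 0.0 <= self.intermediate_reuse <= 1.0:
            raise ValueError("intermediate_reuse outside [0,1]")
        if self.article_support_mean < 1.0:
            raise ValueError("article_support_mean must be >= 1")


def generate_kg(
    config: SyntheticConfig,
    rel_vocab: RelationVocabulary | None = None,
) -> tuple[KnowledgeGraph, list[tuple[str, str, int]], dict]:
    """Generate (graph, labeled pairs, ground-truth manifest), reproducibly.

    Warns (in the manifest) when no planted chain separates the classes.
    """
    config.validate()
    if rel_vocab is None:
        _, rel_vocab = default_vocabularies()
    rng = np.random.default_rng(config.seed)

    drugs = [f"D{i}" for i in range(config.n_drugs)]
    genes = [f"G{i}" for i in range(config.n_genes)]
    concepts = [f"C{i}" for i in range(config.n_concepts)]
    articles = [f"A{i}" for i in range(config.n_articles)]
    node_type: dict[str, str] = {d: DRUG_TYPE for d in drugs}
    node_type.update({g: GENE_TYPE for g in genes})
    ctypes = list(config.concept_types)
    for c in concepts:
        node_type[c] = ctypes[int(rng.integers(len(ctypes)))]

    pairs_all = [(d, g) for d in drugs for g in genes]
    n_pos = round(config.pos_fraction * len(pairs_all))
    pos_idx = set(rng.choice(len(pairs_all), size=n_pos, replace=False).tolist())
    pairs = [(d, g, int(i in pos_idx)) for i, (d, g) in enumerate(pairs_all)]

    preds: list[Predication] = []
    seen_rows: set[tuple[str, ...]] = set()
    support_p = 1.0 / config.article_support_mean
    n_intermediates = 0

    def add_semantic(s: str, rel: str, o: str) -> None:
        k = min(int(rng.geometric(support_p)), config.n_articles)
        arts = rng.choice(config.n_articles, size=k, replace=False)
        for a in sorted(arts.tolist()):
            row = (s, node_type[s], rel, o, node_type[o], articles[a])
            if row not in seen_rows:
                seen_rows.add(row)
                preds.append(Predication(*row))

    def add_mention(concept: str, article: str) -> None:
        row = (concept, node_type[concept], MENTIONED_IN, article, "", article)
        if row not in seen_rows:
            seen_rows.add(row)
            preds.append(Predication(*row))

    def add_mesh(article: str, concept: str) -> None:
        row = (article, "", HAS_MESH, concept, node_type[concept], article)
        if row not in seen_rows:
            seen_rows.add(row)
            preds.append(Predication(*row))

    article_set = set(articles)

    def wire_chain(drug: str, gene: str, chain: RelationalChain) -> list[str]:
        """Wire one fresh path drug -> ... -> gene realising the chain."""
        nonlocal n_intermediates
        nodes = [drug]
        for i, rel in enumerate(chain):
            last = i == len(chain) - 1
            prev = nodes[-1]
            prev_is_article = prev in article_set
            if last:
                nxt = gene
                if rel in (MENTIONED_IN, HAS_MESH) and not prev_is_article:
                    raise ValueError(
                        f"chain {chain} would attach {rel} between two concepts"
                    )
            elif rel == MENTIONED_IN and not prev_is_article:
                nxt = articles[int(rng.integers(config.n_articles))]
            elif rel == HAS_MESH and not prev_is_article:
                nxt = articles[int(rng.integers(config.n_articles))]
            elif rng.random() < config.intermediate_reuse:
                nxt = None
                for _ in range(10):
                    cand = concepts[int(rng.integers(config.n_concepts))]
                    if cand not in nodes:
                        nxt = cand
                        break
                if nxt is None:
                    nxt = f"X{n_intermediates}"
                    n_intermediates += 1
                    node_type[nxt] = ctypes[int(rng.integers(len(ctypes)))]
            else:
                nxt = f"X{n_intermediates}"
                n_intermediates += 1
                node_type[nxt] = ctypes[int(rng.integers(len(ctypes)))]
            if rel == MENTIONED_IN:
                if prev_is_article:
                    add_mention(nxt, prev)
                else:
                    add_mention(prev, nxt)
            elif rel == HAS_MESH:
                if prev_is_article:
                    add_mesh(prev, nxt)
                else:
                    add_mesh(nxt, prev)
            else:
                add_semantic(prev, rel, nxt)
            nodes.append(nxt)
        return nodes

    manifest_pairs: dict[str, dict] = {}
    for d, g, y in pairs:
        planted: list[dict] = []
        for chain, p_pos, p_neg in config.planted_chains:
            p = p_pos if y == 1 else p_neg
            if rng.random() < p:
                nodes = wire_chain(d, g, tuple(chain))
                planted.append({"chain": list(chain), "nodes": nodes})
        manifest_pairs[f"{d}|{g}"] = {"label": y, "planted": planted}

    # background semantic noise over concepts, drugs and genes
    semantic_rels = [
        r for r in rel_vocab.scored if r not in (MENTIONED_IN, HAS_MESH)
    ]
    endpoints = concepts + drugs + genes
    for s in endpoints:
        for _ in range(int(rng.poisson(config.background_edge_rate))):
            o = endpoints[int(rng.integers(len(endpoints)))]
            if o == s:
                continue
            rel = semantic_rels[int(rng.integers(len(semantic_rels)))]
            add_semantic(s, rel, o)

    # mention and MeSH noise
    if config.n_articles:
        for s in endpoints:
            for _ in range(int(rng.poisson(config.mention_rate))):
                add_mention(s, articles[int(rng.integers(config.n_articles))])
        for a in articles:
            for _ in range(int(rng.poisson(config.has_mesh_rate))):
                add_mesh(a, concepts[int(rng.integers(config.n_concepts))])

    graph = KnowledgeGraph(preds, rel_vocab)
    informative = any(p_pos > p_neg for _, p_pos, p_neg in config.planted_chains)
    manifest = {
        "config": _config_dict(config),
        "pairs": manifest_pairs,
        "n_intermediates": n_intermediates,
        "node_counts": {
            "drugs": config.n_drugs,
            "genes": config.n_genes,
            "concepts": config.n_concepts,
            "articles": config.n_articles,
            "intermediates": n_intermediates,
        },
        "informative": informative,
    }
    if not informative:
        manifest["warning"] = "no planted chain separates the classes"
    return graph, pairs, manifest


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["planted_chains"] = [
        {"chain": list(c), "p_pos": pp, "p_neg": pn} for c, pp, pn in config.planted_chains
    ]
    return d


# -- deterministic worked-example fixture ---------------------------------


def fig3_fixture() -> tuple[KnowledgeGraph, tuple[str, str], dict]:
    """A drug-gene pair joined by exactly two length-3 paths.

    The drug (Gefitinib-like, type phsu) reaches the gene (ERBB3-like,
    type gngm) through (INTERACTS_WITH, TREATS, AFFECTS) and through
    (INTERACTS_WITH, MENTIONED_IN, MENTIONED_IN) — the second path runs
    into an article node and back out via the gene's own mention edge.
    Every edge has unit article support. The manifest lists the expected
    nonzero SE feature names and the conventional PR ranks (0 and 5) of
    the two chains.
    """
    drug, gene = "C1122962", "C0812265"  # Gefitinib, ERBB3
    rows = [
        # path 1: drug -IW-> kinase -TREATS-> carcinoma -AFFECTS-> gene
        (drug, DRUG_TYPE, "INTERACTS_WITH", "C_KINASE", "aapp", "PMID1"),
        ("C_KINASE", "aapp", "TREATS", "C_CARCINOMA", "neop", "PMID2"),
        ("C_CARCINOMA", "neop", "AFFECTS", gene, GENE_TYPE, "PMID3"),
        # path 2: drug -IW-> receptor -MENTIONED_IN-> article <-MENTIONED_IN- gene
        (drug, DRUG_TYPE, "INTERACTS_WITH", "C_RECEPTOR", "aapp", "PMID4"),
        ("C_RECEPTOR", "aapp", MENTIONED_IN, "PMID9", "", "PMID9"),
        (gene, GENE_TYPE, MENTIONED_IN, "PMID9", "", "PMID9"),
    ]
    graph = KnowledgeGraph([Predication(*r) for r in rows])
    manifest = {
        "pair": [drug, gene],
        "chains": {
            "PATH0": ["INTERACTS_WITH", "TREATS", "AFFECTS"],
            "PATH5": ["INTERACTS_WITH", "MENTIONED_IN", "MENTIONED_IN"],
        },
        "expected_se_nonzero": {
            "rel1_INTERACTS_WITH": 2,
            "rel2_TREATS": 1,
            "rel3_AFFECTS": 1,
            "rel2_MENTIONED_IN": 1,
            "rel3_MENTIONED_IN": 1,
            "nod1_phsu": 2,
            "nod2_aapp": 2,
            "nod3_neop": 1,
        },
        "expected_pr_nonzero": {"PATH0": 1, "PATH5": 1},
    }
    return graph, (drug, gene), manifest


def fig3_chainlist() -> ChainList:
    """A six-entry chain list placing the fixture's chains at ranks 0 and 5.

    The intermediate ranks are filler chains that match no fixture path,
    mirroring the worked example's 'zero everywhere else' reading.
    """
    filler = [
        ("TREATS",),
        ("AFFECTS",),
        ("INTERACTS_WITH", "INTERACTS_WITH"),
        ("TREATS", "MENTIONED_IN", "MENTIONED_IN"),
    ]
    scores = [ChainScore(("INTERACTS_WITH", "TREATS", "AFFECTS"), 1.0, 0.0)]
    scores += [
        ChainScore(c, 0.5 - 0.05 * i, 0.0) for i, c in enumerate(filler)
    ]
    scores.append(
        ChainScore(("INTERACTS_WITH", "MENTIONED_IN", "MENTIONED_IN"), 0.2, 0.0)
    )
    return ChainList(scores)


def write_simulation(outdir, graph: KnowledgeGraph, pairs, manifest) -> None:
    """Write predications.tsv, pairs.csv and manifest.json into outdir."""
    import csv
    from pathlib import Path as FilePath

    from .kg_model import write_predications

    outdir = FilePath(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_predications(graph, outdir / "predications.tsv")
    with open(outdir / "pairs.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["drug_id", "gene_id", "label"])
        writer.writerows(pairs)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
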