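"""Synthetic knowledge graphs with planted, recoverable signal.

Two substrates for development and testing:

* :func:`worked_example_graph` — a small, hand-specified graph (G0) of four
  genes, a trait, a pathway, a biological process and two publications whose
  motif matches, distances and scores can be checked by hand.
* :func:`generate_kg` — a seeded random generator that emits genes with
  genomic positions, background evidence nodes carrying keyword-free text,
  and *planted* motif-conforming evidence paths whose terminal node text
  contains a chosen keyword.  The accompanying :class:`GroundTruth` records
  exactly which nodes/edges were planted, so ranking recovery can be asserted
  against construction rather than against the ranker itself.

Background text is drawn from a fixed plant-biology vocabulary; a planted
keyword colliding with that vocabulary is a configuration error, keeping the
ground truth unambiguous.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ArgumentError, ConfigError
from .kg_model import ConceptNode, KnowledgeGraph, RelationEdge
from .motif import SemanticMotif, parse_motifs

#: Motif set used by the worked example and as the generator default:
#: direct trait co-occurrence, ortholog-mediated pathway membership,
#: ortholog-mediated process annotation, and direct publication links.
CANONICAL_MOTIF_TEXT = """\
# canonical evidence-path patterns
M1: Gene -[cooccurs_with]-> Trait
M2: Gene -[ortholog]- Gene -[participates_in]-> Pathway
M3: Gene -[ortholog]- Gene -[has_annotation]-> BioProc
M4: Gene -[published_in]-> Publication
"""

#: Keyword-free background vocabulary for generated node text.
BACKGROUND_VOCAB = (
    "root", "leaf", "xylem", "phloem", "stomata", "tiller", "anther",
    "awn", "spike", "grain", "height", "yield", "photosynthesis",
    "chlorophyll", "meristem", "senescence", "lignin", "cuticle",
    "trichome", "vernalization", "culm", "pollen", "endosperm",
)


def canonical_motifs() -> list[SemanticMotif]:
    return parse_motifs(CANONICAL_MOTIF_TEXT)


def worked_example_graph() -> KnowledgeGraph:
    """The fixed worked-example graph G0 (9 nodes, 5 edges).

    Four genes (G1, G2, G3 and the cross-species ortholog O1), the trait
    "seed dormancy", the pathway "flavonoid biosynthesis", the process
    "seed germination" and two unconnected publications.  Byte-identical
    across calls.
    """
    nodes = [
        ConceptNode("G1", "Gene", {"name": "G1", "taxon": "Triticum aestivum",
                                   "chromosome": "4", "start": 9_950_000, "end": 9_960_000}),
        ConceptNode("G2", "Gene", {"name": "G2", "taxon": "Triticum aestivum",
                                   "chromosome": "4", "start": 10_200_000, "end": 10_210_000}),
        ConceptNode("G3", "Gene", {"name": "G3", "taxon": "Triticum aestivum",
                                   "chromosome": "1", "start": 5_000_000, "end": 5_004_000}),
        ConceptNode("O1", "Gene", {"name": "O1", "taxon": "Saccharomyces cerevisiae"}),
        ConceptNode("T1", "Trait", {"name": "seed dormancy"}),
        ConceptNode("X1", "Pathway", {"name": "flavonoid biosynthesis"}),
        ConceptNode("B1", "BioProc", {"name": "seed germination"}),
        ConceptNode("P1", "Publication", {"name": "Regulation of germination timing", "year": 2018}),
        ConceptNode("P2", "Publication", {"name": "Anthocyanin pigment pathways", "year": 2020}),
    ]
    edges = [
        RelationEdge("e1", "G1", "T1", "cooccurs_with"),
        RelationEdge("e2", "G2", "T1", "cooccurs_with"),
        RelationEdge("e3", "G1", "O1", "ortholog"),
        RelationEdge("e4", "O1", "X1", "participates_in"),
        RelationEdge("e5", "O1", "B1", "has_annotation"),
    ]
    graph = KnowledgeGraph()
    for node in nodes:
        graph.add_node(node)
    for edge in edges:
        graph.add_edge(edge)
    graph.rebuild_indices()
    return graph


@dataclass
class GeneratorConfig:
    """Conditions of a generated study: sizes, signal and noise levels."""

    n_genes: int = 20
    n_traits: int = 10
    n_publications: int = 15
    n_pathways: int = 5
    motif_text: str = CANONICAL_MOTIF_TEXT
    #: (gene id, keyword, number of planted evidence paths) triples
    planted: Sequence[tuple[str, str, int]] = ()
    year_range: tuple[int, int] = (2000, 2020)
    background_edge_prob: float = 0.05
    n_chromosomes: int = 3
    chromosome_length: int = 40_000_000
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_traits, self.n_publications, self.n_pathways) < 0:
            raise ConfigError("counts must be non-negative")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigError("background_edge_prob must lie in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError("year_range must be (min, max)")


@dataclass
class PlantedEvidence:
    gene_id: str
    keyword: str
    node_ids: list[list[str]] = field(default_factory=list)  # one list per path
    edge_ids: list[list[str]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """What was planted where, and who should win each keyword search."""

    planted: dict[str, PlantedEvidence] = field(default_factory=dict)
    #: keyword → set of gene ids expected to outrank all background genes
    expected_top: dict[str, set[str]] = field(default_factory=dict)
    background_genes: set[str] = field(default_factory=set)


def _gene_id(i: int) -> str:
    return f"G{i + 1:03d}"


def _background_text(rng: np.random.Generator, n_words: int = 3) -> str:
    words = rng.choice(len(BACKGROUND_VOCAB), size=n_words, replace=True)
    return " ".join(BACKGROUND_VOCAB[w] for w in words)


def generate_kg(config: GeneratorConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a graph and its ground truth; identical output per seed."""
    config.validate()
    motifs = parse_motifs(config.motif_text)
    vocab_tokens = set(BACKGROUND_VOCAB)
    for _, keyword, _ in config.planted:
        if set(keyword.lower().split()) & vocab_tokens:
            raise ConfigError(
                f"planted keyword {keyword!r} collides with the background vocabulary"
            )
    rng = np.random.default_rng(config.seed)
    graph = KnowledgeGraph()
    truth = GroundTruth()

    gene_ids = [_gene_id(i) for i in range(config.n_genes)]
    for gid in gene_ids:
        chrom = str(int(rng.integers(1, config.n_chromosomes + 1)))
        start = int(rng.integers(1, config.chromosome_length))
        length = int(rng.integers(1_000, 10_000))
        graph.add_node(
            ConceptNode(
                gid,
                "Gene",
                {
                    "name": gid,
                    "chromosome": chrom,
                    "start": start,
                    "end": start + length,
                },
            )
        )
    trait_ids = [f"T{i + 1:03d}" for i in range(config.n_traits)]
    for tid in trait_ids:
        graph.add_node(ConceptNode(tid, "Trait", {"name": _background_text(rng)}))
    pathway_ids = [f"PW{i + 1:03d}" for i in range(config.n_pathways)]
    for pid in pathway_ids:
        graph.add_node(ConceptNode(pid, "Pathway", {"name": _background_text(rng)}))
    pub_ids = [f"P{i + 1:03d}" for i in range(config.n_publications)]
    lo, hi = config.year_range
    for pid in pub_ids:
        graph.add_node(
            ConceptNode(
                pid,
                "Publication",
                {"name": _background_text(rng, 5), "year": int(rng.integers(lo, hi + 1))},
            )
        )

    edge_counter = 0

    def add_edge(src: str, dst: str, etype: str) -> str:
        nonlocal edge_counter
        edge_counter += 1
        eid = f"e{edge_counter:05d}"
        graph.add_edge(RelationEdge(eid, src, dst, etype))
        return eid

    # background wiring: each pair wired independently at the noise rate
    p = config.background_edge_prob
    for gid in gene_ids:
        for tid in trait_ids:
            if rng.random() < p:
                add_edge(gid, tid, "cooccurs_with")
        for pid in pub_ids:
            if rng.random() < p:
                add_edge(gid, pid, "published_in")
        for pwid in pathway_ids:
            if rng.random() < p:
                add_edge(gid, pwid, "participates_in")
        if len(gene_ids) > 1 and rng.random() < p:
            partner = gene_ids[int(rng.integers(0, len(gene_ids)))]
            if partner != gid:
                add_edge(gid, partner, "ortholog")

    # planted evidence: motif-conforming paths with keyword-bearing terminals
    planted_gene_ids = {g for g, _, _ in config.planted}
    missing = planted_gene_ids - set(gene_ids)
    if missing:
        raise ConfigError(f"planted genes not generated: {sorted(missing)}")
    aux_counter = 0
    plant_motifs = [m for m in motifs if m.id in ("M1", "M3", "M4")] or motifs
    for gid, keyword, n_paths in config.planted:
        record = PlantedEvidence(gene_id=gid, keyword=keyword)
        for j in range(n_paths):
            motif = plant_motifs[j % len(plant_motifs)]
            nodes = [gid]
            edges = []
            current = gid
            for k, step in enumerate(motif.steps):
                aux_counter += 1
                terminal = k == len(motif.steps) - 1
                new_id = f"S{aux_counter:04d}"
                text = (
                    f"{keyword} associated {step.target_type.lower()} {aux_counter}"
                    if terminal
                    else _background_text(rng)
                )
                props: dict = {"name": text}
                if step.target_type == "Publication":
                    props["year"] = int(rng.integers(lo, hi + 1))
                if step.target_type == "Gene":
                    props["name"] = new_id  # helper orthologs carry no signal
                graph.add_node(ConceptNode(new_id, step.target_type, props))
                rel = sorted(step.relation_types)[0]
                if step.direction == "in":
                    eid = add_edge(new_id, current, rel)
                else:
                    eid = add_edge(current, new_id, rel)
                nodes.append(new_id)
                edges.append(eid)
                current = new_id
            record.node_ids.append(nodes)
            record.edge_ids.append(edges)
        truth.planted[gid] = record
        truth.expected_top.setdefault(keyword, set()).add(gid)

    graph.rebuild_indices()
    truth.background_genes = set(graph.gene_ids()) - planted_gene_ids
    return graph, truth


def random_typed_graph(
    n_nodes: int,
    n_edges: int,
    seed: int,
    node_types: Sequence[str] = ("Gene", "Trait", "Pathway", "BioProc", "Publication"),
    edge_types: Sequence[str] = (
        "cooccurs_with",
        "ortholog",
        "participates_in",
        "has_annotation",
        "published_in",
    ),
) -> KnowledgeGraph:
    """An arbitrary small typed multigraph (for exhaustive-oracle testing).

    At least one Gene node is guaranteed; self-loops and parallel edges may
    occur, which is intentional — the matcher must handle both.
    """
    if n_nodes < 1:
        raise ArgumentError("need at least one node")
    rng = np.random.default_rng(seed)
    graph = KnowledgeGraph()
    for i in range(n_nodes):
        ntype = "Gene" if i == 0 else node_types[int(rng.integers(0, len(node_types)))]
        graph.add_node(ConceptNode(f"n{i:02d}", ntype, {"name": f"node {i}"}))
    ids = sorted(graph.nodes)
    for j in range(n_edges):
        src = ids[int(rng.integers(0, n_nodes))]
        dst = ids[int(rng.integers(0, n_nodes))]
        etype = edge_types[int(rng.integers(0, len(edge_types)))]
        graph.add_edge(RelationEdge(f"e{j:03d}", src, dst, etype))
    graph.rebuild_indices()
    return graph


DEFECT_KINDS = frozenset({"dangling_edge", "duplicate_id", "missing_position"})


def inject_defects(graph: KnowledgeGraph, kinds: set[str]) -> KnowledgeGraph:
    """Copy ``graph`` with exactly the named defects, for validation tests."""
    unknown = set(kinds) - DEFECT_KINDS
    if unknown:
        raise ArgumentError(f"unknown defect kinds: {sorted(unknown)}")
    node_recs, edge_recs = graph.to_records()
    node_recs = [dict(r, properties=dict(r["properties"])) for r in node_recs]
    edge_recs = [dict(r, properties=dict(r["properties"])) for r in edge_recs]
    if "dangling_edge" in kinds:
        edge_recs.append(
            {
                "id": "defect_dangling",
                "source": node_recs[0]["id"] if node_recs else "ZZ",
                "target": "ZZ_missing",
                "type": "cooccurs_with",
                "properties": {},
            }
        )
    if "duplicate_id" in kinds:
        if not node_recs:
            raise ArgumentError("cannot duplicate a node id in an empty graph")
        node_recs.append(dict(node_recs[0]))
    if "missing_position" in kinds:
        gene = next((r for r in node_recs if r["type"] == "Gene"), None)
        if gene is None:
            raise ArgumentError("no gene to strip a position from")
        for key in ("chromosome", "start", "end"):
            gene["properties"].pop(key, None)
    return KnowledgeGraph.from_records(node_recs, edge_recs)
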