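"""Independent reference implementations used only to cross-check results.

These deliberately take the slow, obvious route: enumerate every simple path
and check it against the pattern (instead of guided search), and recompute
scores by direct scans over the graph (instead of the prebuilt index).
"""

from __future__ import annotations

import math

import networkx as nx

from kgrank.index_rank import BooleanQuery, Term, Not, And, Or, node_document, tokenize
from kgrank.kg_model import KnowledgeGraph
from kgrank.motif import MatchedPath, SemanticMotif


# -- motif matching oracle --------------------------------------------------


def enumerate_simple_paths(graph: KnowledgeGraph, start: str, max_edges: int):
    """Every simple path (nodes, edges) from ``start`` with 1..max_edges edges."""
    out = []

    def walk(nodes, edges):
        if edges:
            out.append((tuple(nodes), tuple(edges)))
        if len(edges) == max_edges:
            return
        current = nodes[-1]
        for eid in graph.adjacency.get(current, ()):
            edge = graph.edges[eid]
            nxt = edge.target if edge.source == current else edge.source
            if nxt in nodes:
                continue
            walk(nodes + [nxt], edges + [eid])

    walk([start], [])
    return out


def path_matches_motif(
    graph: KnowledgeGraph, motif: SemanticMotif, nodes, edges
) -> bool:
    """Can the edge sequence be consumed by the motif's steps in order?"""
    steps = motif.steps

    def hop_ok(edge_idx, step) -> bool:
        edge = graph.edges[edges[edge_idx]]
        a, b = nodes[edge_idx], nodes[edge_idx + 1]
        if edge.type not in step.relation_types:
            return False
        if graph.nodes[b].type != step.target_type:
            return False
        if step.direction == "out":
            return edge.source == a and edge.target == b
        if step.direction == "in":
            return edge.target == a and edge.source == b
        return {edge.source, edge.target} == {a, b}

    def accept(edge_idx, step_idx, hops) -> bool:
        if step_idx == len(steps):
            return edge_idx == len(edges)
        step = steps[step_idx]
        if hops >= step.min_hops and accept(edge_idx, step_idx + 1, 0):
            return True
        if hops < step.max_hops and edge_idx < len(edges) and hop_ok(edge_idx, step):
            return accept(edge_idx + 1, step_idx, hops + 1)
        return False

    return accept(0, 0, 0)


def brute_force_matches(
    graph: KnowledgeGraph, gene: str, motif: SemanticMotif
) -> set[MatchedPath]:
    return {
        MatchedPath(motif.id, nodes, edges)
        for nodes, edges in enumerate_simple_paths(graph, gene, motif.max_length)
        if path_matches_motif(graph, motif, nodes, edges)
    }


# -- distance oracle --------------------------------------------------------


def bfs_distance_within_matched(graph: KnowledgeGraph, gcs) -> dict[str, int]:
    """Shortest-path lengths from the gene over the matched-edge subgraph."""
    g = nx.Graph()
    g.add_node(gcs.gene_id)
    for eid in gcs.edge_ids:
        edge = graph.edges[eid]
        g.add_edge(edge.source, edge.target)
    return nx.single_source_shortest_path_length(g, gcs.gene_id)


# -- scoring oracle ---------------------------------------------------------


def _phrase_count(doc, run):
    if len(run) == 1:
        return doc.count(run[0])
    k = len(run)
    return sum(1 for i in range(len(doc) - k + 1) if tuple(doc[i : i + k]) == run)


def _eval(node, doc) -> bool:
    if isinstance(node, Term):
        return _phrase_count(doc, node.tokens) > 0
    if isinstance(node, Not):
        return not _eval(node.child, doc)
    if isinstance(node, And):
        return all(_eval(c, doc) for c in node.children)
    if isinstance(node, Or):
        return any(_eval(c, doc) for c in node.children)
    raise TypeError(node)


def brute_force_gcs_nodes(graph: KnowledgeGraph, gene: str, motifs):
    """(node set, min edge-offset per node) from enumerated matches only."""
    nodes: set[str] = {gene}
    dist: dict[str, int] = {gene: 0}
    for motif in motifs:
        for path in brute_force_matches(graph, gene, motif):
            for offset, nid in enumerate(path.node_ids):
                nodes.add(nid)
                if nid != gene and (nid not in dist or offset < dist[nid]):
                    dist[nid] = offset
    return nodes, dist


def brute_force_scores(
    graph: KnowledgeGraph,
    motifs,
    query: BooleanQuery,
) -> dict[str, float]:
    """Per-gene scores recomputed with no index and no guided matcher."""
    genes = graph.gene_ids()
    per_gene = {g: brute_force_gcs_nodes(graph, g, motifs) for g in genes}
    member_count: dict[str, int] = {}
    for nodes, _ in per_gene.values():
        for nid in nodes:
            member_count[nid] = member_count.get(nid, 0) + 1
    n_gcs = len(genes)
    indexed = sorted(member_count)
    docs = {nid: tuple(node_document(graph.nodes[nid])) for nid in indexed}
    corpus_size = sum(1 for nid in indexed if docs[nid])

    def rel(nid: str) -> float:
        if query.is_empty:
            return 1.0
        doc = docs[nid]
        if not _eval(query.root, doc):
            return 0.0
        total = 0.0
        for term in query.positive_terms:
            tf = _phrase_count(doc, term.tokens)
            if tf:
                df = sum(1 for other in indexed if _phrase_count(docs[other], term.tokens) > 0)
                total += tf * (1.0 + math.log((corpus_size + 1) / (df + 1)))
        return total

    scores: dict[str, float] = {}
    for gene in genes:
        nodes, dist = per_gene[gene]
        total = 0.0
        for nid in nodes:
            r = rel(nid)
            if r > 0.0:
                d = 1.0 if dist[nid] == 0 else 1.0 / dist[nid]
                total += math.log(n_gcs / member_count[nid]) * d * r
        scores[gene] = total
    return scores


def region_scan(graph: KnowledgeGraph, chromosome: str, start: int, end: int):
    """Brute-force interval overlap over every gene node."""
    hits = []
    for node in graph.nodes.values():
        if node.type != "Gene" or not node.has_position():
            continue
        if node.chromosome == chromosome and not (node.end < start or node.start > end):
            hits.append(node)
    return sorted(hits, key=lambda n: (n.start, n.id))
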