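"""Semantic-motif path patterns: a line-based DSL, parser and graph matcher.

A semantic motif encodes a biologically plausible chain of evidence rooted at
a gene, e.g. gene → ortholog → GO annotation.  Each motif is a sequence of
typed steps; a step names the relation types it may traverse (alternatives
separated by ``|``), a direction, an optional hop range for variable-length
repetition, and the node type every hop of the step must land on.

Grammar (one motif per line, ``#`` starts a comment, optional ``label:``)::

    motif    := [label ":"] "Gene" step+
    step     := arrowL "[" reltypes hops? "]" arrowR nodetype
    arrowL   := "-" | "<-"
    arrowR   := "-" | "->"
    reltypes := ident ("|" ident)*
    hops     := "{" int "," int "}"

Direction is ``out`` when arrowR is ``->``, ``in`` when arrowL is ``<-`` and
``any`` when both are plain dashes.  Matching returns complete simple paths
only: no node is revisited, self-loops never match, and every hop of a
variable-length step must land on the step's target type (mirroring how
typed variable-length traversals behave in property-graph query languages).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ArgumentError, MotifSyntaxError, NodeLookupError
from .kg_model import KnowledgeGraph

#: Default cap on hops within a single variable-length step.
DEFAULT_STEP_HOP_CAP = 3
#: Default cap on the total length (in edges) of a matched path.
DEFAULT_TOTAL_EDGE_CAP = 6


@dataclass(frozen=True)
class MotifStep:
    relation_types: frozenset[str]
    direction: str  # 'out' | 'in' | 'any'
    min_hops: int
    max_hops: int
    target_type: str


@dataclass(frozen=True)
class SemanticMotif:
    id: str
    steps: tuple[MotifStep, ...]
    start_type: str = "Gene"

    @property
    def max_length(self) -> int:
        return sum(s.max_hops for s in self.steps)


@dataclass(frozen=True)
class MatchedPath:
    """One complete match: node ids (first = start gene) and the edges used."""

    motif_id: str
    node_ids: tuple[str, ...]
    edge_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.edge_ids)

    def validate(self, graph: KnowledgeGraph) -> None:
        """Assert the node/edge alternation and simple-path invariants."""
        if len(self.node_ids) != len(self.edge_ids) + 1:
            raise ArgumentError("path must alternate nodes and edges")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ArgumentError("path revisits a node")
        for i, eid in enumerate(self.edge_ids):
            edge = graph.edges[eid]
            pair = {self.node_ids[i], self.node_ids[i + 1]}
            if pair != {edge.source, edge.target}:
                raise ArgumentError(f"edge {eid!r} does not connect consecutive nodes")


_LABEL_RE = re.compile(r"^\s*(?P<label>[A-Za-z_][\w.-]*)\s*:\s*(?P<rest>.*)$")
_STEP_RE = re.compile(
    r"""\s*(?P<arrow_l><-|-)\s*
        \[\s*(?P<rels>[A-Za-z_]\w*(?:\s*\|\s*[A-Za-z_]\w*)*)\s*
        (?:\{\s*(?P<min>\d+)\s*,\s*(?P<max>\d+)\s*\})?\s*\]\s*
        (?P<arrow_r>->|-)\s*
        (?P<type>[A-Za-z_]\w*)""",
    re.VERBOSE,
)


def _parse_line(
    line: str, lineno: int, auto_id: str, step_cap: int, total_cap: int
) -> SemanticMotif:
    label_match = _LABEL_RE.match(line)
    if label_match:
        motif_id, body = label_match.group("label"), label_match.group("rest")
    else:
        motif_id, body = auto_id, line
    body = body.strip()
    if not body.startswith("Gene"):
        raise MotifSyntaxError(f"line {lineno}: motif must start with 'Gene'")
    pos = len("Gene")
    steps: list[MotifStep] = []
    while pos < len(body):
        m = _STEP_RE.match(body, pos)
        if m is None:
            raise MotifSyntaxError(
                f"line {lineno}: cannot parse step at column {pos + 1}: {body[pos:]!r}"
            )
        arrow_l, arrow_r = m.group("arrow_l"), m.group("arrow_r")
        if arrow_l == "<-" and arrow_r == "->":
            raise MotifSyntaxError(f"line {lineno}: step cannot point both ways")
        direction = "out" if arrow_r == "->" else "in" if arrow_l == "<-" else "any"
        rels = frozenset(r.strip() for r in m.group("rels").split("|"))
        min_hops = int(m.group("min")) if m.group("min") else 1
        max_hops = int(m.group("max")) if m.group("max") else min_hops
        if min_hops < 1 or min_hops > max_hops:
            raise MotifSyntaxError(
                f"line {lineno}: invalid hop range {{{min_hops},{max_hops}}}"
            )
        if max_hops > step_cap:
            raise MotifSyntaxError(
                f"line {lineno}: hop range exceeds per-step cap of {step_cap}"
            )
        steps.append(MotifStep(rels, direction, min_hops, max_hops, m.group("type")))
        pos = m.end()
    if not steps:
        raise MotifSyntaxError(f"line {lineno}: motif has no steps")
    motif = SemanticMotif(id=motif_id, steps=tuple(steps))
    if motif.max_length > total_cap:
        raise MotifSyntaxError(
            f"line {lineno}: motif length {motif.max_length} exceeds total cap {total_cap}"
        )
    return motif


def parse_motifs(
    text: str,
    step_cap: int = DEFAULT_STEP_HOP_CAP,
    total_cap: int = DEFAULT_TOTAL_EDGE_CAP,
) -> list[SemanticMotif]:
    """Parse motif DSL source into motifs; unlabeled motifs get ids M1..Mk."""
    motifs: list[SemanticMotif] = []
    counter = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        counter += 1
        motifs.append(_parse_line(line, lineno, f"M{counter}", step_cap, total_cap))
    return motifs


def _hop_targets(graph: KnowledgeGraph, node_id: str, step: MotifStep):
    """Yield (edge_id, neighbour) pairs legal for one hop of ``step``.

    Sorted by edge id, so traversal — and therefore every derived result —
    is deterministic.  Self-loops are excluded (a hop must change node).
    """
    for eid in graph.adjacency.get(node_id, ()):
        edge = graph.edges[eid]
        if edge.type not in step.relation_types:
            continue
        if edge.source == edge.target:
            continue
        if step.direction == "out":
            if edge.source != node_id:
                continue
            nbr = edge.target
        elif step.direction == "in":
            if edge.target != node_id:
                continue
            nbr = edge.source
        else:
            nbr = edge.other(node_id)
        if graph.nodes[nbr].type == step.target_type:
            yield eid, nbr


def match_motif(
    graph: KnowledgeGraph, gene: str, motif: SemanticMotif
) -> set[MatchedPath]:
    """All complete simple-path matches of ``motif`` rooted at ``gene``.

    Exhaustive depth-first search; the hop caps baked into the motif are the
    only pruning.  A path that satisfies all steps is reported even when a
    longer extension of the same variable-length step also matches (both are
    distinct complete matches).
    """
    if gene not in graph.nodes:
        raise NodeLookupError(f"gene {gene!r} not in graph")
    if graph.nodes[gene].type != motif.start_type:
        raise ArgumentError(
            f"node {gene!r} has type {graph.nodes[gene].type!r}, expected {motif.start_type!r}"
        )
    steps = motif.steps
    results: set[MatchedPath] = set()

    def walk(node: str, step_idx: int, hops: int, nodes: list[str], edges: list[str], visited: set[str]) -> None:
        step = steps[step_idx]
        if hops >= step.min_hops:
            if step_idx == len(steps) - 1:
                results.add(MatchedPath(motif.id, tuple(nodes), tuple(edges)))
            else:
                walk(node, step_idx + 1, 0, nodes, edges, visited)
        if hops < step.max_hops:
            for eid, nbr in _hop_targets(graph, node, step):
                if nbr in visited:
                    continue
                walk(
                    nbr,
                    step_idx,
                    hops + 1,
                    nodes + [nbr],
                    edges + [eid],
                    visited | {nbr},
                )

    walk(gene, 0, 0, [gene], [], {gene})
    return results


def motif_stats(
    graph: KnowledgeGraph, motifs: Iterable[SemanticMotif]
) -> pd.DataFrame:
    """Per-motif match statistics over every gene in the graph.

    Returns one row per motif (duplicates included as given) with the number
    of genes having at least one match and the total number of matched paths.
    """
    genes = graph.gene_ids()
    rows = []
    for motif in motifs:
        genes_with_match = 0
        total_paths = 0
        for gene in genes:
            paths = match_motif(graph, gene, motif)
            if paths:
                genes_with_match += 1
                total_paths += len(paths)
        rows.append(
            {
                "motif_id": motif.id,
                "genes_with_match": genes_with_match,
                "total_paths": total_paths,
            }
        )
    return pd.DataFrame(rows, columns=["motif_id", "genes_with_match", "total_paths"])
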