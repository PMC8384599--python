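"""Typed heterogeneous knowledge-graph model with kgjson I/O and region lookup.

The graph container is deliberately lightweight: nodes and edges are stored in
id-keyed maps, together with two derived indices (per-node incident edges and a
node-type index) that are always rebuildable from the primary maps.  Parallel
edges between the same node pair are allowed as long as they carry distinct
ids, which is essential for multi-evidence biological relations (a gene can
both co-occur with and regulate the same trait).

Coordinates are 1-based inclusive base pairs; a region query returns any gene
whose interval overlaps the query interval by at least one base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import networkx as nx

from .errors import ArgumentError, FormatError, GraphValidationError

#: Node types the default configuration knows about.  Unknown types are legal
#: (the model is meant to be extended per knowledge-graph build) but are
#: reported as validation warnings so typos surface early.
DEFAULT_NODE_TYPES = frozenset(
    {
        "Gene",
        "Protein",
        "Trait",
        "Phenotype",
        "SNP",
        "Publication",
        "BioProc",
        "CellComp",
        "MolFunc",
        "Pathway",
        "Enzyme",
    }
)

DEFAULT_EDGE_TYPES = frozenset(
    {
        "ortholog",
        "paralog",
        "cooccurs_with",
        "interacts_with",
        "regulates",
        "has_annotation",
        "participates_in",
        "has_variation",
        "published_in",
    }
)


@dataclass
class ConceptNode:
    """A typed entity in the knowledge graph.

    ``properties`` is a free-form string-keyed map; the keys the rest of the
    package interprets are ``name``, ``synonyms`` (list of strings),
    ``description``/``text``, ``year`` (publications), ``taxon`` (genes) and
    the genomic position triple ``chromosome``/``start``/``end``.
    """

    id: str
    type: str
    properties: dict[str, Any] = field(default_factory=dict)

    @property
    def chromosome(self) -> str | None:
        return self.properties.get("chromosome")

    @property
    def start(self) -> int | None:
        return self.properties.get("start")

    @property
    def end(self) -> int | None:
        return self.properties.get("end")

    def has_position(self) -> bool:
        return (
            self.chromosome is not None
            and self.start is not None
            and self.end is not None
        )


@dataclass
class RelationEdge:
    """A typed, directed relation between two concept nodes."""

    id: str
    source: str
    target: str
    type: str
    properties: dict[str, Any] = field(default_factory=dict)

    def other(self, node_id: str) -> str:
        if node_id == self.source:
            return self.target
        if node_id == self.target:
            return self.source
        raise ArgumentError(f"node {node_id!r} is not an endpoint of edge {self.id!r}")


@dataclass
class ValidationReport:
    """Findings of :func:`validate_graph`; the graph is valid iff no errors."""

    dangling_edges: list[str] = field(default_factory=list)
    duplicate_node_ids: list[str] = field(default_factory=list)
    duplicate_edge_ids: list[str] = field(default_factory=list)
    unknown_type_nodes: list[str] = field(default_factory=list)
    genes_without_position: list[str] = field(default_factory=list)

    @property
    def errors(self) -> list[str]:
        out = [f"edge {e!r} references a missing node" for e in self.dangling_edges]
        out += [f"duplicate node id {n!r}" for n in self.duplicate_node_ids]
        out += [f"duplicate edge id {e!r}" for e in self.duplicate_edge_ids]
        return out

    @property
    def warnings(self) -> list[str]:
        out = [f"node {n!r} has a type outside the vocabulary" for n in self.unknown_type_nodes]
        out += [f"gene {n!r} has no genomic position" for n in self.genes_without_position]
        return out

    @property
    def valid(self) -> bool:
        return not self.errors


class KnowledgeGraph:
    """Container for a typed multigraph with derived adjacency/type indices.

    Duplicate ids encountered while building from raw records are remembered
    (first record wins) so :func:`validate_graph` can report them even though
    the id-keyed maps cannot hold two entries.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, ConceptNode] = {}
        self.edges: dict[str, RelationEdge] = {}
        self.adjacency: dict[str, list[str]] = {}
        self.type_index: dict[str, set[str]] = {}
        self.duplicate_node_ids: list[str] = []
        self.duplicate_edge_ids: list[str] = []

    # -- construction -----------------------------------------------------

    def add_node(self, node: ConceptNode) -> None:
        if node.id in self.nodes:
            self.duplicate_node_ids.append(node.id)
            return
        self.nodes[node.id] = node
        self.adjacency.setdefault(node.id, [])
        self.type_index.setdefault(node.type, set()).add(node.id)

    def add_edge(self, edge: RelationEdge) -> None:
        if edge.id in self.edges:
            self.duplicate_edge_ids.append(edge.id)
            return
        self.edges[edge.id] = edge
        for endpoint in (edge.source, edge.target):
            if endpoint in self.nodes:
                self.adjacency.setdefault(endpoint, []).append(edge.id)

    def rebuild_indices(self) -> None:
        self.adjacency = {nid: [] for nid in self.nodes}
        self.type_index = {}
        for node in self.nodes.values():
            self.type_index.setdefault(node.type, set()).add(node.id)
        for edge in sorted(self.edges.values(), key=lambda e: e.id):
            for endpoint in {edge.source, edge.target}:
                if endpoint in self.adjacency:
                    self.adjacency[endpoint].append(edge.id)
        for incident in self.adjacency.values():
            incident.sort()

    @classmethod
    def from_records(
        cls,
        node_records: Iterable[Mapping[str, Any]],
        edge_records: Iterable[Mapping[str, Any]],
    ) -> "KnowledgeGraph":
        """Build leniently from kgjson-shaped dictionaries.

        Structural problems (duplicates, dangling endpoints) are recorded, not
        raised, so a defective graph can still be inspected and validated.
        """
        graph = cls()
        for rec in node_records:
            graph.add_node(
                ConceptNode(
                    id=str(rec["id"]),
                    type=str(rec["type"]),
                    properties=dict(rec.get("properties", {})),
                )
            )
        for rec in edge_records:
            graph.add_edge(
                RelationEdge(
                    id=str(rec["id"]),
                    source=str(rec["source"]),
                    target=str(rec["target"]),
                    type=str(rec["type"]),
                    properties=dict(rec.get("properties", {})),
                )
            )
        graph.rebuild_indices()
        return graph

    # -- views -------------------------------------------------------------

    def nodes_of_type(self, node_type: str) -> list[ConceptNode]:
        return [self.nodes[nid] for nid in sorted(self.type_index.get(node_type, ()))]

    def gene_ids(self) -> list[str]:
        return sorted(self.type_index.get("Gene", ()))

    def neighbours(self, node_id: str) -> list[str]:
        out: set[str] = set()
        for eid in self.adjacency.get(node_id, ()):
            out.add(self.edges[eid].other(node_id))
        return sorted(out)

    def to_records(self) -> tuple[list[dict], list[dict]]:
        node_recs = [
            {"id": n.id, "type": n.type, "properties": n.properties}
            for n in sorted(self.nodes.values(), key=lambda n: n.id)
        ]
        edge_recs = [
            {
                "id": e.id,
                "source": e.source,
                "target": e.target,
                "type": e.type,
                "properties": e.properties,
            }
            for e in sorted(self.edges.values(), key=lambda e: e.id)
        ]
        return node_recs, edge_recs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.to_records() == other.to_records()

    def __repr__(self) -> str:
        return f"KnowledgeGraph(nodes={len(self.nodes)}, edges={len(self.edges)})"


# -- I/O -------------------------------------------------------------------


def load_graph(path: str | Path, format: str = "kgjson") -> KnowledgeGraph:
    """Load and validate a knowledge graph from a kgjson file.

    Raises :class:`FormatError` on JSON/schema problems (with the offending
    field named) and :class:`GraphValidationError` when the parsed graph has
    dangling endpoints or duplicate ids.
    """
    if format != "kgjson":
        raise ArgumentError(f"unsupported graph format {format!r}")
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(payload, dict) or "nodes" not in payload or "edges" not in payload:
        raise FormatError(f"{path}: kgjson requires a top-level object with 'nodes' and 'edges'")
    for section in ("nodes", "edges"):
        if not isinstance(payload[section], list):
            raise FormatError(f"{path}: field {section!r} must be a list")
    required = {"nodes": ("id", "type"), "edges": ("id", "source", "target", "type")}
    for section, keys in required.items():
        for i, rec in enumerate(payload[section]):
            for key in keys:
                if key not in rec:
                    raise FormatError(
                        f"{path}: {section}[{i}] is missing required field {key!r}"
                    )
    graph = KnowledgeGraph.from_records(payload["nodes"], payload["edges"])
    report = validate_graph(graph)
    if not report.valid:
        raise GraphValidationError("; ".join(report.errors))
    return graph


def _node_visible(node: ConceptNode) -> bool:
    return node.properties.get("visible", True) is not False


def save_graph(
    graph: KnowledgeGraph,
    path: str | Path,
    visible_only: bool = False,
    meta: Mapping[str, Any] | None = None,
) -> Path:
    """Write a graph as canonical kgjson (nodes/edges sorted by id).

    With ``visible_only`` nodes whose ``visible`` property is ``False`` — the
    hidden-not-removed flag set by the filtering step — are omitted along with
    their incident edges.  ``meta`` adds an optional top-level object that
    loaders ignore (used by the filtered-subgraph export).
    """
    node_recs, edge_recs = graph.to_records()
    if visible_only:
        keep = {r["id"] for r in node_recs if _node_visible(graph.nodes[r["id"]])}
        node_recs = [r for r in node_recs if r["id"] in keep]
        edge_recs = [r for r in edge_recs if r["source"] in keep and r["target"] in keep]
    payload: dict[str, Any] = {"nodes": node_recs, "edges": edge_recs}
    if meta is not None:
        payload["meta"] = dict(meta)
    path = Path(path)
    path.write_text(
        json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    return path


def to_networkx(graph: KnowledgeGraph) -> nx.MultiDiGraph:
    """Convert to a networkx multigraph (used for GraphML export)."""
    g = nx.MultiDiGraph()
    for node in graph.nodes.values():
        attrs = {k: v for k, v in node.properties.items() if isinstance(v, (str, int, float, bool))}
        g.add_node(node.id, type=node.type, **attrs)
    for edge in graph.edges.values():
        attrs = {k: v for k, v in edge.properties.items() if isinstance(v, (str, int, float, bool))}
        g.add_edge(edge.source, edge.target, key=edge.id, type=edge.type, **attrs)
    return g


def export_graphml(graph: KnowledgeGraph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(to_networkx(graph), path)
    return path


# -- validation ------------------------------------------------------------


def validate_graph(
    graph: KnowledgeGraph,
    node_vocabulary: frozenset[str] = DEFAULT_NODE_TYPES,
) -> ValidationReport:
    """Check structural invariants; see :class:`ValidationReport`.

    Dangling endpoints and duplicate ids are errors; unknown node types and
    genes without genomic positions are warnings (the vocabulary is meant to
    be extended, and many gene models legitimately lack coordinates).
    """
    report = ValidationReport(
        duplicate_node_ids=list(graph.duplicate_node_ids),
        duplicate_edge_ids=list(graph.duplicate_edge_ids),
    )
    for edge in sorted(graph.edges.values(), key=lambda e: e.id):
        if edge.source not in graph.nodes or edge.target not in graph.nodes:
            report.dangling_edges.append(edge.id)
    for node in sorted(graph.nodes.values(), key=lambda n: n.id):
        if node.type not in node_vocabulary:
            report.unknown_type_nodes.append(node.id)
        if node.type == "Gene" and not node.has_position():
            report.genes_without_position.append(node.id)
    return report


def genes_in_region(
    graph: KnowledgeGraph, chromosome: str, start: int, end: int
) -> list[ConceptNode]:
    """Gene nodes on ``chromosome`` overlapping ``[start, end]`` by >= 1 bp.

    Coordinates are 1-based inclusive; results are sorted by start position
    then id.  Genes without positions are never returned.
    """
    if start > end:
        raise ArgumentError(f"region start {start} exceeds end {end}")
    hits = [
        node
        for node in graph.nodes_of_type("Gene")
        if node.has_position()
        and node.chromosome == chromosome
        and node.start <= end
        and node.end >= start
    ]
    hits.sort(key=lambda n: (n.start, n.id))
    return hits
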