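"""Interestingness filtering: reduce a GCS to the paths worth displaying.

A gene-centric subgraph with hundreds of nodes overwhelms a viewer, so two
strategies pick the displayed subset.  With keywords, only matched paths that
contain at least one keyword-relevant node are shown (the non-matching
intermediates on those paths stay visible — they connect the gene to its
evidence), and if too many publications survive, only the most recent ones
are kept (default cap 50).  Without keywords, the paths ending in a Trait or
Phenotype node are shown, the relationship most users care about first.

Hidden nodes are flagged, never deleted: the FilteredSubgraph keeps the full
GCS, records which nodes/edges are visible, and marks visible nodes that have
hidden neighbours ("shadowed", the cue that more information is available).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from pathlib import Path

from .errors import ArgumentError
from .gcs import GeneCentricSubgraph
from .index_rank import BooleanQuery, SDRIndex, relevance
from .kg_model import DEFAULT_NODE_TYPES, KnowledgeGraph, save_graph

#: Default cap on visible publications after keyword filtering.
DEFAULT_PUB_CAP = 50

TRAIT_TYPES = frozenset({"Trait", "Phenotype"})


@dataclass
class FilteredSubgraph:
    gcs: GeneCentricSubgraph
    visible_nodes: set[str]
    visible_edges: set[str]
    mode: str  # 'keyword' | 'default_traits'
    shadowed: set[str]

    @property
    def hidden_nodes(self) -> set[str]:
        return self.gcs.node_ids - self.visible_nodes


def _compute_shadowed(gcs: GeneCentricSubgraph, visible: set[str]) -> set[str]:
    shadowed: set[str] = set()
    for eid in gcs.edge_ids:
        a, b = gcs.edge_endpoints(eid)
        if a in visible and b not in visible:
            shadowed.add(a)
        elif b in visible and a not in visible:
            shadowed.add(b)
    return shadowed


def _cap_publications(
    gcs: GeneCentricSubgraph,
    visible_nodes: set[str],
    visible_edges: set[str],
    pub_cap: int | None,
) -> tuple[set[str], set[str]]:
    pubs = sorted(n for n in visible_nodes if gcs.node_types[n] == "Publication")
    if pub_cap is None or len(pubs) <= pub_cap:
        return visible_nodes, visible_edges
    # newest first; a missing year sorts oldest; ties broken by id
    pubs.sort(key=lambda n: (-gcs.node_years.get(n, -(10**9)), n))
    drop = set(pubs[pub_cap:])
    visible_nodes = visible_nodes - drop
    visible_edges = {
        e
        for e in visible_edges
        if all(end in visible_nodes for end in gcs.edge_endpoints(e))
    }
    return visible_nodes, visible_edges


def filter_by_keywords(
    gcs: GeneCentricSubgraph,
    index: SDRIndex,
    query: BooleanQuery,
    pub_cap: int | None = DEFAULT_PUB_CAP,
) -> FilteredSubgraph:
    """Keep the matched paths that contain at least one keyword-relevant node.

    ``pub_cap=None`` disables the publication recency cap.
    """
    if query.is_empty:
        raise ArgumentError("keyword filtering needs a non-empty query; use filter_default_traits")
    node_r = {nid: relevance(index, query, nid) for nid in gcs.node_ids}
    visible_nodes: set[str] = {gcs.gene_id}
    visible_edges: set[str] = set()
    for path in gcs.paths:
        if any(node_r[nid] > 0.0 for nid in path.node_ids):
            visible_nodes.update(path.node_ids)
            visible_edges.update(path.edge_ids)
    visible_nodes, visible_edges = _cap_publications(gcs, visible_nodes, visible_edges, pub_cap)
    return FilteredSubgraph(
        gcs=gcs,
        visible_nodes=visible_nodes,
        visible_edges=visible_edges,
        mode="keyword",
        shadowed=_compute_shadowed(gcs, visible_nodes),
    )


def filter_default_traits(gcs: GeneCentricSubgraph) -> FilteredSubgraph:
    """Keep the matched paths terminating in a Trait or Phenotype node."""
    visible_nodes: set[str] = {gcs.gene_id}
    visible_edges: set[str] = set()
    for path in gcs.paths:
        if gcs.node_types[path.node_ids[-1]] in TRAIT_TYPES:
            visible_nodes.update(path.node_ids)
            visible_edges.update(path.edge_ids)
    return FilteredSubgraph(
        gcs=gcs,
        visible_nodes=visible_nodes,
        visible_edges=visible_edges,
        mode="default_traits",
        shadowed=_compute_shadowed(gcs, visible_nodes),
    )


def expand_by_type(filtered: FilteredSubgraph, node_type: str) -> FilteredSubgraph:
    """Unhide every hidden node of ``node_type`` plus its connecting segments.

    The data-level analogue of clicking a type in an interactive legend: each
    hidden node of the type is connected to the visible set through a
    shortest hidden segment (breadth-first over the GCS), and those segment
    nodes/edges become visible too.  Idempotent; never exceeds the GCS.
    """
    gcs = filtered.gcs
    known_types = DEFAULT_NODE_TYPES | set(gcs.node_types.values())
    if node_type not in known_types:
        raise ArgumentError(f"unknown node type {node_type!r}")
    targets = {
        n
        for n in gcs.node_ids
        if gcs.node_types[n] == node_type and n not in filtered.visible_nodes
    }
    if not targets:
        return FilteredSubgraph(
            gcs=gcs,
            visible_nodes=set(filtered.visible_nodes),
            visible_edges=set(filtered.visible_edges),
            mode=filtered.mode,
            shadowed=set(filtered.shadowed),
        )
    # multi-source BFS from the visible set across the whole GCS; parent
    # pointers give one shortest connecting segment per reached node.
    # Sorted frontier expansion keeps tie-breaks deterministic.
    incident: dict[str, list[str]] = {n: [] for n in gcs.node_ids}
    for eid in sorted(gcs.edge_ids):
        a, b = gcs.edge_endpoints(eid)
        if a in incident and b in incident and a != b:
            incident[a].append(eid)
            incident[b].append(eid)
    parent: dict[str, tuple[str, str] | None] = {n: None for n in filtered.visible_nodes}
    frontier = deque(sorted(filtered.visible_nodes))
    while frontier:
        current = frontier.popleft()
        for eid in incident[current]:
            a, b = gcs.edge_endpoints(eid)
            nxt = b if current == a else a
            if nxt not in parent:
                parent[nxt] = (current, eid)
                frontier.append(nxt)
    visible_nodes = set(filtered.visible_nodes)
    visible_edges = set(filtered.visible_edges)
    for target in sorted(targets):
        if target not in parent:
            continue  # disconnected from the visible set within the GCS
        node = target
        while node not in visible_nodes:
            visible_nodes.add(node)
            step = parent[node]
            if step is None:
                break
            prev, eid = step
            visible_edges.add(eid)
            node = prev
    return FilteredSubgraph(
        gcs=gcs,
        visible_nodes=visible_nodes,
        visible_edges=visible_edges,
        mode=filtered.mode,
        shadowed=_compute_shadowed(gcs, visible_nodes),
    )


def export_filtered(
    filtered: FilteredSubgraph, graph: KnowledgeGraph, path: str | Path
) -> Path:
    """Write the filtered subgraph as kgjson with visible/shadowed flags.

    The file carries the *whole* GCS (hidden-not-removed), each node tagged
    with ``visible`` and ``shadowed`` booleans, plus a ``meta`` object naming
    the root gene and filter mode so the view can be re-expanded later.
    """
    gcs = filtered.gcs
    sub = KnowledgeGraph()
    for nid in sorted(gcs.node_ids):
        node = graph.nodes[nid]
        props = dict(node.properties)
        props["visible"] = nid in filtered.visible_nodes
        props["shadowed"] = nid in filtered.shadowed
        sub.add_node(type(node)(id=node.id, type=node.type, properties=props))
    for eid in sorted(gcs.edge_ids):
        edge = graph.edges[eid]
        props = dict(edge.properties)
        props["visible"] = eid in filtered.visible_edges
        sub.add_edge(type(edge)(edge.id, edge.source, edge.target, edge.type, props))
    sub.rebuild_indices()
    return save_graph(
        sub, path, meta={"gene_id": gcs.gene_id, "mode": filtered.mode}
    )


def load_filtered(path: str | Path, graph: KnowledgeGraph) -> FilteredSubgraph:
    """Reload a filtered-subgraph export produced by :func:`export_filtered`."""
    import json

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    meta = payload.get("meta", {})
    gene_id = meta.get("gene_id")
    if gene_id is None:
        raise ArgumentError(f"{path}: missing meta.gene_id; not a filtered-subgraph export")
    from .gcs import GeneCentricSubgraph as _GCS

    node_ids = {rec["id"] for rec in payload["nodes"]}
    edge_ids = {rec["id"] for rec in payload["edges"]}
    gcs = _GCS(
        gene_id=gene_id,
        node_ids=node_ids,
        edge_ids=edge_ids,
        distance={},
        via_motifs={},
        node_types={rec["id"]: rec["type"] for rec in payload["nodes"]},
        node_years={
            rec["id"]: rec["properties"]["year"]
            for rec in payload["nodes"]
            if isinstance(rec.get("properties", {}).get("year"), int)
        },
    )
    gcs._endpoints = {
        rec["id"]: (rec["source"], rec["target"]) for rec in payload["edges"]
    }
    visible = {
        rec["id"] for rec in payload["nodes"] if rec["properties"].get("visible", True)
    }
    visible_edges = {
        rec["id"] for rec in payload["edges"] if rec["properties"].get("visible", True)
    }
    return FilteredSubgraph(
        gcs=gcs,
        visible_nodes=visible,
        visible_edges=visible_edges,
        mode=meta.get("mode", "keyword"),
        shadowed=_compute_shadowed(gcs, visible),
    )
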