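"""Gene-centric subgraphs: the union of a gene's motif matches.

The GCS is the evidence neighbourhood of one gene — every node and edge that
lies on at least one semantic-motif path rooted at the gene.  Each node keeps
its minimum distance from the gene *measured along matched paths* (a short
non-motif shortcut in the full graph must not shrink the distance, because
only motif-conforming paths confer relevance), and the set of motifs that
contributed it.  A gene matching no motif still owns a singleton GCS {gene},
so the minimum GCS size is always 1.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ArgumentError
from .kg_model import KnowledgeGraph
from .motif import MatchedPath, SemanticMotif, match_motif


@dataclass
class GeneCentricSubgraph:
    gene_id: str
    node_ids: set[str]
    edge_ids: set[str]
    distance: dict[str, int]  # min edge-offset from the gene along matched paths
    via_motifs: dict[str, set[str]]
    node_types: dict[str, str]
    node_years: dict[str, int]  # publication years, for the recency cap
    paths: tuple[MatchedPath, ...] = ()

    @property
    def size(self) -> int:
        """Number of nodes (the statistic reported by :func:`gcs_stats`)."""
        return len(self.node_ids)

    def edge_endpoints(self, edge_id: str) -> tuple[str, str]:
        return self._endpoints[edge_id]

    def __post_init__(self) -> None:
        self._endpoints: dict[str, tuple[str, str]] = {}

    def attach_endpoints(self, graph: KnowledgeGraph) -> None:
        self._endpoints = {
            eid: (graph.edges[eid].source, graph.edges[eid].target)
            for eid in self.edge_ids
        }


def build_gcs(
    graph: KnowledgeGraph, gene: str, motifs: Iterable[SemanticMotif]
) -> GeneCentricSubgraph:
    """Union of all motif matches rooted at ``gene``, with min distances."""
    node_ids: set[str] = {gene}
    edge_ids: set[str] = set()
    distance: dict[str, int] = {gene: 0}
    via: dict[str, set[str]] = {}
    all_paths: list[MatchedPath] = []
    for motif in motifs:
        for path in match_motif(graph, gene, motif):
            all_paths.append(path)
            edge_ids.update(path.edge_ids)
            for offset, nid in enumerate(path.node_ids):
                node_ids.add(nid)
                if nid != gene:
                    prev = distance.get(nid)
                    if prev is None or offset < prev:
                        distance[nid] = offset
                    via.setdefault(nid, set()).add(motif.id)
    gcs = GeneCentricSubgraph(
        gene_id=gene,
        node_ids=node_ids,
        edge_ids=edge_ids,
        distance=distance,
        via_motifs=via,
        node_types={nid: graph.nodes[nid].type for nid in node_ids},
        node_years={
            nid: graph.nodes[nid].properties["year"]
            for nid in node_ids
            if isinstance(graph.nodes[nid].properties.get("year"), int)
        },
        paths=tuple(sorted(all_paths, key=lambda p: (p.motif_id, p.node_ids, p.edge_ids))),
    )
    gcs.attach_endpoints(graph)
    return gcs


def build_all_gcs(
    graph: KnowledgeGraph, motifs: Iterable[SemanticMotif]
) -> dict[str, GeneCentricSubgraph]:
    """One GCS per Gene node; this map is the pre-indexing corpus."""
    motifs = list(motifs)
    return {gene: build_gcs(graph, gene, motifs) for gene in graph.gene_ids()}


@dataclass(frozen=True)
class GcsStats:
    count: int
    min_size: int
    max_size: int
    mean_size: float


def gcs_stats(all_gcs: Mapping[str, GeneCentricSubgraph]) -> GcsStats:
    """Node-count summary over all GCSs; mean rounded to 3 decimals."""
    if not all_gcs:
        raise ArgumentError("gcs_stats requires at least one GCS")
    sizes = [g.size for g in all_gcs.values()]
    return GcsStats(
        count=len(sizes),
        min_size=min(sizes),
        max_size=max(sizes),
        mean_size=round(statistics.fmean(sizes), 3),
    )


# -- optional on-disk cache -------------------------------------------------


def save_gcs_store(all_gcs: Mapping[str, GeneCentricSubgraph], path: str | Path) -> Path:
    payload = {
        gene: {
            "nodes": sorted(g.node_ids),
            "edges": sorted(g.edge_ids),
            "distances": {n: d for n, d in sorted(g.distance.items())},
            "motifs": {n: sorted(m) for n, m in sorted(g.via_motifs.items())},
            "node_types": dict(sorted(g.node_types.items())),
            "node_years": dict(sorted(g.node_years.items())),
            "paths": [
                {"motif_id": p.motif_id, "nodes": list(p.node_ids), "edges": list(p.edge_ids)}
                for p in g.paths
            ],
        }
        for gene, g in sorted(all_gcs.items())
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


def load_gcs_store(path: str | Path, graph: KnowledgeGraph) -> dict[str, GeneCentricSubgraph]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    store: dict[str, GeneCentricSubgraph] = {}
    for gene, rec in payload.items():
        gcs = GeneCentricSubgraph(
            gene_id=gene,
            node_ids=set(rec["nodes"]),
            edge_ids=set(rec["edges"]),
            distance={n: int(d) for n, d in rec["distances"].items()},
            via_motifs={n: set(m) for n, m in rec["motifs"].items()},
            node_types=dict(rec["node_types"]),
            node_years={n: int(y) for n, y in rec["node_years"].items()},
            paths=tuple(
                MatchedPath(p["motif_id"], tuple(p["nodes"]), tuple(p["edges"]))
                for p in rec["paths"]
            ),
        )
        gcs.attach_endpoints(graph)
        store[gene] = gcs
    return store
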