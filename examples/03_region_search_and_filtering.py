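"""Region-to-candidate search with evidence-network filtering.

Mimics the QTL workflow: take a genomic interval, list the genes inside it,
rank them, then reduce the top gene's evidence network to the displayed
paths — keyword mode hides everything not on a path to keyword-bearing
text, and the interactive-legend analogue re-expands hidden node types.
"""

from kgrank import (
    build_all_gcs,
    build_index,
    canonical_motifs,
    expand_by_type,
    filter_by_keywords,
    filter_default_traits,
    genes_in_region,
    parse_query,
    rank_genes,
    worked_example_graph,
)

graph = worked_example_graph()
motifs = canonical_motifs()[:3]
all_gcs = build_all_gcs(graph, motifs)
index = build_index(graph, all_gcs)

# a petal-size-QTL-style interval on chromosome 4, in base pairs
candidates = genes_in_region(graph, "4", 9_920_000, 10_180_000)
print("genes in 4:9,920,000-10,180,000:", [g.id for g in candidates])

ranked = rank_genes(index, parse_query(""), candidates)
top = ranked[0]
print("top candidate:", top.gene_id, f"(score {top.score:.4f})")

gcs = all_gcs[top.gene_id]
trait_view = filter_default_traits(gcs)
print("\nno-keyword view shows only trait/phenotype paths:")
print("  visible:", sorted(trait_view.visible_nodes), "| hidden:", sorted(trait_view.hidden_nodes))

query = parse_query("dormancy")
keyword_view = filter_by_keywords(gcs, index, query)
print("\nkeyword view for 'dormancy':")
print("  visible:", sorted(keyword_view.visible_nodes), "| shadowed:", sorted(keyword_view.shadowed))

expanded = expand_by_type(keyword_view, "Pathway")
print("\nafter expanding Pathway nodes (plus their connectors):")
print("  visible:", sorted(expanded.visible_nodes))
print(
    "\nHidden nodes stay inside the subgraph (hidden, not removed); the"
    " shadow flag marks visible nodes with hidden neighbours."
)
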