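# Methods

## The model

`kgrank` treats gene discovery as scoring evidence neighbourhoods in a typed
property graph.  The central assumption is that relevance is *transferable
along biologically plausible paths only*: a GO process linked to a gene's
ortholog says something about the gene; the same process reached through an
arbitrary chain of co-occurrences does not.  Plausibility is made explicit
as semantic motifs — path patterns rooted at a Gene node — and everything
downstream (subgraph extraction, distances, scoring, filtering) operates on
motif matches, never on raw connectivity.

### Motif matching

Motifs are matched as **simple paths** (no node revisited, self-loops never
match): the alternative — walks — makes counts explode on cyclic homology
subgraphs without adding evidence.  A variable-length step (`{min,max}`)
requires every hop, intermediate and final, to land on the step's target
node type, mirroring how typed variable-length traversals behave in
property-graph query languages.  Hops are capped (3 per step, 6 edges per
motif, both overridable in `parse_motifs`) so worst-case enumeration stays
bounded.  Matching is exhaustive DFS with sorted adjacency iteration; the
result is a set, and every derived artefact (GCS, ranking, exports) is
deterministic.

### Gene-centric subgraphs

The GCS of gene *g* is the union of all its motif matches, intermediates
included — nodes at distance > 1 are scored, so they must be present.  The
distance recorded per node is the minimum edge-offset across matched paths,
*not* the shortest path in the whole graph: a short non-motif shortcut must
not inflate the confidence of distant evidence.  (On the motif sets shipped
here the two notions coincide, and a BFS-over-matched-edges oracle verifies
that in tests; with adversarial motif mixes they can differ, and the
along-matched-paths definition wins.)  A gene with no matches owns the
singleton GCS {g}, so GCS size is always ≥ 1.

### SDR weights

* **Specificity** S(x) = ln(N/n): N = number of genes (= GCSs), n = GCSs
  containing x; 1 ≤ n ≤ N, S = 0 iff the node sits in every GCS.
* **Distance** D(g,x) = 1/dist(g,x), with D = 1 for the gene itself
  (distance 0).  The convention matters: it lets a keyword hit on the
  gene's own name or description contribute to its score.
* **Relevance** R(t,x):  node text is the concatenation of its `name`,
  `synonyms`, `description`/`text` properties, tokenized by lowercasing and
  splitting on non-alphanumerics (no stemming, no stopword removal —
  gene symbols and ontology jargon survive better untouched).  R is exactly
  1 for every node when the query is empty, exactly 0 when the node fails
  the Boolean expression, otherwise Σ TF·IDF over the positive terms
  present.  Phrases count as contiguous token runs.  NOT-terms exclude a
  node outright rather than subtracting score.

Natural logarithms are used for both S and IDF; any fixed base rescales S
monotonically, but mixing S with IDF requires one documented choice
(`build_index(log=...)` overrides it).  IDF is smoothed as
1 + ln((M+1)/(df+1)) — the same smoothing scikit-learn uses — so ubiquitous
terms keep a positive weight and df = 0 cannot divide by zero.  M counts the
indexed nodes (those in ≥ 1 GCS) with non-empty text: nodes outside every
GCS carry no transferable evidence, are not searchable, and therefore do
not belong in the corpus.

The gene score is Σ S·D·R over GCS nodes with R > 0 (all nodes when the
query is empty).  S, D and the inverted text index are precomputed at
`build_index`, so each lookup is O(1) and ranking is one linear pass; a
brute-force recomputation with no index is the oracle in the test suite.
Ranking ties break lexicographically by gene id.  Under a non-empty query,
zero-scoring genes are dropped — a search result, not a census.

The evidence ranking orders non-gene nodes by R·S (relevant *and*
gene-specific first), then by how many result genes link them, then by id.
This is a deliberate substitute for set-enrichment statistics, which would
need a null model the graph does not provide; a hypergeometric variant
would slot into the same interface.

### Interestingness filtering

Keyword mode keeps whole matched paths containing ≥ 1 node with R > 0 —
truncating them would disconnect the gene from its evidence.  If visible
publications then exceed the cap (default 50), only the most recent by
`year` stay visible (missing year = oldest; ties by id).  Trait mode keeps
matched paths terminating in Trait/Phenotype.  Both produce a
`FilteredSubgraph` whose hidden nodes remain inside the GCS; `visible_only`
export drops them, the default export flags them.  `expand_by_type` unhides
a node type plus the shortest hidden segments (multi-source BFS within the
GCS) reconnecting it to the visible set; it is idempotent and re-filtering
returns exactly the pre-expansion view.  Sibling paths to an
already-visible evidence node are *not* kept unless they contain a match of
their own — showing them would reintroduce the clutter filtering exists to
remove.

## Synthetic graphs

The generator emulates the statistical shape the method needs, not any real
species: genes with uniform positions on 3 synthetic chromosomes (40 Mb),
background traits/pathways/publications carrying text from a fixed
keyword-free plant-biology vocabulary, background edges drawn independently
per gene–node pair, and planted evidence — motif-conforming paths whose
terminal text contains a chosen keyword, recorded in a `GroundTruth` so
recovery is asserted against construction.  Defaults (20 genes, 10 traits,
15 publications, 5 pathways, background edge probability 0.05, 5 planted
genes × 3 evidence paths in tests, publication years 2000–2020) are the
conditions the test suite and examples run under; oracle-equivalence tests
scale up to ~200-node graphs, which one CPU handles in seconds.  What the
generator does **not** emulate: hub-dominated degree distributions,
correlated annotation structure, realistic literature text, or
million-node scale — passing tests demonstrate correctness of the
algorithms, not retrieval quality on a production knowledge graph.

A planted keyword colliding with the background vocabulary is rejected at
config time; otherwise "background gene outranks planted gene" could be a
text coincidence rather than a bug.

## Numerical and degenerate-input choices

* Genomic coordinates are 1-based inclusive; region overlap is ≥ 1 bp.
* Scores are plain float sums of logarithms; no tolerance tricks are
  needed, and exact equality is asserted only for the conventions that are
  exact by definition (R = 0, R = 1).
* Empty graph: valid, loads and saves; a graph with no genes yields an
  empty GCS map, and index construction over it is an error.
* Duplicate ids and dangling endpoints are recorded by the lenient
  record-level constructor and reported by `validate_graph`; `load_graph`
  refuses such files.  Unknown node types only warn — type vocabularies
  are meant to be extended per knowledge-graph build.
* Parallel edges of different types between one node pair are distinct
  edges and may appear in the same GCS.

## Known limitations

* Motif matching is exponential in the worst case (dense graphs, long
  variable-length steps); the hop caps are the only guard.  Genome-scale
  graphs would need memoized or indexed traversal.
* TF-IDF here is the classic raw-count formulation; no field boosts, length
  normalization, BM25, stemming or fuzzy matching.
* The GCS store is recomputed on demand (an explicit JSON cache exists but
  no invalidation logic beyond "rebuild").
* Evidence "enrichment" is an ordering heuristic (R·S), not a calibrated
  statistic.
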