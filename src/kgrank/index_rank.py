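"""SDR weights, Boolean keyword queries, and candidate-gene ranking.

Every node x in the knowledge graph carries three weights:

* **Specificity** ``S(x) = ln(N / n)`` where N is the number of gene-centric
  subgraphs (one per gene) and n is the number of them containing x.  A
  publication cited by hundreds of genes is less diagnostic than one linked
  to a single gene.
* **Distance** ``D(g, x) = 1 / dist(g, x)`` with dist measured along matched
  motif paths; evidence inferred through longer chains (homology, secondary
  interactions) is weighted down.  The gene itself, at distance 0, takes
  D = 1 by convention so keyword hits on the gene's own name contribute.
* **Relevance** ``R(t, x) = TF x IDF`` of the query terms t in the node's
  text, with R = 0 when the node does not satisfy the Boolean expression and
  R = 1 for every node when no keywords are given.

The per-gene ranking score is ``sum(S * D * R)`` over the GCS nodes that
match the query (all GCS nodes when the query is empty).  S, D and the text
index are precomputed once so that scoring a search result is a single
linear pass using constant-time lookups.

Natural logarithms are used for both S and IDF; IDF is smoothed as
``1 + ln((M + 1) / (df + 1))`` (M = corpus size) so ubiquitous terms keep a
positive weight and unseen terms do not divide by zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .errors import ArgumentError, NodeLookupError, QuerySyntaxError
from .gcs import GeneCentricSubgraph
from .kg_model import ConceptNode, KnowledgeGraph

_TOKEN_RE = re.compile(r"[^0-9a-z]+")

#: Node properties concatenated into the searchable "document" of a node.
TEXT_PROPERTIES = ("name", "synonyms", "description", "text")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumerics; no stemming, no stopwords."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


def node_document(node: ConceptNode) -> list[str]:
    parts: list[str] = []
    for key in TEXT_PROPERTIES:
        value = node.properties.get(key)
        if value is None:
            continue
        if isinstance(value, (list, tuple)):
            parts.extend(str(v) for v in value)
        else:
            parts.append(str(value))
    return tokenize(" ".join(parts))


# -- Boolean queries --------------------------------------------------------


@dataclass(frozen=True)
class Term:
    """A term or quoted phrase, stored as its token run."""

    tokens: tuple[str, ...]


@dataclass(frozen=True)
class Not:
    child: "QueryNode"


@dataclass(frozen=True)
class And:
    children: tuple["QueryNode", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["QueryNode", ...]


QueryNode = Union[Term, Not, And, Or]


@dataclass(frozen=True)
class BooleanQuery:
    """Parsed keyword expression; ``root`` is None for the no-keyword mode."""

    root: QueryNode | None
    positive_terms: tuple[Term, ...]

    @property
    def is_empty(self) -> bool:
        return self.root is None


def _collect_positive(node: QueryNode, negated: bool, out: list[Term]) -> None:
    if isinstance(node, Term):
        if not negated:
            out.append(node)
    elif isinstance(node, Not):
        _collect_positive(node.child, not negated, out)
    else:
        for child in node.children:
            _collect_positive(child, negated, out)


_QUERY_TOKEN_RE = re.compile(r'\s*(?:(?P<quote>"[^"]*")|(?P<lparen>\()|(?P<rparen>\))|(?P<word>[^\s()"]+))')


def _lex_query(raw: str) -> list[tuple[str, str, int]]:
    if raw.count('"') % 2:
        raise QuerySyntaxError(f"unbalanced quote at position {raw.rfind(chr(34))}")
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(raw):
        m = _QUERY_TOKEN_RE.match(raw, pos)
        if m is None or m.end() == pos:
            if raw[pos:].strip():
                raise QuerySyntaxError(f"cannot read query at position {pos}")
            break
        if m.group("quote") is not None:
            tokens.append(("PHRASE", m.group("quote")[1:-1], m.start()))
        elif m.group("lparen"):
            tokens.append(("LPAREN", "(", m.start()))
        elif m.group("rparen"):
            tokens.append(("RPAREN", ")", m.start()))
        else:
            word = m.group("word")
            upper = word.upper()
            if upper in ("AND", "OR", "NOT"):
                tokens.append((upper, word, m.start()))
            else:
                tokens.append(("WORD", word, m.start()))
        pos = m.end()
    return tokens


class _QueryParser:
    """Recursive descent; precedence NOT > AND > OR, adjacency means OR."""

    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def parse(self) -> QueryNode:
        node = self.parse_or()
        if self.peek() is not None:
            raise QuerySyntaxError(
                f"unexpected {self.tokens[self.i][1]!r} at position {self.tokens[self.i][2]}"
            )
        return node

    def parse_or(self) -> QueryNode:
        children = [self.parse_and()]
        while True:
            tok = self.peek()
            if tok == "OR":
                self.i += 1
                children.append(self.parse_and())
            elif tok in ("WORD", "PHRASE", "NOT", "LPAREN"):
                # bare whitespace between operands is an implicit OR
                children.append(self.parse_and())
            else:
                break
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> QueryNode:
        children = [self.parse_not()]
        while self.peek() == "AND":
            self.i += 1
            children.append(self.parse_not())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_not(self) -> QueryNode:
        if self.peek() == "NOT":
            self.i += 1
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> QueryNode:
        tok = self.peek()
        if tok == "LPAREN":
            start = self.tokens[self.i][2]
            self.i += 1
            node = self.parse_or()
            if self.peek() != "RPAREN":
                raise QuerySyntaxError(f"unbalanced parenthesis opened at position {start}")
            self.i += 1
            return node
        if tok in ("WORD", "PHRASE"):
            _, text, pos = self.tokens[self.i]
            self.i += 1
            tokens = tuple(tokenize(text))
            if not tokens:
                raise QuerySyntaxError(f"empty term at position {pos}")
            return Term(tokens)
        pos = self.tokens[self.i][2] if self.i < len(self.tokens) else len(self.tokens)
        raise QuerySyntaxError(f"expected a term at position {pos}")


def parse_query(raw: str) -> BooleanQuery:
    """Parse a Boolean keyword expression.

    Case-insensitive; double quotes delimit phrases; NOT binds tighter than
    AND which binds tighter than OR; bare whitespace between operands is an
    implicit OR (so ``dormancy germination`` means either term).  An empty or
    whitespace-only string yields the no-keyword query.
    """
    tokens = _lex_query(raw)
    if not tokens:
        return BooleanQuery(root=None, positive_terms=())
    root = _QueryParser(tokens).parse()
    positives: list[Term] = []
    _collect_positive(root, False, positives)
    if not positives:
        raise QuerySyntaxError("query must contain at least one non-negated term")
    seen: dict[Term, None] = {}
    for term in positives:
        seen.setdefault(term)
    return BooleanQuery(root=root, positive_terms=tuple(seen))


# -- SDR index --------------------------------------------------------------


class SDRIndex:
    """Precomputed specificity, distances and text index over the GCS corpus.

    Built once per (graph, motif set); afterwards every S, D and R lookup is
    dictionary access — no graph traversal, no text scan — so ranking a
    result set is linear in the number of GCS nodes visited.
    """

    def __init__(self, log) -> None:
        self.N: int = 0
        self.M: int = 0
        self.gcs_count: dict[str, int] = {}
        self.specificity: dict[str, float] = {}
        self.inverted_index: dict[str, dict[str, int]] = {}
        self.doc_freq: dict[str, int] = {}
        self.doc_tokens: dict[str, tuple[str, ...]] = {}
        self.distances: dict[str, dict[str, int]] = {}
        self.node_type: dict[str, str] = {}
        self.genes: list[str] = []
        self._log = log
        self._phrase_df_cache: dict[tuple[str, ...], int] = {}

    # membership ---------------------------------------------------------

    def is_indexed(self, node_id: str) -> bool:
        return node_id in self.gcs_count

    def require(self, node_id: str) -> None:
        if not self.is_indexed(node_id):
            raise NodeLookupError(f"node {node_id!r} is not in any gene-centric subgraph")

    # term statistics ----------------------------------------------------

    @staticmethod
    def _count_run(doc: Sequence[str], run: tuple[str, ...]) -> int:
        if len(run) == 1:
            return sum(1 for t in doc if t == run[0])
        k = len(run)
        return sum(1 for i in range(len(doc) - k + 1) if tuple(doc[i : i + k]) == run)

    def term_frequency(self, term: Term, node_id: str) -> int:
        if len(term.tokens) == 1:
            return self.inverted_index.get(term.tokens[0], {}).get(node_id, 0)
        return self._count_run(self.doc_tokens.get(node_id, ()), term.tokens)

    def document_frequency(self, term: Term) -> int:
        if len(term.tokens) == 1:
            return self.doc_freq.get(term.tokens[0], 0)
        if term.tokens not in self._phrase_df_cache:
            # phrase df is resolved through the inverted index of its rarest
            # token, so only candidate documents are scanned
            candidates = min(
                (self.inverted_index.get(t, {}) for t in term.tokens),
                key=len,
                default={},
            )
            self._phrase_df_cache[term.tokens] = sum(
                1
                for nid in candidates
                if self._count_run(self.doc_tokens[nid], term.tokens) > 0
            )
        return self._phrase_df_cache[term.tokens]

    def idf(self, term: Term) -> float:
        return 1.0 + self._log((self.M + 1) / (self.document_frequency(term) + 1))


def build_index(
    graph: KnowledgeGraph,
    all_gcs: Mapping[str, GeneCentricSubgraph],
    log=math.log,
) -> SDRIndex:
    """Build the SDR index from a graph and its GCS corpus.

    The corpus consists of every node appearing in at least one GCS; a node
    outside all GCSs carries no transferable evidence and is not indexed.
    ``log`` is the logarithm used for both S and IDF (natural by default).
    """
    if not all_gcs:
        raise ArgumentError("cannot build an index over an empty gene set")
    index = SDRIndex(log)
    index.N = len(all_gcs)
    index.genes = sorted(all_gcs)
    counts: dict[str, int] = {}
    for gene, gcs in sorted(all_gcs.items()):
        index.distances[gene] = dict(gcs.distance)
        for nid in gcs.node_ids:
            counts[nid] = counts.get(nid, 0) + 1
    index.gcs_count = counts
    index.specificity = {nid: log(index.N / n) for nid, n in counts.items()}
    for nid in sorted(counts):
        node = graph.nodes[nid]
        index.node_type[nid] = node.type
        doc = tuple(node_document(node))
        index.doc_tokens[nid] = doc
        if doc:
            index.M += 1
        for token in doc:
            bucket = index.inverted_index.setdefault(token, {})
            bucket[nid] = bucket.get(nid, 0) + 1
    index.doc_freq = {token: len(bucket) for token, bucket in index.inverted_index.items()}
    return index


# -- relevance and scoring --------------------------------------------------


def _evaluate(index: SDRIndex, node: QueryNode, node_id: str) -> bool:
    if isinstance(node, Term):
        return index.term_frequency(node, node_id) > 0
    if isinstance(node, Not):
        return not _evaluate(index, node.child, node_id)
    if isinstance(node, And):
        return all(_evaluate(index, c, node_id) for c in node.children)
    return any(_evaluate(index, c, node_id) for c in node.children)


def relevance(index: SDRIndex, query: BooleanQuery, node_id: str) -> float:
    """TF-IDF relevance of a node to the query.

    Exactly 1.0 under the no-keyword query; exactly 0.0 when the node's text
    fails the Boolean expression; otherwise the sum of TF x IDF over the
    positive terms present in the node.  NOT-terms act as a hard exclusion.
    """
    index.require(node_id)
    if query.is_empty:
        return 1.0
    if not _evaluate(index, query.root, node_id):
        return 0.0
    total = 0.0
    for term in query.positive_terms:
        tf = index.term_frequency(term, node_id)
        if tf:
            total += tf * index.idf(term)
    return total


def _distance_weight(dist: int) -> float:
    return 1.0 if dist == 0 else 1.0 / dist


def sdr_score(index: SDRIndex, query: BooleanQuery, gcs: GeneCentricSubgraph) -> float:
    """The per-gene ranking score: sum of S*D*R over the gene's GCS.

    With keywords, only nodes with R > 0 contribute; without keywords every
    GCS node contributes with R = 1.
    """
    index.require(gcs.gene_id)
    dist = index.distances[gcs.gene_id]
    total = 0.0
    for nid in gcs.node_ids:
        r = relevance(index, query, nid)
        if r > 0.0:
            total += index.specificity[nid] * _distance_weight(dist[nid]) * r
    return total


@dataclass
class RankedGene:
    """One row of the ranked gene table."""

    gene_id: str
    score: float
    matched_nodes: set[tuple[str, float]] = field(default_factory=set)
    evidence_summary: dict[str, int] = field(default_factory=dict)


def _resolve_candidates(
    index: SDRIndex,
    candidates: Union[str, Iterable[Union[str, ConceptNode]]],
) -> list[str]:
    if isinstance(candidates, str):
        if candidates != "all":
            raise ArgumentError("string candidates must be the literal 'all'")
        return list(index.genes)
    resolved = []
    for c in candidates:
        gid = c.id if isinstance(c, ConceptNode) else c
        if gid not in index.distances:
            raise NodeLookupError(f"candidate {gid!r} is not an indexed gene")
        resolved.append(gid)
    return resolved


def rank_genes(
    index: SDRIndex,
    query: BooleanQuery,
    candidates: Union[str, Iterable[Union[str, ConceptNode]]] = "all",
) -> list[RankedGene]:
    """Rank candidate genes by score, descending; ties broken by gene id.

    Candidates may be gene ids, region-lookup nodes, or the literal ``"all"``.
    Under a non-empty query, genes whose GCS contains no matching node score
    zero and are dropped from the result, mirroring search-result semantics.
    One pass over candidate GCS nodes using precomputed lookups only.
    """
    ranked: list[RankedGene] = []
    for gene in _resolve_candidates(index, candidates):
        dist = index.distances[gene]
        score = 0.0
        matched: set[tuple[str, float]] = set()
        summary: dict[str, int] = {}
        for nid in dist:
            r = relevance(index, query, nid)
            if r > 0.0:
                score += index.specificity[nid] * _distance_weight(dist[nid]) * r
                matched.add((nid, r))
                if nid != gene:
                    t = index.node_type[nid]
                    summary[t] = summary.get(t, 0) + 1
        if query.is_empty or score > 0.0:
            ranked.append(
                RankedGene(
                    gene_id=gene,
                    score=score,
                    matched_nodes=matched,
                    evidence_summary=dict(sorted(summary.items())),
                )
            )
    ranked.sort(key=lambda rg: (-rg.score, rg.gene_id))
    return ranked


@dataclass(frozen=True)
class EvidenceRow:
    """One row of the ranked evidence table."""

    node_id: str
    node_type: str
    relevance: float
    linked_genes: int  # result genes whose GCS contains this node
    n_total: int  # GCSs containing this node graph-wide


def rank_evidence(
    index: SDRIndex, query: BooleanQuery, result_genes: Iterable[str]
) -> list[EvidenceRow]:
    """Ranked non-gene evidence nodes across the result genes' GCSs.

    Ordered by R*S descending (relevant and specific first), then by the
    number of linked result genes, then by id.
    """
    result_genes = sorted(set(result_genes))
    if not result_genes:
        raise ArgumentError("rank_evidence requires a non-empty result gene set")
    linked: dict[str, int] = {}
    for gene in result_genes:
        index.require(gene)
        for nid in index.distances[gene]:
            linked[nid] = linked.get(nid, 0) + 1
    rows: list[EvidenceRow] = []
    for nid in sorted(linked):
        if index.node_type[nid] == "Gene":
            continue
        r = relevance(index, query, nid)
        if r > 0.0:
            rows.append(
                EvidenceRow(
                    node_id=nid,
                    node_type=index.node_type[nid],
                    relevance=r,
                    linked_genes=linked[nid],
                    n_total=index.gcs_count[nid],
                )
            )
    rows.sort(key=lambda e: (-e.relevance * index.specificity[e.node_id], -e.linked_genes, e.node_id))
    return rows


# -- tabular exports --------------------------------------------------------


def gene_view_table(graph: KnowledgeGraph, ranked: Sequence[RankedGene]) -> pd.DataFrame:
    """The ranked gene table: position, score and per-type evidence counts."""
    rows = []
    for rg in ranked:
        node = graph.nodes[rg.gene_id]
        rows.append(
            {
                "gene_id": rg.gene_id,
                "chromosome": node.chromosome if node.chromosome is not None else "",
                "start": node.start if node.start is not None else "",
                "end": node.end if node.end is not None else "",
                "score": round(rg.score, 4),
                "evidence_summary": ";".join(
                    f"{t}:{c}" for t, c in rg.evidence_summary.items()
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "score", "evidence_summary"]
    )


def evidence_view_table(rows: Sequence[EvidenceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_id": r.node_id,
                "type": r.node_type,
                "relevance": round(r.relevance, 4),
                "linked_genes": r.linked_genes,
                "n_total": r.n_total,
            }
            for r in rows
        ],
        columns=["node_id", "type", "relevance", "linked_genes", "n_total"],
    )
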