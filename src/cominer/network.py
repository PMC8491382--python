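"""Disease–disease association (DDA) networks from document co-mentions.

Two normalized disease concepts are *co-mentioned* when both appear in the
same title+abstract; a pair counts once per document regardless of how many
times either disease is mentioned, and an edge's support is the number of
documents contributing the pair.  UNKNOWN mentions never enter an edge, and
self-pairs (two surfaces normalizing to the same concept) are excluded.

Downstream operations rank target–partner edges by support, filter partners
by the number of distinct target diseases they connect to, split nodes into
cancerous / non-cancerous via MeSH tree-number prefixes (C04 = Neoplasms),
and export edge lists and GraphML.
"""

from __future__ import annotations

import io
from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, NamedTuple

import networkx as nx

from .errors import UsageError, ValidationError
from .lexicon import ConceptLexicon
from .model import AnnotatedDocument, ConceptID

__all__ = [
    "DDAEdge",
    "TargetSet",
    "document_comentions",
    "aggregate_comentions",
    "rank_and_filter",
    "RankResult",
    "partition_by_tree",
    "count_unique_partners",
    "export_graph",
]

Pair = tuple[ConceptID, ConceptID]


def _canonical_pair(a: ConceptID, b: ConceptID) -> Pair:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DDAEdge:
    """An unordered disease pair with a support score.

    ``support`` is a document co-mention count (``source="comention"``) or a
    Jaccard similarity of gene sets (``source="gene_overlap"``).
    ``provenance`` is the contributing document-id set for co-mention edges
    and the shared-gene count for gene-overlap edges.
    """

    a: ConceptID
    b: ConceptID
    support: float
    source: Literal["comention", "gene_overlap"] = "comention"
    provenance: frozenset[str] | int = frozenset()

    def __post_init__(self) -> None:
        if self.a.is_unknown() or self.b.is_unknown():
            raise ValidationError("DDA edges may not involve UNKNOWN concepts")
        if self.a == self.b:
            raise ValidationError("DDA edges require two distinct concepts")
        if self.support < 0:
            raise ValidationError("edge support must be non-negative")
        if self.a > self.b:  # store pair in canonical order
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def pair(self) -> Pair:
        return (self.a, self.b)

    @property
    def key(self) -> str:
        return f"{self.a.canonical}--{self.b.canonical}"

    def other(self, targets: "TargetSet | frozenset[ConceptID]") -> ConceptID:
        members = targets.targets if isinstance(targets, TargetSet) else targets
        if self.a in members and self.b not in members:
            return self.b
        if self.b in members and self.a not in members:
            return self.a
        raise UsageError(f"edge {self.key} is not a target–partner edge")


@dataclass(frozen=True)
class TargetSet:
    """The query diseases a network is built around (by default the three
    blood-cancer families: leukemia, lymphoma, multiple myeloma)."""

    targets: frozenset[ConceptID]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError("target set must be nonempty")

    def __contains__(self, cid: ConceptID) -> bool:
        return cid in self.targets

    @classmethod
    def of(cls, *ids: ConceptID | str) -> "TargetSet":
        return cls(
            frozenset(
                c if isinstance(c, ConceptID) else ConceptID.parse(c) for c in ids
            )
        )


def document_comentions(doc: AnnotatedDocument) -> set[frozenset[ConceptID]]:
    """All unordered pairs of distinct non-UNKNOWN concepts in one document;
    each pair at most once regardless of mention multiplicity."""
    concepts = sorted(
        {m.concept_id for m in doc.mentions if not m.concept_id.is_unknown()}
    )
    return {frozenset(p) for p in combinations(concepts, 2)}


def aggregate_comentions(
    docs: Iterable[AnnotatedDocument],
    count_mode: Literal["document", "occurrence"] = "document",
) -> list[DDAEdge]:
    """One edge per observed pair; support = number of contributing
    documents (default) or, in ``occurrence`` mode, the number of
    co-occurring mention pairs summed over documents.  Edges are returned in
    canonical pair order."""
    doc_sets: dict[frozenset[ConceptID], set[str]] = defaultdict(set)
    occurrence: Counter = Counter()
    for doc in docs:
        pairs = document_comentions(doc)
        if count_mode == "occurrence":
            counts = Counter(
                m.concept_id for m in doc.mentions if not m.concept_id.is_unknown()
            )
            for pair in pairs:
                x, y = sorted(pair)
                occurrence[pair] += counts[x] * counts[y]
        for pair in pairs:
            doc_sets[pair].add(doc.doc_id)
    edges = []
    for pair, ids in doc_sets.items():
        x, y = sorted(pair)
        support = occurrence[pair] if count_mode == "occurrence" else len(ids)
        edges.append(DDAEdge(x, y, support, "comention", frozenset(ids)))
    return sorted(edges, key=lambda e: e.key)


class RankResult(NamedTuple):
    """Output of :func:`rank_and_filter`: the ranked target–partner edges
    and, reported separately, edges between two targets."""

    edges: list[DDAEdge]
    target_target: list[DDAEdge]


def rank_and_filter(
    edges: Iterable[DDAEdge],
    targets: TargetSet,
    k: int = 100,
    min_target_links: int = 2,
    rank_by: Literal["edges", "partners"] = "edges",
) -> RankResult:
    """Top-k DDA selection around the target diseases.

    Keeps edges with exactly one endpoint in ``targets``; a partner disease
    survives only if it is linked to at least ``min_target_links`` distinct
    targets.  Surviving edges are ranked by support descending (ties broken
    by canonical pair rendering) and the top ``k`` returned.  In
    ``partners`` mode the top ``k`` *partner diseases* (by their best edge
    support) are selected and all their edges returned, for the reading of
    "top 100" as a node count rather than an edge count.
    """
    if k < 1:
        raise UsageError("k must be >= 1")
    target_partner: list[DDAEdge] = []
    target_target: list[DDAEdge] = []
    links: dict[ConceptID, set[ConceptID]] = defaultdict(set)
    for e in edges:
        a_in, b_in = e.a in targets, e.b in targets
        if a_in and b_in:
            target_target.append(e)
        elif a_in or b_in:
            target_partner.append(e)
            partner = e.b if a_in else e.a
            target = e.a if a_in else e.b
            links[partner].add(target)
    surviving = [
        e for e in target_partner
        if len(links[e.other(targets)]) >= min_target_links
    ]
    surviving.sort(key=lambda e: (-e.support, e.key))
    target_target.sort(key=lambda e: (-e.support, e.key))
    if rank_by == "partners":
        chosen: list[ConceptID] = []
        for e in surviving:
            p = e.other(targets)
            if p not in chosen:
                chosen.append(p)
            if len(chosen) == k:
                break
        keep = set(chosen)
        return RankResult(
            [e for e in surviving if e.other(targets) in keep], target_target
        )
    if rank_by != "edges":
        raise UsageError(f"unknown rank_by mode {rank_by!r}")
    return RankResult(surviving[:k], target_target)


def partition_by_tree(
    nodes: Iterable[ConceptID],
    lexicon: ConceptLexicon,
    cancer_prefixes: Iterable[str] = ("C04",),
) -> tuple[set[ConceptID], set[ConceptID], set[ConceptID]]:
    """Split nodes into (cancerous, non_cancerous, unclassified) by MeSH
    tree-number prefix; nodes without tree numbers are unclassified."""
    prefixes = tuple(cancer_prefixes)
    cancerous: set[ConceptID] = set()
    non_cancerous: set[ConceptID] = set()
    unclassified: set[ConceptID] = set()
    for node in nodes:
        trees = lexicon.tree_numbers(node)
        if not trees:
            unclassified.add(node)
        elif any(t.startswith(p) for t in trees for p in prefixes):
            cancerous.add(node)
        else:
            non_cancerous.add(node)
    return cancerous, non_cancerous, unclassified


def count_unique_partners(edges: Iterable[DDAEdge], targets: TargetSet) -> int:
    """Number of distinct non-target partner concepts across an edge list."""
    return len({e.other(targets) for e in edges})


def export_graph(
    edges: Iterable[DDAEdge],
    fmt: Literal["tsv", "graphml"] = "tsv",
    lexicon: ConceptLexicon | None = None,
) -> str:
    """Serialize a DDA network.

    ``tsv``: columns concept_a, concept_b, support, source, n_docs.
    ``graphml``: standard GraphML with node ``label`` attributes (preferred
    names when a lexicon is supplied) and edge ``support`` / ``source``
    attributes.  Output is deterministic: nodes and edges are emitted in
    canonical order.
    """
    edges = sorted(edges, key=lambda e: e.key)
    if fmt == "tsv":
        lines = ["concept_a\tconcept_b\tsupport\tsource\tn_docs"]
        for e in edges:
            n_docs = (
                len(e.provenance)
                if isinstance(e.provenance, frozenset)
                else e.provenance
            )
            support = int(e.support) if float(e.support).is_integer() else e.support
            lines.append(
                f"{e.a.canonical}\t{e.b.canonical}\t{support}\t{e.source}\t{n_docs}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "graphml":
        g = nx.Graph()
        nodes = sorted({c for e in edges for c in e.pair})
        for n in nodes:
            label = lexicon.preferred_name(n) if lexicon else n.canonical
            g.add_node(n.canonical, label=label)
        for e in edges:
            g.add_edge(
                e.a.canonical, e.b.canonical, support=float(e.support), source=e.source
            )
        buf = io.BytesIO()
        nx.write_graphml(g, buf)
        return buf.getvalue().decode()
    raise UsageError(f"unknown export format {fmt!r}")
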