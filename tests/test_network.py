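"""Co-mention DDA networks: aggregation, ranking, partitioning, export."""

import io
from collections import Counter
from itertools import combinations

import networkx as nx
import pytest

from cominer import (
    AnnotatedDocument,
    ConceptID,
    DDAEdge,
    Document,
    Mention,
    TargetSet,
    UNKNOWN,
    aggregate_comentions,
    count_unique_partners,
    document_comentions,
    export_graph,
    partition_by_tree,
    rank_and_filter,
)
from cominer.errors import UsageError, ValidationError

A = ConceptID("MESH", "D000001")
B = ConceptID("MESH", "D000002")
C = ConceptID("MESH", "D000003")
D = ConceptID("MESH", "D000004")
T1 = ConceptID("MESH", "D000101")
T2 = ConceptID("MESH", "D000102")


def _doc(doc_id, concepts):
    """One document mentioning each given concept once (UNKNOWN allowed)."""
    words = [f"w{i}" for i in range(len(concepts))]
    title = "t"
    abstract = " ".join(words)
    mentions = []
    pos = len(title) + 1
    for w, cid in zip(words, concepts):
        mentions.append(Mention(pos, pos + len(w), w, "Disease", cid))
        pos += len(w) + 1
    return AnnotatedDocument(Document(doc_id, title, abstract), mentions)


class TestDocumentComentions:
    def test_three_concepts_give_three_pairs(self):
        assert document_comentions(_doc("1", [A, B, C])) == {
            frozenset(p) for p in combinations([A, B, C], 2)
        }

    def test_repeated_single_concept_gives_no_pair(self):
        assert document_comentions(_doc("1", [A] * 5)) == set()

    def test_unknown_is_excluded(self):
        assert document_comentions(_doc("1", [UNKNOWN, A])) == set()


class TestDDAEdgeInvariants:
    def test_pair_stored_in_canonical_order(self):
        e = DDAEdge(B, A, 1.0)
        assert e.pair == (A, B)

    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            DDAEdge(A, A, 1.0)

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValidationError):
            DDAEdge(A, UNKNOWN, 1.0)


class TestAggregateComentions:
    def test_support_counts_documents_not_mentions(self):
        docs = [_doc("1", [A, B, A, B]), _doc("2", [A, B]), _doc("3", [A])]
        (edge,) = aggregate_comentions(docs)
        assert edge.pair == (A, B)
        assert edge.support == 2
        assert edge.provenance == frozenset({"1", "2"})

    def test_occurrence_mode_counts_mention_pairs(self):
        docs = [_doc("1", [A, B, A])]
        (edge,) = aggregate_comentions(docs, count_mode="occurrence")
        assert edge.support == 2  # two A mentions x one B mention

    def test_empty_corpus(self):
        assert aggregate_comentions([]) == []

    def test_support_conservation_identity(self, synth_bundle):
        _, _, _, corpus = synth_bundle
        edges = aggregate_comentions(corpus.gold)
        assert sum(e.support for e in edges) == sum(
            len(document_comentions(d)) for d in corpus.gold
        )

    def test_supports_equal_generator_ground_truth(self, synth_bundle):
        _, _, _, corpus = synth_bundle
        edges = aggregate_comentions(corpus.gold)
        assert {frozenset(e.pair): e.support for e in edges} == dict(corpus.pair_counts)


def _edges(*triples):
    return [DDAEdge(a, b, s) for a, b, s in triples]


class TestRankAndFilter:
    targets = TargetSet(frozenset({T1, T2}))

    def test_partner_linked_to_single_target_excluded(self):
        edges = _edges((T1, A, 5), (T1, B, 9), (T2, B, 1))
        result = rank_and_filter(edges, self.targets, k=10, min_target_links=2)
        assert {e.other(self.targets) for e in result.edges} == {B}

    def test_ranked_by_support_with_canonical_tie_break(self):
        edges = _edges((T1, A, 5), (T2, A, 5), (T1, B, 5), (T2, B, 7))
        result = rank_and_filter(edges, self.targets, k=10)
        keys = [(e.support, e.key) for e in result.edges]
        assert keys == sorted(keys, key=lambda t: (-t[0], t[1]))

    def test_target_target_edges_reported_separately(self):
        edges = _edges((T1, T2, 3), (T1, A, 5), (T2, A, 2))
        result = rank_and_filter(edges, self.targets, k=10)
        assert [e.pair for e in result.target_target] == [(T1, T2)]
        assert all(e.pair != (T1, T2) for e in result.edges)

    def test_top_k_monotone_in_k(self):
        edges = _edges((T1, A, 5), (T2, A, 4), (T1, B, 3), (T2, B, 9), (T1, C, 2), (T2, C, 2))
        prev = []
        for k in range(1, 7):
            cur = rank_and_filter(edges, self.targets, k=k).edges
            assert cur[: len(prev)] == prev
            prev = cur

    def test_partner_ranking_mode_selects_nodes(self):
        edges = _edges((T1, A, 9), (T2, A, 1), (T1, B, 5), (T2, B, 5), (T1, C, 3), (T2, C, 3))
        result = rank_and_filter(edges, self.targets, k=2, rank_by="partners")
        assert {e.other(self.targets) for e in result.edges} == {A, B}
        assert len(result.edges) == 4

    def test_empty_targets_rejected(self):
        with pytest.raises(ValidationError):
            TargetSet(frozenset())

    def test_bad_k_rejected(self):
        with pytest.raises(UsageError):
            rank_and_filter([], self.targets, k=0)


class TestPartitionByTree:
    def test_three_way_partition(self, small_lexicon):
        nodes = {
            ConceptID("MESH", "D009101"),  # C04 -> cancerous
            ConceptID("MESH", "D000740"),  # C15 -> non-cancerous
            ConceptID("OMIM", "614371"),   # no trees -> unclassified
        }
        cancer, non_cancer, unclassified = partition_by_tree(nodes, small_lexicon)
        assert cancer == {ConceptID("MESH", "D009101")}
        assert non_cancer == {ConceptID("MESH", "D000740")}
        assert unclassified == {ConceptID("OMIM", "614371")}
        assert cancer | non_cancer | unclassified == nodes

    def test_custom_prefixes(self, small_lexicon):
        nodes = {ConceptID("MESH", "D000740")}
        cancer, _, _ = partition_by_tree(nodes, small_lexicon, cancer_prefixes=("C15",))
        assert cancer == nodes


class TestCountUniquePartners:
    def test_distinct_partner_concepts(self):
        targets = TargetSet(frozenset({T1, T2}))
        edges = _edges((T1, A, 1), (T2, A, 2), (T1, B, 3))
        assert count_unique_partners(edges, targets) == 2

    def test_partner_count_at_most_edge_count(self):
        targets = TargetSet(frozenset({T1, T2}))
        edges = _edges((T1, A, 1), (T2, B, 2), (T1, C, 3))
        assert count_unique_partners(edges, targets) <= len(edges)


class TestExportGraph:
    def test_empty_edge_list_yields_valid_documents(self):
        assert export_graph([], "tsv").startswith("concept_a")
        g = nx.read_graphml(io.BytesIO(export_graph([], "graphml").encode()))
        assert len(g) == 0

    def test_triangle_exports_three_nodes_three_edges(self):
        edges = _edges((A, B, 1), (B, C, 2), (A, C, 3))
        g = nx.read_graphml(io.BytesIO(export_graph(edges, "graphml").encode()))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_graphml_round_trip_preserves_edge_multiset(self):
        edges = _edges((A, B, 4), (B, C, 2), (T1, A, 7))
        g = nx.read_graphml(io.BytesIO(export_graph(edges, "graphml").encode()))
        got = Counter(
            (tuple(sorted((u, v))), data["support"]) for u, v, data in g.edges(data=True)
        )
        want = Counter(
            ((e.a.canonical, e.b.canonical), float(e.support)) for e in edges
        )
        assert got == want

    def test_tsv_has_support_and_provenance_columns(self):
        e = DDAEdge(A, B, 3, "comention", frozenset({"1", "2", "3"}))
        lines = export_graph([e], "tsv").splitlines()
        assert lines[1].split("\t") == [
            "MESH:D000001", "MESH:D000002", "3", "comention", "3"
        ]

    def test_node_labels_use_preferred_names(self, small_lexicon):
        e = DDAEdge(ConceptID("MESH", "D005334"), ConceptID("MESH", "D000740"), 1)
        g = nx.read_graphml(
            io.BytesIO(export_graph([e], "graphml", small_lexicon).encode())
        )
        assert g.nodes["MESH:D005334"]["label"] == "Fever"

    def test_unknown_format_rejected(self):
        with pytest.raises(UsageError):
            export_graph([], "dot")
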