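"""Gene-overlap DDA networks and agreement between two DDA networks.

A gene-association database (DisGeNET-style) relates two diseases when their
gene sets share at least a threshold number of genes (20 by default), and
ranks such pairs by the Jaccard index of the gene sets.  This module derives
those edges from a disease→gene-set table and quantifies the overlap between
a co-mention network and a gene-overlap network: which fraction of one
network's disease pairs the other recovers, and which pairs are unique to
each.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from .errors import SchemaError, UsageError, ValidationError
from .lexicon import IDMap
from .model import ConceptID
from .network import DDAEdge, TargetSet, Pair, _canonical_pair

__all__ = [
    "GeneAssociationTable",
    "OverlapReport",
    "jaccard",
    "genelist_ddas",
    "compare_dda_sets",
]


def jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; 0 by convention when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass
class GeneAssociationTable:
    """Disease → gene-symbol set associations.

    Symbols are compared case-sensitively as given (``case_fold=True`` at
    load time folds dirty inputs).
    """

    assoc: dict[ConceptID, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, genes in self.assoc.items():
            if not genes or any(not g for g in genes):
                raise ValidationError(
                    f"{cid.canonical}: gene set must contain nonempty symbols"
                )

    def __len__(self) -> int:
        return len(self.assoc)

    def __contains__(self, cid: ConceptID) -> bool:
        return cid in self.assoc

    def genes(self, cid: ConceptID) -> frozenset[str]:
        return self.assoc.get(cid, frozenset())

    @classmethod
    def from_tsv(
        cls, stream: TextIO | str, case_fold: bool = False
    ) -> "GeneAssociationTable":
        """Long-format TSV: concept_id, gene_symbol (one pair per row;
        a header row ``concept_id\tgene_symbol`` is accepted and skipped)."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        assoc: dict[ConceptID, set[str]] = {}
        for lineno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "concept_id":
                continue
            if len(row) < 2:
                raise SchemaError(
                    f"gene table line {lineno}: need concept_id and gene_symbol"
                )
            gene = row[1].strip()
            if case_fold:
                gene = gene.casefold()
            assoc.setdefault(ConceptID.parse(row[0]), set()).add(gene)
        return cls({k: frozenset(v) for k, v in assoc.items()})

    def to_tsv(self) -> str:
        lines = ["concept_id\tgene_symbol"]
        for cid in sorted(self.assoc):
            for gene in sorted(self.assoc[cid]):
                lines.append(f"{cid.canonical}\t{gene}")
        return "\n".join(lines) + "\n"


def genelist_ddas(
    table: GeneAssociationTable,
    targets: TargetSet,
    min_shared: int = 20,
) -> list[DDAEdge]:
    """Gene-overlap DDA edges between each target and every other disease.

    A (target, other) pair qualifies when the gene sets share at least
    ``min_shared`` genes (boundary inclusive).  Edge support is the Jaccard
    index of the two gene sets; provenance is the shared-gene count.  Edges
    are ranked by Jaccard descending with canonical tie-break.
    """
    missing = [t.canonical for t in sorted(targets.targets) if t not in table]
    if missing:
        raise UsageError(f"target(s) absent from gene table: {', '.join(missing)}")
    edges: dict[Pair, DDAEdge] = {}
    for target in sorted(targets.targets):
        t_genes = table.genes(target)
        for other in sorted(table.assoc):
            if other == target:
                continue
            o_genes = table.genes(other)
            shared = len(t_genes & o_genes)
            if shared < min_shared:
                continue
            pair = _canonical_pair(target, other)
            if pair not in edges:
                edges[pair] = DDAEdge(
                    pair[0], pair[1], jaccard(set(t_genes), set(o_genes)),
                    "gene_overlap", shared,
                )
    return sorted(edges.values(), key=lambda e: (-e.support, e.key))


@dataclass(frozen=True)
class OverlapReport:
    """Agreement between two DDA edge sets matched on concept pairs only
    (support values and sources are ignored)."""

    n_a: int
    n_b: int
    shared_edges: frozenset[Pair]
    unique_a: frozenset[Pair]
    unique_b: frozenset[Pair]
    recovered_fraction_of_b: float
    unique_fraction_of_a: float
    unique_fraction_of_b: float
    untranslated_b: int = 0

    def as_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": len(self.shared_edges),
            "recovered_fraction_of_b": self.recovered_fraction_of_b,
            "unique_fraction_of_a": self.unique_fraction_of_a,
            "unique_fraction_of_b": self.unique_fraction_of_b,
            "untranslated_b": self.untranslated_b,
        }


def _translate_pair(pair: Pair, id_map: IDMap) -> set[Pair] | None:
    """All renderings of a pair under the id map; None when an endpoint has
    no translation.  Non-CUI endpoints pass through unchanged."""
    sides: list[set[ConceptID]] = []
    for cid in pair:
        mapped = id_map.get(cid.canonical) or id_map.get(cid.accession)
        if mapped:
            sides.append(set(mapped))
        elif re.fullmatch(r"C\d{7}", cid.accession):
            return None  # CUI-shaped (C + 7 digits) with no translation
        else:
            sides.append({cid})
    out = {
        _canonical_pair(x, y) for x in sides[0] for y in sides[1] if x != y
    }
    return out or None


def compare_dda_sets(
    a: Iterable[DDAEdge],
    b: Iterable[DDAEdge],
    id_map: IDMap | None = None,
) -> OverlapReport:
    """Overlap statistics between edge sets ``a`` and ``b``.

    With an ``id_map``, ``b``'s endpoints are first translated into ``a``'s
    namespace; a CUI mapping to several concepts expands the edge to every
    combination and the edge matches when any combination occurs in ``a``.
    Edges of ``b`` with an unmappable endpoint are excluded from the
    fractions and counted in ``untranslated_b``.  An empty ``b`` yields a
    recovered fraction of 1.0 by (vacuous-truth) convention.
    """
    a_pairs = {e.pair for e in a}
    b_raw = [e.pair for e in {e.pair: e for e in b}.values()]

    untranslated = 0
    b_variants: list[tuple[Pair, set[Pair]]] = []
    for pair in b_raw:
        variants = _translate_pair(pair, id_map) if id_map else {pair}
        if variants is None:
            untranslated += 1
            continue
        b_variants.append((pair, variants))

    matched_a: set[Pair] = set()
    matched_b: set[Pair] = set()
    for orig, variants in b_variants:
        hit = variants & a_pairs
        if hit:
            matched_b.add(orig)
            matched_a.update(hit)

    n_a, n_b = len(a_pairs), len(b_variants)
    unique_a = frozenset(a_pairs - matched_a)
    unique_b = frozenset(p for p, _ in b_variants if p not in matched_b)
    return OverlapReport(
        n_a=n_a,
        n_b=n_b,
        shared_edges=frozenset(matched_a),
        unique_a=unique_a,
        unique_b=unique_b,
        recovered_fraction_of_b=(len(matched_b) / n_b) if n_b else 1.0,
        unique_fraction_of_a=(len(unique_a) / n_a) if n_a else 0.0,
        unique_fraction_of_b=(len(unique_b) / n_b) if n_b else 0.0,
        untranslated_b=untranslated,
    )
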