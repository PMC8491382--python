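"""Disease concept lexicon: MeSH-style XML parsing, term indexing, and
cross-ontology id translation (UMLS CUI -> MeSH/OMIM).

The lexicon is the terminology the normalization step maps mentions into.  It
can be built from MeSH descriptor / supplementary-record XML (the schema of
the ``desc2021`` / ``supp2021`` FTP files), or from a plain TSV
``concept_id<TAB>preferred_name<TAB>synonym...`` for fixtures and small
vocabularies.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

from lxml import etree

from .errors import ParseError, SchemaError, ValidationError
from .model import ConceptID

__all__ = [
    "ConceptEntry",
    "ConceptLexicon",
    "IDMap",
    "normalize_term",
    "parse_mesh_descriptors",
    "entries_to_mesh_xml",
    "build_lookup",
    "load_id_map",
    "translate_ids",
]


def normalize_term(text: str) -> str:
    """Canonical lookup key for a term: NFKC-compatibility normalized,
    case-folded, punctuation replaced by spaces (preserving token boundaries
    of hyphenated names), whitespace collapsed and stripped.
    """
    text = unicodedata.normalize("NFKC", text).casefold()
    text = "".join(c if c.isalnum() else " " for c in text)
    return " ".join(text.split())


@dataclass(frozen=True)
class ConceptEntry:
    """One concept: id, preferred name, synonym set and MeSH tree numbers."""

    concept_id: ConceptID
    preferred_name: str
    synonyms: frozenset[str] = frozenset()
    tree_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        # canonical form: the preferred name is itself a synonym
        object.__setattr__(self, "synonyms", frozenset(self.synonyms) | {self.preferred_name})

    @property
    def all_names(self) -> frozenset[str]:
        return self.synonyms


@dataclass
class ConceptLexicon:
    """Concept entries plus an inverted index of normalized terms.

    ``term_index`` maps every normalized name/synonym to the set of concepts
    carrying it; collisions (one term shared by several concepts) are
    preserved as multi-element sets and resolved downstream by canonical-id
    order.
    """

    entries: dict[ConceptID, ConceptEntry] = field(default_factory=dict)
    term_index: dict[str, frozenset[ConceptID]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, term: str) -> frozenset[ConceptID]:
        """Concepts whose name/synonym set contains ``term`` (after
        normalization); empty frozenset on no hit."""
        return self.term_index.get(normalize_term(term), frozenset())

    def lookup_normalized(self, key: str) -> frozenset[ConceptID]:
        """Like :meth:`lookup` for an already-normalized key."""
        return self.term_index.get(key, frozenset())

    def preferred_name(self, concept_id: ConceptID) -> str:
        entry = self.entries.get(concept_id)
        return entry.preferred_name if entry else concept_id.canonical

    def tree_numbers(self, concept_id: ConceptID) -> frozenset[str]:
        entry = self.entries.get(concept_id)
        return entry.tree_numbers if entry else frozenset()

    @property
    def max_term_tokens(self) -> int:
        """Longest indexed term, in tokens; bounds the recognizer window."""
        return max((len(t.split()) for t in self.term_index), default=0)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_entries(cls, entries: Iterable[ConceptEntry]) -> "ConceptLexicon":
        return build_lookup(list(entries))

    @classmethod
    def from_tsv(cls, stream: TextIO | str) -> "ConceptLexicon":
        """Plain-TSV lexicon: concept_id, preferred name, then any number of
        synonym columns; an optional final column ``trees=C04.557;C15`` adds
        tree numbers."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        entries = []
        for row in csv.reader(stream, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise SchemaError(f"lexicon row needs id and name: {row!r}")
            trees: frozenset[str] = frozenset()
            syn_cols = row[2:]
            if syn_cols and syn_cols[-1].startswith("trees="):
                trees = frozenset(
                    t for t in syn_cols[-1][len("trees="):].split(";") if t
                )
                syn_cols = syn_cols[:-1]
            entries.append(
                ConceptEntry(
                    ConceptID.parse(row[0]),
                    row[1],
                    frozenset(s for s in syn_cols if s),
                    trees,
                )
            )
        return build_lookup(entries)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        for cid in sorted(self.entries):
            e = self.entries[cid]
            row = [cid.canonical, e.preferred_name]
            row.extend(sorted(e.synonyms - {e.preferred_name}))
            if e.tree_numbers:
                row.append("trees=" + ";".join(sorted(e.tree_numbers)))
            writer.writerow(row)
        return buf.getvalue()


def build_lookup(entries: list[ConceptEntry]) -> ConceptLexicon:
    """Index entries by the normalized form of every name and synonym.

    Raises :class:`ValidationError` on duplicate concept ids.  Terms whose
    normalized form is empty (pure punctuation) are skipped.
    """
    lex = ConceptLexicon()
    index: dict[str, set[ConceptID]] = {}
    for entry in entries:
        if entry.concept_id in lex.entries:
            raise ValidationError(
                f"duplicate concept id {entry.concept_id.canonical}"
            )
        lex.entries[entry.concept_id] = entry
        for name in entry.all_names:
            key = normalize_term(name)
            if key:
                index.setdefault(key, set()).add(entry.concept_id)
    lex.term_index = {k: frozenset(v) for k, v in index.items()}
    return lex


# -- MeSH XML ---------------------------------------------------------------

_RECORD_TAGS = {
    "DescriptorRecord": ("DescriptorUI", "DescriptorName"),
    "SupplementalRecord": ("SupplementalRecordUI", "SupplementalRecordName"),
}


def parse_mesh_descriptors(stream) -> list[ConceptEntry]:
    """Parse MeSH descriptor or supplementary-record XML into concept
    entries.

    Handles the subset of the DescriptorRecordSet / SupplementalRecordSet
    schema that carries names, synonyms (all ``Term/String`` values under
    ``ConceptList``) and ``TreeNumberList``.  Records without a UI raise a
    record error naming the record index; malformed XML raises
    :class:`ParseError`.
    """
    try:
        tree = etree.parse(stream) if not isinstance(stream, str) else etree.fromstring(
            stream.encode()
        ).getroottree()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed MeSH XML: {exc}")
    entries: list[ConceptEntry] = []
    index = 0
    for tag, (ui_tag, name_tag) in _RECORD_TAGS.items():
        for record in tree.iter(tag):
            index += 1
            ui = record.findtext(ui_tag)
            if not ui:
                raise SchemaError(f"record #{index} ({tag}) missing {ui_tag}")
            name = record.findtext(f"{name_tag}/String") or ""
            if not name:
                raise SchemaError(f"record {ui}: missing {name_tag}")
            synonyms = {
                s.text for s in record.iterfind(".//TermList/Term/String") if s.text
            }
            trees = {
                t.text
                for t in record.iterfind("TreeNumberList/TreeNumber")
                if t.text
            }
            entries.append(
                ConceptEntry(
                    ConceptID("MESH", ui),
                    name,
                    frozenset(synonyms),
                    frozenset(trees),
                )
            )
    return entries


def entries_to_mesh_xml(entries: Iterable[ConceptEntry]) -> str:
    """Serialize entries as DescriptorRecordSet XML; inverse of
    :func:`parse_mesh_descriptors` (used by the synthetic fixture
    generator)."""
    root = etree.Element("DescriptorRecordSet")
    for e in entries:
        rec = etree.SubElement(root, "DescriptorRecord")
        etree.SubElement(rec, "DescriptorUI").text = e.concept_id.accession
        name = etree.SubElement(rec, "DescriptorName")
        etree.SubElement(name, "String").text = e.preferred_name
        if e.tree_numbers:
            tl = etree.SubElement(rec, "TreeNumberList")
            for t in sorted(e.tree_numbers):
                etree.SubElement(tl, "TreeNumber").text = t
        cl = etree.SubElement(rec, "ConceptList")
        concept = etree.SubElement(cl, "Concept")
        tl = etree.SubElement(concept, "TermList")
        for s in sorted(e.all_names):
            term = etree.SubElement(tl, "Term")
            etree.SubElement(term, "String").text = s
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# -- id translation ---------------------------------------------------------

_CUI_RE = re.compile(r"C\d+$")


@dataclass
class IDMap:
    """Translation table from UMLS CUIs to MeSH/OMIM concept ids."""

    pairs: dict[str, frozenset[ConceptID]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, source_id: str) -> frozenset[ConceptID]:
        return self.pairs.get(source_id, frozenset())


def load_id_map(stream: TextIO | str) -> IDMap:
    """Load a two-column TSV (source CUI, target concept id); repeated source
    rows accumulate into a target set."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs: dict[str, set[ConceptID]] = {}
    for lineno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or row[0].startswith("#"):
            continue
        if len(row) < 2:
            raise SchemaError(f"id-map line {lineno}: need source and target")
        src = row[0].strip()
        if not _CUI_RE.match(src):
            raise SchemaError(f"id-map line {lineno}: {src!r} is not a CUI")
        pairs.setdefault(src, set()).add(ConceptID.parse(row[1]))
    return IDMap({k: frozenset(v) for k, v in pairs.items()})


def translate_ids(
    ids: Iterable[str],
    id_map: IDMap,
    policy: str = "drop",
) -> tuple[set[ConceptID], set[str]]:
    """Apply the map to a set of source ids.

    Returns ``(translated, unmapped)``.  ``policy`` controls unmapped ids:
    ``"drop"`` leaves them only in the unmapped set; ``"keep-as-foreign"``
    is reported via the unmapped set as well (callers decide how to carry
    foreign ids, since they are not :class:`ConceptID` values).
    """
    if policy not in ("drop", "keep-as-foreign"):
        raise ValidationError(f"unknown translation policy {policy!r}")
    translated: set[ConceptID] = set()
    unmapped: set[str] = set()
    for src in ids:
        targets = id_map.get(src)
        if targets:
            translated.update(targets)
        else:
            unmapped.add(src)
    return translated, unmapped
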