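"""Core domain objects: concept identifiers, documents, and offset-anchored
disease mentions.

Offset convention
-----------------
All mention offsets are 0-based, half-open character offsets into the
*composed text* of a document: ``title + " " + abstract`` (the bare title when
the abstract is empty).  This matches the convention of PubTator-distributed
corpora such as NCBI Disease and BC5CDR, and makes ``composed[start:end] ==
surface`` an exact, checkable invariant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering

from .errors import ValidationError

__all__ = [
    "ConceptID",
    "UNKNOWN",
    "Document",
    "Mention",
    "AnnotatedDocument",
    "compose_text",
]

_CUI_RE = re.compile(r"C\d+$")
_MESH_ACC_RE = re.compile(r"[CD]\d{6,9}$")


@total_ordering
@dataclass(frozen=True)
class ConceptID:
    """A disease concept identifier in the MeSH or OMIM namespace.

    Canonical rendering is ``"MESH:D009101"`` / ``"OMIM:123456"``.  The module
    constant :data:`UNKNOWN` is the distinguished sink for mentions that could
    not be normalized; it lives outside both namespaces and renders as
    ``"UNKNOWN"``.
    """

    namespace: str
    accession: str

    NAMESPACES = ("MESH", "OMIM")

    def __post_init__(self) -> None:
        if self.namespace not in self.NAMESPACES and self.namespace != "UNKNOWN":
            raise ValidationError(f"unknown concept namespace: {self.namespace!r}")

    @property
    def canonical(self) -> str:
        if self.namespace == "UNKNOWN":
            return "UNKNOWN"
        return f"{self.namespace}:{self.accession}"

    def is_unknown(self) -> bool:
        return self.namespace == "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical

    def __lt__(self, other: "ConceptID") -> bool:
        return self.canonical < other.canonical

    @classmethod
    def parse(cls, text: str) -> "ConceptID":
        """Parse a concept identifier as written in corpora and tables.

        Accepts explicit ``MESH:``/``OMIM:`` prefixes, bare MeSH descriptor or
        supplementary accessions (``D009101``, ``C538324``), and bare numeric
        OMIM ids.  ``-1``, ``""`` and ``"UNKNOWN"`` map to :data:`UNKNOWN`.
        """
        text = text.strip()
        if text in ("", "-1", "UNKNOWN", "unknown"):
            return UNKNOWN
        if ":" in text:
            ns, _, acc = text.partition(":")
            ns = ns.upper()
            if ns == "MESH" and _MESH_ACC_RE.match(acc):
                return cls("MESH", acc)
            if ns == "OMIM" and acc.isdigit():
                return cls("OMIM", acc)
            raise ValidationError(f"unparseable concept id: {text!r}")
        if _MESH_ACC_RE.match(text):
            return cls("MESH", text)
        if text.isdigit():
            return cls("OMIM", text)
        raise ValidationError(f"unparseable concept id: {text!r}")


UNKNOWN = ConceptID("UNKNOWN", "")


@dataclass(frozen=True)
class Document:
    """A title+abstract unit identified by a corpus id (typically a PMID)."""

    doc_id: str
    title: str
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("doc_id must be nonempty")
        if not self.title:
            raise ValidationError(f"document {self.doc_id!r}: title must be nonempty")


def compose_text(document: Document) -> str:
    """Title and abstract joined by a single space (title alone if the
    abstract is empty); the string all mention offsets refer to."""
    if document.abstract:
        return f"{document.title} {document.abstract}"
    return document.title


@dataclass(frozen=True)
class Mention:
    """A disease mention anchored to the composed text of its document.

    ``raw_concept`` preserves composite annotation fields (several ids joined
    by ``|`` or ``+``) verbatim; ``concept_id`` then holds the first id.
    """

    start: int
    end: int
    surface: str
    entity_type: str = "Disease"
    concept_id: ConceptID = UNKNOWN
    raw_concept: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid mention offsets [{self.start}, {self.end})"
            )
        if not self.entity_type:
            raise ValidationError("entity_type must be nonempty")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def with_concept(self, concept_id: ConceptID) -> "Mention":
        return Mention(
            self.start, self.end, self.surface, self.entity_type,
            concept_id, self.raw_concept,
        )


@dataclass
class AnnotatedDocument:
    """A document plus its mentions, kept sorted by (start, end)."""

    document: Document
    mentions: list[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mentions = sorted(self.mentions, key=lambda m: (m.start, m.end))

    @property
    def doc_id(self) -> str:
        return self.document.doc_id

    def validate(self) -> None:
        """Check every mention's offsets and surface against the composed
        text; raises :class:`ValidationError` naming the document."""
        text = compose_text(self.document)
        for m in self.mentions:
            if m.end > len(text):
                raise ValidationError(
                    f"document {self.doc_id!r}: mention [{m.start}, {m.end}) "
                    f"exceeds composed text length {len(text)}"
                )
            slice_ = text[m.start:m.end]
            if slice_ != m.surface:
                raise ValidationError(
                    f"document {self.doc_id!r}: mention [{m.start}, {m.end}) "
                    f"surface {m.surface!r} != composed slice {slice_!r}"
                )
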