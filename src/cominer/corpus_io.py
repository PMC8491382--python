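"""Read and write abstract corpora: PubTator files and id/title/abstract
tables.

PubTator records are blank-line separated::

    1001|t|Fever study
    1001|a|Fever and lymphoma.
    1001<TAB>12<TAB>17<TAB>Fever<TAB>Disease<TAB>D005334

Mention offsets refer to ``title + " " + abstract`` (see :mod:`cominer.model`).
Reading validates every mention surface against the composed text;
:func:`write_pubtator` is the exact inverse of :func:`read_pubtator` on
canonical-form input.
"""

from __future__ import annotations

import csv
import io
import re
from typing import Iterable, TextIO

from .errors import ParseError, SchemaError, ValidationError
from .model import AnnotatedDocument, ConceptID, Document, Mention, UNKNOWN

__all__ = [
    "read_pubtator",
    "write_pubtator",
    "read_abstract_table",
    "write_abstract_table",
]

_TITLE_RE = re.compile(r"^(?P<id>[^|]+)\|t\|(?P<text>.*)$")
_ABSTRACT_RE = re.compile(r"^(?P<id>[^|]+)\|a\|(?P<text>.*)$")
_COMPOSITE_SPLIT = re.compile(r"[|+]")


def _parse_concept_field(raw: str) -> tuple[ConceptID, str | None]:
    """Composite fields ('D001+D002', 'D001|D002') reduce to the first id;
    the raw field is preserved for round-tripping."""
    raw = raw.strip()
    parts = [p for p in _COMPOSITE_SPLIT.split(raw) if p]
    if len(parts) <= 1:
        return ConceptID.parse(raw), None
    return ConceptID.parse(parts[0]), raw


def _render_concept_field(m: Mention) -> str:
    if m.raw_concept is not None:
        return m.raw_concept
    if m.concept_id.is_unknown():
        return "-1"
    return m.concept_id.canonical


def _as_lines(stream: TextIO | str) -> Iterable[tuple[int, str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for i, line in enumerate(stream, start=1):
        yield i, line.rstrip("\n")


def read_pubtator(stream: TextIO | str) -> list[AnnotatedDocument]:
    """Parse a PubTator stream (or string) into annotated documents.

    Raises :class:`ParseError` (with line number) on malformed lines and
    :class:`ValidationError` when a mention's offsets disagree with the
    composed text.
    """
    docs: list[AnnotatedDocument] = []
    cur_id: str | None = None
    title = abstract = ""
    mentions: list[Mention] = []
    seen_ids: set[str] = set()

    def flush() -> None:
        nonlocal cur_id, title, abstract, mentions
        if cur_id is None:
            return
        if cur_id in seen_ids:
            raise ValidationError(f"duplicate doc_id {cur_id!r} in corpus")
        seen_ids.add(cur_id)
        doc = AnnotatedDocument(Document(cur_id, title, abstract), mentions)
        doc.validate()
        docs.append(doc)
        cur_id, title, abstract, mentions = None, "", "", []

    for lineno, line in _as_lines(stream):
        if not line.strip():
            flush()
            continue
        m = _TITLE_RE.match(line)
        if m and "\t" not in line.split("|", 1)[0]:
            flush()
            cur_id, title = m.group("id"), m.group("text")
            continue
        m = _ABSTRACT_RE.match(line)
        if m and cur_id is not None and m.group("id") == cur_id:
            abstract = m.group("text")
            continue
        fields = line.split("\t")
        if len(fields) not in (5, 6):
            raise ParseError(
                f"expected a title/abstract line or a 5/6-field mention line, "
                f"got {line!r}", line=lineno,
            )
        if cur_id is None or fields[0] != cur_id:
            raise ParseError(
                f"mention line for {fields[0]!r} outside its record", line=lineno
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"non-integer offsets in {line!r}", line=lineno)
        concept, raw = (UNKNOWN, None)
        if len(fields) == 6:
            try:
                concept, raw = _parse_concept_field(fields[5])
            except ValidationError as exc:
                raise ParseError(str(exc), line=lineno)
        mentions.append(
            Mention(start, end, fields[3], fields[4], concept, raw)
        )
    flush()
    return docs


def write_pubtator(docs: Iterable[AnnotatedDocument]) -> str:
    """Serialize annotated documents to canonical PubTator text.

    Each document becomes a title line, an abstract line (omitted when the
    abstract is empty), its mention lines sorted by offsets, and a blank
    separator line.  Validates offsets before writing.
    """
    out: list[str] = []
    for doc in docs:
        doc.validate()
        d = doc.document
        out.append(f"{d.doc_id}|t|{d.title}")
        if d.abstract:
            out.append(f"{d.doc_id}|a|{d.abstract}")
        for m in doc.mentions:
            out.append(
                "\t".join(
                    (
                        d.doc_id,
                        str(m.start),
                        str(m.end),
                        m.surface,
                        m.entity_type,
                        _render_concept_field(m),
                    )
                )
            )
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


_REQUIRED_COLUMNS = ("id", "title", "abstract")


def read_abstract_table(stream: TextIO | str, delimiter: str = "\t") -> list[Document]:
    """Read a delimited table with header columns id, title, abstract.

    Fields may be quoted (csv conventions), so titles containing the
    delimiter survive a round-trip.  Duplicate ids raise
    :class:`ValidationError`; missing columns raise :class:`SchemaError`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream, delimiter=delimiter)
    cols = reader.fieldnames or []
    missing = [c for c in _REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"abstract table missing column(s): {', '.join(missing)}")
    docs: list[Document] = []
    seen: set[str] = set()
    for row in reader:
        doc_id = (row["id"] or "").strip()
        if doc_id in seen:
            raise ValidationError(f"duplicate id {doc_id!r} in abstract table")
        seen.add(doc_id)
        docs.append(Document(doc_id, row["title"] or "", row["abstract"] or ""))
    return docs


def write_abstract_table(docs: Iterable[Document], delimiter: str = "\t") -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(_REQUIRED_COLUMNS)
    for d in docs:
        writer.writerow((d.doc_id, d.title, d.abstract))
    return buf.getvalue()
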