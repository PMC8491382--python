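"""Mention normalization and the composed annotation pipeline.

Normalization maps a recognized surface form to a concept id by exact lookup
of its normalized term in the lexicon; surfaces absent from the terminology
fall into the explicit UNKNOWN sink.  When one term is shared by several
concepts, the lexicographically smallest canonical id wins — a deterministic
stand-in for learned concept ranking.

:func:`annotate_corpus` chains recognition and normalization over a corpus
and returns the annotated documents together with a summary (document,
mention and unknown-mention counts), skipping — with a logged warning —
documents that fail validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import ValidationError
from .lexicon import ConceptLexicon
from .model import AnnotatedDocument, ConceptID, Document, Mention, UNKNOWN
from .ner import Recognizer, DictionaryRecognizer, RecognizerConfig, validate_mentions

__all__ = ["normalize_mention", "annotate_corpus", "AnnotationResult"]

logger = logging.getLogger(__name__)


def normalize_mention(surface: str, lexicon: ConceptLexicon) -> ConceptID:
    """Concept id for a mention surface, or UNKNOWN when the term is not in
    the terminology.  Multi-concept collisions resolve to the smallest
    canonical id (stable across runs)."""
    hits = lexicon.lookup(surface)
    if not hits:
        return UNKNOWN
    return min(hits)


@dataclass
class AnnotationResult:
    """Annotated documents plus corpus-level bookkeeping."""

    documents: list[AnnotatedDocument] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


def annotate_corpus(
    docs: Iterable[Document],
    lexicon: ConceptLexicon,
    config: RecognizerConfig | None = None,
    recognizer: Recognizer | None = None,
) -> AnnotationResult:
    """Recognize then normalize every document.

    A custom ``recognizer`` (plug-in engine) replaces the built-in dictionary
    tagger; its output is validated against the mention contract and failing
    documents are skipped and counted rather than aborting the corpus.
    """
    if len(lexicon) == 0:
        raise ValidationError("annotation requires a nonempty lexicon")
    engine: Recognizer = recognizer or DictionaryRecognizer(
        lexicon, config or RecognizerConfig()
    )
    out: list[AnnotatedDocument] = []
    n_mentions = n_unknown = n_skipped = 0
    for doc in docs:
        try:
            raw = engine.recognize(doc)
            validate_mentions(doc, raw)
        except ValidationError as exc:
            logger.warning("skipping document %s: %s", doc.doc_id, exc)
            n_skipped += 1
            continue
        mentions: list[Mention] = []
        for m in raw:
            cid = m.concept_id
            if cid.is_unknown():
                cid = normalize_mention(m.surface, lexicon)
            mentions.append(m.with_concept(cid))
            n_mentions += 1
            if cid.is_unknown():
                n_unknown += 1
        annotated = AnnotatedDocument(doc, mentions)
        annotated.validate()
        out.append(annotated)
    summary = {
        "documents": len(out),
        "skipped": n_skipped,
        "mentions": n_mentions,
        "unknown_mentions": n_unknown,
        "unknown_rate": (n_unknown / n_mentions) if n_mentions else 0.0,
    }
    return AnnotationResult(out, summary)
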