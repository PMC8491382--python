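"""Disease mention recognition.

The built-in engine is a deterministic dictionary tagger: a greedy,
left-to-right, longest-match scan over token n-grams whose normalized form
hits the lexicon term index.  Matches are anchored to token boundaries, so a
lexicon term never fires inside a longer word ("oma" never matches inside
"lymphoma").  Neural recognizers conforming to the same ``Document -> list of
Mention`` contract can be plugged in via :class:`Recognizer`; the validator
enforces the contract (sorted, non-overlapping, offset-consistent mentions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .errors import ValidationError
from .lexicon import ConceptLexicon, normalize_term
from .model import Document, Mention, compose_text

__all__ = [
    "TokenSpan",
    "RecognizerConfig",
    "tokenize",
    "recognize",
    "DictionaryRecognizer",
    "Recognizer",
    "validate_mentions",
]

# maximal runs of letters/digits (underscore excluded)
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

TokenSpan = tuple[int, int]


def tokenize(text: str) -> list[TokenSpan]:
    """Character spans of maximal alphanumeric runs, in order."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]


@dataclass(frozen=True)
class RecognizerConfig:
    """Dictionary-tagger settings.

    ``max_ngram`` caps the candidate window in tokens (longest disease names
    in MeSH run to ~10 tokens); ``case_sensitive`` restricts matching to
    terms identical after punctuation normalization but without case folding.
    """

    max_ngram: int = 10
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.max_ngram < 1:
            raise ValidationError("max_ngram must be >= 1")


def _normalize_cased(text: str) -> str:
    # punctuation-to-space and whitespace collapse, but no case folding
    text = "".join(c if c.isalnum() else " " for c in text)
    return " ".join(text.split())


def recognize(
    document: Document,
    lexicon: ConceptLexicon,
    config: RecognizerConfig | None = None,
) -> list[Mention]:
    """Greedy longest-match dictionary recognition over the composed text.

    Returns non-overlapping mentions sorted by offset, entity type
    ``"Disease"``, concept id left UNKNOWN (normalization is a separate
    step).  Deterministic: identical input and config give identical output.
    """
    config = config or RecognizerConfig()
    if len(lexicon) == 0:
        raise ValidationError("recognizer requires a nonempty lexicon")
    text = compose_text(document)
    tokens = tokenize(text)
    window = min(config.max_ngram, max(lexicon.max_term_tokens, 1))

    cased_index: set[str] | None = None
    if config.case_sensitive:
        cased_index = {
            _normalize_cased(name)
            for entry in lexicon.entries.values()
            for name in entry.all_names
        }

    mentions: list[Mention] = []
    i = 0
    n_tok = len(tokens)
    while i < n_tok:
        matched = 0
        for n in range(min(window, n_tok - i), 0, -1):
            start = tokens[i][0]
            end = tokens[i + n - 1][1]
            candidate = text[start:end]
            if cased_index is not None:
                hit = _normalize_cased(candidate) in cased_index and bool(
                    lexicon.lookup(candidate)
                )
            else:
                hit = bool(lexicon.lookup(candidate))
            if hit:
                mentions.append(Mention(start, end, candidate))
                matched = n
                break
        i += matched if matched else 1
    return mentions


@runtime_checkable
class Recognizer(Protocol):
    """Plug-in contract: any callable component producing valid, sorted,
    non-overlapping mentions for a document may replace the built-in
    engine."""

    def recognize(self, document: Document) -> list[Mention]: ...


@dataclass(frozen=True)
class DictionaryRecognizer:
    """The built-in engine bound to a lexicon and config (satisfies
    :class:`Recognizer`)."""

    lexicon: ConceptLexicon
    config: RecognizerConfig = RecognizerConfig()

    def recognize(self, document: Document) -> list[Mention]:
        return recognize(document, self.lexicon, self.config)


def validate_mentions(document: Document, mentions: list[Mention]) -> None:
    """Enforce the recognizer contract: offsets within the composed text,
    surfaces equal to their slices, and no overlapping spans."""
    text = compose_text(document)
    prev_end = -1
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        if m.end > len(text) or text[m.start:m.end] != m.surface:
            raise ValidationError(
                f"document {document.doc_id!r}: mention [{m.start}, {m.end}) "
                f"does not match composed text"
            )
        if m.start < prev_end:
            raise ValidationError(
                f"document {document.doc_id!r}: overlapping mentions at "
                f"offset {m.start}"
            )
        prev_end = m.end
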