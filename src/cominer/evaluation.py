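"""Precision / recall / F1 scoring of predicted annotations against gold.

Two levels, following the strict conventions of the BC5CDR-style community
scorer:

* **span level** (recognition): a predicted mention is a true positive iff an
  unmatched gold mention in the same document has exactly the same
  ``(start, end)`` boundaries; matching is one-to-one, with no partial credit
  for overlapping spans.
* **concept level** (normalization): per-document sets of distinct
  non-UNKNOWN concept ids are compared; tp = |gold ∩ pred|, fp = |pred \\
  gold|, fn = |gold \\ pred|, summed over documents.  UNKNOWN predictions are
  never true positives.  In ``gold_spans`` mode predictions are re-derived by
  normalizing the gold spans' surfaces (normalization scored under a perfect
  recognizer); in ``predicted_spans`` mode the full pipeline output is
  scored, so recognition errors cascade into the concept-level score.

Metrics use the conventions P = tp/(tp+fp), R = tp/(tp+fn),
F1 = 2PR/(P+R), with zero denominators mapping to 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal

from .errors import ValidationError
from .lexicon import ConceptLexicon
from .model import AnnotatedDocument, ConceptID
from .nen import normalize_mention

__all__ = [
    "EvalCounts",
    "EvalResult",
    "metrics_from_counts",
    "harmonic_f1",
    "round2",
    "evaluate_ner",
    "evaluate_nen",
]


@dataclass(frozen=True)
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("tp/fp/fn must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class EvalResult:
    counts: EvalCounts
    precision: float
    recall: float
    f1: float

    def rounded(self) -> dict[str, float]:
        """Metrics rounded half-up to two decimals, the precision at which
        such scores are conventionally reported."""
        return {
            "precision": round2(self.precision),
            "recall": round2(self.recall),
            "f1": round2(self.f1),
        }

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 as the harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metrics_from_counts(counts: EvalCounts) -> EvalResult:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvalResult(counts, precision, recall, harmonic_f1(precision, recall))


def _align(
    gold: Iterable[AnnotatedDocument], pred: Iterable[AnnotatedDocument]
) -> list[tuple[AnnotatedDocument, AnnotatedDocument]]:
    gold_by_id = {d.doc_id: d for d in gold}
    pred_by_id = {d.doc_id: d for d in pred}
    if set(gold_by_id) != set(pred_by_id):
        only_g = sorted(set(gold_by_id) - set(pred_by_id))[:5]
        only_p = sorted(set(pred_by_id) - set(gold_by_id))[:5]
        raise ValidationError(
            f"gold and predicted corpora cover different documents "
            f"(gold-only: {only_g}, pred-only: {only_p})"
        )
    return [(gold_by_id[i], pred_by_id[i]) for i in sorted(gold_by_id)]


def evaluate_ner(
    gold: Iterable[AnnotatedDocument],
    pred: Iterable[AnnotatedDocument],
) -> EvalResult:
    """Exact-span scoring: one-to-one matching of identical (start, end)
    pairs within each document.  With exact boundaries the maximum one-to-one
    matching is the per-span multiset intersection."""
    counts = EvalCounts()
    for g, p in _align(gold, pred):
        g_spans = Counter(m.span for m in g.mentions)
        p_spans = Counter(m.span for m in p.mentions)
        tp = sum((g_spans & p_spans).values())
        counts = counts + EvalCounts(
            tp, sum(p_spans.values()) - tp, sum(g_spans.values()) - tp
        )
    return metrics_from_counts(counts)


def _concept_set(doc: AnnotatedDocument) -> set[ConceptID]:
    return {m.concept_id for m in doc.mentions if not m.concept_id.is_unknown()}


def _concept_multiset(doc: AnnotatedDocument) -> Counter:
    return Counter(
        m.concept_id for m in doc.mentions if not m.concept_id.is_unknown()
    )


def evaluate_nen(
    gold: Iterable[AnnotatedDocument],
    pred: Iterable[AnnotatedDocument] | None = None,
    mode: Literal["gold_spans", "predicted_spans"] = "predicted_spans",
    lexicon: ConceptLexicon | None = None,
    per_mention: bool = False,
) -> EvalResult:
    """Concept-level scoring.

    ``predicted_spans``: score ``pred`` (full pipeline output; recognition
    errors cascade).  ``gold_spans``: ignore ``pred`` and re-derive
    predictions by normalizing each gold span's surface through ``lexicon``
    (normalization under a perfect recognizer).  ``per_mention`` switches
    from distinct-id sets to id multisets.
    """
    gold = list(gold)
    if mode == "gold_spans":
        if lexicon is None:
            raise ValidationError("gold_spans mode requires a lexicon")
        pred = [
            AnnotatedDocument(
                g.document,
                [m.with_concept(normalize_mention(m.surface, lexicon)) for m in g.mentions],
            )
            for g in gold
        ]
    elif mode == "predicted_spans":
        if pred is None:
            raise ValidationError("predicted_spans mode requires predictions")
    else:
        raise ValidationError(f"unknown NEN evaluation mode {mode!r}")

    counts = EvalCounts()
    for g, p in _align(gold, pred):
        if per_mention:
            gs, ps = _concept_multiset(g), _concept_multiset(p)
            tp = sum((gs & ps).values())
            fp = sum(ps.values()) - tp
            fn = sum(gs.values()) - tp
        else:
            gset, pset = _concept_set(g), _concept_set(p)
            tp = len(gset & pset)
            fp = len(pset - gset)
            fn = len(gset - pset)
        counts = counts + EvalCounts(tp, fp, fn)
    return metrics_from_counts(counts)
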