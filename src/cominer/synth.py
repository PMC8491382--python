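"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here with bookkeeping the
analysis modules can be checked against: disease lexicons (with matching
MeSH-schema XML), corpora with mentions planted at recorded offsets and
known per-pair co-mention counts, corrupted predictions with controlled
false-negative / false-positive / boundary-jitter / misnormalization rates,
and gene-association tables realizing requested pairwise overlaps exactly.

Generated disease names are pronounceable multi-token strings built from a
syllable alphabet disjoint from the filler-text vocabulary, so a planted
surface can only ever match its own lexicon entry; filler words can never
produce accidental mentions.  All generators take explicit integer seeds and
are fully deterministic.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .errors import UsageError, ValidationError
from .lexicon import (
    ConceptEntry,
    ConceptLexicon,
    build_lookup,
    entries_to_mesh_xml,
    normalize_term,
)
from .model import AnnotatedDocument, ConceptID, Document, Mention, UNKNOWN
from .compare import GeneAssociationTable
from .network import TargetSet

__all__ = [
    "CorpusSpec",
    "CorruptionSpec",
    "SyntheticCorpus",
    "generate_lexicon",
    "generate_corpus",
    "corrupt_annotations",
    "generate_gene_sets",
]

# Disease-name syllables and filler-word syllables are disjoint alphabets.
_NAME_SYLLABLES = [
    "bra", "cro", "dul", "fen", "gly", "hep", "kor", "lem", "myx", "nod",
    "pla", "qui", "rho", "sar", "tux", "vel", "wis", "zyg",
]
_NAME_SUFFIXES = ["oma", "itis", "osis", "emia", "pathy", "plasia"]
_FILLER_WORDS = [
    "the", "of", "and", "in", "patients", "study", "results", "observed",
    "analysis", "clinical", "data", "treatment", "cohort", "reported",
    "between", "association", "with", "cases", "during", "followup",
]


def _rng(seed: int) -> random.Random:
    if seed is None:
        raise UsageError("an explicit integer seed is required")
    return random.Random(seed)


def generate_lexicon(
    n_concepts: int,
    synonyms_per_concept: int = 2,
    seed: int = 0,
    cancer_fraction: float = 0.3,
    n_collisions: int = 0,
) -> tuple[ConceptLexicon, str]:
    """A synthetic disease lexicon and its MeSH-schema XML rendering.

    Names are unique multi-token pseudo-disease terms; roughly
    ``cancer_fraction`` of the concepts carry a C04-prefixed tree number
    (the Neoplasms branch), the rest a non-C04 tree.  ``n_collisions``
    extra shared synonyms can be requested to exercise ambiguity handling.
    The XML parses back to an identical lexicon.
    """
    if n_concepts < 1:
        raise UsageError("n_concepts must be >= 1")
    rng = _rng(seed)
    used_terms: set[str] = set()

    def fresh_name(n_tokens: int) -> str:
        while True:
            tokens = [
                "".join(rng.choice(_NAME_SYLLABLES) for _ in range(2))
                for _ in range(n_tokens - 1)
            ]
            tokens.append(
                "".join(rng.choice(_NAME_SYLLABLES) for _ in range(2))
                + rng.choice(_NAME_SUFFIXES)
            )
            name = " ".join(tokens).capitalize()
            key = normalize_term(name)
            if key not in used_terms:
                used_terms.add(key)
                return name

    entries: list[ConceptEntry] = []
    for i in range(n_concepts):
        cid = ConceptID("MESH", f"D{900000 + i:06d}")
        preferred = fresh_name(rng.randint(2, 3))
        synonyms = {preferred}
        for _ in range(max(synonyms_per_concept - 1, 0)):
            synonyms.add(fresh_name(rng.randint(1, 3)))
        if rng.random() < cancer_fraction:
            tree = f"C04.{rng.randint(100, 999)}"
        else:
            tree = f"C{rng.randint(5, 20):02d}.{rng.randint(100, 999)}"
        entries.append(
            ConceptEntry(cid, preferred, frozenset(synonyms), frozenset({tree}))
        )

    if n_collisions:
        if n_concepts < 2:
            raise UsageError("collisions need at least two concepts")
        for j in range(n_collisions):
            shared = fresh_name(2)
            a, b = rng.sample(range(n_concepts), 2)
            for idx in (a, b):
                e = entries[idx]
                entries[idx] = ConceptEntry(
                    e.concept_id, e.preferred_name,
                    e.synonyms | {shared}, e.tree_numbers,
                )

    lexicon = build_lookup(entries)
    return lexicon, entries_to_mesh_xml(entries)


@dataclass(frozen=True)
class CorpusSpec:
    """Conditions for corpus generation.

    Each document mentions a handful of diseases; a ``target_inclusion_rate``
    fraction of documents include one to three target diseases (mimicking a
    query-retrieved corpus where every abstract matched at least one query
    disease).  The number of distinct diseases per document is drawn around
    ``mean_mentions`` with spread ``dispersion`` (rounded, clipped at zero).
    """

    n_docs: int
    vocab: ConceptLexicon
    seed: int
    mean_mentions: float = 3.0
    dispersion: float = 1.0
    target_inclusion_rate: float = 0.9
    targets: TargetSet | None = None

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise UsageError("n_docs must be >= 0")
        if not 0.0 <= self.target_inclusion_rate <= 1.0:
            raise UsageError("target_inclusion_rate must be in [0, 1]")


@dataclass
class SyntheticCorpus:
    """Generator output: raw documents, exact gold annotations, and the
    ground-truth per-pair document co-mention counts."""

    documents: list[Document] = field(default_factory=list)
    gold: list[AnnotatedDocument] = field(default_factory=list)
    pair_counts: Counter = field(default_factory=Counter)


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Plant disease surface forms in filler text at recorded offsets.

    Titles are pure filler; mentions live in the abstract (offsets are into
    the composed title+" "+abstract string).  Planted surfaces are separated
    by at least one filler word, so gold spans sit on clean token
    boundaries.  Ground-truth ``pair_counts`` counts each distinct concept
    pair once per document.
    """
    rng = _rng(spec.seed)
    vocab_ids = sorted(spec.vocab.entries)
    if not vocab_ids:
        raise UsageError("corpus generation requires a nonempty vocabulary")
    target_ids = sorted(spec.targets.targets) if spec.targets else []
    partner_ids = [c for c in vocab_ids if c not in set(target_ids)]

    corpus = SyntheticCorpus()
    for d in range(spec.n_docs):
        doc_id = f"SYN{d:06d}"
        # choose the distinct concepts this document mentions
        n = max(0, int(rng.gauss(spec.mean_mentions, spec.dispersion) + 0.5))
        concepts: list[ConceptID] = []
        if target_ids and rng.random() < spec.target_inclusion_rate:
            concepts.extend(rng.sample(target_ids, rng.randint(1, min(3, len(target_ids)))))
        pool = [c for c in (partner_ids or vocab_ids) if c not in concepts]
        rng.shuffle(pool)
        while len(concepts) < n and pool:
            concepts.append(pool.pop())

        title = " ".join(rng.choice(_FILLER_WORDS) for _ in range(rng.randint(3, 6)))
        title = title[0].upper() + title[1:]
        # build the abstract word-by-word, planting each concept once or more
        mentions: list[Mention] = []
        abstract_parts: list[str] = []
        cursor = len(title) + 1  # abstract offsets within composed text

        def emit_filler(k: int) -> None:
            nonlocal cursor
            for _ in range(k):
                w = rng.choice(_FILLER_WORDS)
                abstract_parts.append(w)
                cursor += len(w) + 1

        plant_order = list(concepts)
        rng.shuffle(plant_order)
        emit_filler(rng.randint(1, 3))
        for cid in plant_order:
            entry = spec.vocab.entries[cid]
            surface = rng.choice(sorted(entry.all_names))
            start = cursor
            abstract_parts.append(surface)
            cursor += len(surface) + 1
            mentions.append(Mention(start, start + len(surface), surface))
            emit_filler(rng.randint(1, 4))

        abstract = " ".join(abstract_parts)
        doc = Document(doc_id, title, abstract)
        gold = AnnotatedDocument(
            doc,
            [m.with_concept(min(spec.vocab.lookup(m.surface))) for m in mentions],
        )
        gold.validate()
        corpus.documents.append(doc)
        corpus.gold.append(gold)
        distinct = sorted({m.concept_id for m in gold.mentions})
        for pair in combinations(distinct, 2):
            corpus.pair_counts[frozenset(pair)] += 1
    return corpus


@dataclass(frozen=True)
class CorruptionSpec:
    """Controlled error injection for evaluation calibration.

    With ``fn_rate`` each gold mention is deleted; spurious mentions are
    inserted at ``fp_rate`` per gold mention (on filler spans, so they never
    coincide with a gold span); ``boundary_jitter_rate`` shifts a surviving
    span's end by one character; ``misnormalization_rate`` swaps a surviving
    mention's concept id for a different one.  Expected recall is
    ``(1 - fn_rate) * (1 - boundary_jitter_rate)`` and expected precision
    follows from the implied tp/fp mix.
    """

    fn_rate: float = 0.0
    fp_rate: float = 0.0
    boundary_jitter_rate: float = 0.0
    misnormalization_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "fp_rate", "boundary_jitter_rate",
                     "misnormalization_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise UsageError(f"{name} must be in [0, 1]")


def corrupt_annotations(
    gold: list[AnnotatedDocument], spec: CorruptionSpec
) -> list[AnnotatedDocument]:
    """Derive predicted annotations from gold with known error rates."""
    rng = _rng(spec.seed)
    all_concepts = sorted(
        {m.concept_id for d in gold for m in d.mentions if not m.concept_id.is_unknown()}
    )
    out: list[AnnotatedDocument] = []
    for doc in gold:
        from .model import compose_text
        from .ner import tokenize

        text = compose_text(doc.document)
        pred: list[Mention] = []
        for m in doc.mentions:
            if rng.random() < spec.fn_rate:
                continue
            mention = m
            if rng.random() < spec.boundary_jitter_rate:
                # shift the end inward (or outward when possible) by 1 char
                if m.end - m.start > 1:
                    mention = Mention(
                        m.start, m.end - 1, text[m.start:m.end - 1],
                        m.entity_type, m.concept_id,
                    )
                elif m.end < len(text):
                    mention = Mention(
                        m.start, m.end + 1, text[m.start:m.end + 1],
                        m.entity_type, m.concept_id,
                    )
            if (
                spec.misnormalization_rate
                and len(all_concepts) > 1
                and rng.random() < spec.misnormalization_rate
            ):
                others = [c for c in all_concepts if c != mention.concept_id]
                mention = mention.with_concept(rng.choice(others))
            pred.append(mention)
        # spurious insertions on filler tokens not overlapping gold spans
        n_fp = sum(1 for _ in doc.mentions if rng.random() < spec.fp_rate)
        if n_fp:
            gold_spans = [(m.start, m.end) for m in doc.mentions]
            taken = gold_spans + [(m.start, m.end) for m in pred]
            candidates = [
                t for t in tokenize(text)
                if all(t[1] <= s or t[0] >= e for s, e in taken)
            ]
            rng.shuffle(candidates)
            for start, end in candidates[:n_fp]:
                concept = rng.choice(all_concepts) if all_concepts else UNKNOWN
                pred.append(
                    Mention(start, end, text[start:end], "Disease", concept)
                )
        predicted = AnnotatedDocument(doc.document, pred)
        predicted.validate()
        out.append(predicted)
    return out


def generate_gene_sets(
    overlaps: dict[tuple[ConceptID, ConceptID], int],
    set_sizes: dict[ConceptID, int] | None = None,
    default_size: int = 50,
    seed: int = 0,
) -> GeneAssociationTable:
    """Gene sets realizing the requested pairwise intersections exactly.

    Each specified pair gets its own disjoint pool of shared genes; the
    remainder of every disease's set is filled with private genes, so every
    unspecified pairwise intersection is exactly 0.  Raises when a disease's
    requested shared pools exceed its set size.
    """
    rng = _rng(seed)
    sizes: dict[ConceptID, int] = dict(set_sizes or {})
    diseases: set[ConceptID] = set(sizes)
    for a, b in overlaps:
        if a == b:
            raise UsageError("overlap pairs must involve two distinct diseases")
        diseases.update((a, b))
    for d in diseases:
        sizes.setdefault(d, default_size)

    shared_total: Counter = Counter()
    for (a, b), n in overlaps.items():
        if n < 0:
            raise UsageError("overlap sizes must be non-negative")
        shared_total[a] += n
        shared_total[b] += n
    for d in diseases:
        if shared_total[d] > sizes[d]:
            raise UsageError(
                f"{d.canonical}: requested shared genes ({shared_total[d]}) "
                f"exceed set size ({sizes[d]})"
            )

    counter = iter(range(10**6))
    def fresh_genes(k: int) -> set[str]:
        return {f"GENE{next(counter):06d}" for _ in range(k)}

    assoc: dict[ConceptID, set[str]] = {d: set() for d in diseases}
    for (a, b), n in sorted(overlaps.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        pool = fresh_genes(n)
        assoc[a] |= pool
        assoc[b] |= pool
    for d in sorted(diseases):
        assoc[d] |= fresh_genes(sizes[d] - len(assoc[d]))
    return GeneAssociationTable({d: frozenset(g) for d, g in assoc.items()})
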