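# Methods

## Problem and pipeline

The toolkit extracts disease–disease associations (DDAs) from biomedical
abstracts by composing two text-mining steps — named-entity recognition
(NER: find disease mention spans) and named-entity normalization (NEN: map
each span to a MeSH/OMIM concept) — and then counting *co-mentions*: two
distinct normalized disease concepts occurring in the same title+abstract.
The resulting co-mention network can be ranked around a set of query
("target") diseases and compared against a gene-overlap DDA network of the
DisGeNET kind, in which two diseases are associated when their gene sets
share at least a threshold number of genes.

## Conventions and their rationale

**Text composition and offsets.** A document's annotation space is the
string `title + " " + abstract` (title alone when the abstract is empty),
with 0-based, half-open character offsets — the convention of
PubTator-distributed corpora. Whether titles and abstracts should instead
be processed separately is genuinely open; composition was chosen because
it makes `composed[start:end] == surface` an exact invariant that the I/O
layer enforces on every read and write, and because co-mention counting is
per-document either way. Input text is never re-normalized at I/O time
(Unicode normalization happens only inside lexicon lookup), keeping offsets
stable.

**Dictionary recognition.** The built-in recognizer scans tokens (maximal
alphanumeric runs) left to right and takes the longest n-gram (n ≤
`max_ngram`, default 10) whose normalized form is an indexed lexicon term,
then continues after the match. Longest-match with token-boundary
anchoring trades recall for precision: nested terms ("myeloma" inside
"multiple myeloma") yield the longer mention only, and a term can never
fire inside a longer word. The engine is deterministic by construction; a
learned recognizer can be substituted through the plug-in contract
(mentions sorted, non-overlapping, slice-consistent), which a validator
enforces per document, skipping and counting failing documents rather than
aborting a corpus.

**Term normalization.** Lookup keys are NFKC-normalized, case-folded, with
punctuation mapped to spaces (not deleted — this preserves token boundaries
of hyphenated names such as "graft-versus-host disease") and whitespace
collapsed. The mapping is idempotent, so normalization commutes with
lookup.

**Normalization and the UNKNOWN sink.** NEN is exact match over normalized
terms. A surface found under several concepts (a synonym collision)
resolves to the lexicographically smallest canonical id
(`MESH:...` < `OMIM:...` ordering included); this also settles MeSH-vs-OMIM
conflicts. The tie-break is an artifact convention chosen for
reproducibility — learned concept rankers would make a different, better
choice. Surfaces absent from the terminology map to the distinguished
`UNKNOWN` sentinel, which is excluded from concept-level scoring and from
all DDA edges. Fuzzy matching is deliberately absent from the baseline: it
would make the acceptance surface nondeterministic.

**Scoring.** Span-level scoring is strict: a predicted mention is a true
positive iff an unmatched gold mention in the same document has identical
boundaries; matching is one-to-one (with exact boundaries, the maximum
one-to-one matching equals the per-span multiset intersection — the test
suite checks this against an exhaustive enumeration oracle). Concept-level
scoring compares per-document sets of distinct non-UNKNOWN ids (a
per-mention multiset mode exists behind a flag). Two concept-level modes
mirror the two questions of interest: `gold_spans` re-normalizes the gold
spans' surfaces, isolating normalization quality under a perfect
recognizer; `predicted_spans` scores the full pipeline so recognition
errors cascade. Zero denominators map to zero. Metrics are kept at full
precision; for comparison with conventionally reported two-decimal scores,
`round2` rounds half-up.

**Co-mention counting.** A pair counts once per document regardless of
mention multiplicity — association evidence is "these diseases appear in
the same paper", not "near each other often in one paper". Per-occurrence
counting (product of mention counts within a document) exists behind
`count_mode="occurrence"`. Self-pairs are excluded: two surfaces
normalizing to the same concept carry no association information.

**Ranking and filtering.** Around a target set, only target–partner edges
are ranked (target–target edges are reported separately); a partner must be
linked to ≥ `min_target_links` (default 2) distinct targets; ranking is by
support descending with ties broken by the canonical pair rendering, so
output order is total and reruns are byte-identical. "Top k" can mean top
k *edges* (default) or top k *partner diseases* (`rank_by="partners"`) —
both readings are defensible and both are exposed.

**Cancer/non-cancer split.** A node is cancerous when any of its MeSH tree
numbers starts with a configured prefix (default `C04`, Neoplasms); nodes
without tree numbers are reported unclassified rather than silently binned.
This ontology-backed proxy is the package's own criterion for the split.

**Gene-overlap DDAs and network comparison.** An edge is emitted for a
(target, other) pair sharing ≥ `min_shared` genes (boundary inclusive;
default 20), with the Jaccard index of the gene sets as support and the
shared-gene count as provenance. Gene symbols are compared case-sensitively
as given (symbol casing is meaningful; a case-folding switch exists for
dirty inputs). Network comparison matches edges on unordered concept pairs
only, after optionally translating one side's UMLS CUIs through an id map;
a CUI mapping to several concepts expands its edges to all combinations
(matched if any occurs), and edges with untranslatable CUI endpoints are
excluded from the fractions and counted separately. An empty reference set
yields a recovered fraction of 1.0 by vacuous-truth convention.

## Synthetic data: what it emulates and what it does not

The generator emulates a query-retrieved corpus around a few target
diseases: by default 90% of documents mention one to three targets plus
partner diseases (≈3 distinct diseases per document, spread 1), with
surfaces planted at recorded offsets between filler words. Disease names
are built from a syllable alphabet disjoint from the filler vocabulary and
non-final name tokens can never equal a full name, so the lexicon-equals-
vocabulary condition guarantees exact recovery — which is the point: it
isolates pipeline bookkeeping (offsets, aggregation, ranking) from matching
difficulty. Corrupted predictions delete mentions with probability
`fn_rate`, insert spurious mentions on filler tokens at `fp_rate` per gold
mention, jitter boundaries, and swap concept ids, giving analytically known
expected recall `(1−fn_rate)(1−jitter)` and precision
`(1−fn_rate)/((1−fn_rate)+fp_rate)` at jitter 0.

Passing on this material therefore shows that the machinery is exact and
calibrated; it does *not* show performance on real prose. Real abstracts
have ambiguous and discontinuous mentions, abbreviations, anaphora, nested
entities and terminology gaps, none of which the generator models — a
dictionary baseline on real corpora will sit well below learned models.
Gene tables realize requested pairwise intersections exactly by giving each
specified pair a private shared-gene pool (unspecified intersections are
exactly zero); correlated overlap structure among many diseases is not
modeled.

## Numerical and degenerate-input choices

Zero-denominator metric conventions as above; Jaccard of two empty sets is
0; an empty corpus yields empty but valid outputs everywhere; empty
lexicons are rejected at annotation time. Determinism demands explicit
seeds on every generator (there is no global RNG state), canonical
orderings at every serialization point, and content-derived tie-breaks
(never hash or insertion order). Composite PubTator concept fields
(`D001|D002`) reduce to the first id for scoring with the raw field
preserved for round-tripping.

## Problem sizes

The shipped checks run at sizes chosen to give tight statistics while
staying lightweight: 1000 documents (~3 mentions each) for exact-recovery
checks, 700 documents (≥ 2000 gold mentions) for corruption calibration
(3-sigma binomial bands), 500 random mini-corpora for the
exhaustive-matching oracle, and 1000 random set pairs for Jaccard
properties. Corpus-scale figures from literature-wide studies (hundreds of
thousands of abstracts, full DisGeNET) require those resources and trained
neural models, and are out of scope here; the package reproduces the
*statistics* on any inputs of that shape.

## Known limitations

- The built-in NER/NEN is an exact-dictionary baseline; no abbreviation
  expansion, no fuzzy or contextual matching, no nested mentions.
- MeSH XML parsing covers the descriptor/supplementary subset needed for
  names, synonyms and tree numbers; pharmacological-action and qualifier
  files contribute synonyms only.
- Co-occurrence significance testing (e.g. hypergeometric enrichment) is
  intentionally absent: ranking is by raw counts, matching the co-mention
  definition above.
- Live PubMed/Entrez retrieval and MEDLINE XML are out of scope; corpora
  enter as PubTator files or id/title/abstract tables.
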