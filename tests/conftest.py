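import pytest

from cominer import ConceptID, TargetSet
from cominer.lexicon import ConceptEntry, build_lookup
from cominer.synth import CorpusSpec, generate_corpus, generate_lexicon


@pytest.fixture(scope="session")
def small_lexicon():
    """Hand-built lexicon with real disease names, a synonym collision, and
    tree numbers on both sides of the cancer split."""
    entries = [
        ConceptEntry(
            ConceptID("MESH", "D009101"), "Multiple Myeloma",
            frozenset({"Multiple Myeloma", "Myeloma"}),
            frozenset({"C04.557.595"}),
        ),
        ConceptEntry(
            ConceptID("MESH", "D007938"), "Leukemia",
            frozenset({"Leukemia", "Leukaemia"}), frozenset({"C04.557.337"}),
        ),
        ConceptEntry(
            ConceptID("MESH", "D008223"), "Lymphoma",
            frozenset({"Lymphoma"}), frozenset({"C04.557.386"}),
        ),
        ConceptEntry(
            ConceptID("MESH", "D000740"), "Anemia",
            frozenset({"Anemia", "Anaemia"}), frozenset({"C15.378.071"}),
        ),
        ConceptEntry(
            ConceptID("MESH", "D005334"), "Fever",
            frozenset({"Fever", "Pyrexia"}), frozenset({"C23.888.119"}),
        ),
        ConceptEntry(
            ConceptID("MESH", "D006086"), "Graft versus host disease",
            frozenset({"Graft-versus-host disease", "GVHD"}),
            frozenset({"C20.452"}),
        ),
        # collision: "Pyrexia" also names this OMIM entry
        ConceptEntry(
            ConceptID("OMIM", "614371"), "Periodic fever syndrome",
            frozenset({"Pyrexia"}), frozenset(),
        ),
    ]
    return build_lookup(entries)


@pytest.fixture(scope="session")
def blood_cancer_targets():
    return TargetSet.of("MESH:D007938", "MESH:D008223", "MESH:D009101")


@pytest.fixture(scope="session")
def synth_bundle():
    """Deterministic generated lexicon + 200-document corpus with targets."""
    lexicon, xml = generate_lexicon(30, synonyms_per_concept=2, seed=11)
    targets = TargetSet(frozenset(sorted(lexicon.entries)[:3]))
    corpus = generate_corpus(
        CorpusSpec(n_docs=200, vocab=lexicon, seed=12, targets=targets)
    )
    return lexicon, xml, targets, corpus
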