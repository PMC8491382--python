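"""Precision/recall/F1 scoring, oracle equivalence, and calibration."""

import random

import pytest

from cominer import (
    AnnotatedDocument,
    ConceptID,
    Document,
    EvalCounts,
    Mention,
    UNKNOWN,
    evaluate_ner,
    evaluate_nen,
    harmonic_f1,
    metrics_from_counts,
)
from cominer.errors import ValidationError
from cominer.evaluation import round2


class TestMetricArithmetic:
    @pytest.mark.parametrize(
        "counts, p, r, f1",
        [
            (EvalCounts(0, 0, 0), 0.0, 0.0, 0.0),
            (EvalCounts(5, 0, 0), 1.0, 1.0, 1.0),
            (EvalCounts(1, 1, 1), 0.5, 0.5, 0.5),
            (EvalCounts(3, 1, 0), 0.75, 1.0, 2 * 0.75 / 1.75),
        ],
    )
    def test_formulas_and_zero_denominator_conventions(self, counts, p, r, f1):
        res = metrics_from_counts(counts)
        assert (res.precision, res.recall) == (p, r)
        assert res.f1 == pytest.approx(f1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            EvalCounts(-1, 0, 0)

    @pytest.mark.parametrize(
        "p, r, reported",
        [(0.87, 0.89, 0.88), (0.80, 0.83, 0.81)],
    )
    def test_f1_rounds_to_two_decimals_half_up(self, p, r, reported):
        assert round2(harmonic_f1(p, r)) == reported

    def test_f1_between_precision_and_recall(self):
        rng = random.Random(7)
        for _ in range(200):
            tp, fp, fn = rng.randint(1, 30), rng.randint(0, 30), rng.randint(0, 30)
            res = metrics_from_counts(EvalCounts(tp, fp, fn))
            assert min(res.precision, res.recall) <= res.f1 + 1e-12
            assert res.f1 <= max(res.precision, res.recall) + 1e-12


def _doc(doc_id, spans, concepts=None):
    """Synthetic annotated document over a long dummy text."""
    text = "x" * 400
    title = text[:50]
    mentions = []
    for i, (s, e) in enumerate(spans):
        cid = (concepts or {}).get(i, UNKNOWN)
        mentions.append(Mention(s, e, text[s:e], "Disease", cid))
    return AnnotatedDocument(Document(doc_id, title, text[51:]), mentions)


def brute_force_span_tp(gold_spans, pred_spans):
    """Independent oracle: maximum one-to-one exact-span matching found by
    exhaustive recursion (each gold mention pairs with an unused identical
    predicted span, or stays unmatched)."""

    def best(g_idx, used):
        if g_idx == len(gold_spans):
            return 0
        score = best(g_idx + 1, used)  # gold mention left unmatched
        for p_idx, span in enumerate(pred_spans):
            if p_idx not in used and span == gold_spans[g_idx]:
                score = max(score, 1 + best(g_idx + 1, used | {p_idx}))
        return score

    return best(0, frozenset())


class TestEvaluateNer:
    def test_identical_annotations_score_one(self):
        docs = [_doc("1", [(0, 8), (20, 28)])]
        res = evaluate_ner(docs, docs)
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_half_overlap_example(self):
        gold = [_doc("1", [(0, 8), (20, 28)])]
        pred = [_doc("1", [(0, 8), (30, 35)])]
        res = evaluate_ner(gold, pred)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (1, 1, 1)
        assert res.precision == res.recall == res.f1 == 0.5

    def test_empty_predictions_use_zero_convention(self):
        gold = [_doc("1", [(0, 8)])]
        pred = [_doc("1", [])]
        res = evaluate_ner(gold, pred)
        assert (res.precision, res.recall, res.f1) == (0.0, 0.0, 0.0)

    def test_doc_id_mismatch_is_alignment_error(self):
        with pytest.raises(ValidationError, match="different documents"):
            evaluate_ner([_doc("1", [])], [_doc("2", [])])

    def test_oracle_equivalence_on_random_small_corpora(self):
        """Matches exhaustive one-to-one matching on >= 500 random cases."""
        rng = random.Random(42)
        for _ in range(500):
            spans = [(s, s + rng.randint(1, 5)) for s in rng.sample(range(0, 390, 7), 6)]
            gold_spans = [rng.choice(spans) for _ in range(rng.randint(0, 5))]
            pred_spans = [rng.choice(spans) for _ in range(rng.randint(0, 5))]
            gold = [_doc("1", gold_spans)]
            pred = [_doc("1", pred_spans)]
            res = evaluate_ner(gold, pred)
            tp = brute_force_span_tp(gold_spans, pred_spans)
            assert res.counts.tp == tp
            assert res.counts.fp == len(pred_spans) - tp
            assert res.counts.fn == len(gold_spans) - tp

    def test_swap_symmetry(self):
        rng = random.Random(9)
        for _ in range(100):
            spans = [(s, s + 3) for s in range(0, 100, 10)]
            gold = [_doc("1", rng.sample(spans, rng.randint(0, 6)))]
            pred = [_doc("1", rng.sample(spans, rng.randint(0, 6)))]
            a, b = evaluate_ner(gold, pred), evaluate_ner(pred, gold)
            assert (a.counts.fp, a.counts.fn) == (b.counts.fn, b.counts.fp)
            assert (a.precision, a.recall) == (b.recall, b.precision)
            assert a.f1 == pytest.approx(b.f1)


A = ConceptID("MESH", "D000001")
B = ConceptID("MESH", "D000002")
C = ConceptID("MESH", "D000003")


class TestEvaluateNen:
    def test_identical_concept_sets_score_one(self):
        docs = [_doc("1", [(0, 4), (10, 14)], {0: A, 1: B})]
        res = evaluate_nen(docs, docs)
        assert res.f1 == 1.0

    def test_set_arithmetic_example(self):
        gold = [_doc("1", [(0, 4), (10, 14)], {0: A, 1: B})]
        pred = [_doc("1", [(0, 4), (10, 14)], {0: B, 1: C})]
        res = evaluate_nen(gold, pred)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (1, 1, 1)

    def test_unknown_predictions_are_never_true_positives(self):
        gold = [_doc("1", [(0, 4)], {0: A})]
        pred = [_doc("1", [(0, 4)])]  # all UNKNOWN
        res = evaluate_nen(gold, pred)
        assert res.counts.tp == 0 and res.counts.fn == 1 and res.counts.fp == 0

    def test_distinct_id_sets_ignore_mention_multiplicity(self):
        gold = [_doc("1", [(0, 4), (10, 14)], {0: A, 1: A})]
        pred = [_doc("1", [(20, 24)], {0: A})]
        res = evaluate_nen(gold, pred)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (1, 0, 0)

    def test_per_mention_flag_counts_multiplicity(self):
        gold = [_doc("1", [(0, 4), (10, 14)], {0: A, 1: A})]
        pred = [_doc("1", [(20, 24)], {0: A})]
        res = evaluate_nen(gold, pred, per_mention=True)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (1, 0, 1)

    def test_gold_spans_mode_scores_normalization_alone(self, small_lexicon):
        # gold concept deliberately differs from what the lexicon returns
        text_doc = Document("1", "fever study", "anemia and fever again")
        gold = [
            AnnotatedDocument(
                text_doc,
                [Mention(12, 18, "anemia", "Disease", ConceptID("MESH", "D000740")),
                 Mention(23, 28, "fever", "Disease", ConceptID("OMIM", "999999"))],
            )
        ]
        res = evaluate_nen(gold, mode="gold_spans", lexicon=small_lexicon)
        # anemia matches; the odd OMIM gold id is not what lookup returns
        assert res.counts.tp == 1 and res.counts.fn == 1 and res.counts.fp == 1

    def test_gold_spans_mode_requires_lexicon(self):
        with pytest.raises(ValidationError):
            evaluate_nen([_doc("1", [])], mode="gold_spans")


class TestCorruptionCalibration:
    def test_measured_rates_match_binomial_expectation(self, synth_bundle):
        """fn_rate=0.2 / fp_rate=0.1 over >= 2000 mentions: recall within 3
        binomial sigma of 0.8, precision within 3 sigma of its implied
        expectation 0.8/0.9."""
        import math

        from cominer.synth import CorpusSpec, CorruptionSpec, corrupt_annotations, generate_corpus

        lexicon, _, targets, _ = synth_bundle
        corpus = generate_corpus(
            CorpusSpec(n_docs=700, vocab=lexicon, seed=77, targets=targets)
        )
        n_gold = sum(len(d.mentions) for d in corpus.gold)
        assert n_gold >= 2000
        pred = corrupt_annotations(
            corpus.gold, CorruptionSpec(fn_rate=0.2, fp_rate=0.1, seed=78)
        )
        res = evaluate_ner(corpus.gold, pred)
        sd_r = math.sqrt(0.8 * 0.2 / n_gold)
        assert abs(res.recall - 0.8) <= 3 * sd_r
        exp_p = 0.8 / 0.9
        n_pred = res.counts.tp + res.counts.fp
        sd_p = math.sqrt(exp_p * (1 - exp_p) / n_pred)
        assert abs(res.precision - exp_p) <= 3 * sd_p
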