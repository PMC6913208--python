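import numpy as np
import pytest

from nner.evaluate import (
    classify_errors,
    classify_match,
    corpus_stats,
    match_entities,
    overlap_length,
    score_documents,
)
from nner.standoff import Document, Entity
from nner.synthetic import DegradeProfile, SynthConfig, degrade_predictions, generate_corpus


def E(eid, cat, start, end):
    return Entity(eid, cat, ((start, end),))


class TestMatchEntities:
    def test_exact_match_in_both_regimes(self):
        gold = [E("T1", "Drug", 10, 21)]
        pred = [E("P1", "Drug", 10, 21)]
        assert match_entities(gold, pred, "strict").tp == 1
        assert match_entities(gold, pred, "lenient").tp == 1

    def test_containment_counts_only_leniently(self):
        gold = [E("T1", "Reason", 10, 41)]
        pred = [E("P1", "Reason", 15, 30)]
        strict = match_entities(gold, pred, "strict")
        lenient = match_entities(gold, pred, "lenient")
        assert (strict.tp, len(strict.false_positives),
                len(strict.false_negatives)) == (0, 1, 1)
        assert lenient.tp == 1

    def test_category_mismatch_never_matches(self):
        gold = [E("T1", "Drug", 10, 21)]
        pred = [E("P1", "Reason", 10, 21)]
        for regime in ("strict", "lenient"):
            res = match_entities(gold, pred, regime)
            assert res.tp == 0

    def test_one_to_one_matching(self):
        gold = [E("T1", "Drug", 0, 10)]
        pred = [E("P1", "Drug", 0, 10), E("P2", "Drug", 2, 8)]
        res = match_entities(gold, pred, "lenient")
        assert res.tp == 1 and len(res.false_positives) == 1

    def test_exact_pairs_win_over_larger_overlaps(self):
        # a wider prediction must not steal the gold from its exact match
        gold = [E("T1", "Drug", 5, 10)]
        pred = [E("P1", "Drug", 0, 15), E("P2", "Drug", 5, 10)]
        res = match_entities(gold, pred, "lenient")
        (g, p), = res.pairs
        assert p.entity_id == "P2"

    def test_strict_tp_subset_of_lenient_tp(self):
        corpus = generate_corpus(SynthConfig(n_documents=20, seed=5))
        preds, _ = degrade_predictions(
            corpus.all_documents,
            DegradeProfile(n_widen=5, n_narrow=5, n_shift=3, n_swap=4,
                           n_hallucinate=3, n_delete=4, seed=1),
        )
        for gdoc, pdoc in zip(corpus.all_documents, preds):
            strict = match_entities(gdoc.entities, pdoc.entities, "strict")
            lenient = match_entities(gdoc.entities, pdoc.entities, "lenient")
            strict_keys = {(g.entity_id, p.entity_id) for g, p in strict.pairs}
            lenient_keys = {(g.entity_id, p.entity_id) for g, p in lenient.pairs}
            assert strict_keys <= lenient_keys

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            match_entities([], [], "fuzzy")


class TestClassifyMatch:
    def test_four_types(self):
        gold = E("T1", "Drug", 10, 21)
        assert classify_match(gold, E("P", "Drug", 10, 21)) == "Strict"
        assert classify_match(gold, E("P", "Drug", 8, 25)) == "Includes"
        assert classify_match(gold, E("P", "Drug", 12, 18)) == "Is included"
        assert classify_match(gold, E("P", "Drug", 15, 25)) == "Partial overlap"

    def test_disjoint_pair_rejected(self):
        with pytest.raises(ValueError):
            classify_match(E("T", "Drug", 0, 5), E("P", "Drug", 10, 15))

    def test_discontinuous_overlap_uses_fragment_union(self):
        gold = Entity("T", "Duration", ((0, 3), (10, 13)))
        pred = E("P", "Duration", 11, 12)
        assert overlap_length(gold, pred) == 1
        assert classify_match(gold, pred) == "Is included"


class TestClassifyErrors:
    def test_category_error(self):
        gold = [E("T1", "Form", 10, 20)]
        fps = [E("P1", "Route", 10, 20)]
        assert classify_errors(gold, fps)["CE"] == 1

    def test_span_error(self):
        gold = [E("T1", "Form", 10, 20)]
        fps = [E("P1", "Drug", 30, 40)]
        assert classify_errors(gold, fps)["SE"] == 1

    def test_ce_plus_se_partitions_false_positives(self):
        rng = np.random.default_rng(2)
        corpus = generate_corpus(SynthConfig(n_documents=6, seed=9))
        preds, _ = degrade_predictions(
            corpus.all_documents,
            DegradeProfile(n_swap=6, n_hallucinate=4, seed=3),
        )
        total_fp = total_err = 0
        for gdoc, pdoc in zip(corpus.all_documents, preds):
            res = match_entities(gdoc.entities, pdoc.entities, "lenient")
            errs = classify_errors(gdoc.entities, res.false_positives)
            total_fp += len(res.false_positives)
            total_err += errs["CE"] + errs["SE"]
        assert total_fp == total_err > 0
        _ = rng


class TestScore:
    def test_perfect_predictions(self):
        corpus = generate_corpus(SynthConfig(n_documents=5, seed=3))
        docs = corpus.all_documents
        preds = [Document(d.doc_id, d.text, list(d.entities)) for d in docs]
        rep = score_documents(docs, preds)
        for regime in (rep.strict, rep.lenient):
            assert regime["micro"]["precision"] == 1.0
            assert regime["micro"]["recall"] == 1.0
        assert set(rep.match_types) == {"Strict"}

    def test_empty_predictions_zero_scores(self):
        corpus = generate_corpus(SynthConfig(n_documents=3, seed=3))
        docs = corpus.all_documents
        preds = [Document(d.doc_id, d.text) for d in docs]
        rep = score_documents(docs, preds)
        assert rep.lenient["micro"]["precision"] == 0.0
        assert rep.lenient["micro"]["recall"] == 0.0
        assert rep.lenient["micro"]["f1"] == 0.0

    def test_hand_scored_fixture(self):
        text = "a" * 100
        gold = Document("d", text, [
            E("T1", "Drug", 0, 8),
            E("T2", "Reason", 20, 30),
            E("T3", "ADE", 40, 50),
            E("T4", "Route", 60, 70),
        ])
        pred = Document("d", text, [
            E("P1", "Drug", 0, 8),        # Strict
            E("P2", "Reason", 18, 32),    # Includes
            E("P3", "ADE", 42, 48),       # Is included
            E("P4", "Drug", 80, 90),      # SE false positive; T4 missed
        ])
        rep = score_documents([gold], [pred])
        assert rep.lenient["micro"]["tp"] == 3
        assert rep.lenient["micro"]["fp"] == 1
        assert rep.lenient["micro"]["fn"] == 1
        assert rep.lenient["micro"]["precision"] == pytest.approx(0.75)
        assert rep.lenient["micro"]["recall"] == pytest.approx(0.75)
        assert rep.match_types == {
            "Strict": 1, "Includes": 1, "Is included": 1,
        }
        assert dict(rep.errors) == {"SE": 1}
        assert rep.strict["micro"]["tp"] == 1

    def test_micro_f_is_harmonic_mean(self):
        corpus = generate_corpus(SynthConfig(n_documents=6, seed=11))
        docs = corpus.all_documents
        preds, _ = degrade_predictions(
            docs, DegradeProfile(n_widen=4, n_delete=3, n_swap=2, seed=0)
        )
        rep = score_documents(docs, preds)
        m = rep.lenient["micro"]
        expected = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        assert abs(m["f1"] - expected) < 1e-12

    def test_match_type_counts_sum_to_lenient_tp(self):
        corpus = generate_corpus(SynthConfig(n_documents=6, seed=13))
        docs = corpus.all_documents
        preds, _ = degrade_predictions(
            docs, DegradeProfile(n_widen=3, n_narrow=3, n_shift=2, seed=0)
        )
        rep = score_documents(docs, preds)
        assert sum(rep.match_types.values()) == rep.lenient["micro"]["tp"]

    def test_unknown_prediction_document_rejected(self):
        gold = [Document("a", "x")]
        pred = [Document("b", "x")]
        with pytest.raises(ValueError, match="unknown document"):
            score_documents(gold, pred)


class TestCorpusStats:
    def _fixture(self):
        # 3 hand-built documents with known counts
        d1 = Document("d1", "velomicin for back pain", [
            E("T1", "Drug", 0, 9),
            E("T2", "Reason", 14, 23),
        ])
        d2 = Document("d2", "pain from velomicin noted", [
            E("T1", "Drug", 10, 19),
            E("T2", "Reason", 0, 19),   # nests the Drug
            E("T3", "ADE", 0, 19),      # polysemous with the Reason
        ])
        d3 = Document("d3", "velomicin velomicin", [])
        return [d1, d2, d3]

    def test_hand_counted_fixture(self):
        stats = corpus_stats(self._fixture())
        assert stats["documents"] == 3
        assert stats["entities"] == 5
        assert stats["per_category"]["Drug"] == 2
        assert stats["per_nest_level"] == {1: 3, 2: 1, 3: 1}
        assert stats["polysemous_entities"] == 2
        assert stats["textually_nested_entities"] == 1

    def test_no_rare_words_when_everything_repeats(self):
        docs = [Document("a", "pain pain drug drug")]
        assert corpus_stats(docs)["rare_word_ratio"] == 0.0

    def test_reference_vocabulary_covers_corpus(self):
        docs = self._fixture()
        vocab = {w for d in docs for w in d.text.lower().split()}
        stats = corpus_stats(docs, vocab)
        assert stats["unknown_word_ratio"] == 0.0
        assert stats["eunk_fraction"] == 0.0
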