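import copy
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from nner.bpe import merge_subword_labels, train_bpe
from nner.evaluate import score_documents
from nner.layered import (
    LayeredNER,
    VariantConfig,
    decompose_gold,
    flatten_gold,
    merge_regions,
    train,
)
from nner.preprocess import preprocess_document
from nner.standoff import Document, Entity
from nner.synthetic import SynthConfig, flat_copy, generate_corpus


def E(eid, cat, start, end):
    return Entity(eid, cat, ((start, end),))


class TestDecomposeGold:
    def test_nested_and_polysemous_pattern(self):
        # Drug inside a span carrying both Reason and ADE
        ents = [
            E("T1", "Drug", 10, 19),
            E("T2", "Reason", 0, 19),
            E("T3", "ADE", 0, 19),
        ]
        levels = decompose_gold(ents)
        assert [(e.category, e.nest_level) for lv in levels for e in lv] == [
            ("Drug", 1), ("Reason", 2), ("ADE", 3),
        ]

    def test_flat_document_single_level(self):
        ents = [E("T1", "Drug", 0, 5), E("T2", "Reason", 10, 20)]
        levels = decompose_gold(ents)
        assert len(levels) == 1
        assert {e.entity_id for e in levels[0]} == {"T1", "T2"}

    def test_level_count_equals_max_nesting_depth(self):
        rng = np.random.default_rng(0)
        corpus = generate_corpus(SynthConfig(
            n_documents=10, seed=2, nesting_rate=0.6, polysemy_rate=0.3
        ))
        max_depth = 0
        for doc in corpus.all_documents:
            levels = decompose_gold(doc.entities)
            for i, lv in enumerate(levels):
                assert lv, f"empty intermediate level {i + 1}"
            max_depth = max(max_depth, len(levels))
        assert max_depth >= 3  # polysemous nested spans reach level 3
        _ = rng

    def test_partial_overlap_rejected(self):
        ents = [E("T1", "Drug", 0, 10), E("T2", "Reason", 5, 15)]
        with pytest.raises(ValueError, match="partially overlap"):
            decompose_gold(ents)

    def test_levels_are_bio_encodable(self):
        corpus = generate_corpus(SynthConfig(n_documents=6, seed=4))
        for doc in corpus.all_documents:
            for level in decompose_gold(doc.entities):
                spans = sorted((e.start, e.end) for e in level)
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 <= s2


class TestFlattenGold:
    def test_outermost_highest_priority_survive(self):
        ents = [
            E("T1", "Drug", 10, 19),
            E("T2", "Reason", 0, 19),
            E("T3", "ADE", 0, 19),
        ]
        flat = flatten_gold(ents)
        assert [(e.category, e.fragments) for e in flat] \
            == [("Reason", ((0, 19),))]

    def test_flat_input_unchanged(self):
        ents = [E("T1", "Drug", 0, 5), E("T2", "ADE", 10, 15)]
        assert {e.entity_id for e in flatten_gold(ents)} == {"T1", "T2"}


class TestMergeRegions:
    def test_three_unit_entity_in_seven_unit_sentence(self):
        reps = np.arange(21, dtype=float).reshape(7, 3)
        out, spans = merge_regions(reps, [(2, 5)])
        assert out.shape == (5, 3)
        np.testing.assert_allclose(out[2], reps[2:5].mean(axis=0))
        assert spans == [(0, 1), (1, 2), (2, 5), (5, 6), (6, 7)]

    def test_no_entities_identity(self):
        reps = np.random.default_rng(0).normal(size=(4, 2))
        out, spans = merge_regions(reps, [])
        np.testing.assert_array_equal(out, reps)
        assert spans == [(i, i + 1) for i in range(4)]

    def test_mean_of_identical_vectors_is_that_vector(self):
        reps = np.tile([[1.5, -2.0]], (5, 1))
        out, _ = merge_regions(reps, [(1, 4)])
        np.testing.assert_allclose(out[1], [1.5, -2.0])

    def test_overlapping_runs_rejected(self):
        reps = np.zeros((6, 2))
        with pytest.raises(ValueError, match="overlapping"):
            merge_regions(reps, [(0, 3), (2, 5)])


@pytest.fixture(scope="module")
def tiny_setup():
    """A small model + corpus shared by the structural tests."""
    corpus = generate_corpus(SynthConfig(
        n_documents=8, sentences_per_doc=5, seed=6,
        nesting_rate=0.5, polysemy_rate=0.3,
    ))
    for d in corpus.all_documents:
        preprocess_document(d)
    words = Counter(t.surface for d in corpus.train for t in d.tokens)
    bpe = train_bpe(words, 120)
    cfg = VariantConfig(
        variant="wcsub", word_dim=6, char_dim=4, char_hidden=3,
        subword_dim=5, hidden_dim=8, subword_vocab_size=bpe.vocab_size_target,
        dropout=0.0, epochs=1, seed=0,
    )
    wv, cv = LayeredNER.build_vocabs(corpus.train)
    model = LayeredNER(cfg, wv, cv, bpe)
    return corpus, model, bpe


class TestComposition:
    def test_char_embed_shape_for_all_lengths(self, tiny_setup):
        _, model, _ = tiny_setup
        for word in ("a", "xy", "velomicin"):
            vec = model.char_embed(word)
            assert vec.shape == (2 * model.config.char_hidden,)

    def test_char_embed_pure(self, tiny_setup):
        _, model, _ = tiny_setup
        np.testing.assert_array_equal(
            model.char_embed("velomicin"), model.char_embed("velomicin")
        )

    def test_input_dims_per_variant(self, tiny_setup):
        corpus, _, bpe = tiny_setup
        wv, cv = LayeredNER.build_vocabs(corpus.train)
        dims = {
            "baseline": 6 + 2 * 3,
            "csub": 2 * 3 + 5,
            "wsub": 6 + 5,
            "wcsub": 6 + 2 * 3 + 5,
        }
        for variant, dim in dims.items():
            cfg = VariantConfig(
                variant=variant, word_dim=6, char_dim=4, char_hidden=3,
                subword_dim=5, hidden_dim=8, dropout=0.0, seed=0,
                subword_vocab_size=bpe.vocab_size_target,
            )
            m = LayeredNER(cfg, wv, cv, None if variant == "baseline" else bpe)
            assert m.input_dim == dim
            doc = corpus.train[0]
            toks = doc.sentence_tokens()[0]
            sent = m.prepare_sentence(doc.doc_id, toks, None)
            X = m.compose_input(sent)
            assert X.shape == (sent.n_units, dim)

    def test_wcsub_subwords_share_word_and_char_slices(self, tiny_setup):
        corpus, model, _ = tiny_setup
        doc = corpus.train[0]
        toks = doc.sentence_tokens()[0]
        sent = model.prepare_sentence(doc.doc_id, toks, None)
        X = model.compose_input(sent)
        shared = model.config.word_dim + 2 * model.config.char_hidden
        for ui in range(sent.n_units - 1):
            if sent.parent[ui] == sent.parent[ui + 1]:
                np.testing.assert_array_equal(
                    X[ui, :shared], X[ui + 1, :shared]
                )

    def test_unknown_word_uses_unk_vector(self, tiny_setup):
        _, model, _ = tiny_setup
        assert model._word_id("zzz-never-seen-zzz") == 0

    def test_subword_variant_requires_bpe(self, tiny_setup):
        corpus, _, _ = tiny_setup
        wv, cv = LayeredNER.build_vocabs(corpus.train)
        with pytest.raises(ValueError, match="BPE"):
            LayeredNER(VariantConfig(variant="csub"), wv, cv, None)


class TestGradients:
    def test_full_model_finite_difference(self, tiny_setup):
        corpus, model, _ = tiny_setup
        model = copy.deepcopy(model)
        sents = model.prepare_corpus(corpus.train[:2])
        sent = max(sents, key=lambda s: len(s.levels))
        assert len(sent.levels) >= 2  # exercise the stacked path
        for p in model.params:
            p.zero_grad()
        model.sentence_loss(sent, train=False)
        grads = {p.name: p.grad.copy() for p in model.params}
        rng = np.random.default_rng(0)
        eps = 1e-6
        for p in model.params[::5]:
            idx = tuple(rng.integers(0, d) for d in p.value.shape)
            old = p.value[idx]
            for p2 in model.params:
                p2.zero_grad()
            p.value[idx] = old + eps
            up = model.sentence_loss(sent, train=False)
            p.value[idx] = old - eps
            dn = model.sentence_loss(sent, train=False)
            p.value[idx] = old
            num = (up - dn) / (2 * eps)
            ana = grads[p.name][idx]
            assert abs(num - ana) / max(1.0, abs(num) + abs(ana)) < 1e-4


@pytest.fixture(scope="module")
def trained():
    corpus = generate_corpus(SynthConfig(
        n_documents=14, sentences_per_doc=6, seed=8,
        nesting_rate=0.5, polysemy_rate=0.2,
    ))
    cfg = VariantConfig(
        variant="wcsub", word_dim=16, char_dim=8, char_hidden=8,
        subword_dim=16, hidden_dim=24, subword_vocab_size=120,
        dropout=0.2, epochs=10, seed=0, lr=5e-3,
    )
    model = train(corpus.train, cfg, dev_docs=corpus.dev)
    return corpus, model


class TestTrainingAndDecoding:

    def test_loss_decreases_over_first_epochs(self, trained):
        _, model = trained
        losses = model.loss_history[:5]
        assert losses[-1] < losses[0]

    def test_decode_terminates_within_cap(self, trained):
        corpus, model = trained
        for doc in corpus.test:
            for toks in doc.sentence_tokens():
                if not toks:
                    continue
                sent = model.prepare_sentence(doc.doc_id, toks, None)
                layers = model.layered_decode(sent)
                assert len(layers) <= model.config.max_layers

    def test_offsets_slice_to_nonempty_text(self, trained):
        corpus, model = trained
        for doc in corpus.test:
            pred = model.predict_document(doc)
            for ent in pred.entities:
                surface = doc.text[ent.start:ent.end]
                assert surface.strip() == surface and surface

    def test_word_labels_equal_merged_subword_labels(self, trained):
        corpus, model = trained
        doc = corpus.test[0]
        toks = doc.sentence_tokens()[0]
        sent = model.prepare_sentence(doc.doc_id, toks, None)
        X = model.compose_input(sent)
        _, unit_labels = model.flat_layer(X, 0)
        merged = merge_subword_labels(unit_labels, sent.alignment)
        layers = model.layered_decode(sent)
        # entities of layer 1 decoded from the merged word labels
        spans = []
        i = 0
        while i < len(merged):
            if merged[i].startswith("B-"):
                cat = merged[i][2:]
                j = i + 1
                while j < len(merged) and merged[j] == f"I-{cat}":
                    j += 1
                spans.append((i, j, cat))
                i = j
            else:
                i += 1
        assert layers[0] == spans

    def test_useful_accuracy_on_heldout(self, trained):
        corpus, model = trained
        preds = [model.predict_document(d) for d in corpus.test]
        rep = score_documents(corpus.test, preds)
        assert rep.lenient["micro"]["f1"] >= 0.7

    def test_save_load_round_trip(self, trained, tmp_path):
        corpus, model = trained
        prefix = str(tmp_path / "ckpt")
        model.save(prefix)
        loaded = LayeredNER.load(prefix)
        for doc in corpus.test[:2]:
            a = model.predict_document(doc)
            b = loaded.predict_document(doc)
            assert a.entity_keys() == b.entity_keys()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train([], VariantConfig(variant="baseline"))


class TestFlatReduction:
    def test_flat_corpus_single_level_gold(self):
        corpus = generate_corpus(flat_copy(SynthConfig(n_documents=6, seed=10)))
        for doc in corpus.all_documents:
            levels = decompose_gold(doc.entities)
            assert len(levels) <= 1
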