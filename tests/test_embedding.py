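import numpy as np
import pytest
from scipy.special import expit

from epipair.corpus import KmerSentence, SequenceRecord, tokenize
from epipair.embedding import (
    EmbeddingModel,
    TrainConfig,
    Vocabulary,
    build_huffman,
    build_vocabulary,
    infer_vector,
    objective,
    train,
)
from .conftest import random_record
from .helpers import reference_huffman_lengths


def make_sentence(kmers, doc_id="D0", k=3):
    return KmerSentence(doc_id=doc_id, kmers=list(kmers), k=k, s=1)


class TestVocabulary:
    def test_worked_example_tokens(self):
        sent = make_sentence(["ATGCAA", "TGCAAC", "GCAACA", "CAACAC"], k=6)
        vocab = build_vocabulary([sent])
        assert vocab.n_words == 4
        assert sorted(vocab.tokens[1:]) == ["ATGCAA", "CAACAC", "GCAACA", "TGCAAC"]

    def test_repeated_token_counts(self):
        vocab = build_vocabulary([make_sentence(["AAA"] * 5)])
        assert vocab.n_words == 1
        assert vocab.counts[vocab.lookup("AAA")] == 5

    def test_random_corpus_counts_sum(self, rng):
        records = [random_record(rng, 60, f"E{i}") for i in range(8)]
        sentences = [tokenize(r, 3, 1) for r in records]
        vocab = build_vocabulary(sentences)
        assert vocab.n_words <= 64
        total = sum(s.T for s in sentences)
        assert vocab.counts.sum() == total

    def test_ambiguous_kmer_maps_to_unk(self):
        rec = SequenceRecord("E", "enhancer", "ACGNNACG")
        sent = tokenize(rec, 3, 1)
        vocab = build_vocabulary([sent])
        sent.tokens = vocab.encode(sent)
        # windows containing N encode as UNK (index 0), count formula unchanged
        assert sent.T == 6
        assert (sent.tokens == 0).sum() == 4
        assert all("N" not in t for t in vocab.tokens[1:])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([make_sentence([])])


class TestHuffman:
    def vocab_from_counts(self, counts):
        return Vocabulary(list(counts), list(counts.values()))

    def test_two_leaves(self):
        tree = build_huffman(self.vocab_from_counts({"AAA": 1, "CCC": 1}))
        assert tree.code_length(1) == 1 and tree.code_length(2) == 1
        assert tree.n_internal == 1

    def test_textbook_three_symbols(self):
        vocab = self.vocab_from_counts({"AAA": 4, "CCC": 1, "GGG": 1})
        tree = build_huffman(vocab)
        lengths = {vocab.tokens[i]: tree.code_length(i) for i in range(1, 4)}
        assert lengths == {"AAA": 1, "CCC": 2, "GGG": 2}

    def test_frequent_words_get_short_codes(self, rng):
        counts = {f"T{i:02d}": int(c) for i, c in enumerate(rng.integers(1, 500, 16))}
        vocab = self.vocab_from_counts(counts)
        tree = build_huffman(vocab)
        for i in range(1, 17):
            for j in range(1, 17):
                if vocab.counts[i] > vocab.counts[j]:
                    assert tree.code_length(i) <= tree.code_length(j)

    @pytest.mark.parametrize("trial", range(10))
    def test_optimal_weighted_length_vs_reference(self, trial):
        rng = np.random.default_rng(100 + trial)
        V = int(rng.integers(2, 40))
        counts = {f"S{i:02d}": int(c) for i, c in enumerate(rng.integers(1, 1000, V))}
        vocab = self.vocab_from_counts(counts)
        tree = build_huffman(vocab)
        ref = reference_huffman_lengths(counts)
        ours = sum(vocab.counts[i] * tree.code_length(i) for i in range(1, V + 1))
        theirs = sum(counts[sym] * depth for sym, depth in ref.items())
        assert ours == theirs

    def test_kraft_sum_is_one(self, rng):
        counts = {f"K{i}": int(c) for i, c in enumerate(rng.integers(1, 50, 20))}
        tree = build_huffman(self.vocab_from_counts(counts))
        assert tree.kraft_sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_vocab_rejected(self):
        with pytest.raises(ValueError):
            build_huffman(self.vocab_from_counts({"AAA": 3}))


class TestNextWordProbability:
    def test_normalisation_hsm(self, tiny_model, tiny_corpus):
        _, sentences = tiny_corpus
        sent = sentences[0]
        p = tiny_model.next_word_probability(sent.tokens[:3], sent.doc_id)
        assert p.sum() == pytest.approx(1.0, abs=1e-8)
        assert p[0] == 0.0  # UNK is never predicted
        assert np.all(p[1:] > 0)

    def test_hsm_matches_brute_force_path_products(self, tiny_model, tiny_corpus):
        """Leaf probability equals the product of branch sigmoids on its path."""
        _, sentences = tiny_corpus
        sent = sentences[0]
        m = tiny_model.config.m
        h = np.concatenate(
            [tiny_model.word_vec[sent.tokens[:m].astype(int)].ravel(),
             tiny_model.doc_vec[tiny_model.doc_index[sent.doc_id]]]
        )
        p = tiny_model.next_word_probability(sent.tokens[:m], sent.doc_id)
        tree = tiny_model.tree
        for leaf in range(1, len(tiny_model.vocab)):
            expected = 1.0
            for bit, pt in zip(tree.codes[leaf], tree.points[leaf]):
                z = float(tiny_model._node_vec[pt] @ h)
                expected *= expit(z) if bit == 1 else expit(-z)
            assert p[leaf] == pytest.approx(expected, rel=1e-10)

    def test_exact_backend_uniform_at_zero_parameters(self):
        sentences = [make_sentence(["AAA", "CCC", "AAA", "CCC", "AAA"])]
        config = TrainConfig(k=3, s=1, m=2, d=4, epochs=1, lr0=1e-12, lr1=1e-13,
                             seed=3, backend="exact")
        model = train(sentences, config)
        model.word_vec[:] = 0.0
        model.doc_vec[:] = 0.0
        model.U[:] = 0.0
        model.b[:] = 0.0
        p = model.next_word_probability([1, 2], "D0")
        assert p[1:] == pytest.approx([0.5, 0.5])

    def test_context_length_and_unknown_doc_errors(self, tiny_model, tiny_corpus):
        _, sentences = tiny_corpus
        sent = sentences[0]
        with pytest.raises(ValueError):
            tiny_model.next_word_probability(sent.tokens[:2], sent.doc_id)
        with pytest.raises(KeyError):
            tiny_model.next_word_probability(sent.tokens[:3], "NOPE")


class TestTraining:
    def test_objective_improves_over_random_init(self, tiny_corpus):
        _, sentences = tiny_corpus
        frozen = TrainConfig(k=3, s=1, m=3, d=8, epochs=1, lr0=1e-12, lr1=1e-13, seed=7)
        trained = TrainConfig(k=3, s=1, m=3, d=8, epochs=10, seed=7)
        base = objective(train(list(sentences), frozen), sentences)
        best = objective(train(list(sentences), trained), sentences)
        assert best > base

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_objective_monotonic_across_seeds(self, seed):
        rng = np.random.default_rng(seed)
        records = [random_record(rng, 80, f"E{i}") for i in range(8)]
        sentences = [tokenize(r, 3, 1) for r in records]
        frozen = TrainConfig(k=3, s=1, m=2, d=6, epochs=1, lr0=1e-12, lr1=1e-13, seed=seed)
        trained = TrainConfig(k=3, s=1, m=2, d=6, epochs=8, seed=seed)
        assert objective(train(list(sentences), trained), sentences) > objective(
            train(list(sentences), frozen), sentences
        )

    def test_identical_sentences_embed_close(self, rng):
        records = [random_record(rng, 100, f"E{i}") for i in range(20)]
        sentences = [tokenize(r, 3, 1) for r in records]
        twin = KmerSentence("TWIN", list(sentences[0].kmers), 3, 1)
        sentences.append(twin)
        model = train(sentences, TrainConfig(k=3, s=1, m=2, d=8, epochs=30, seed=5))
        vecs = model.doc_vec / np.linalg.norm(model.doc_vec, axis=1, keepdims=True)
        sims = vecs @ vecs[model.doc_index["E0"]]
        twin_sim = sims[model.doc_index["TWIN"]]
        others = np.delete(sims, [model.doc_index["E0"], model.doc_index["TWIN"]])
        assert twin_sim > np.percentile(others, 95)

    def test_bit_identical_under_fixed_seed(self, tiny_corpus):
        _, sentences = tiny_corpus
        config = TrainConfig(k=3, s=1, m=3, d=8, epochs=4, seed=42)
        m1 = train(list(sentences), config)
        m2 = train(list(sentences), config)
        assert np.array_equal(m1.doc_vec, m2.doc_vec)
        assert np.array_equal(m1.word_vec, m2.word_vec)

    def test_all_short_sentences_rejected(self):
        sentences = [make_sentence(["AAA", "CCC"])]
        with pytest.raises(ValueError, match="lower m"):
            train(sentences, TrainConfig(k=3, s=1, m=5, d=4, epochs=1, seed=1))


class TestEmbedAndInfer:
    def test_embed_returns_d_vector_twice_identical(self, tiny_model):
        v1 = tiny_model.embed("ENHANCER_0")
        v2 = tiny_model.embed("ENHANCER_0")
        assert v1.shape == (8,)
        assert np.array_equal(v1, v2)
        assert 0 < np.linalg.norm(v1) < np.inf

    def test_unseen_doc_id_directs_to_infer(self, tiny_model):
        with pytest.raises(KeyError, match="infer_vector"):
            tiny_model.embed("UNSEEN")

    def test_infer_recovers_training_doc(self, rng):
        records = [random_record(rng, 150, f"E{i}") for i in range(15)]
        sentences = [tokenize(r, 3, 1) for r in records]
        model = train(sentences, TrainConfig(k=3, s=1, m=2, d=8, epochs=20, seed=2))
        v = infer_vector(model, sentences[0], epochs=20, seed=9)
        vecs = model.doc_vec / np.linalg.norm(model.doc_vec, axis=1, keepdims=True)
        sims = vecs @ (v / np.linalg.norm(v))
        own = sims[model.doc_index["E0"]]
        assert own > np.median(np.delete(sims, model.doc_index["E0"]))

    def test_infer_zero_epochs_is_random_init_and_reproducible(self, tiny_model, tiny_corpus):
        _, sentences = tiny_corpus
        v0a = infer_vector(tiny_model, sentences[0], epochs=0, seed=5)
        v0b = infer_vector(tiny_model, sentences[0], epochs=0, seed=5)
        assert np.array_equal(v0a, v0b)
        va = infer_vector(tiny_model, sentences[0], epochs=5, seed=5)
        vb = infer_vector(tiny_model, sentences[0], epochs=5, seed=5)
        assert np.array_equal(va, vb)
        assert not np.array_equal(v0a, va)

    def test_infer_rejects_short_sentence(self, tiny_model):
        with pytest.raises(ValueError):
            infer_vector(tiny_model, make_sentence(["AAA"]))


class TestPersistence:
    def test_round_trip_lossless(self, tiny_model, tmp_path):
        path = tmp_path / "model.bin"
        tiny_model.save(path)
        back = EmbeddingModel.load(path)
        assert back.vocab.tokens == tiny_model.vocab.tokens
        assert np.array_equal(back.word_vec, tiny_model.word_vec)
        assert np.array_equal(back.doc_vec, tiny_model.doc_vec)
        assert np.array_equal(back._node_vec, tiny_model._node_vec)
        assert back.config == tiny_model.config
        assert back.doc_ids == tiny_model.doc_ids

    def test_save_is_byte_deterministic(self, tiny_model, tmp_path):
        p1, p2 = tmp_path / "a.bin", tmp_path / "b.bin"
        tiny_model.save(p1)
        tiny_model.save(p2)
        assert p1.read_bytes() == p2.read_bytes()
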