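"""Tokenization, stop words, vocabulary threshold, and embeddings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ohc_accept.embeddings import get_embeddings, load_word2vec_text, save_word2vec_text
from ohc_accept.preprocess import (
    MaxMatchTokenizer,
    TokenSequence,
    Vocabulary,
    build_vocab,
    load_stopwords,
    remove_stopwords,
    tokenize,
)


class TestTokenize:
    def test_whitespace_default(self):
        assert tokenize("mouth ulcer pain").tokens == ["mouth", "ulcer", "pain"]

    def test_empty_text(self):
        seq = tokenize("")
        assert seq.tokens == [] and seq.is_empty

    def test_dictionary_term_kept_whole(self):
        tok = MaxMatchTokenizer(words=["高血压", "口腔溃疡"], user_dicts=[["硝苯地平缓释片"]])
        out = tok("高血压吃硝苯地平缓释片")
        assert "硝苯地平缓释片" in out
        assert out[0] == "高血压"

    def test_maxmatch_prefers_longest(self):
        tok = MaxMatchTokenizer(words=["ab", "abc"])
        assert tok("abcd") == ["abc", "d"]

    def test_maxmatch_unknown_chars_single(self):
        tok = MaxMatchTokenizer(words=["xy"])
        assert tok("axyb") == ["a", "xy", "b"]


class TestStopwords:
    def test_removal_preserves_order(self):
        seq = TokenSequence(["the", "ulcer", "is", "painful"])
        out = remove_stopwords(seq, {"the", "is"})
        assert out.tokens == ["ulcer", "painful"]

    def test_empty_set_is_identity(self):
        seq = TokenSequence(["a", "b"])
        assert remove_stopwords(seq, set()).tokens == ["a", "b"]

    def test_all_stopwords_gives_empty(self):
        seq = TokenSequence(["um", "uh"])
        out = remove_stopwords(seq, {"um", "uh"})
        assert out.is_empty

    def test_idempotent(self):
        seq = TokenSequence(["the", "ulcer", "the"])
        sw = {"the"}
        once = remove_stopwords(seq, sw)
        assert remove_stopwords(once, sw).tokens == once.tokens

    def test_load_from_file(self, tmp_path):
        p = tmp_path / "stop.txt"
        p.write_text("the\nis\n\n的\n", encoding="utf-8")
        assert load_stopwords(p) == {"the", "is", "的"}


class TestVocabulary:
    def test_frequency_threshold_boundary(self):
        # 30 occurrences survives the "below 30" replacement rule; 29 does not
        seqs = [["fever"]] * 30 + [["qx"]] * 29
        vocab = build_vocab(seqs, min_count=30)
        assert "fever" in vocab
        assert "qx" not in vocab
        assert vocab.lookup("qx") == vocab.unk_index

    def test_min_count_one_keeps_everything(self):
        vocab = build_vocab([["a", "b"], ["b"]], min_count=1)
        assert "a" in vocab and "b" in vocab

    def test_unseen_token_maps_to_unk(self):
        vocab = build_vocab([["a"] * 5], min_count=1)
        assert vocab.lookup("never-seen") == vocab.unk_index

    def test_empty_corpus(self):
        vocab = build_vocab([], min_count=30)
        assert len(vocab) == 2  # PAD + UNK

    def test_indices_dense(self):
        vocab = build_vocab([["a"] * 3, ["b"] * 3, ["c"] * 3], min_count=2)
        assert sorted(vocab.token_to_index.values()) == list(range(len(vocab)))

    def test_order_invariance(self):
        a = build_vocab([["x"] * 4, ["y"] * 2], min_count=2)
        b = build_vocab([["y"] * 2, ["x"] * 4], min_count=2)
        assert a.token_to_index == b.token_to_index

    def test_save_load_round_trip(self, tmp_path):
        vocab = build_vocab([["a"] * 3, ["b"] * 2], min_count=2)
        vocab.save(tmp_path / "v.json")
        back = Vocabulary.load(tmp_path / "v.json")
        assert back.token_to_index == vocab.token_to_index
        assert back.min_count == vocab.min_count

    @given(st.lists(st.lists(st.sampled_from("abcdef"), max_size=8), max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_lookup_total(self, seqs):
        vocab = build_vocab(seqs, min_count=2)
        for s in seqs:
            for t in s:
                assert 0 <= vocab.lookup(t) < len(vocab)


class TestEmbeddings:
    def test_random_init_deterministic(self):
        vocab = build_vocab([["a"] * 3], min_count=1)
        t1 = get_embeddings(vocab, "random_init", dim=8, seed=7)
        t2 = get_embeddings(vocab, "random_init", dim=8, seed=7)
        np.testing.assert_array_equal(t1.vectors, t2.vectors)

    def test_pad_row_zero(self):
        vocab = build_vocab([["a"] * 3], min_count=1)
        t = get_embeddings(vocab, "random_init", dim=8, seed=7)
        np.testing.assert_array_equal(t.vectors[vocab.pad_index], 0.0)

    def test_load_pretrained_matches_file(self, tmp_path):
        vocab = build_vocab([["alpha"] * 3, ["beta"] * 3], min_count=1)
        t = get_embeddings(vocab, "random_init", dim=4, seed=1)
        path = tmp_path / "emb.txt"
        save_word2vec_text(t, path)
        loaded = get_embeddings(vocab, "load_pretrained", dim=4, seed=2, pretrained_path=path)
        np.testing.assert_allclose(loaded.vectors, t.vectors, atol=1e-5)

    def test_load_pretrained_dim_mismatch(self, tmp_path):
        vocab = build_vocab([["a"] * 3], min_count=1)
        t = get_embeddings(vocab, "random_init", dim=4, seed=1)
        path = tmp_path / "emb.txt"
        save_word2vec_text(t, path)
        with pytest.raises(ValueError, match="dimension"):
            get_embeddings(vocab, "load_pretrained", dim=8, pretrained_path=path)

    def test_word2vec_text_round_trip(self, tmp_path):
        vocab = build_vocab([["a"] * 3, ["b"] * 3], min_count=1)
        t = get_embeddings(vocab, "random_init", dim=4, seed=3)
        path = tmp_path / "emb.txt"
        save_word2vec_text(t, path)
        d = load_word2vec_text(path)
        assert set(d) == set(vocab.token_to_index)
        np.testing.assert_allclose(d["a"], t.lookup("a"), atol=1e-5)

    def test_train_word2vec_shape_and_finite(self):
        rng = np.random.default_rng(0)
        seqs = [[f"w{rng.integers(20)}" for _ in range(10)] for _ in range(40)]
        vocab = build_vocab(seqs, min_count=1)
        t = get_embeddings(vocab, "train_word2vec", dim=16, seed=5,
                           corpus_tokens=seqs, epochs=1)
        assert t.vectors.shape == (len(vocab), 16)
        assert np.all(np.isfinite(t.vectors))

    def test_train_word2vec_cooccurrence_similarity(self):
        # tokens that always co-occur should embed closer than unrelated ones
        pair = [["sun", "moon"] * 5 for _ in range(60)]
        other = [["rock", "lava"] * 5 for _ in range(60)]
        seqs = pair + other
        vocab = build_vocab(seqs, min_count=1)
        t = get_embeddings(vocab, "train_word2vec", dim=16, seed=5,
                           corpus_tokens=seqs, epochs=3)

        def cos(a, b):
            va, vb = t.lookup(a), t.lookup(b)
            return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb) + 1e-12))

        assert cos("sun", "moon") > cos("sun", "rock")
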