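"""Encoder training behaviour, feature extraction, and persistence."""

import numpy as np
import pytest

import ohc_accept as oa
from ohc_accept.embeddings import get_embeddings
from ohc_accept.encoder import (
    CoAttentionEncoder,
    export_attention,
    extract_textual_features,
    load_checkpoint,
    prepare_pairs,
    save_checkpoint,
)
from ohc_accept.preprocess import build_vocab, tokenize

SMALL = dict(state_size=16, embedding_dim=16, max_question_len=24,
             max_answer_len=24, batch_size=32, mlp_hidden=16)


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = oa.GeneratorConfig(n_questions=60, q_len_mean=10.0, a_len_mean=12.0,
                             beta_num=(0.0, 0.0, 0.0, 0.0), seed=21)
    corpus, _ = oa.generate(cfg)
    corpus = oa.filter_and_label(corpus)
    toks = [tokenize(r.question_text).tokens for r in corpus] + [
        tokenize(r.answer_text).tokens for r in corpus
    ]
    vocab = build_vocab(toks, min_count=1)
    emb = get_embeddings(vocab, "random_init", dim=16, seed=0)
    data, y, groups = prepare_pairs(corpus, vocab, max_question_len=24, max_answer_len=24)
    return corpus, vocab, emb, data, y


def fit_encoder(tiny_setup, **over):
    corpus, vocab, emb, data, y = tiny_setup
    kw = dict(SMALL, embeddings=emb, epochs=2, seed=5)
    kw.update(over)
    est = CoAttentionEncoder(**kw)
    est.fit(data, y)
    return est, data, y


class TestTraining:
    def test_loss_decreases_over_epochs(self, tiny_setup):
        est, _, _ = fit_encoder(tiny_setup, epochs=3)
        losses = est.train_report_.train_losses
        assert losses[-1] < losses[0]

    def test_same_seed_identical_report(self, tiny_setup):
        est1, _, _ = fit_encoder(tiny_setup)
        est2, _, _ = fit_encoder(tiny_setup)
        assert est1.train_report_.to_dict() == est2.train_report_.to_dict()

    def test_zero_learning_rate_freezes_parameters(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est = CoAttentionEncoder(**SMALL, embeddings=emb, epochs=3, seed=5,
                                 learning_rate=0.0, dropout_rate=0.0, patience=10)
        init = EncoderSnapshot = None
        est.fit(data, y)
        losses = est.train_report_.train_losses
        assert np.allclose(losses, losses[0], atol=1e-6)

    def test_single_class_raises(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est = CoAttentionEncoder(**SMALL, embeddings=emb, epochs=1, seed=5)
        with pytest.raises(ValueError, match="both classes"):
            est.fit(data, np.ones_like(y))

    def test_heldout_split_disjoint_and_covering(self, tiny_setup):
        est, data, y = fit_encoder(tiny_setup)
        tr, ho = est.train_indices_, est.heldout_indices_
        assert len(np.intersect1d(tr, ho)) == 0
        assert len(tr) + len(ho) == len(y)
        assert len(ho) == pytest.approx(0.2 * len(y), abs=2)

    @pytest.mark.parametrize("ctx", ["lstm", "mlp"])
    def test_both_context_functions_train(self, tiny_setup, ctx):
        est, data, _ = fit_encoder(tiny_setup, context_fn=ctx, epochs=1)
        h = est.transform(data)
        expected_len = SMALL["state_size"] if ctx == "lstm" else SMALL["max_answer_len"]
        assert h.shape == (len(data), expected_len)
        assert np.all(np.isfinite(h))


class TestInference:
    def test_transform_deterministic_and_aligned(self, tiny_setup):
        est, data, _ = fit_encoder(tiny_setup)
        h1 = est.transform(data)
        h2 = est.transform(data)
        np.testing.assert_array_equal(h1, h2)
        assert h1.shape[0] == len(data)

    def test_different_answers_give_different_features(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est, _, _ = fit_encoder(tiny_setup)
        groups = {}
        for i, r in enumerate(corpus):
            groups.setdefault(r.question_id, []).append(i)
        pair = next(v for v in groups.values() if len(v) >= 2)
        h = est.transform(data)
        assert not np.allclose(h[pair[0]], h[pair[1]])

    def test_predict_proba_rows_sum_to_one(self, tiny_setup):
        est, data, _ = fit_encoder(tiny_setup)
        p = est.predict_proba(data)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_extract_textual_features_wrapper(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est, _, _ = fit_encoder(tiny_setup)
        feats = extract_textual_features(corpus, est, vocab)
        assert feats.shape[0] == len(corpus)

    def test_sklearn_get_set_params(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est = CoAttentionEncoder(**SMALL, embeddings=emb)
        params = est.get_params()
        assert params["state_size"] == SMALL["state_size"]
        est.set_params(epochs=7)
        assert est.epochs == 7


class TestCheckpoint:
    def test_round_trip_preserves_features(self, tiny_setup, tmp_path):
        corpus, vocab, emb, data, y = tiny_setup
        est, _, _ = fit_encoder(tiny_setup)
        path = tmp_path / "enc.npz"
        save_checkpoint(est, path, vocab=vocab)
        back, vocab2 = load_checkpoint(path)
        assert vocab2.token_to_index == vocab.token_to_index
        np.testing.assert_allclose(back.transform(data), est.transform(data), atol=1e-6)
        np.testing.assert_array_equal(back.heldout_indices_, est.heldout_indices_)


class TestAttentionExport:
    def test_export_structure_and_normalisation(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est, _, _ = fit_encoder(tiny_setup)
        rec = corpus[0]
        rep = export_attention(rec.question_text, rec.answer_text, est, vocab)
        SQ = np.asarray(rep["SQ"])
        SA = np.asarray(rep["SA"])
        assert SQ.shape == (len(rep["answer_tokens"]), len(rep["question_tokens"]))
        np.testing.assert_allclose(SQ.sum(axis=0), 1.0, atol=1e-5)
        np.testing.assert_allclose(SA.sum(axis=0), 1.0, atol=1e-5)

    def test_stopwords_removed_from_labels(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est, _, _ = fit_encoder(tiny_setup)
        rec = corpus[0]
        first = rec.question_text.split()[0]
        rep = export_attention(rec.question_text, rec.answer_text, est, vocab,
                               stopwords={first})
        assert first not in rep["question_tokens"]

    def test_oov_tokens_labeled_unk(self, tiny_setup):
        corpus, vocab, emb, data, y = tiny_setup
        est, _, _ = fit_encoder(tiny_setup)
        rec = corpus[0]
        rep = export_attention("zzz-not-in-vocab " + rec.question_text,
                               rec.answer_text, est, vocab)
        assert rep["question_tokens"][0] == "UNK"
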