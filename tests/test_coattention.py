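"""Co-attention pipeline against brute-force scalar oracles."""

import numpy as np
import pytest

from ohc_accept.coattention import (
    EncoderConfig,
    EncoderModel,
    affinity,
    attention_scores,
    classify,
    coattention_context,
    cross_entropy_loss,
    project_question,
)


# ---------------------------------------------------------------------------
# scalar triple-loop oracle, independent of the matrix implementation
# ---------------------------------------------------------------------------

def oracle_pipeline(A, Q, q_mask, a_mask):
    """affinity -> attention -> context by explicit scalar loops."""
    l, m = A.shape
    _, n = Q.shape
    L = np.zeros((m, n))
    for i in range(m):
        for j in range(n):
            for k in range(l):
                L[i, j] += A[k, i] * Q[k, j]
    SQ = np.zeros((m, n))
    for j in range(n):
        if not q_mask[j]:
            continue
        exps = [np.exp(L[i, j]) if a_mask[i] else 0.0 for i in range(m)]
        z = sum(exps)
        for i in range(m):
            SQ[i, j] = exps[i] / z
    SA = np.zeros((n, m))
    for i in range(m):
        if not a_mask[i]:
            continue
        exps = [np.exp(L[i, j]) if q_mask[j] else 0.0 for j in range(n)]
        z = sum(exps)
        for j in range(n):
            SA[j, i] = exps[j] / z
    CQ = np.zeros((l, n))
    for k in range(l):
        for j in range(n):
            for i in range(m):
                CQ[k, j] += A[k, i] * SQ[i, j]
    stacked = np.vstack([Q, CQ])
    CA = np.zeros((2 * l, m))
    for k in range(2 * l):
        for i in range(m):
            for j in range(n):
                CA[k, i] += stacked[k, j] * SA[j, i]
    return L, SQ, SA, CQ, CA


def random_instance(rng, l=None, n=None, m=None, masked=True):
    l = l or int(rng.integers(1, 5))
    n = n or int(rng.integers(1, 7))
    m = m or int(rng.integers(1, 7))
    A = rng.standard_normal((l, m))
    Q = rng.standard_normal((l, n))
    if masked and n > 1 and m > 1:
        q_mask = np.r_[np.ones(int(rng.integers(1, n + 1))), np.zeros(n)][:n]
        a_mask = np.r_[np.ones(int(rng.integers(1, m + 1))), np.zeros(m)][:m]
    else:
        q_mask, a_mask = np.ones(n), np.ones(m)
    return A, Q, q_mask, a_mask


class TestAgainstOracle:
    def test_matrix_pipeline_equals_triple_loop(self, rng):
        for _ in range(100):
            A, Q, q_mask, a_mask = random_instance(rng)
            Lo, SQo, SAo, CQo, CAo = oracle_pipeline(A, Q, q_mask, a_mask)
            L = affinity(A, Q)
            SQ, SA = attention_scores(L, q_mask, a_mask)
            CQ, CA = coattention_context(Q, A, SQ, SA)
            np.testing.assert_allclose(L, Lo, atol=1e-10)
            np.testing.assert_allclose(SQ, SQo, atol=1e-10)
            np.testing.assert_allclose(SA, SAo, atol=1e-10)
            np.testing.assert_allclose(CQ, CQo, atol=1e-10)
            np.testing.assert_allclose(CA, CAo, atol=1e-10)


class TestAffinity:
    def test_zero_annihilates(self):
        assert np.all(affinity(np.zeros((3, 4)), np.ones((3, 5))) == 0.0)

    def test_hand_product(self):
        A = np.array([[1.0, 2.0]])  # l=1, m=2
        Q = np.array([[3.0, 4.0, 5.0]])  # l=1, n=3
        np.testing.assert_array_equal(
            affinity(A, Q), [[3.0, 4.0, 5.0], [6.0, 8.0, 10.0]]
        )

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            affinity(np.zeros((3, 2)), np.zeros((4, 2)))


class TestAttentionScores:
    def test_uniform_when_logits_zero(self):
        SQ, SA = attention_scores(np.zeros((4, 2)))
        np.testing.assert_allclose(SQ, 0.25)
        np.testing.assert_allclose(SA, 0.5)

    def test_single_unmasked_position_degenerates(self):
        L = np.zeros((3, 2))
        SQ, _ = attention_scores(L, a_mask=np.array([0.0, 1.0, 0.0]))
        np.testing.assert_array_equal(SQ[:, 0], [0.0, 1.0, 0.0])

    def test_scalar_softmax_column(self):
        L = np.array([[1.0], [2.0]])
        SQ, _ = attention_scores(L)
        e1, e2 = np.exp(1.0), np.exp(2.0)
        np.testing.assert_allclose(SQ[:, 0], [e1 / (e1 + e2), e2 / (e1 + e2)])

    def test_columns_sum_to_one(self, rng):
        A, Q, q_mask, a_mask = random_instance(rng, l=3, n=5, m=4)
        SQ, SA = attention_scores(affinity(A, Q), q_mask, a_mask)
        np.testing.assert_allclose(
            SQ.sum(axis=0)[q_mask == 1], 1.0, atol=1e-6
        )
        np.testing.assert_allclose(
            SA.sum(axis=0)[a_mask == 1], 1.0, atol=1e-6
        )
        assert np.all(SQ[a_mask == 0, :] == 0.0)
        assert np.all(SA[q_mask == 0, :] == 0.0)

    def test_fully_masked_column_raises(self):
        with pytest.raises(ValueError):
            attention_scores(np.zeros((2, 2)), a_mask=np.zeros(2))


class TestContext:
    def test_one_hot_selection(self, rng):
        l, n, m = 3, 4, 2
        Q = rng.standard_normal((l, n))
        A = rng.standard_normal((l, m))
        SQ = np.full((m, n), 1.0 / m)
        SA = np.zeros((n, m))
        SA[2, 0] = 1.0
        SA[0, 1] = 1.0
        CQ, CA = coattention_context(Q, A, SQ, SA)
        stacked = np.vstack([Q, CQ])
        np.testing.assert_allclose(CA[:, 0], stacked[:, 2])
        np.testing.assert_allclose(CA[:, 1], stacked[:, 0])

    def test_zero_propagation(self):
        CQ, CA = coattention_context(
            np.zeros((2, 3)), np.zeros((2, 4)),
            np.full((4, 3), 0.25), np.full((3, 4), 1 / 3),
        )
        assert np.all(CA == 0.0)

    def test_ca_shape_is_2l_by_m(self, rng):
        for _ in range(10):
            A, Q, q_mask, a_mask = random_instance(rng)
            SQ, SA = attention_scores(affinity(A, Q), q_mask, a_mask)
            _, CA = coattention_context(Q, A, SQ, SA)
            assert CA.shape == (2 * Q.shape[0], A.shape[1])


class TestProjectionAndHead:
    def test_zero_weights_give_zero(self):
        Qp = np.ones((3, 4))
        np.testing.assert_array_equal(
            project_question(Qp, np.zeros((3, 3)), np.zeros(3)), 0.0
        )

    def test_saturation(self):
        Qp = np.full((2, 3), 50.0)
        Q = project_question(Qp, np.eye(2), np.zeros(2))
        np.testing.assert_allclose(Q, 1.0)

    def test_matches_elementwise_tanh(self, rng):
        Qp = rng.standard_normal((3, 5))
        W = rng.standard_normal((3, 3)) * 0.3
        b = rng.standard_normal(3) * 0.1
        np.testing.assert_allclose(
            project_question(Qp, W, b), np.tanh(W @ Qp + b[:, None]), atol=1e-12
        )

    def test_classify_zero_logits(self):
        p0, p1 = classify(np.zeros(4), np.zeros((4, 2)), np.zeros(2))
        assert (p0, p1) == (0.5, 0.5)

    def test_classify_saturated(self):
        p0, p1 = classify(np.ones(1), np.array([[0.0, 20.0]]), np.zeros(2))
        assert p1 > 0.999999 and p0 + p1 == pytest.approx(1.0)

    def test_classify_matches_scalar_softmax(self, rng):
        h = rng.standard_normal(3)
        W = rng.standard_normal((3, 2))
        b = rng.standard_normal(2)
        z = h @ W + b
        e = np.exp(z - z.max())
        p0, p1 = classify(h, W, b)
        np.testing.assert_allclose([p0, p1], e / e.sum(), atol=1e-12)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy_loss(np.array([1.0, 0.0]), np.array([1, 0])) == 0.0

    def test_half_probabilities(self):
        val = cross_entropy_loss(np.full(4, 0.5), np.array([1, 0, 1, 0]))
        assert val == pytest.approx(4 * np.log(2.0))

    def test_nonnegative(self, rng):
        p = rng.random(50)
        y = rng.integers(0, 2, 50)
        assert cross_entropy_loss(p, y) >= 0.0

    def test_saturated_probability_clamped_warns(self):
        with pytest.warns(UserWarning):
            val = cross_entropy_loss(np.array([0.0]), np.array([1]))
        assert np.isfinite(val)


@pytest.fixture(scope="module")
def model():
    cfg = EncoderConfig(state_size=6, embedding_dim=5, max_question_len=8,
                        max_answer_len=8, precision="double", seed=3)
    rng = np.random.default_rng(0)
    return EncoderModel(cfg, rng.standard_normal((20, 5)))


class TestEncodedPair:
    def test_shapes(self, model):
        pair = model.encode_pair([1, 2, 3], [4, 5, 6, 7])
        l, n, m = 6, 3, 4
        assert pair.Qprime.shape == (l, n)
        assert pair.A.shape == (l, m)
        assert pair.Q.shape == (l, n)
        assert pair.L.shape == (m, n)
        assert pair.SQ.shape == (m, n)
        assert pair.SA.shape == (n, m)
        assert pair.CQ.shape == (l, n)
        assert pair.CA.shape == (2 * l, m)

    def test_internally_consistent_with_functional_ops(self, model):
        pair = model.encode_pair([1, 2, 3], [4, 5, 6, 7])
        np.testing.assert_allclose(pair.L, affinity(pair.A, pair.Q), atol=1e-10)
        SQ, SA = attention_scores(pair.L, pair.q_mask, pair.a_mask)
        np.testing.assert_allclose(pair.SQ, SQ, atol=1e-10)
        np.testing.assert_allclose(pair.SA, SA, atol=1e-10)
        CQ, CA = coattention_context(pair.Q, pair.A, SQ, SA)
        np.testing.assert_allclose(pair.CQ, CQ, atol=1e-10)
        np.testing.assert_allclose(pair.CA, CA, atol=1e-10)

    def test_single_token_question(self, model):
        pair = model.encode_pair([2], [3, 4])
        assert pair.Qprime.shape == (6, 1)

    def test_deterministic(self, model):
        p1 = model.encode_pair([1, 2], [3, 4])
        p2 = model.encode_pair([1, 2], [3, 4])
        np.testing.assert_array_equal(p1.CA, p2.CA)

    def test_projection_bounded(self, model):
        pair = model.encode_pair([1, 2, 3], [4, 5])
        assert np.all(np.abs(pair.Q) < 1.0)

    def test_empty_sequence_raises(self, model):
        with pytest.raises(ValueError):
            model.encode_pair([], [1, 2])

    def test_answer_word_order_changes_ca(self, model):
        p1 = model.encode_pair([1, 2, 3], [4, 5, 6])
        p2 = model.encode_pair([1, 2, 3], [6, 5, 4])
        assert not np.allclose(p1.CA, p2.CA)
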