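"""The co-attention sentence encoder: model state and forward computation.

A (question, answer) token-index pair is encoded by two LSTMs into
per-word states Q' (l x n) and A (l x m); the question is projected with
a nonlinearity, Q = tanh(W_Q Q' + b_Q).  The affinity matrix L = A^T Q
scores every answer-word/question-word pair; normalising L over answer
positions gives S_Q and over question positions gives S_A, so every
unmasked attention column is a convex-combination weight vector.  The
attended summaries are C_Q = A S_Q and the co-dependent answer
representation C_A = [Q; C_Q] S_A (2l x m).  A context function reduces
C_A to a fixed-length vector h: either a third LSTM over the columns
(last unmasked state, length l) or a shared per-column MLP producing one
scalar per answer position (length M after padding).  h feeds a softmax
head for the binary accepted/not-accepted decision, trained with
cross-entropy.

Note on C_Q: it is computed as A S_Q, which algebraically is an
answer-state summary per question word, although this quantity is often
described as a question summary; the algebra here is exactly A S_Q.

This module holds the numerics: single-pair numpy ops (also used by the
brute-force oracles in the tests) and the batched, taped forward pass
used for training.  The sklearn-style estimator lives in
:mod:`ohc_accept.encoder`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "EncoderConfig",
    "EncoderModel",
    "EncodedPair",
    "affinity",
    "attention_scores",
    "coattention_context",
    "project_question",
    "classify",
    "cross_entropy_loss",
]

logger = logging.getLogger(__name__)


@dataclass
class EncoderConfig:
    """Hyper-parameters of the sentence encoder.

    Defaults: LSTM state size 100, embedding
    dimension 100, batch size 100, learning rate 0.001; dropout (0.5) on
    the context representation and global-norm gradient clipping (5.0)
    guard against overfitting.  ``context_fn`` selects the reduction of
    C_A: "lstm" (last hidden state) or "mlp" (per-column scalar).
    """

    state_size: int = 100
    embedding_dim: int = 100
    context_fn: str = "lstm"  # "lstm" | "mlp"
    share_qa_lstm: bool = False
    max_question_len: int = 64
    max_answer_len: int = 64
    dropout_rate: float = 0.5
    clip_norm: float = 5.0
    learning_rate: float = 0.001
    batch_size: int = 100
    epochs: int = 20
    patience: int = 3
    mlp_hidden: int = 100
    fine_tune_embeddings: bool = False
    heldout_fraction: float = 0.2
    precision: str = "single"  # "single" for training speed, "double" for oracles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.context_fn not in ("lstm", "mlp"):
            raise ValueError(f"unknown context_fn {self.context_fn!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")

    @property
    def dtype(self):
        return np.float32 if self.precision == "single" else np.float64

    @property
    def feature_length(self) -> int:
        """Length of the textual feature vector h."""
        return self.state_size if self.context_fn == "lstm" else self.max_answer_len

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EncodedPair:
    """All intermediate matrices for one (question, answer) pair."""

    Qprime: np.ndarray  # l x n
    A: np.ndarray       # l x m
    Q: np.ndarray       # l x n
    L: np.ndarray       # m x n
    SQ: np.ndarray      # m x n
    SA: np.ndarray      # n x m
    CQ: np.ndarray      # l x n
    CA: np.ndarray      # 2l x m
    q_mask: np.ndarray  # length n, binary
    a_mask: np.ndarray  # length m, binary


# ---------------------------------------------------------------------------
# single-pair numpy operations (public surface; also oracle targets)
# ---------------------------------------------------------------------------

def project_question(Qprime: np.ndarray, Wq: np.ndarray, bq: np.ndarray) -> np.ndarray:
    """Q = tanh(W_Q Q' + b_Q); the bias broadcasts over columns."""
    return np.tanh(Wq @ Qprime + np.asarray(bq).reshape(-1, 1))


def affinity(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """L = A^T Q, one score per (answer word, question word) pair."""
    A = np.asarray(A, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if A.shape[0] != Q.shape[0]:
        raise ValueError(f"state-size mismatch: A has l={A.shape[0]}, Q has l={Q.shape[0]}")
    return A.T @ Q


def _masked_softmax_np(x: np.ndarray, mask: np.ndarray, axis: int) -> np.ndarray:
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), x.shape)
    if not np.all(mask.any(axis=axis)):
        raise ValueError("attention normalisation over a fully masked axis")
    m = np.where(mask, x, -np.inf).max(axis=axis, keepdims=True)
    e = np.where(mask, np.exp(np.where(mask, x - m, 0.0)), 0.0)
    return e / e.sum(axis=axis, keepdims=True)


def attention_scores(
    L: np.ndarray,
    q_mask: np.ndarray | None = None,
    a_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention score matrices (S_Q, S_A) from the affinity matrix.

    S_Q (m x n) normalises each question-word column over answer
    positions; S_A (n x m) normalises each answer-word column over
    question positions.  PAD positions get exactly zero weight and are
    excluded from the normalisers.
    """
    L = np.asarray(L, dtype=np.float64)
    m, n = L.shape
    a_mask = np.ones(m) if a_mask is None else np.asarray(a_mask, dtype=np.float64)
    q_mask = np.ones(n) if q_mask is None else np.asarray(q_mask, dtype=np.float64)
    SQ = _masked_softmax_np(L, a_mask[:, None], axis=0) * q_mask[None, :]
    SA = _masked_softmax_np(L.T, q_mask[:, None], axis=0) * a_mask[None, :]
    return SQ, SA


def coattention_context(
    Q: np.ndarray, A: np.ndarray, SQ: np.ndarray, SA: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """C_Q = A S_Q (l x n) and C_A = [Q; C_Q] S_A (2l x m)."""
    Q, A = np.asarray(Q, np.float64), np.asarray(A, np.float64)
    l = Q.shape[0]
    if A.shape[0] != l:
        raise ValueError("Q and A disagree on the state size")
    if SQ.shape != (A.shape[1], Q.shape[1]) or SA.shape != (Q.shape[1], A.shape[1]):
        raise ValueError("attention matrices have inconsistent shapes")
    CQ = A @ SQ
    CA = np.vstack([Q, CQ]) @ SA
    return CQ, CA


def classify(h: np.ndarray, Wo: np.ndarray, bo: np.ndarray) -> tuple[float, float]:
    """Softmax head: probabilities (p0, p1); p1 is acceptance probability."""
    z = np.asarray(h, np.float64) @ Wo + bo
    z = z - z.max()
    e = np.exp(z)
    p = e / e.sum()
    return float(p[0]), float(p[1])


def cross_entropy_loss(
    p1: np.ndarray, labels: np.ndarray, reduction: str = "sum"
) -> float:
    """Binary cross-entropy over acceptance probabilities.

    L = -sum_i [y_i log p1_i + (1 - y_i) log(1 - p1_i)], optionally
    averaged.  Probabilities exactly 0/1 facing the opposite label are
    clamped at 1e-12 with a warning.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    eps = 1e-12
    if np.any((p1 <= 0) & (labels == 1)) or np.any((p1 >= 1) & (labels == 0)):
        warnings.warn("probability saturated against its label; clamping at 1e-12")
    ll = labels * np.log(np.maximum(p1, eps)) + (1.0 - labels) * np.log(
        np.maximum(1.0 - p1, eps)
    )
    total = -float(ll.sum())
    return total / len(p1) if reduction == "mean" else total


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def _lstm_params(rng: np.random.Generator, in_dim: int, l: int) -> tuple[np.ndarray, np.ndarray]:
    W = _xavier(rng, in_dim + l, 4 * l)
    b = np.zeros(4 * l)
    b[l : 2 * l] = 1.0  # forget-gate bias, the usual stabiliser
    return W, b


class EncoderModel:
    """Parameter container for the sentence encoder.

    Parameters are :class:`~ohc_accept.autodiff.Tensor` leaves; the
    embedding matrix is a frozen constant unless
    ``config.fine_tune_embeddings`` is set.
    """

    def __init__(self, config: EncoderConfig, embedding_matrix: np.ndarray):
        self.config = config
        l, d = config.state_size, config.embedding_dim
        if embedding_matrix.shape[1] != d:
            raise ValueError(
                f"embedding matrix dim {embedding_matrix.shape[1]} != config dim {d}"
            )
        rng = np.random.default_rng(config.seed)
        dt = config.dtype
        self.embeddings = Tensor(
            np.asarray(embedding_matrix, dtype=dt).copy(),
            requires_grad=config.fine_tune_embeddings,
        )
        p: dict[str, Tensor] = {}
        Wq_lstm, bq_lstm = _lstm_params(rng, d, l)
        p["lstm_q.W"], p["lstm_q.b"] = ad.parameter(Wq_lstm, dt), ad.parameter(bq_lstm, dt)
        if config.share_qa_lstm:
            p["lstm_a.W"], p["lstm_a.b"] = p["lstm_q.W"], p["lstm_q.b"]
        else:
            Wa_lstm, ba_lstm = _lstm_params(rng, d, l)
            p["lstm_a.W"], p["lstm_a.b"] = ad.parameter(Wa_lstm, dt), ad.parameter(ba_lstm, dt)
        p["proj.W"] = ad.parameter(_xavier(rng, l, l), dt)
        p["proj.b"] = ad.parameter(np.zeros(l), dt)
        if config.context_fn == "lstm":
            Wc, bc = _lstm_params(rng, 2 * l, l)
            p["ctx.W"], p["ctx.b"] = ad.parameter(Wc, dt), ad.parameter(bc, dt)
        else:
            H = config.mlp_hidden
            p["mlp.W1"] = ad.parameter(_xavier(rng, 2 * l, H), dt)
            p["mlp.b1"] = ad.parameter(np.zeros(H), dt)
            p["mlp.W2"] = ad.parameter(_xavier(rng, H, 1), dt)
            p["mlp.b2"] = ad.parameter(np.zeros(1), dt)
        p["head.W"] = ad.parameter(_xavier(rng, config.feature_length, 2), dt)
        p["head.b"] = ad.parameter(np.zeros(2), dt)
        self.params = p

    def trainable(self) -> list[tuple[str, Tensor]]:
        seen: set[int] = set()
        out = []
        if self.config.fine_tune_embeddings:
            out.append(("embeddings", self.embeddings))
        for k, v in self.params.items():
            if id(v) not in seen:
                seen.add(id(v))
                out.append((k, v))
        return out

    # -- forward --------------------------------------------------------

    def _lstm(
        self,
        X: Tensor,
        mask: np.ndarray,
        W: Tensor,
        b: Tensor,
    ) -> tuple[Tensor, Tensor]:
        """Run an LSTM over X (B x T x in); PAD steps keep the carried state.

        Returns (H: B x T x l, h_last: B x l); because PAD steps carry the
        state through, H[:, -1] is the state at the last unmasked step.
        """
        T = X.shape[1]
        H = ad.lstm_sequence(X, mask, W, b, self.config.state_size)
        return H, H[:, T - 1, :]

    def forward(
        self,
        q_idx: np.ndarray,
        a_idx: np.ndarray,
        q_mask: np.ndarray,
        a_mask: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
        return_intermediates: bool = False,
    ):
        """Batched forward pass to classification logits.

        q_idx/a_idx are B x n / B x m integer index arrays (already
        truncated); masks are float arrays of the same shapes.  With
        ``train`` dropout is applied on the context representation h.
        """
        cfg = self.config
        if not np.all(q_mask.any(axis=1)) or not np.all(a_mask.any(axis=1)):
            raise ValueError("a sequence in the batch is entirely PAD")
        q_mask = np.asarray(q_mask, dtype=cfg.dtype)
        a_mask = np.asarray(a_mask, dtype=cfg.dtype)
        Xq = self.embeddings[q_idx]  # B x n x d
        Xa = self.embeddings[a_idx]
        Hq, _ = self._lstm(Xq, q_mask, self.params["lstm_q.W"], self.params["lstm_q.b"])
        Ha, _ = self._lstm(Xa, a_mask, self.params["lstm_a.W"], self.params["lstm_a.b"])
        # Q = tanh(W_Q Q' + b): applied per column, i.e. per word state
        Q_bnl = (Hq @ self.params["proj.W"].transpose() + self.params["proj.b"]).tanh()
        Q = Q_bnl.transpose(0, 2, 1)          # B x l x n
        A = Ha.transpose(0, 2, 1)             # B x l x m
        L = Ha @ Q                            # B x m x n  (= A^T Q per pair)
        SQ = ad.masked_softmax(L, a_mask[:, :, None], axis=1) * q_mask[:, None, :]
        SA = ad.masked_softmax(L.transpose(0, 2, 1), q_mask[:, :, None], axis=1) * a_mask[:, None, :]
        CQ = A @ SQ                           # B x l x n
        CA = ad.concat([Q, CQ], axis=1) @ SA  # B x 2l x m
        if cfg.context_fn == "lstm":
            cols = CA.transpose(0, 2, 1)      # B x m x 2l
            _, h_feat = self._lstm(cols, a_mask, self.params["ctx.W"], self.params["ctx.b"])
        else:
            cols = CA.transpose(0, 2, 1)
            hid = (cols @ self.params["mlp.W1"] + self.params["mlp.b1"]).tanh()
            s = hid @ self.params["mlp.W2"] + self.params["mlp.b2"]  # B x m x 1
            s = s.reshape(s.shape[0], s.shape[1]) * a_mask
            h_feat = s.pad_axis(1, cfg.max_answer_len)
        if train and cfg.dropout_rate > 0:
            if dropout_rng is None:
                raise ValueError("training forward pass needs a dropout rng")
            h_feat = h_feat * ad.dropout_mask(
                dropout_rng, h_feat.shape, cfg.dropout_rate, dtype=cfg.dtype
            )
        logits = h_feat @ self.params["head.W"] + self.params["head.b"]
        if return_intermediates:
            inter = {
                "Qprime": Hq, "A_states": Ha, "Q": Q, "L": L,
                "SQ": SQ, "SA": SA, "CQ": CQ, "CA": CA, "h": h_feat,
            }
            return logits, inter
        return logits

    def encode_sequences(
        self, q_idx: Sequence[int], a_idx: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """LSTM state matrices (Q' l x n, A l x m) for one unpadded pair."""
        pair = self.encode_pair(q_idx, a_idx)
        return pair.Qprime, pair.A

    def encode_pair(
        self, q_idx: Sequence[int], a_idx: Sequence[int]
    ) -> EncodedPair:
        """All intermediate matrices for a single unpadded pair (no grad)."""
        q = np.asarray(q_idx, dtype=np.int64)[None, :]
        a = np.asarray(a_idx, dtype=np.int64)[None, :]
        if q.shape[1] == 0 or a.shape[1] == 0:
            raise ValueError("cannot encode an empty token sequence")
        qm = np.ones_like(q, dtype=np.float64)
        am = np.ones_like(a, dtype=np.float64)
        with ad.no_grad():
            _, inter = self.forward(q, a, qm, am, return_intermediates=True)
        return EncodedPair(
            Qprime=inter["Qprime"].data[0].T,
            A=inter["A_states"].data[0].T,
            Q=inter["Q"].data[0],
            L=inter["L"].data[0],
            SQ=inter["SQ"].data[0],
            SA=inter["SA"].data[0],  # n x m
            CQ=inter["CQ"].data[0],
            CA=inter["CA"].data[0],
            q_mask=qm[0],
            a_mask=am[0],
        )

    # -- persistence ----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"embeddings": self.embeddings.data}
        for k, v in self.params.items():
            out[k] = v.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        dt = self.config.dtype
        self.embeddings.data = np.asarray(arrays["embeddings"], dtype=dt)
        for k, v in self.params.items():
            v.data = np.asarray(arrays[k], dtype=dt)


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: list[tuple[str, Tensor]], lr: float, clip_norm: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.clip_norm = clip_norm
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params}
        self.v = {k: np.zeros_like(p.data) for k, p in params}

    def step(self) -> float:
        """Clip gradients to the configured global norm, then update.

        Returns the pre-clip global gradient norm.
        """
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params}
        gnorm = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
        scale = 1.0
        if self.clip_norm > 0 and gnorm > self.clip_norm:
            scale = self.clip_norm / (gnorm + 1e-12)
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params:
            g = grads[k] * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return gnorm
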