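"""Training and inference for the co-attention sentence encoder.

:class:`CoAttentionEncoder` is a scikit-learn-style estimator: ``fit``
trains the encoder end-to-end for acceptance classification on an
internal seeded 80/20 split (the held-out 20% monitors generalisation
and drives early stopping), ``transform`` extracts the textual feature
vector h for each pair with dropout off, and ``predict_proba`` exposes
the encoder's own softmax head.

Token sequences are padded/truncated to fixed lengths N (question) and
M (answer) with binary masks; truncation keeps the head of the sequence
and is counted.  A pair whose question or answer is empty after
preprocessing is flagged; at transform time it is represented by a
single UNK token so output stays aligned 1:1 with input records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from .coattention import Adam, EncoderConfig, EncoderModel
from .corpus import Corpus
from .embeddings import EmbeddingTable
from .preprocess import TokenSequence, Vocabulary, remove_stopwords, tokenize

__all__ = [
    "PairData",
    "TrainReport",
    "prepare_pairs",
    "CoAttentionEncoder",
    "train_encoder",
    "extract_textual_features",
    "export_attention",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)


@dataclass
class PairData:
    """Index-encoded, padded question/answer pairs with masks."""

    q_idx: np.ndarray   # n_pairs x N  int64
    a_idx: np.ndarray   # n_pairs x M  int64
    q_mask: np.ndarray  # n_pairs x N  float64
    a_mask: np.ndarray  # n_pairs x M  float64
    n_truncated_q: int = 0
    n_truncated_a: int = 0
    flagged: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return self.q_idx.shape[0]

    def subset(self, idx) -> "PairData":
        idx = np.asarray(idx)
        return PairData(
            q_idx=self.q_idx[idx], a_idx=self.a_idx[idx],
            q_mask=self.q_mask[idx], a_mask=self.a_mask[idx],
        )


@dataclass
class TrainReport:
    """Per-epoch losses and held-out performance of one training run."""

    train_losses: list[float]
    heldout_losses: list[float]
    heldout_accuracy: float
    heldout_majority_rate: float
    best_epoch: int
    seed: int
    n_train: int
    n_heldout: int

    def to_dict(self) -> dict:
        return asdict(self)


def _pad_encode(
    token_lists: Sequence[Sequence[str]],
    vocab: Vocabulary,
    max_len: int,
) -> tuple[np.ndarray, np.ndarray, int, list[int]]:
    n = len(token_lists)
    idx = np.full((n, max_len), vocab.pad_index, dtype=np.int64)
    mask = np.zeros((n, max_len), dtype=np.float64)
    truncated = 0
    flagged: list[int] = []
    for i, toks in enumerate(token_lists):
        enc = vocab.encode(list(toks))
        if not enc:
            flagged.append(i)
            enc = [vocab.unk_index]  # placeholder keeps alignment
        if len(enc) > max_len:
            truncated += 1
            enc = enc[:max_len]  # head truncation
        idx[i, : len(enc)] = enc
        mask[i, : len(enc)] = 1.0
    return idx, mask, truncated, flagged


def prepare_pairs(
    corpus: Corpus,
    vocab: Vocabulary,
    tokenizer=None,
    stopwords: set[str] | None = None,
    max_question_len: int = 64,
    max_answer_len: int = 64,
) -> tuple[PairData, np.ndarray, np.ndarray]:
    """Corpus -> (PairData, labels, question groups).

    Labels are -1 where a record is unlabeled; groups carry question_id
    for leakage-free fold assignment downstream.
    """
    stopwords = stopwords or set()
    q_tokens, a_tokens, labels, groups = [], [], [], []
    for rec in corpus:
        qt = remove_stopwords(tokenize(rec.question_text, tokenizer, "question"), stopwords)
        at = remove_stopwords(tokenize(rec.answer_text, tokenizer, "answer"), stopwords)
        q_tokens.append(qt.tokens)
        a_tokens.append(at.tokens)
        labels.append(rec.label if rec.label is not None else -1)
        groups.append(rec.question_id)
    q_idx, q_mask, trunc_q, flag_q = _pad_encode(q_tokens, vocab, max_question_len)
    a_idx, a_mask, trunc_a, flag_a = _pad_encode(a_tokens, vocab, max_answer_len)
    if trunc_q or trunc_a:
        logger.info("truncated %d questions and %d answers", trunc_q, trunc_a)
    flagged = sorted(set(flag_q) | set(flag_a))
    if flagged:
        logger.warning("%d records empty after preprocessing; flagged", len(flagged))
    data = PairData(
        q_idx=q_idx, a_idx=a_idx, q_mask=q_mask, a_mask=a_mask,
        n_truncated_q=trunc_q, n_truncated_a=trunc_a, flagged=flagged,
    )
    return data, np.asarray(labels, dtype=np.int64), np.asarray(groups, dtype=object)


def _batch_slices(data: PairData, idx: np.ndarray):
    """Trim a batch to its own max sequence lengths (saves LSTM steps)."""
    qs = data.q_mask[idx]
    as_ = data.a_mask[idx]
    n = max(int(qs.sum(axis=1).max()), 1)
    m = max(int(as_.sum(axis=1).max()), 1)
    return (
        data.q_idx[idx][:, :n], data.a_idx[idx][:, :m],
        qs[:, :n], as_[:, :m],
    )


class CoAttentionEncoder(BaseEstimator, TransformerMixin):
    """Co-attention sentence encoder as a scikit-learn estimator.

    ``fit(X, y)`` takes a :class:`PairData` and binary labels and trains
    the encoder by minimising cross-entropy with Adam, dropout on the
    context representation and global-norm gradient clipping.  An 80/20
    stratified split made inside ``fit`` (seeded) separates training
    data from the held-out monitor set; early stopping restores the
    parameters of the best held-out epoch.

    Constructor parameters mirror :class:`EncoderConfig`; ``embeddings``
    is the pre-trained table (an :class:`EmbeddingTable` or raw matrix),
    frozen during training unless ``fine_tune_embeddings``.
    """

    def __init__(
        self,
        embeddings: EmbeddingTable | np.ndarray | None = None,
        state_size: int = 100,
        embedding_dim: int = 100,
        context_fn: str = "lstm",
        share_qa_lstm: bool = False,
        max_question_len: int = 64,
        max_answer_len: int = 64,
        dropout_rate: float = 0.5,
        clip_norm: float = 5.0,
        learning_rate: float = 0.001,
        batch_size: int = 100,
        epochs: int = 20,
        patience: int = 3,
        mlp_hidden: int = 100,
        fine_tune_embeddings: bool = False,
        heldout_fraction: float = 0.2,
        precision: str = "single",
        seed: int = 0,
    ):
        self.embeddings = embeddings
        self.state_size = state_size
        self.embedding_dim = embedding_dim
        self.context_fn = context_fn
        self.share_qa_lstm = share_qa_lstm
        self.max_question_len = max_question_len
        self.max_answer_len = max_answer_len
        self.dropout_rate = dropout_rate
        self.clip_norm = clip_norm
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.mlp_hidden = mlp_hidden
        self.fine_tune_embeddings = fine_tune_embeddings
        self.heldout_fraction = heldout_fraction
        self.precision = precision
        self.seed = seed

    # -- config plumbing -------------------------------------------------

    def _config(self) -> EncoderConfig:
        return EncoderConfig(
            state_size=self.state_size,
            embedding_dim=self.embedding_dim,
            context_fn=self.context_fn,
            share_qa_lstm=self.share_qa_lstm,
            max_question_len=self.max_question_len,
            max_answer_len=self.max_answer_len,
            dropout_rate=self.dropout_rate,
            clip_norm=self.clip_norm,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            patience=self.patience,
            mlp_hidden=self.mlp_hidden,
            fine_tune_embeddings=self.fine_tune_embeddings,
            heldout_fraction=self.heldout_fraction,
            precision=self.precision,
            seed=self.seed,
        )

    def _embedding_matrix(self) -> np.ndarray:
        if self.embeddings is None:
            raise ValueError("CoAttentionEncoder needs an embedding table")
        if isinstance(self.embeddings, EmbeddingTable):
            return self.embeddings.vectors
        return np.asarray(self.embeddings, dtype=np.float64)

    # -- training --------------------------------------------------------

    def fit(self, X: PairData, y) -> "CoAttentionEncoder":
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("PairData and labels are misaligned")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training requires both classes to be present")
        cfg = self._config()
        rng = np.random.default_rng(cfg.seed)
        model = EncoderModel(cfg, self._embedding_matrix())

        # stratified 80/20 split for encoder training vs held-out monitoring
        heldout: list[int] = []
        for c in classes:
            members = np.flatnonzero(y == c)
            members = members[rng.permutation(members.size)]
            k = max(1, int(round(cfg.heldout_fraction * members.size)))
            heldout.extend(members[:k].tolist())
        heldout_idx = np.sort(np.asarray(heldout, dtype=np.int64))
        train_idx = np.setdiff1d(np.arange(len(y)), heldout_idx)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("training split degenerated to a single class")

        opt = Adam(model.trainable(), lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
        train_losses: list[float] = []
        heldout_losses: list[float] = []
        best = (np.inf, -1, None)  # (heldout loss, epoch, snapshot)
        for epoch in range(cfg.epochs):
            order = train_idx[rng.permutation(train_idx.size)]
            running = 0.0
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                qi, ai, qm, am = _batch_slices(X, batch)
                logits = model.forward(qi, ai, qm, am, train=True, dropout_rng=rng)
                loss, _ = ad.softmax_cross_entropy(logits, y[batch], reduction="mean")
                running += float(loss.data) * batch.size
                for _, p in model.trainable():
                    p.zero_grad()
                loss.backward()
                opt.step()
            tr_loss = running / order.size
            ho_loss, ho_acc = self._evaluate(model, X, y, heldout_idx)
            train_losses.append(tr_loss)
            heldout_losses.append(ho_loss)
            logger.info(
                "epoch %d: train loss %.4f, held-out loss %.4f acc %.3f",
                epoch + 1, tr_loss, ho_loss, ho_acc,
            )
            if ho_loss < best[0]:
                best = (ho_loss, epoch, {k: v.copy() for k, v in model.state_arrays().items()})
            elif epoch - best[1] >= cfg.patience:
                logger.info("early stopping at epoch %d", epoch + 1)
                break
        if best[2] is not None:
            model.load_state_arrays(best[2])
        _, ho_acc = self._evaluate(model, X, y, heldout_idx)
        majority = float(np.mean(y[heldout_idx] == np.bincount(y[train_idx]).argmax()))

        self.model_ = model
        self.classes_ = classes
        self.train_indices_ = train_idx
        self.heldout_indices_ = heldout_idx
        self.train_report_ = TrainReport(
            train_losses=train_losses,
            heldout_losses=heldout_losses,
            heldout_accuracy=float(ho_acc),
            heldout_majority_rate=majority,
            best_epoch=best[1],
            seed=cfg.seed,
            n_train=int(train_idx.size),
            n_heldout=int(heldout_idx.size),
        )
        return self

    def _evaluate(
        self, model: EncoderModel, X: PairData, y: np.ndarray, idx: np.ndarray
    ) -> tuple[float, float]:
        """Mean cross-entropy and accuracy on a subset, dropout off."""
        total, correct = 0.0, 0
        bs = self._config().batch_size
        with ad.no_grad():
            for start in range(0, idx.size, bs):
                batch = idx[start : start + bs]
                qi, ai, qm, am = _batch_slices(X, batch)
                logits = model.forward(qi, ai, qm, am, train=False)
                loss, p = ad.softmax_cross_entropy(logits, y[batch], reduction="sum")
                total += float(loss.data)
                correct += int(np.sum(p.argmax(axis=1) == y[batch]))
        n = max(int(idx.size), 1)
        return total / n, correct / n

    # -- inference -------------------------------------------------------

    def _forward_features(self, X: PairData, want: str) -> np.ndarray:
        check_is_fitted(self, "model_")
        out = []
        bs = self._config().batch_size
        with ad.no_grad():
            for start in range(0, len(X), bs):
                idx = np.arange(start, min(start + bs, len(X)))
                qi, ai, qm, am = _batch_slices(X, idx)
                logits, inter = self.model_.forward(
                    qi, ai, qm, am, train=False, return_intermediates=True
                )
                if want == "h":
                    h = inter["h"].data
                    if self.context_fn == "mlp" and h.shape[1] < self.max_answer_len:
                        h = np.pad(h, ((0, 0), (0, self.max_answer_len - h.shape[1])))
                    out.append(h)
                else:
                    z = logits.data - logits.data.max(axis=1, keepdims=True)
                    e = np.exp(z)
                    out.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(out) if out else np.empty((0, 0))

    def transform(self, X: PairData) -> np.ndarray:
        """Textual feature vectors h, one row per pair (deterministic)."""
        return self._forward_features(X, "h")

    def predict_proba(self, X: PairData) -> np.ndarray:
        return self._forward_features(X, "proba")

    def predict(self, X: PairData) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X: PairData, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_encoder(
    corpus: Corpus,
    vocab: Vocabulary,
    embeddings: EmbeddingTable,
    config: EncoderConfig | None = None,
    tokenizer=None,
    stopwords: set[str] | None = None,
) -> tuple[CoAttentionEncoder, TrainReport]:
    """Prepare pairs from a labeled corpus and fit the encoder."""
    cfg = config or EncoderConfig()
    data, y, _ = prepare_pairs(
        corpus, vocab, tokenizer, stopwords,
        cfg.max_question_len, cfg.max_answer_len,
    )
    est = CoAttentionEncoder(embeddings=embeddings, **cfg.to_dict())
    est.fit(data, y)
    return est, est.train_report_


def extract_textual_features(
    corpus: Corpus,
    encoder: CoAttentionEncoder,
    vocab: Vocabulary,
    tokenizer=None,
    stopwords: set[str] | None = None,
) -> np.ndarray:
    """h_text for every record, aligned 1:1 with the corpus order."""
    data, _, _ = prepare_pairs(
        corpus, vocab, tokenizer, stopwords,
        encoder.max_question_len, encoder.max_answer_len,
    )
    return encoder.transform(data)


def export_attention(
    question_text: str,
    answer_text: str,
    encoder: CoAttentionEncoder,
    vocab: Vocabulary,
    tokenizer=None,
    stopwords: set[str] | None = None,
    path: str | Path | None = None,
) -> dict:
    """Attention matrices with token labels for one pair, heatmap-ready.

    Labels are the post-preprocessing tokens (stop words removed,
    out-of-vocabulary tokens shown as UNK).  S_Q columns (per question
    word, over answer words) and S_A columns (per answer word, over
    question words) each sum to 1.
    """
    check_is_fitted(encoder, "model_")
    stopwords = stopwords or set()
    q_seq = remove_stopwords(tokenize(question_text, tokenizer, "question"), stopwords)
    a_seq = remove_stopwords(tokenize(answer_text, tokenizer, "answer"), stopwords)
    q_toks = q_seq.tokens[: encoder.max_question_len]
    a_toks = a_seq.tokens[: encoder.max_answer_len]
    if not q_toks or not a_toks:
        raise ValueError("cannot export attention for an empty sequence")
    pair = encoder.model_.encode_pair(vocab.encode(q_toks), vocab.encode(a_toks))
    report = {
        "question_tokens": vocab.visible_tokens(q_toks),
        "answer_tokens": vocab.visible_tokens(a_toks),
        "SQ": pair.SQ.tolist(),  # answer x question
        "SA": pair.SA.tolist(),  # question x answer
    }
    if path is not None:
        Path(path).write_text(
            json.dumps(report, ensure_ascii=False, indent=1), encoding="utf-8"
        )
    return report


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(
    encoder: CoAttentionEncoder, path: str | Path, vocab: Vocabulary | None = None
) -> None:
    """Serialise a fitted encoder (config + parameters, optional vocab)."""
    check_is_fitted(encoder, "model_")
    arrays = encoder.model_.state_arrays()
    arrays["__config__"] = np.array(json.dumps(encoder.model_.config.to_dict()))
    if hasattr(encoder, "heldout_indices_"):
        arrays["__heldout_idx__"] = encoder.heldout_indices_
        arrays["__train_idx__"] = encoder.train_indices_
    if vocab is not None:
        arrays["__vocab__"] = np.array(vocab.index_to_token(), dtype=object)
        arrays["__min_count__"] = np.array(vocab.min_count)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> tuple[CoAttentionEncoder, Vocabulary | None]:
    """Restore a fitted encoder (and its vocabulary, if embedded)."""
    with np.load(path, allow_pickle=True) as npz:
        arrays = {k: npz[k] for k in npz.files}
    cfg = EncoderConfig(**json.loads(str(arrays.pop("__config__"))))
    vocab = None
    if "__vocab__" in arrays:
        tokens = [str(t) for t in arrays.pop("__vocab__")]
        vocab = Vocabulary(
            token_to_index={t: i for i, t in enumerate(tokens)},
            min_count=int(arrays.pop("__min_count__")),
        )
    heldout = arrays.pop("__heldout_idx__", None)
    train_ix = arrays.pop("__train_idx__", None)
    emb = arrays["embeddings"]
    est = CoAttentionEncoder(embeddings=emb, **cfg.to_dict())
    model = EncoderModel(cfg, emb)
    model.load_state_arrays(arrays)
    est.model_ = model
    est.classes_ = np.array([0, 1])
    if heldout is not None:
        est.heldout_indices_ = np.asarray(heldout, dtype=np.int64)
        est.train_indices_ = np.asarray(train_ix, dtype=np.int64)
    return est, vocab
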