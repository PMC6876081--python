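"""Word-embedding provisioning for the sentence encoder.

Three modes are supported: training skip-gram word2vec on a token corpus,
loading pre-trained vectors from the word2vec text format, and seeded
random initialisation for tests.  In all modes the table has one row per
vocabulary index and the PAD row is held at zero.

The skip-gram trainer is a compact negative-sampling implementation
(window 5, 5 negatives, unigram^0.75 noise distribution) sufficient for
the corpus sizes this package trains on; it is not tuned for web-scale
corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .preprocess import TokenSequence, Vocabulary

__all__ = ["EmbeddingTable", "get_embeddings", "load_word2vec_text", "save_word2vec_text"]


@dataclass
class EmbeddingTable:
    """A V x d real matrix aligned with a :class:`Vocabulary`."""

    vectors: np.ndarray
    vocab: Vocabulary

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.vocab):
            raise ValueError(
                f"vectors have {self.vectors.shape[0]} rows for a vocabulary "
                f"of size {len(self.vocab)}"
            )
        self.vectors[self.vocab.pad_index, :] = 0.0

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def lookup(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab.lookup(token)]


def _seeded_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    # U(-0.5, 0.5): unit-ish vector norms, usable directly as frozen features
    return rng.uniform(-0.5, 0.5, size=shape)


def _sgns_init(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    # the usual +-0.5/d starting point for skip-gram training
    return rng.uniform(-0.5, 0.5, size=shape) / shape[1]


def get_embeddings(
    vocab: Vocabulary,
    mode: str = "random_init",
    dim: int = 100,
    seed: int = 0,
    corpus_tokens: Iterable[TokenSequence | Sequence[str]] | None = None,
    pretrained_path: str | Path | None = None,
    epochs: int = 3,
    window: int = 5,
    negatives: int = 5,
    lr: float = 0.025,
) -> EmbeddingTable:
    """Provision an embedding table for ``vocab``.

    mode="train_word2vec" trains skip-gram with negative sampling on
    ``corpus_tokens``; mode="load_pretrained" reads a word2vec-text file
    (missing tokens fall back to seeded random rows); mode="random_init"
    draws every row from a seeded uniform distribution.
    """
    rng = np.random.default_rng(seed)
    V = len(vocab)
    if mode == "random_init":
        vectors = _seeded_uniform(rng, (V, dim))
    elif mode == "load_pretrained":
        if pretrained_path is None:
            raise ValueError("load_pretrained requires pretrained_path")
        loaded = load_word2vec_text(pretrained_path)
        file_dim = next(iter(loaded.values())).shape[0] if loaded else dim
        if file_dim != dim:
            raise ValueError(
                f"pretrained file dimension {file_dim} != requested dim {dim}"
            )
        vectors = _seeded_uniform(rng, (V, dim))
        for token, idx in vocab.token_to_index.items():
            if token in loaded:
                vectors[idx] = loaded[token]
    elif mode == "train_word2vec":
        if corpus_tokens is None:
            raise ValueError("train_word2vec requires corpus_tokens")
        vectors = _train_sgns(
            vocab, corpus_tokens, dim, rng,
            epochs=epochs, window=window, negatives=negatives, lr=lr,
        )
    else:
        raise ValueError(f"unknown embedding mode {mode!r}")
    return EmbeddingTable(vectors=np.ascontiguousarray(vectors, dtype=np.float64), vocab=vocab)


def _train_sgns(
    vocab: Vocabulary,
    corpus_tokens: Iterable[TokenSequence | Sequence[str]],
    dim: int,
    rng: np.random.Generator,
    epochs: int,
    window: int,
    negatives: int,
    lr: float,
) -> np.ndarray:
    """Skip-gram with negative sampling; returns the input-vector matrix."""
    V = len(vocab)
    sents: list[np.ndarray] = []
    counts = np.zeros(V, dtype=np.float64)
    for seq in corpus_tokens:
        toks = seq.tokens if isinstance(seq, TokenSequence) else list(seq)
        idx = np.asarray(vocab.encode(toks), dtype=np.int64)
        idx = idx[idx != vocab.pad_index]
        if idx.size >= 2:
            sents.append(idx)
            np.add.at(counts, idx, 1.0)
    W_in = _sgns_init(rng, (V, dim))
    W_out = np.zeros((V, dim))
    if not sents:
        return W_in
    noise = counts**0.75
    noise[vocab.pad_index] = 0.0
    if noise.sum() == 0:
        noise[:] = 1.0
        noise[vocab.pad_index] = 0.0
    noise_cdf = np.cumsum(noise / noise.sum())
    for epoch in range(epochs):
        step_lr = lr * (1.0 - epoch / max(epochs, 1)) + 1e-4
        order = rng.permutation(len(sents))
        for si in order:
            sent = sents[si]
            n = len(sent)
            # skip-gram pairs with per-position random window shrinkage
            wins = rng.integers(1, window + 1, size=n)
            centers, contexts = [], []
            for i in range(n):
                lo, hi = max(0, i - int(wins[i])), min(n, i + int(wins[i]) + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(sent[i])
                        contexts.append(sent[j])
            if not centers:
                continue
            centers = np.asarray(centers)
            P = len(centers)
            targets = np.empty((P, negatives + 1), dtype=np.int64)
            targets[:, 0] = contexts
            targets[:, 1:] = np.searchsorted(
                noise_cdf, rng.random((P, negatives))
            )
            labels = np.zeros((P, negatives + 1))
            labels[:, 0] = 1.0
            # one mini-batched SGD step per sentence (stale within the batch)
            v = W_in[centers]                       # P x d
            u = W_out[targets]                      # P x k+1 x d
            scores = expit(np.einsum("pd,pkd->pk", v, u))
            g = (labels - scores) * step_lr
            np.add.at(W_in, centers, np.einsum("pk,pkd->pd", g, u))
            np.add.at(W_out, targets, g[:, :, None] * v[:, None, :])
    return W_in


def load_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Read the word2vec text format: header "V d", then "token v1 .. vd"."""
    path = Path(path)
    out: dict[str, np.ndarray] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: bad word2vec header {header!r}")
        _, d = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < d + 1:
                continue
            token = parts[0]
            vec = np.asarray(parts[1 : d + 1], dtype=np.float64)
            out[token] = vec
    return out


def save_word2vec_text(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table in the word2vec text format."""
    inv = table.vocab.index_to_token()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(inv)} {table.dim}\n")
        for i, token in enumerate(inv):
            vals = " ".join(f"{x:.6g}" for x in table.vectors[i])
            fh.write(f"{token} {vals}\n")
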