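"""Tokenization, stop-word removal, and the frequency-thresholded vocabulary.

Tokenization is a pluggable strategy.  The default splits on whitespace,
which suits the synthetic corpora and any pre-segmented text.  For Chinese
clinical text a dictionary-driven forward-maximum-matching segmenter is
provided; it accepts user dictionaries (e.g. medical thesauri) so that
multi-character disease and drug names are kept as single tokens.

The vocabulary keeps only tokens whose corpus frequency reaches
``min_count`` (default 30); everything rarer, and anything never seen,
maps to the UNK index.  A PAD index is reserved for batching; its
embedding row is zero and it is masked out of attention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "TokenSequence",
    "WhitespaceTokenizer",
    "MaxMatchTokenizer",
    "load_stopwords",
    "load_user_dict",
    "remove_stopwords",
    "Vocabulary",
    "build_vocab",
]

PAD_TOKEN = "PAD"
UNK_TOKEN = "UNK"

Tokenizer = Callable[[str], list[str]]


@dataclass
class TokenSequence:
    """An ordered token list from one question or answer."""

    tokens: list[str]
    source: str = "question"  # "question" | "answer"

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def is_empty(self) -> bool:
        return len(self.tokens) == 0


class WhitespaceTokenizer:
    """Split on Unicode whitespace. The default segmenter."""

    def __call__(self, text: str) -> list[str]:
        return text.split()


class MaxMatchTokenizer:
    """Greedy forward maximum-matching segmenter over a word dictionary.

    Intended for unsegmented (e.g. Chinese) text: at each position the
    longest dictionary word is consumed; characters not starting any
    dictionary word become single-character tokens.  User dictionaries
    (one word per line) extend the base lexicon so domain terms survive
    as units.
    """

    def __init__(self, words: Iterable[str] = (), user_dicts: Iterable[Iterable[str]] = ()):
        self.lexicon: set[str] = {w for w in words if w}
        for d in user_dicts:
            self.lexicon.update(w for w in d if w)
        self.max_len = max((len(w) for w in self.lexicon), default=1)

    def add_words(self, words: Iterable[str]) -> None:
        for w in words:
            if w:
                self.lexicon.add(w)
                self.max_len = max(self.max_len, len(w))

    def __call__(self, text: str) -> list[str]:
        tokens: list[str] = []
        i, n = 0, len(text)
        while i < n:
            if text[i].isspace():
                i += 1
                continue
            match = text[i]
            for j in range(min(n, i + self.max_len), i + 1, -1):
                if text[i:j] in self.lexicon:
                    match = text[i:j]
                    break
            tokens.append(match)
            i += len(match)
        return tokens


def load_stopwords(path: str | Path) -> set[str]:
    """Load a stop-word list: plain text, one token per line."""
    out: set[str] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            w = line.strip()
            if w:
                out.add(w)
    return out


def load_user_dict(path: str | Path) -> list[str]:
    """Load a user dictionary: plain text, one word per line."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return [w.strip() for w in fh if w.strip()]


def tokenize(
    text: str,
    tokenizer: Tokenizer | None = None,
    source: str = "question",
) -> TokenSequence:
    """Tokenize ``text`` with the given strategy (default whitespace)."""
    tok = tokenizer if tokenizer is not None else WhitespaceTokenizer()
    return TokenSequence(tokens=tok(text), source=source)


def remove_stopwords(seq: TokenSequence, stopwords: set[str]) -> TokenSequence:
    """Order-preserving removal of exact stop-word matches. Idempotent."""
    return TokenSequence(
        tokens=[t for t in seq.tokens if t not in stopwords],
        source=seq.source,
    )


@dataclass
class Vocabulary:
    """Token-to-index map with dense indices and a total UNK fallback.

    Index 0 is PAD, index 1 is UNK; retained corpus tokens follow.  Every
    retained token had corpus frequency >= ``min_count`` ("below 30" is
    replaced, so a count of exactly 30 is kept).
    """

    token_to_index: dict[str, int] = field(default_factory=dict)
    min_count: int = 30
    unk_token: str = UNK_TOKEN
    pad_token: str = PAD_TOKEN

    def __post_init__(self) -> None:
        if not self.token_to_index:
            self.token_to_index = {self.pad_token: 0, self.unk_token: 1}

    @property
    def pad_index(self) -> int:
        return self.token_to_index[self.pad_token]

    @property
    def unk_index(self) -> int:
        return self.token_to_index[self.unk_token]

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def lookup(self, token: str) -> int:
        """Total: never-seen tokens map to the UNK index."""
        return self.token_to_index.get(token, self.unk_index)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        get = self.token_to_index.get
        unk = self.unk_index
        return [get(t, unk) for t in tokens]

    def decode(self, indices: Sequence[int]) -> list[str]:
        inv = self.index_to_token()
        return [inv[i] for i in indices]

    def index_to_token(self) -> list[str]:
        inv = [""] * len(self.token_to_index)
        for t, i in self.token_to_index.items():
            inv[i] = t
        return inv

    def visible_tokens(self, tokens: Sequence[str]) -> list[str]:
        """Tokens as the model sees them: out-of-vocabulary becomes UNK."""
        return [t if t in self.token_to_index else self.unk_token for t in tokens]

    def save(self, path: str | Path) -> None:
        import json

        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(
                {"token_to_index": self.token_to_index, "min_count": self.min_count},
                fh, ensure_ascii=False,
            )

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        import json

        with Path(path).open("r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(token_to_index=d["token_to_index"], min_count=d["min_count"])


def build_vocab(
    corpus_tokens: Iterable[TokenSequence | Sequence[str]],
    min_count: int = 30,
) -> Vocabulary:
    """Build a vocabulary over the full corpus with a frequency threshold.

    Counting is commutative, so the result is invariant to record order;
    retained tokens are indexed in (count desc, token asc) order for
    determinism.  An empty corpus yields just {PAD, UNK}.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for seq in corpus_tokens:
        toks = seq.tokens if isinstance(seq, TokenSequence) else seq
        counts.update(toks)
    vocab = Vocabulary(min_count=min_count)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count and t not in vocab.token_to_index),
        key=lambda t: (-counts[t], t),
    )
    for t in kept:
        vocab.token_to_index[t] = len(vocab.token_to_index)
    return vocab
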