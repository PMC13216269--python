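"""Subword tokenization and token-to-word aggregation.

Reports are lowercased, stripped of punctuation, and each word is split
left-to-right into chunks of at most ``max_subword_len`` characters.  This
deterministic chunking stands in for a trained WordPiece/BPE vocabulary: it
preserves the one property the alignment method relies on — words spanning
several tokens whose contextual embeddings must be averaged back to word
level before local alignment.  A full-scale tokenizer can be substituted
behind the same :class:`TokenizedReport` interface.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Vocabulary", "TokenizedReport", "normalize_words",
           "tokenize_report", "aggregate_token_embeddings", "build_vocabulary"]

PAD, CLS, UNK = "[PAD]", "[CLS]", "[UNK]"

_WORD_RE = re.compile(r"[a-z0-9]+")


def normalize_words(report: str) -> list[str]:
    """Lowercase and keep alphanumeric runs as words (punctuation dropped)."""
    return _WORD_RE.findall(report.lower())


@dataclass
class Vocabulary:
    """Dense subword-to-id map with PAD=0, CLS=1, UNK=2.

    Carries the chunk length it was built with so every later
    tokenization uses the same subword scheme.
    """

    token_to_id: dict[str, int] = field(
        default_factory=lambda: {PAD: 0, CLS: 1, UNK: 2})
    max_subword_len: int = 6

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def add(self, subword: str) -> int:
        if subword not in self.token_to_id:
            self.token_to_id[subword] = len(self.token_to_id)
        return self.token_to_id[subword]

    def lookup(self, subword: str) -> int:
        return self.token_to_id.get(subword, self.unk_id)

    def to_json(self) -> str:
        return json.dumps({"token_to_id": self.token_to_id,
                           "max_subword_len": self.max_subword_len})

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        if "token_to_id" not in d:        # plain-map form
            return cls(d)
        return cls(d["token_to_id"], d.get("max_subword_len", 6))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text())


@dataclass
class TokenizedReport:
    """Subword token sequence with word-span bookkeeping.

    ``tokens[0]`` is always CLS; ``word_map[w] = (start, end)`` is the
    half-open token-index span of word ``w``.  Spans are contiguous,
    non-overlapping, exclude the CLS position, and cover 1..N-1.
    """

    tokens: list[str]
    token_ids: list[int]
    word_map: list[tuple[int, int]]
    words: list[str]

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_words(self) -> int:
        return len(self.words)


def _chunk(word: str, max_len: int) -> list[str]:
    return [word[i:i + max_len] for i in range(0, len(word), max_len)]


def tokenize_report(report: str, vocab: Vocabulary,
                    max_subword_len: int | None = None,
                    grow_vocab: bool = False) -> TokenizedReport:
    """Tokenize a report into CLS + subword chunks with word spans.

    Unknown subwords map to UNK unless ``grow_vocab`` is set (used when
    building the corpus vocabulary).
    """
    if max_subword_len is None:
        max_subword_len = vocab.max_subword_len
    if max_subword_len < 1:
        raise ValueError("max_subword_len must be >= 1")
    words = normalize_words(report)
    if not words:
        raise ValueError("report is empty after normalization")
    tokens = [CLS]
    ids = [vocab.cls_id]
    word_map: list[tuple[int, int]] = []
    for w in words:
        start = len(tokens)
        for sub in _chunk(w, max_subword_len):
            tokens.append(sub)
            ids.append(vocab.add(sub) if grow_vocab else vocab.lookup(sub))
        word_map.append((start, len(tokens)))
    return TokenizedReport(tokens=tokens, token_ids=ids,
                           word_map=word_map, words=words)


def build_vocabulary(reports: list[str], max_subword_len: int = 6) -> Vocabulary:
    vocab = Vocabulary(max_subword_len=max_subword_len)
    for r in reports:
        tokenize_report(r, vocab, max_subword_len, grow_vocab=True)
    return vocab


def aggregate_token_embeddings(token_embs, word_map: list[tuple[int, int]]):
    """Average token columns into word columns: (d, N) -> (d, W).

    Works on plain arrays and on autodiff tensors; each word vector is the
    arithmetic mean of its span's token vectors.
    """
    from .nn.autograd import Tensor, concatenate

    is_tensor = isinstance(token_embs, Tensor)
    N = token_embs.shape[-1]
    cols = []
    for start, end in word_map:
        if not (0 <= start < end <= N):
            raise ValueError(f"invalid span ({start}, {end}) for N={N}")
        span = token_embs[..., start:end]
        cols.append(span.mean(axis=-1, keepdims=True) if is_tensor
                    else np.asarray(span).mean(axis=-1, keepdims=True))
    if is_tensor:
        return concatenate(cols, axis=-1)
    return np.concatenate(cols, axis=-1)
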