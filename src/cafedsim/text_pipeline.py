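"""User-post corpora to fixed-size numeric classifier inputs.

A user record is a list of tokenized posts plus a binary depression label.
The pipeline removes stopwords, concatenates the posts into one token
sequence of fixed length L (right-padded / truncated), looks tokens up in a
word-embedding table (word2vec text format), and min-max normalizes dense
feature matrices to [0, 1].

Embedding fine-tuning modes follow the usual text-CNN variants:

* ``rand``     — embeddings randomly initialized, trainable;
* ``static``   — pre-trained embeddings, frozen (unknown tokens get a
  seeded random row, also frozen);
* ``nostatic`` — pre-trained embeddings, fine-tuned during training.

Corpora are pre-tokenized (JSONL with token lists); no segmenter is bundled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UserRecord",
    "EmbeddingTable",
    "SequenceEncoder",
    "EMBEDDING_MODES",
    "PAD_ID",
    "load_corpus_jsonl",
    "save_corpus_jsonl",
    "load_stopwords",
    "remove_stopwords",
    "concat_posts",
    "minmax_normalize",
    "load_word2vec",
    "save_word2vec",
    "make_embedding_layer",
    "bag_of_words",
]

EMBEDDING_MODES = ("rand", "static", "nostatic")

#: Reserved padding row (zero vector, never trained).
PAD_ID = 0


@dataclass
class UserRecord:
    user_id: str
    posts: list[list[str]]
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be binary, got {self.label!r}")

    def all_tokens(self) -> list[str]:
        return [tok for post in self.posts for tok in post]


@dataclass
class EmbeddingTable:
    """token -> row mapping over a |V| x d real matrix."""

    vocabulary: dict[str, int]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] <= 0:
            raise ValueError("embedding matrix must be |V| x d with d > 0")
        if len(self.vocabulary) != self.matrix.shape[0]:
            raise ValueError("vocabulary size does not match matrix rows")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])


# -- corpus I/O -----------------------------------------------------------

def load_corpus_jsonl(path) -> list[UserRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(UserRecord(obj["user_id"], obj["posts"], int(obj["label"])))
    return records


def save_corpus_jsonl(records: Iterable[UserRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {"user_id": rec.user_id, "posts": rec.posts, "label": rec.label},
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


def load_stopwords(path) -> set[str]:
    """One token per line, UTF-8; blank lines ignored.  An empty file is a no-op set."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


# -- preprocessing --------------------------------------------------------

def remove_stopwords(posts: Sequence[Sequence[str]], stopwords: set[str]) -> list[list[str]]:
    """Drop stopword tokens, preserving order; idempotent."""
    return [[tok for tok in post if tok not in stopwords] for post in posts]


@dataclass
class SequenceMatrix:
    token_ids: np.ndarray  # length exactly L, PAD_ID-padded
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in EMBEDDING_MODES:
            raise ValueError(f"mode must be one of {EMBEDDING_MODES}")


def concat_posts(tokens_or_record, L: int, pad_id: int = PAD_ID, *, encode=None) -> np.ndarray:
    """Concatenate a user's posts into one sequence of length exactly L.

    Posts are joined in stored (assumed chronological) order, truncated at L
    tokens or right-padded with ``pad_id``.  ``encode`` maps a token to an
    integer id; by default tokens must already be integers.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    posts = tokens_or_record.posts if isinstance(tokens_or_record, UserRecord) else tokens_or_record
    flat: list[int] = []
    for post in posts:
        for tok in post:
            flat.append(encode(tok) if encode is not None else int(tok))
            if len(flat) == L:
                break
        if len(flat) == L:
            break
    if not flat:
        logger.warning("record has zero tokens after preprocessing; emitting all-pad sequence")
    out = np.full(L, pad_id, dtype=np.int64)
    out[: len(flat)] = flat
    return out


@dataclass
class SequenceEncoder:
    """Token -> id mapping derived from an embedding table.

    Row 0 is the padding id; in-vocabulary tokens map to ``row + 1``.
    Tokens absent from the table are assigned fresh ids on first sight
    (their embedding rows are seeded random; see :func:`make_embedding_layer`).
    """

    table: EmbeddingTable
    unknown: dict[str, int] = field(default_factory=dict)

    def encode_token(self, token: str) -> int:
        row = self.table.vocabulary.get(token)
        if row is not None:
            return row + 1
        if token not in self.unknown:
            self.unknown[token] = 1 + len(self.table.vocabulary) + len(self.unknown)
        return self.unknown[token]

    @property
    def n_ids(self) -> int:
        return 1 + len(self.table.vocabulary) + len(self.unknown)

    def encode_record(self, record: UserRecord, L: int) -> np.ndarray:
        return concat_posts(record, L, PAD_ID, encode=self.encode_token)


# -- normalization --------------------------------------------------------

def minmax_normalize(features: np.ndarray, stats="fit"):
    """Per-column min-max scaling to [0, 1].

    ``stats="fit"`` computes (min, max) on the given (training) matrix and
    returns them alongside the scaled matrix; passing fitted stats applies
    them, clipping out-of-range values into [0, 1] (logged).  Constant
    columns map to 0.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    if isinstance(stats, str):
        if stats != "fit":
            raise ValueError("stats must be 'fit' or a (min, max) pair")
        lo, hi = X.min(axis=0), X.max(axis=0)
    else:
        lo, hi = (np.asarray(a, dtype=np.float64) for a in stats)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (X - lo) / safe
    out[:, span == 0] = 0.0
    n_clipped = int(np.sum((out < 0) | (out > 1)))
    if n_clipped:
        logger.info("min-max normalization clipped %d out-of-range values", n_clipped)
        out = np.clip(out, 0.0, 1.0)
    return out, (lo, hi)


def bag_of_words(records: Sequence[UserRecord], vocabulary: dict[str, int]) -> np.ndarray:
    """Token-count features over a fixed vocabulary (one row per user)."""
    X = np.zeros((len(records), len(vocabulary)), dtype=np.float64)
    for i, rec in enumerate(records):
        for tok in rec.all_tokens():
            j = vocabulary.get(tok)
            if j is not None:
                X[i, j] += 1.0
    return X


# -- word2vec text format -------------------------------------------------

def load_word2vec(path) -> EmbeddingTable:
    """Read an embedding table in word2vec text format.

    First line ``|V| d``, then one ``token v1 ... vd`` line per word.
    """
    vocabulary: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        n, d = (int(x) for x in fh.readline().split())
        matrix = np.empty((n, d), dtype=np.float64)
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            token, vals = parts[0], parts[1:]
            if len(vals) != d:
                raise ValueError(f"line {i + 2}: expected {d} values, got {len(vals)}")
            if token in vocabulary:
                raise ValueError(f"duplicate token {token!r}")
            vocabulary[token] = i
            matrix[i] = [float(v) for v in vals]
    return EmbeddingTable(vocabulary, matrix)


def save_word2vec(table: EmbeddingTable, path) -> None:
    tokens = sorted(table.vocabulary, key=table.vocabulary.get)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {table.dim}\n")
        for token in tokens:
            row = table.matrix[table.vocabulary[token]]
            fh.write(token + " " + " ".join(repr(float(v)) for v in row) + "\n")


# -- embedding layer construction ----------------------------------------

def make_embedding_layer(
    table: EmbeddingTable,
    mode: str,
    rng: np.random.Generator,
    encoder: SequenceEncoder | None = None,
    init_scale: float = 0.1,
) -> tuple[np.ndarray, bool]:
    """Initial embedding weights and trainable flag for a given mode.

    The returned matrix has ``1 + |V| + |unknown|`` rows: row 0 is the
    all-zero padding vector, rows 1..|V| correspond to table rows, and any
    unknown-token rows are seeded random draws.  ``rand`` ignores the table
    values entirely (seeded random init, trainable); ``static`` copies the
    table and freezes everything; ``nostatic`` copies the table and trains.
    """
    if mode not in EMBEDDING_MODES:
        raise ValueError(f"mode must be one of {EMBEDDING_MODES}")
    n_unknown = len(encoder.unknown) if encoder is not None else 0
    n_rows = 1 + table.matrix.shape[0] + n_unknown
    if mode == "rand":
        weights = rng.uniform(-init_scale, init_scale, size=(n_rows, table.dim))
        weights[PAD_ID] = 0.0
        return weights, True
    weights = np.zeros((n_rows, table.dim))
    weights[1 : 1 + table.matrix.shape[0]] = table.matrix
    if n_unknown:
        logger.info("%d unknown tokens initialized with seeded random rows", n_unknown)
        weights[1 + table.matrix.shape[0] :] = rng.uniform(
            -init_scale, init_scale, size=(n_unknown, table.dim)
        )
    return weights, mode == "nostatic"
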