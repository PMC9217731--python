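"""Synthetic inputs for every experiment the simulator supports.

Real depression corpora are private crawler output, so the generator
emulates one at matching shape: each user gets a Bernoulli(prevalence)
label and posts drawn from class-conditional multinomials over a shared
Zipf-weighted vocabulary.  The two class distributions differ only on a
small set of signal tokens, whose log-probabilities are shifted by
``signal_strength`` in the positive class — a controllable, linearly
detectable depression-signal vocabulary.  Defaults mirror the shape of
the study population this stands in for: 900 users with 327 positive.

A second generator produces a labeled vector dataset (Gaussian class
blobs, 60,000 records, 10 balanced classes by default) standing in for
MNIST in the partitioning experiments, and ``partition`` splits any
labeled dataset IID, pathologically non-IID (label-sorted shards dealt
round-robin), or size-imbalanced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .text_pipeline import EmbeddingTable, UserRecord, save_corpus_jsonl, save_word2vec

__all__ = [
    "CorpusSpec",
    "PartitionSpec",
    "gen_corpus",
    "gen_embedding_table",
    "gen_vectors",
    "partition",
    "split_train_test",
    "write_corpus_bundle",
]


@dataclass(frozen=True)
class CorpusSpec:
    n_users: int = 900
    prevalence: float = 327 / 900
    vocab_size: int = 2000
    signal_tokens: int = 50
    signal_strength: float = 2.0
    posts_per_user: tuple[int, int] = (3, 10)
    post_length: tuple[int, int] = (5, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.prevalence * self.n_users < 1:
            raise ValueError("expected at least one positive user")
        if self.signal_tokens >= self.vocab_size:
            raise ValueError("signal_tokens must be < vocab_size")


@dataclass(frozen=True)
class PartitionSpec:
    scheme: str = "iid"
    n_devices: int = 10
    n_shards: int = 0
    shard_size: int = 0
    shards_per_device: int = 0
    min_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("iid", "shards", "imbalanced"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "shards" and self.n_shards != self.n_devices * self.shards_per_device:
            raise ValueError("shards scheme requires n_shards = n_devices * shards_per_device")


def _token_name(i: int) -> str:
    return f"w{i:05d}"


def gen_corpus(spec: CorpusSpec) -> tuple[list[UserRecord], np.ndarray]:
    """Generate user records plus the ground-truth per-token label log-odds.

    Token frequencies follow a Zipf law; the positive class up-weights the
    ``signal_tokens`` most frequent tokens' logits by ``signal_strength``.
    Deterministic in ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    base_logits = -np.log(np.arange(1, spec.vocab_size + 1, dtype=np.float64))
    pos_logits = base_logits.copy()
    pos_logits[: spec.signal_tokens] += spec.signal_strength

    def probs(logits):
        p = np.exp(logits - logits.max())
        return p / p.sum()

    p_neg, p_pos = probs(base_logits), probs(pos_logits)
    log_odds = np.log(p_pos) - np.log(p_neg)

    records = []
    for u in range(spec.n_users):
        label = int(rng.random() < spec.prevalence)
        p = p_pos if label else p_neg
        n_posts = int(rng.integers(spec.posts_per_user[0], spec.posts_per_user[1] + 1))
        posts = []
        for _ in range(n_posts):
            n_tok = int(rng.integers(spec.post_length[0], spec.post_length[1] + 1))
            ids = rng.choice(spec.vocab_size, size=n_tok, p=p)
            posts.append([_token_name(i) for i in ids])
        records.append(UserRecord(f"u{u:05d}", posts, label))
    return records, log_odds


def gen_embedding_table(vocab_size: int, dim: int, seed: int) -> EmbeddingTable:
    """Seeded random embedding table over the generator's vocabulary."""
    rng = np.random.default_rng(seed)
    vocabulary = {_token_name(i): i for i in range(vocab_size)}
    return EmbeddingTable(vocabulary, rng.normal(0.0, 0.1, size=(vocab_size, dim)))


def gen_vectors(
    n: int, n_classes: int, dim: int, class_sep: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class blobs with balanced labels (MNIST-shaped stand-in).

    Class means sit at distance ``class_sep`` from the origin along random
    unit directions; samples add unit-variance isotropic noise.  Counts per
    class differ by at most one when ``n_classes`` does not divide ``n``.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_classes, dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    means = class_sep * dirs
    counts = np.full(n_classes, n // n_classes)
    counts[: n % n_classes] += 1
    y = np.repeat(np.arange(n_classes), counts)
    X = means[y] + rng.normal(size=(n, dim))
    order = rng.permutation(n)
    return X[order], y[order]


def partition(labels: np.ndarray, spec: PartitionSpec) -> list[np.ndarray]:
    """Split indices 0..N-1 into per-device shards.

    iid         seeded shuffle, near-equal contiguous cuts;
    shards      stable sort by label, cut into ``n_shards`` contiguous
                shards of ``shard_size``, seeded-shuffle the shard ids and
                deal them round-robin — the pathological non-IID regime
                where most devices see very few distinct labels;
    imbalanced  device sizes from a seeded power law, each >= min_size.
    """
    labels = np.asarray(labels)
    N = labels.size
    rng = np.random.default_rng(spec.seed)
    if spec.scheme == "iid":
        perm = rng.permutation(N)
        sizes = np.full(spec.n_devices, N // spec.n_devices)
        sizes[: N % spec.n_devices] += 1
        return [np.sort(chunk) for chunk in np.split(perm, np.cumsum(sizes)[:-1])]
    if spec.scheme == "shards":
        if spec.n_shards * spec.shard_size != N:
            raise ValueError("n_shards * shard_size must equal the dataset size")
        order = np.argsort(labels, kind="stable")
        shards = np.split(order, spec.n_shards)
        dealt: list[list[np.ndarray]] = [[] for _ in range(spec.n_devices)]
        for j, sid in enumerate(rng.permutation(spec.n_shards)):
            dealt[j % spec.n_devices].append(shards[sid])
        return [np.sort(np.concatenate(parts)) for parts in dealt]
    # imbalanced
    if N < spec.n_devices * spec.min_size:
        raise ValueError("dataset too small for min_size per device")
    raw = rng.pareto(1.5, spec.n_devices) + 1.0
    sizes = np.maximum(spec.min_size, np.floor(raw / raw.sum() * N).astype(int))
    # repair the total while respecting the minimum
    while sizes.sum() > N:
        sizes[np.argmax(sizes)] -= 1
    sizes[np.argmax(sizes)] += N - sizes.sum()
    perm = rng.permutation(N)
    return [np.sort(chunk) for chunk in np.split(perm, np.cumsum(sizes)[:-1])]


def split_train_test(
    records: list[UserRecord], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[UserRecord], list[UserRecord]]:
    """Stratified train/test split of a corpus (per-class seeded shuffle)."""
    rng = np.random.default_rng(seed)
    train: list[UserRecord] = []
    test: list[UserRecord] = []
    for label in (0, 1):
        idx = [i for i, r in enumerate(records) if r.label == label]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        test.extend(records[i] for i in idx[:n_test])
        train.extend(records[i] for i in idx[n_test:])
    return train, test


def write_corpus_bundle(spec: CorpusSpec, outdir, embedding_dim: int = 32) -> dict:
    """Emit corpus.jsonl + embeddings.txt + manifest.json into ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    records, log_odds = gen_corpus(spec)
    save_corpus_jsonl(records, os.path.join(outdir, "corpus.jsonl"))
    table = gen_embedding_table(spec.vocab_size, embedding_dim, spec.seed + 1)
    save_word2vec(table, os.path.join(outdir, "embeddings.txt"))
    manifest = {
        "spec": asdict(spec),
        "embedding_dim": embedding_dim,
        "n_positive": int(sum(r.label for r in records)),
        "files": ["corpus.jsonl", "embeddings.txt"],
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
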