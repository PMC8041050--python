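"""Word embeddings trained with skip-gram plus synonym supervision.

The question matcher needs word vectors in which medical synonyms (fever /
pyrexia, dyspnea / shortness of breath) land close together even when the
corpus is too small for co-occurrence alone to discover that.  We therefore
train a standard skip-gram model with negative sampling and add a weak
supervision term: declared synonym pairs are injected as extra positive
skip-gram examples and gently pulled together in vector space each epoch.

The trainer is fully seeded, so identical inputs and seed give bitwise
identical vectors.  The :class:`EmbeddingModel` is a plain container, so
pretrained vectors from any source can be plugged into the matcher instead.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass

import numpy as np

__all__ = ["EmbeddingModel", "tokenize", "train_embeddings"]

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"[0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokenizer (order-preserving, keeps duplicates)."""
    return _WORD_RE.findall(text.lower())


@dataclass
class EmbeddingModel:
    """A vocabulary and one fixed-length real vector per word."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # shape (len(vocabulary), dimension)
    dimension: int

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.dimension):
            raise ValueError("vector matrix shape does not match vocabulary")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    def vector(self, word: str) -> np.ndarray | None:
        idx = self.vocabulary.get(word)
        return None if idx is None else self.vectors[idx]

    def save(self, path) -> None:
        """Persist vocabulary and vectors to one archive (round-trips exactly)."""
        meta = json.dumps({"vocabulary": self.vocabulary, "dimension": self.dimension})
        np.savez(path, meta=np.str_(meta), vectors=self.vectors)

    @classmethod
    def load(cls, path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return cls(meta["vocabulary"], data["vectors"].copy(), meta["dimension"])

    def cosine(self, w1: str, w2: str) -> float:
        v1, v2 = self.vector(w1), self.vector(w2)
        if v1 is None or v2 is None:
            raise KeyError(f"word not in vocabulary: {w1 if v1 is None else w2}")
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        return 0.0 if denom == 0 else float(v1 @ v2 / denom)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus: list[str],
    synonym_pairs: list[tuple[str, str]] | None = None,
    dimension: int = 32,
    seed: int = 0,
    *,
    window: int = 3,
    min_count: int = 1,
    epochs: int = 5,
    negatives: int = 5,
    learning_rate: float = 0.05,
    synonym_boost: int = 10,
    synonym_pull: float = 0.05,
) -> EmbeddingModel:
    """Train word vectors on a sentence corpus with optional synonym pairs.

    Parameters
    ----------
    corpus
        Sentences (free text); tokenized internally.
    synonym_pairs
        Word pairs that should receive near-identical vectors.  Pairs with a
        word absent from the corpus vocabulary are skipped with a warning.
    dimension
        Vector length, >= 2.
    seed
        Seeds sampling and initialization; same inputs + seed reproduce the
        vectors bitwise.
    synonym_boost
        How many times each synonym pair is replayed as a positive skip-gram
        example per epoch (the weak-supervision term).
    synonym_pull
        Per-epoch step size of the direct attraction between synonym vectors.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if dimension < 2:
        raise ValueError("dimension must be >= 2")

    sentences = [tokenize(s) for s in corpus]
    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab_words = sorted(
        (w for w, c in counts.items() if c >= min_count),
        key=lambda w: (-counts[w], w),
    )
    if not vocab_words:
        raise ValueError("no word reaches the minimum count")
    vocab = {w: i for i, w in enumerate(vocab_words)}
    nvoc = len(vocab)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((nvoc, dimension)) - 0.5) / dimension
    w_out = np.zeros((nvoc, dimension))

    # (center, context) pairs from a symmetric window
    centers, contexts = [], []
    for sent in sentences:
        ids = [vocab[w] for w in sent if w in vocab]
        for i, c in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])

    syn_ids: list[tuple[int, int]] = []
    for a, b in synonym_pairs or []:
        ia, ib = vocab.get(a.lower()), vocab.get(b.lower())
        if ia is None or ib is None:
            logger.warning("synonym pair (%r, %r) skipped: word not in corpus", a, b)
            continue
        syn_ids.append((ia, ib))
    for ia, ib in syn_ids:
        for _ in range(synonym_boost):
            centers.extend((ia, ib))
            contexts.extend((ib, ia))

    centers_arr = np.asarray(centers, dtype=np.int64)
    contexts_arr = np.asarray(contexts, dtype=np.int64)
    npairs = centers_arr.size
    if npairs == 0:
        raise ValueError("corpus produced no co-occurrence pairs")

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[w] for w in vocab_words], dtype=float) ** 0.75
    neg_p = freq / freq.sum()

    # classic sequential SGD (one update per skip-gram sample), which keeps
    # frequent-word updates stable where a summed batch update would not
    for epoch in range(epochs):
        lr = learning_rate * (1.0 - epoch / max(epochs, 1))
        order = rng.permutation(npairs)
        negs = rng.choice(nvoc, size=(npairs, negatives), p=neg_p)
        for n, i in enumerate(order):
            c, o = centers_arr[i], contexts_arr[i]
            vc = w_in[c]
            rows = np.concatenate(([o], negs[n]))
            targets = w_out[rows]  # (1+K, d)
            g = _sigmoid(targets @ vc)
            g[0] -= 1.0  # positive sample pulls toward sigma = 1
            w_in[c] = vc - lr * (g @ targets)
            w_out[rows] = targets - lr * np.outer(g, vc)
        # direct attraction between synonym vectors
        for ia, ib in syn_ids:
            delta = synonym_pull * (w_in[ib] - w_in[ia])
            w_in[ia] = w_in[ia] + delta
            w_in[ib] = w_in[ib] - delta

    return EmbeddingModel(vocab, w_in, dimension)
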