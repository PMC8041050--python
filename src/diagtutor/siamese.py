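"""Siamese recurrent question matcher.

Two copies of the *same* LSTM encoder (weight sharing is structural: there is
one parameter set, applied to both inputs) map a pair of questions to hidden
states ``h1, h2``; their semantic-equivalence score is the Manhattan-distance
similarity

    similarity(q1, q2) = exp(-||h1 - h2||_1)  in (0, 1],

which equals 1 exactly when the hidden states coincide.  Training minimizes
the squared error between this score and a binary equivalence label.  The
ranker scores a student's question against every reference question of the
simulation, keeps scores strictly above a probability threshold, and returns
at most three matches — returning more would leak reference questions the
student has not yet thought of.

Everything is plain numpy: the encoder is a single-layer LSTM (gates in
i, f, g, o order, forget bias 1) with front padding, an UNK row for
out-of-vocabulary words (zero-initialized, trainable), and hand-derived
backpropagation through time.  Small training sets are fit with full-batch
gradient descent and a backtracking step size, which makes the per-epoch loss
trace monotone non-increasing; larger sets use minibatch Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingModel, tokenize

__all__ = [
    "LabeledPair",
    "RankedMatch",
    "SiameseMatcher",
    "train_matcher",
    "rank_questions",
    "evaluate_rank_accuracy",
]

_FULL_BATCH_MAX = 64  # at or below this many pairs, use backtracking GD


@dataclass(frozen=True)
class LabeledPair:
    """A question pair labeled semantically equivalent (1) or not (0)."""

    question_a: str
    question_b: str
    equivalent: int

    def __post_init__(self) -> None:
        if not self.question_a or not self.question_b:
            raise ValueError("labeled pair questions must be non-empty")
        if self.equivalent not in (0, 1):
            raise ValueError("equivalence label must be 0 or 1")


@dataclass(frozen=True)
class RankedMatch:
    reference_question_id: str
    probability: float


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class SiameseMatcher:
    """Shared-weight LSTM encoder with exp(-L1) pair similarity."""

    def __init__(
        self,
        embedding: EmbeddingModel,
        hidden_size: int = 50,
        max_len: int = 30,
        seed: int = 0,
    ):
        if hidden_size < 1 or max_len < 1:
            raise ValueError("hidden_size and max_len must be positive")
        self.vocabulary = dict(embedding.vocabulary)
        self.dimension = embedding.dimension
        self.hidden_size = hidden_size
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        d, h = self.dimension, hidden_size
        # row 0 is the trainable UNK vector (zero-initialized)
        emb = np.vstack([np.zeros((1, d)), np.asarray(embedding.vectors, dtype=float)])
        sx = np.sqrt(6.0 / (d + 4 * h))
        sh = np.sqrt(6.0 / (h + 4 * h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        self.params: dict[str, np.ndarray] = {
            "Emb": emb,
            "Wx": rng.uniform(-sx, sx, size=(d, 4 * h)),
            "Wh": rng.uniform(-sh, sh, size=(h, 4 * h)),
            "b": b,
        }

    # ------------------------------------------------------------------ io

    def _ids(self, question: str) -> list[int]:
        tokens = tokenize(question)
        if not tokens:
            raise ValueError("question is empty; prompt the student for input")
        tokens = tokens[: self.max_len]
        return [self.vocabulary.get(t, -1) + 1 for t in tokens]  # 0 = UNK

    def _pad(self, questions: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Front-pad token ids to a common length; mask marks real tokens."""
        seqs = [self._ids(q) for q in questions]
        T = max(len(s) for s in seqs)
        ids = np.zeros((len(seqs), T), dtype=np.int64)
        mask = np.zeros((len(seqs), T))
        for i, s in enumerate(seqs):
            ids[i, T - len(s) :] = s
            mask[i, T - len(s) :] = 1.0
        return ids, mask

    # ------------------------------------------------------------- forward

    def _forward(self, ids: np.ndarray, mask: np.ndarray, keep_cache: bool = False):
        B, T = ids.shape
        H = self.hidden_size
        Emb, Wx, Wh, b = (self.params[k] for k in ("Emb", "Wx", "Wh", "b"))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x = Emb[ids[:, t]]
            z = x @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            m = mask[:, t : t + 1]
            if keep_cache:
                cache.append((x, h, c, i, f, g, o, c_new))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        return h, cache

    def _backward(
        self,
        ids: np.ndarray,
        mask: np.ndarray,
        cache: list,
        dh: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> None:
        """Accumulate BPTT gradients for one branch into ``grads``."""
        T = ids.shape[1]
        H = self.hidden_size
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dc = np.zeros_like(dh)
        for t in reversed(range(T)):
            x, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            m = mask[:, t : t + 1]
            dh_eff = m * dh
            dc_eff = m * dc
            tc = np.tanh(c_new)
            do = dh_eff * tc
            dc_new = dc_eff + dh_eff * o * (1 - tc**2)
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            np.add.at(grads["Emb"], ids[:, t], dz @ Wx.T)
            dh = dz @ Wh.T + (1 - m) * dh
            dc = dc_new * f + (1 - m) * dc

    # -------------------------------------------------------------- public

    def encode(self, question: str) -> np.ndarray:
        """Final hidden state of the encoder for one question (length h)."""
        ids, mask = self._pad([question])
        h, _ = self._forward(ids, mask)
        return h[0]

    def encode_many(self, questions: list[str]) -> np.ndarray:
        ids, mask = self._pad(questions)
        h, _ = self._forward(ids, mask)
        return h

    def pair_similarity(self, q1: str, q2: str) -> float:
        """exp(-Manhattan distance) between the two hidden states, in (0, 1]."""
        h = self.encode_many([q1, q2])
        return float(np.exp(-np.abs(h[0] - h[1]).sum()))

    # ------------------------------------------------------------ training

    def _batch_loss_and_grads(
        self,
        ids1: np.ndarray,
        mask1: np.ndarray,
        ids2: np.ndarray,
        mask2: np.ndarray,
        y: np.ndarray,
        want_grads: bool = True,
    ):
        h1, cache1 = self._forward(ids1, mask1, keep_cache=want_grads)
        h2, cache2 = self._forward(ids2, mask2, keep_cache=want_grads)
        diff = h1 - h2
        sim = np.exp(-np.abs(diff).sum(axis=1))
        resid = sim - y
        loss = float(np.mean(resid**2))
        if not want_grads:
            return loss, None
        B = y.size
        coef = (2.0 / B) * resid * sim  # dL/d(L1 distance) has opposite sign
        dh1 = -coef[:, None] * np.sign(diff)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._backward(ids1, mask1, cache1, dh1, grads)
        self._backward(ids2, mask2, cache2, -dh1, grads)
        return loss, grads

    def train(
        self,
        pairs: list[LabeledPair],
        epochs: int = 30,
        learning_rate: float = 0.02,
        seed: int = 0,
        batch_size: int = 64,
    ) -> list[float]:
        """Fit the encoder on labeled pairs; returns the per-epoch loss trace.

        Small sets (<= 64 pairs) are fit by full-batch gradient descent with a
        backtracking step size, guaranteeing a monotone non-increasing trace;
        larger sets use minibatch Adam with seeded shuffling.
        """
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not pairs:
            raise ValueError("no training pairs supplied")
        labels = {p.equivalent for p in pairs}
        if len(labels) < 2:
            raise ValueError(
                "training set contains a single class; need both equivalent "
                "and inequivalent pairs"
            )
        ids1, mask1 = self._pad([p.question_a for p in pairs])
        ids2, mask2 = self._pad([p.question_b for p in pairs])
        y = np.array([p.equivalent for p in pairs], dtype=float)

        if len(pairs) <= _FULL_BATCH_MAX:
            return self._train_gd(ids1, mask1, ids2, mask2, y, epochs, learning_rate)
        return self._train_adam(
            ids1, mask1, ids2, mask2, y, epochs, learning_rate, seed, batch_size
        )

    def _train_gd(self, ids1, mask1, ids2, mask2, y, epochs, lr) -> list[float]:
        loss, grads = self._batch_loss_and_grads(ids1, mask1, ids2, mask2, y)
        trace = []
        for _ in range(epochs):
            stepped = False
            for _try in range(25):
                candidate = {k: v - lr * grads[k] for k, v in self.params.items()}
                saved = self.params
                self.params = candidate
                new_loss, new_grads = self._batch_loss_and_grads(
                    ids1, mask1, ids2, mask2, y
                )
                if new_loss <= loss:
                    loss, grads = new_loss, new_grads
                    lr *= 1.1
                    stepped = True
                    break
                self.params = saved
                lr *= 0.5
            if not stepped:  # converged to numerical precision
                pass
            trace.append(loss)
        return trace

    def _train_adam(
        self, ids1, mask1, ids2, mask2, y, epochs, lr, seed, batch_size
    ) -> list[float]:
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = y.size
        trace = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, grads = self._batch_loss_and_grads(
                    ids1[idx], mask1[idx], ids2[idx], mask2[idx], y[idx]
                )
                epoch_losses.append(loss)
                step += 1
                for k in self.params:
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    self.params[k] = self.params[k] - lr * mhat / (np.sqrt(vhat) + eps)
            trace.append(float(np.mean(epoch_losses)))
        return trace

    # ---------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Write vocabulary, embedding matrix, encoder weights and
        hyperparameters to a single archive; load/save round-trips bit-exact."""
        meta = json.dumps(
            {
                "vocabulary": self.vocabulary,
                "dimension": self.dimension,
                "hidden_size": self.hidden_size,
                "max_len": self.max_len,
            }
        )
        np.savez(path, meta=np.str_(meta), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SiameseMatcher":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            obj = cls.__new__(cls)
            obj.vocabulary = meta["vocabulary"]
            obj.dimension = meta["dimension"]
            obj.hidden_size = meta["hidden_size"]
            obj.max_len = meta["max_len"]
            obj.params = {k: data[k].copy() for k in ("Emb", "Wx", "Wh", "b")}
        return obj


def load_labeled_pairs(path: str | Path) -> list[LabeledPair]:
    """Read a UTF-8 TSV of (question_a, question_b, label in {0,1})."""
    pairs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        a, b, label = line.split("\t")
        pairs.append(LabeledPair(a, b, int(label)))
    return pairs


def train_matcher(
    matcher: SiameseMatcher,
    pairs: list[LabeledPair],
    epochs: int = 30,
    learning_rate: float = 0.02,
    seed: int = 0,
) -> tuple[SiameseMatcher, list[float]]:
    """Train ``matcher`` in place on labeled pairs; returns it with the loss trace."""
    trace = matcher.train(pairs, epochs=epochs, learning_rate=learning_rate, seed=seed)
    return matcher, trace


def rank_questions(
    matcher,
    student_question: str,
    references: list[tuple[str, str]],
    threshold: float = 0.5,
) -> list[RankedMatch]:
    """Score every reference question, keep scores strictly above the
    threshold, and return at most three matches sorted by descending score
    (ties by smallest reference id).  An empty list means "no questions"."""
    if not references:
        raise ValueError("reference question list is empty")
    scored = [
        (rid, matcher.pair_similarity(student_question, text))
        for rid, text in references
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [
        RankedMatch(rid, p) for rid, p in scored if p > threshold
    ][:3]


def evaluate_rank_accuracy(
    matcher,
    testset: list[tuple[str, str]],
    references: list[tuple[str, str]],
    k: int = 1,
) -> float:
    """Fraction of test questions whose true reference is among the top k.

    Evaluation ranks all references without any threshold, so rank-k accuracy
    is non-decreasing in k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not testset:
        raise ValueError("test set is empty")
    ref_ids = {rid for rid, _ in references}
    missing = [tid for _, tid in testset if tid not in ref_ids]
    if missing:
        raise ValueError(f"true reference ids absent from references: {missing}")
    ref_texts = [t for _, t in references]
    ref_h = matcher.encode_many(ref_texts)
    hits = 0
    for question, true_id in testset:
        qh = matcher.encode(question)
        sims = np.exp(-np.abs(ref_h - qh).sum(axis=1))
        order = sorted(
            range(len(references)), key=lambda i: (-sims[i], references[i][0])
        )
        top = {references[i][0] for i in order[:k]}
        hits += true_id in top
    return hits / len(testset)
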