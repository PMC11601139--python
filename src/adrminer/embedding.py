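"""Skip-gram word embeddings with negative sampling, trained on tokenized posts.

Implemented directly on numpy (batched SGD over (center, context) pairs with
a dynamically shrunk window and a unigram^0.75 negative-sampling table) so the
pipeline has no heavyweight dependencies.  Tagged terms are single vocabulary
items, so e.g. ``ketotop_1_drug`` gets one vector.

Vectors persist in the de-facto word2vec text format: a ``count dim`` header
line followed by one ``term v1 ... vd`` line per word.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocess import TokenizedPost


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


@dataclass
class EmbeddingModel:
    vocabulary: dict[str, int]  # term -> row index
    vectors: np.ndarray  # |V| x d
    training_params: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, term: str) -> bool:
        return term in self.vocabulary

    def vector(self, term: str) -> np.ndarray:
        if term not in self.vocabulary:
            raise KeyError(f"term not in embedding vocabulary: {term!r}")
        return self.vectors[self.vocabulary[term]]

    def terms(self) -> list[str]:
        return list(self.vocabulary)


def train_embeddings(
    posts: Iterable[TokenizedPost],
    dim: int = 300,
    window: int = 5,
    min_count: int = 1,
    epochs: int = 5,
    negative: int = 5,
    seed: int = 0,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    batch_size: int = 64,
) -> EmbeddingModel:
    """Train skip-gram vectors over the rendered-token vocabulary.

    Deterministic for a fixed corpus + parameters + seed (single worker).
    """
    if dim < 2:
        raise ValueError(f"embedding dim must be >= 2, got {dim}")
    sentences = [p.rendered for p in posts]
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")
    counts = Counter(tok for sent in sentences for tok in sent)
    # deterministic vocabulary order: frequency desc, then lexicographic
    vocab_terms = sorted(
        (t for t, c in counts.items() if c >= min_count), key=lambda t: (-counts[t], t)
    )
    if not vocab_terms:
        raise ValueError("no term meets min_count; vocabulary is empty")
    vocabulary = {t: i for i, t in enumerate(vocab_terms)}
    V = len(vocabulary)

    rng = np.random.default_rng(seed)
    W = ((rng.random((V, dim)) - 0.5) / dim).astype(np.float64)  # input vectors
    C = np.zeros((V, dim), dtype=np.float64)  # output (context) vectors

    freq = np.array([counts[t] for t in vocab_terms], dtype=np.float64)
    noise = freq**0.75
    noise /= noise.sum()

    encoded = [[vocabulary[t] for t in sent if t in vocabulary] for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]

    # total pair budget for linear learning-rate decay
    approx_pairs = max(1, sum(len(s) for s in encoded) * (window + 1) // 1) * max(1, epochs)
    pair_seen = 0

    for _epoch in range(epochs):
        centers: list[int] = []
        contexts: list[int] = []
        for sent in encoded:
            n = len(sent)
            reduced = rng.integers(1, window + 1, size=n)
            for i, w in enumerate(sent):
                span = int(reduced[i])
                lo, hi = max(0, i - span), min(n, i + span + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(w)
                        contexts.append(sent[j])
        if not centers:
            continue
        order = rng.permutation(len(centers))
        cen = np.asarray(centers)[order]
        ctx = np.asarray(contexts)[order]
        for start in range(0, len(cen), batch_size):
            b_cen = cen[start : start + batch_size]
            b_ctx = ctx[start : start + batch_size]
            B = len(b_cen)
            alpha = max(min_lr, lr * (1.0 - pair_seen / approx_pairs))
            pair_seen += B

            neg = rng.choice(V, size=(B, negative), p=noise)
            w_in = W[b_cen]  # B x d

            # positive pairs
            pos_score = _sigmoid(np.einsum("bd,bd->b", w_in, C[b_ctx]))
            g_pos = (pos_score - 1.0)[:, None]  # B x 1
            grad_in = g_pos * C[b_ctx]
            np.add.at(C, b_ctx, -alpha * g_pos * w_in)

            # negative samples
            c_neg = C[neg]  # B x k x d
            neg_score = _sigmoid(np.einsum("bd,bkd->bk", w_in, c_neg))
            g_neg = neg_score[:, :, None]  # B x k x 1
            grad_in += np.einsum("bkd->bd", g_neg * c_neg)
            np.add.at(C, neg, -alpha * g_neg * w_in[:, None, :])

            np.add.at(W, b_cen, -alpha * grad_in)

    params = {
        "mode": "skip-gram",
        "dim": dim,
        "window": window,
        "min_count": min_count,
        "epochs": epochs,
        "negative": negative,
        "seed": seed,
    }
    return EmbeddingModel(vocabulary, W, params)


def cosine_similarity(model: EmbeddingModel, a: str, b: str) -> float:
    """cos(a, b) in [-1, 1]; symmetric; cos(a, a) == 1 within 1e-6."""
    va, vb = model.vector(a), model.vector(b)
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    if denom == 0.0:
        return 0.0
    return float(np.clip(np.dot(va, vb) / denom, -1.0, 1.0))


def nearest_neighbors(model: EmbeddingModel, term: str, k: int = 10) -> list[tuple[str, float]]:
    """Top-k terms by cosine similarity (query excluded), ties lexicographic."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    v = model.vector(term)
    norms = np.linalg.norm(model.vectors, axis=1)
    norms[norms == 0.0] = 1.0
    vn = np.linalg.norm(v)
    sims = model.vectors @ v / (norms * (vn if vn else 1.0))
    ranked = sorted(
        ((t, float(sims[i])) for t, i in model.vocabulary.items() if t != term),
        key=lambda ts: (-round(ts[1], 12), ts[0]),
    )
    return ranked[:k]


def save_word2vec(model: EmbeddingModel, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(model.vocabulary)} {model.dim}\n")
        for term, idx in model.vocabulary.items():
            vec = " ".join(f"{x:.8g}" for x in model.vectors[idx])
            fh.write(f"{term} {vec}\n")
    return path


def load_word2vec(path: str | Path) -> EmbeddingModel:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        count, dim = int(header[0]), int(header[1])
        vocabulary: dict[str, int] = {}
        vectors = np.zeros((count, dim), dtype=np.float64)
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split(" ")
            term, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise ValueError(f"{path}: wrong vector length for term {term!r}")
            vocabulary[term] = i
            vectors[i] = [float(x) for x in vals]
    if len(vocabulary) != count:
        raise ValueError(f"{path}: header count {count} != {len(vocabulary)} vectors")
    return EmbeddingModel(vocabulary, vectors, {"loaded_from": str(path)})


def terms_for(posts: Sequence[TokenizedPost]) -> Counter:
    """Frequency table of rendered tokens (helper for diagnostics)."""
    return Counter(tok for p in posts for tok in p.rendered)
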