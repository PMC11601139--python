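"""Many-to-one recurrent binary classifiers over padded integer sequences.

The headline configuration mirrors the study setup: Bi-LSTM with 256 hidden
units, 300-dimensional embeddings, sigmoid output, Adam, binary cross-entropy,
learning rate 0.001, batch size 64, 50 epochs, 7:3 stratified train/test
split and a 0.5 decision threshold.  ``gru`` and ``cnn_bilstm`` variants run
through the identical train/predict contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from ..embedding import EmbeddingModel
from .encoding import OOV_INDEX, PAD_INDEX, EncodedPost, VocabularyEncoding, as_matrix
from .nets import Adam, Conv1D, GRULayer, LSTMLayer, MaxPool1D, sigmoid

ARCHITECTURES = ("bilstm", "gru", "cnn_bilstm")


@dataclass
class ModelConfig:
    architecture: str = "bilstm"
    hidden_units: int = 256
    embedding_dim: int = 300
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 50
    threshold: float = 0.5
    split_ratio: float = 0.7
    seed: int = 0
    early_stopping: bool = False
    patience: int = 5
    validation_fraction: float = 0.1
    freeze_embeddings: bool = False
    conv_filters: int = 128
    conv_width: int = 3

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError(f"split_ratio must lie in (0, 1), got {self.split_ratio}")


class _Network:
    """Embedding -> (optional conv/pool) -> bidirectional recurrence -> sigmoid."""

    def __init__(self, config: ModelConfig, vocab_size: int, embed_init: Optional[np.ndarray]):
        rng = np.random.default_rng(config.seed)
        d = config.embedding_dim
        H = config.hidden_units
        self.config = config
        self.E = rng.normal(0.0, 0.05, (vocab_size, d))
        self.E[PAD_INDEX] = 0.0
        self.E[OOV_INDEX] = 0.0
        if embed_init is not None:
            rows, vecs = embed_init
            self.E[rows] = vecs
        rec = LSTMLayer if config.architecture != "gru" else GRULayer
        self.conv = None
        self.pool = None
        d_rec = d
        if config.architecture == "cnn_bilstm":
            self.conv = Conv1D(d, config.conv_filters, config.conv_width, rng, "conv")
            self.pool = MaxPool1D(2)
            d_rec = config.conv_filters
        self.fwd = rec(d_rec, H, rng, "fwd")
        self.bwd = rec(d_rec, H, rng, "bwd")
        s = 1.0 / np.sqrt(2 * H)
        self.Wd = rng.uniform(-s, s, (2 * H, 1))
        self.bd = np.zeros(1)

    def params(self) -> dict[str, np.ndarray]:
        p = {"E": self.E, "Wd": self.Wd, "bd": self.bd}
        p.update(self.fwd.params())
        p.update(self.bwd.params())
        if self.conv is not None:
            p.update(self.conv.params())
        return p

    def forward(self, X: np.ndarray) -> np.ndarray:
        emb = self.E[X]  # B, L, d
        feats = emb
        if self.conv is not None:
            feats = self.pool.forward(self.conv.forward(emb))
        hf = self.fwd.forward(feats)
        hb = self.bwd.forward(feats[:, ::-1])
        h = np.concatenate([hf, hb], axis=1)
        logits = h @ self.Wd + self.bd
        self._X, self._h = X, h
        return sigmoid(logits).ravel()

    def backward(self, p: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        B = len(y)
        dlogit = ((p - y) / B)[:, None]  # d(BCE)/dlogit through the sigmoid
        dWd = self._h.T @ dlogit
        dbd = dlogit.sum(axis=0)
        dh = dlogit @ self.Wd.T
        H = self.config.hidden_units
        dxf, gf = self.fwd.backward(dh[:, :H])
        dxb, gb = self.bwd.backward(dh[:, H:])
        dfeats = dxf + dxb[:, ::-1]
        grads = {"Wd": dWd, "bd": dbd, **gf, **gb}
        if self.conv is not None:
            dconv = self.pool.backward(dfeats)
            demb, gc = self.conv.backward(dconv)
            grads.update(gc)
        else:
            demb = dfeats
        if not self.config.freeze_embeddings:
            dE = np.zeros_like(self.E)
            np.add.at(dE, self._X, demb)
            dE[PAD_INDEX] = 0.0
            grads["E"] = dE
        return grads


@dataclass
class TrainedModel:
    config: ModelConfig
    encoding: VocabularyEncoding
    network: _Network
    training_log: list[dict] = field(default_factory=list)
    trained: bool = True
    max_len: int = 0


def split_train_test(
    posts: Sequence[EncodedPost], ratio: float = 0.7, seed: int = 0
) -> tuple[list[EncodedPost], list[EncodedPost]]:
    """Stratified, seeded train/test split of labeled posts."""
    posts = list(posts)
    labels = [p.label for p in posts]
    if any(lab is None for lab in labels):
        raise ValueError("split_train_test requires every post to carry a label")
    counts = {c: labels.count(c) for c in set(labels)}
    if len(counts) < 2 or min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 members for a stratified split, got {counts}")
    train_posts, test_posts = train_test_split(
        posts, train_size=ratio, random_state=seed, shuffle=True, stratify=labels
    )
    return list(train_posts), list(test_posts)


def _embedding_init(
    encoding: VocabularyEncoding, vectors: Optional[EmbeddingModel]
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    if vectors is None:
        return None
    rows, vecs = [], []
    for term, idx in encoding.index.items():
        if term in vectors:
            rows.append(idx)
            vecs.append(vectors.vector(term))
    if not rows:
        return None
    return np.asarray(rows), np.stack(vecs)


def train(
    train_posts: Sequence[EncodedPost],
    config: ModelConfig,
    encoding: VocabularyEncoding,
    init_vectors: Optional[EmbeddingModel] = None,
) -> TrainedModel:
    """Fit the configured architecture with Adam on binary cross-entropy.

    The embedding layer is initialized from ``init_vectors`` where the
    vocabularies overlap (requires matching dimensionality) and is fine-tuned
    unless ``freeze_embeddings`` is set.  ``epochs == 0`` returns a scorable
    model flagged untrained.
    """
    posts = list(train_posts)
    if not posts:
        raise ValueError("training set is empty")
    X, y = as_matrix(posts)
    if (y < 0).any():
        raise ValueError("training posts must all be labeled")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if init_vectors is not None and init_vectors.dim != config.embedding_dim:
        raise ValueError(
            f"init vector dim {init_vectors.dim} != config embedding_dim {config.embedding_dim}"
        )

    net = _Network(config, encoding.size, _embedding_init(encoding, init_vectors))
    model = TrainedModel(config, encoding, net, max_len=X.shape[1])
    if config.epochs == 0:
        model.trained = False
        return model

    rng = np.random.default_rng(config.seed)
    val_X = val_y = None
    if config.early_stopping:
        idx_train, idx_val = train_test_split(
            np.arange(len(y)),
            test_size=config.validation_fraction,
            random_state=config.seed,
            stratify=y,
        )
        val_X, val_y = X[idx_val], y[idx_val]
        X, y = X[idx_train], y[idx_train]

    opt = Adam(config.learning_rate)
    best_val = np.inf
    best_state: Optional[dict[str, np.ndarray]] = None
    stale = 0
    eps = 1e-12
    for epoch in range(config.epochs):
        order = rng.permutation(len(y))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            p = net.forward(X[sel])
            yb = y[sel].astype(np.float64)
            loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
            losses.append(loss * len(sel))
            grads = net.backward(p, yb)
            opt.step(net.params(), grads)
        entry = {"epoch": epoch + 1, "loss": float(np.sum(losses) / len(y))}
        if val_X is not None:
            pv = _score(net, val_X, config.batch_size)
            entry["val_loss"] = float(
                -np.mean(val_y * np.log(pv + eps) + (1 - val_y) * np.log(1 - pv + eps))
            )
            if entry["val_loss"] < best_val - 1e-6:
                best_val = entry["val_loss"]
                best_state = {k: v.copy() for k, v in net.params().items()}
                stale = 0
            else:
                stale += 1
        model.training_log.append(entry)
        if val_X is not None and stale >= config.patience:
            break
    if best_state is not None:
        for k, v in net.params().items():
            v[...] = best_state[k]
    return model


def _score(net: _Network, X: np.ndarray, batch_size: int) -> np.ndarray:
    out = np.empty(len(X))
    for start in range(0, len(X), batch_size):
        out[start : start + batch_size] = net.forward(X[start : start + batch_size])
    return out


def predict_proba(model: TrainedModel, posts: Sequence[EncodedPost]) -> np.ndarray:
    """One sigmoid score per post, order preserved; batching-invariant."""
    posts = list(posts)
    if not posts:
        return np.empty(0)
    X, _ = as_matrix(posts)
    if X.shape[1] != model.max_len:
        raise ValueError(f"sequence length {X.shape[1]} != model length {model.max_len}")
    return _score(model.network, X, model.config.batch_size)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary decision: 1 iff score >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    scores = np.asarray(scores, dtype=float)
    return (scores >= threshold).astype(np.int64)


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    """Persist config snapshot, encoding table, weights and training log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": asdict(model.config),
        "trained": model.trained,
        "max_len": model.max_len,
        "vocab_size": model.encoding.size,
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    model.encoding.save(directory / "encoding.tsv")
    np.savez(directory / "weights.npz", **model.network.params())
    with (directory / "training_log.csv").open("w", encoding="utf-8") as fh:
        fh.write("epoch,loss,val_loss\n")
        for e in model.training_log:
            fh.write(f"{e['epoch']},{e['loss']},{e.get('val_loss', '')}\n")
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text(encoding="utf-8"))
    config = ModelConfig(**meta["config"])
    encoding = VocabularyEncoding.load(directory / "encoding.tsv")
    net = _Network(config, meta["vocab_size"], None)
    with np.load(directory / "weights.npz") as data:
        for k, v in net.params().items():
            v[...] = data[k]
    model = TrainedModel(config, encoding, net, trained=meta["trained"], max_len=meta["max_len"])
    return model
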