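"""Convolutional sentence classifier over word embeddings.

Architecture: embedding lookup x_i -> windowed convolution
con_i = ReLU(w_k . x_{i:i+k-1} + b_k) for each window size k ->
max-over-time pooling m_k = max_i con_i -> fully connected layer
O = w m + b -> softmax over {target, other}.

Implemented directly in NumPy with explicit gradients so the whole path is
dependency-light and bitwise deterministic under a single seed (embeddings
are frozen by default). Optimization is mini-batch Adam on the softmax
cross-entropy; model selection keeps the parameters with the best dev
accuracy across epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from neurofind.corpus_io import Label
from neurofind.errors import ConfigurationError, DegenerateInputError


# ---------------------------------------------------------------------------
# Embedding table
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    """Token -> d-dimensional vector lookup with an OOV sentinel row."""

    vocabulary: dict[str, int]
    vectors: np.ndarray  # (|V|, d); row ``oov_index`` is the OOV sentinel
    oov_index: int

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise ConfigurationError("vectors must be a |V| x d matrix with d > 0")
        n_rows = self.vectors.shape[0]
        if not (0 <= self.oov_index < n_rows):
            raise ConfigurationError("oov_index out of range")
        if any(not (0 <= i < n_rows) for i in self.vocabulary.values()):
            raise ConfigurationError("vocabulary index out of range")

    @property
    def d(self) -> int:
        return int(self.vectors.shape[1])

    def index_of(self, token: str) -> int:
        return self.vocabulary.get(token, self.oov_index)

    @classmethod
    def from_vectors(cls, tokens: Sequence[str], matrix: np.ndarray) -> "EmbeddingTable":
        """Build a table from parallel token list and vector matrix; appends
        a zero OOV sentinel row."""
        matrix = np.asarray(matrix, dtype=np.float64)
        vocab = {tok: i for i, tok in enumerate(tokens)}
        if len(vocab) != len(tokens):
            raise ConfigurationError("duplicate tokens in embedding table")
        vectors = np.vstack([matrix, np.zeros((1, matrix.shape[1]))])
        return cls(vocabulary=vocab, vectors=vectors, oov_index=len(tokens))

    def save(self, path: str | Path) -> None:
        """Word-vector text format: header '<n> <d>', then one token and d
        floats per line."""
        tokens = sorted(self.vocabulary, key=self.vocabulary.get)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(tokens)} {self.d}\n")
            for tok in tokens:
                row = " ".join(repr(float(v)) for v in self.vectors[self.vocabulary[tok]])
                fh.write(f"{tok} {row}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            tokens, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                tokens.append(parts[0])
                rows.append([float(v) for v in parts[1 : d + 1]])
        if len(tokens) != n:
            raise ConfigurationError(f"{path}: header promises {n} rows, found {len(tokens)}")
        return cls.from_vectors(tokens, np.array(rows))


@dataclass(frozen=True)
class EmbeddedSentence:
    tokens: tuple[str, ...]
    matrix: np.ndarray  # (n, d) after padding


def embed_sentence(
    tokens: Sequence[str], table: EmbeddingTable, min_length: int = 1
) -> EmbeddedSentence:
    """Row-wise embedding lookup; OOV tokens map to the sentinel row and
    sentences shorter than ``min_length`` are padded with zero rows."""
    if not tokens:
        raise DegenerateInputError("cannot embed an empty token list")
    rows = table.vectors[[table.index_of(t) for t in tokens]]
    if len(tokens) < min_length:
        pad = np.zeros((min_length - len(tokens), table.d))
        rows = np.vstack([rows, pad])
    return EmbeddedSentence(tokens=tuple(tokens), matrix=rows)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class CnnConfig:
    window_sizes: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 100
    dropout: float = 0.5
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    tau_pos: float = 0.5


@dataclass
class CnnParameters:
    """All learned weights plus the hyperparameters that shaped them."""

    d: int
    config: CnnConfig
    conv_w: dict[int, np.ndarray]  # k -> (k*d, n_filters)
    conv_b: dict[int, np.ndarray]  # k -> (n_filters,)
    out_w: np.ndarray  # (2, total_filters)
    out_b: np.ndarray  # (2,)
    seed: int = 0

    def copy(self) -> "CnnParameters":
        return CnnParameters(
            d=self.d,
            config=self.config,
            conv_w={k: w.copy() for k, w in self.conv_w.items()},
            conv_b={k: b.copy() for k, b in self.conv_b.items()},
            out_w=self.out_w.copy(),
            out_b=self.out_b.copy(),
            seed=self.seed,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"conv_w_{k}": w for k, w in self.conv_w.items()}
        arrays.update({f"conv_b_{k}": b for k, b in self.conv_b.items()})
        np.savez(path / "params.npz", out_w=self.out_w, out_b=self.out_b, **arrays)
        meta = {
            "d": self.d,
            "seed": self.seed,
            "window_sizes": list(self.config.window_sizes),
            "n_filters": self.config.n_filters,
            "dropout": self.config.dropout,
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "learning_rate": self.config.learning_rate,
            "tau_pos": self.config.tau_pos,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CnnParameters":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        data = np.load(path / "params.npz")
        config = CnnConfig(
            window_sizes=tuple(meta["window_sizes"]),
            n_filters=meta["n_filters"],
            dropout=meta["dropout"],
            epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            learning_rate=meta["learning_rate"],
            tau_pos=meta["tau_pos"],
        )
        return cls(
            d=meta["d"],
            config=config,
            conv_w={k: data[f"conv_w_{k}"] for k in config.window_sizes},
            conv_b={k: data[f"conv_b_{k}"] for k in config.window_sizes},
            out_w=data["out_w"],
            out_b=data["out_b"],
            seed=meta["seed"],
        )


def init_parameters(d: int, config: CnnConfig, seed: int) -> CnnParameters:
    rng = np.random.default_rng(seed)
    conv_w, conv_b = {}, {}
    for k in config.window_sizes:
        fan_in = k * d
        limit = np.sqrt(6.0 / (fan_in + config.n_filters))
        conv_w[k] = rng.uniform(-limit, limit, size=(fan_in, config.n_filters))
        conv_b[k] = np.zeros(config.n_filters)
    total = config.n_filters * len(config.window_sizes)
    limit = np.sqrt(6.0 / (total + 2))
    out_w = rng.uniform(-limit, limit, size=(2, total))
    return CnnParameters(
        d=d, config=config, conv_w=conv_w, conv_b=conv_b,
        out_w=out_w, out_b=np.zeros(2), seed=seed,
    )


def _windows(X: np.ndarray, k: int) -> np.ndarray:
    """(B, n, d) -> (B, n-k+1, k*d) concatenated sliding windows."""
    B, n, d = X.shape
    P = n - k + 1
    view = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, P, d, k)
    return np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(B, P, k * d)


def _forward_batch(X: np.ndarray, params: CnnParameters, drop_mask: np.ndarray | None = None):
    """Forward pass on a zero-padded batch; returns (probs, cache)."""
    if X.shape[2] != params.d:
        raise ConfigurationError(
            f"embedding dimension {X.shape[2]} does not match model d={params.d}"
        )
    if X.shape[1] < max(params.config.window_sizes):
        raise ConfigurationError("sentence shorter than the largest window size")
    pooled, cache_k = [], {}
    for k in params.config.window_sizes:
        Xw = _windows(X, k)  # (B, P, k*d)
        Z = Xw @ params.conv_w[k] + params.conv_b[k]  # (B, P, F)
        A = np.maximum(Z, 0.0)
        arg = A.argmax(axis=1)  # (B, F)
        m = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
        pooled.append(m)
        cache_k[k] = (Xw, Z, arg)
    M = np.concatenate(pooled, axis=1)  # (B, KF)
    Md = M * drop_mask if drop_mask is not None else M
    logits = Md @ params.out_w.T + params.out_b  # (B, 2)
    shifted = logits - logits.max(axis=1, keepdims=True)
    expo = np.exp(shifted)
    probs = expo / expo.sum(axis=1, keepdims=True)
    return probs, (X, cache_k, M, Md, drop_mask, probs)


def cnn_forward(embedded: EmbeddedSentence, params: CnnParameters) -> np.ndarray:
    """Class probabilities (other, target) for one embedded sentence."""
    probs, _ = _forward_batch(embedded.matrix[None, :, :], params)
    return probs[0]


def _backward_batch(cache, params: CnnParameters, y: np.ndarray):
    """Cross-entropy gradients for a batch; y is the int class vector."""
    X, cache_k, M, Md, drop_mask, probs = cache
    B = X.shape[0]
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "out_w": dlogits.T @ Md,
        "out_b": dlogits.sum(axis=0),
        "conv_w": {},
        "conv_b": {},
    }
    dMd = dlogits @ params.out_w
    dM = dMd * drop_mask if drop_mask is not None else dMd
    offset = 0
    F = params.config.n_filters
    for k in params.config.window_sizes:
        Xw, Z, arg = cache_k[k]
        dm = dM[:, offset : offset + F]  # (B, F)
        offset += F
        dA = np.zeros_like(Z)
        np.put_along_axis(dA, arg[:, None, :], dm[:, None, :], axis=1)
        dZ = dA * (Z > 0)
        kd = Xw.shape[2]
        grads["conv_w"][k] = Xw.reshape(-1, kd).T @ dZ.reshape(-1, F)
        grads["conv_b"][k] = dZ.sum(axis=(0, 1))
    return grads


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, name: str, param: np.ndarray, grad: np.ndarray) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        m = self.m.setdefault(name, np.zeros_like(param))
        v = self.v.setdefault(name, np.zeros_like(param))
        m *= b1
        m += (1 - b1) * grad
        v *= b2
        v += (1 - b2) * grad * grad
        mhat = m / (1 - b1**self.t)
        vhat = v / (1 - b2**self.t)
        param -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainResult:
    params: CnnParameters
    dev_accuracy: float
    history: list[float] = field(default_factory=list)  # dev accuracy per epoch


def _pad_batch(matrices: list[np.ndarray], min_len: int) -> np.ndarray:
    n = max(min_len, max(m.shape[0] for m in matrices))
    d = matrices[0].shape[1]
    X = np.zeros((len(matrices), n, d))
    for i, m in enumerate(matrices):
        X[i, : m.shape[0], :] = m
    return X


def _accuracy(
    sentences: list[np.ndarray], y: np.ndarray, params: CnnParameters, min_len: int
) -> float:
    correct = 0
    bs = 256
    for i in range(0, len(sentences), bs):
        X = _pad_batch(sentences[i : i + bs], min_len)
        probs, _ = _forward_batch(X, params)
        correct += int((probs.argmax(axis=1) == y[i : i + bs]).sum())
    return correct / len(sentences)


def train_cnn(
    train_sentences: Sequence[tuple[Sequence[str], int]],
    dev_sentences: Sequence[tuple[Sequence[str], int]],
    table: EmbeddingTable,
    config: CnnConfig | None = None,
    seed: int = 0,
) -> TrainResult:
    """Train the sentence CNN; labels are 0 (other) / 1 (target).

    Embeddings are frozen. All randomness (init, shuffling, dropout) flows
    from ``seed``; the returned parameters are the epoch snapshot with the
    best dev accuracy.
    """
    if config is None:
        config = CnnConfig()
    train_labels = {label for _, label in train_sentences}
    if len(train_labels) < 2:
        raise DegenerateInputError("training data must contain both classes")
    min_len = max(config.window_sizes)
    emb_train = [embed_sentence(t, table, min_len).matrix for t, _ in train_sentences]
    y_train = np.array([label for _, label in train_sentences], dtype=int)
    emb_dev = [embed_sentence(t, table, min_len).matrix for t, _ in dev_sentences]
    y_dev = np.array([label for _, label in dev_sentences], dtype=int)

    rng = np.random.default_rng(seed)
    params = init_parameters(table.d, config, seed)
    adam = _Adam(config.learning_rate)
    total_f = config.n_filters * len(config.window_sizes)

    best = params.copy()
    best_acc = -1.0
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(emb_train))
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            X = _pad_batch([emb_train[j] for j in idx], min_len)
            if config.dropout > 0:
                keep = 1.0 - config.dropout
                mask = (rng.random((len(idx), total_f)) < keep) / keep
            else:
                mask = None
            _, cache = _forward_batch(X, params, drop_mask=mask)
            grads = _backward_batch(cache, params, y_train[idx])
            adam.t += 1
            adam.step("out_w", params.out_w, grads["out_w"])
            adam.step("out_b", params.out_b, grads["out_b"])
            for k in config.window_sizes:
                adam.step(f"conv_w_{k}", params.conv_w[k], grads["conv_w"][k])
                adam.step(f"conv_b_{k}", params.conv_b[k], grads["conv_b"][k])
        acc = _accuracy(emb_dev, y_dev, params, min_len)
        history.append(acc)
        if acc > best_acc:
            best_acc = acc
            best = params.copy()
    return TrainResult(params=best, dev_accuracy=best_acc, history=history)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def sentence_scores(
    sentences: Sequence[Sequence[str]], params: CnnParameters, table: EmbeddingTable
) -> np.ndarray:
    """Positive-class probability for each token sequence."""
    min_len = max(params.config.window_sizes)
    if not sentences:
        return np.zeros(0)
    mats = [embed_sentence(t, table, min_len).matrix for t in sentences]
    out = np.zeros(len(mats))
    bs = 256
    for i in range(0, len(mats), bs):
        X = _pad_batch(mats[i : i + bs], min_len)
        probs, _ = _forward_batch(X, params)
        out[i : i + bs] = probs[:, 1]
    return out


def aggregate_document(scores: Sequence[float], tau_pos: float = 0.5) -> Label:
    """Max-probability aggregation: POSITIVE iff any sentence score >= tau.
    The ML path never emits INDETERMINATE."""
    if len(scores) and max(scores) >= tau_pos:
        return Label.POSITIVE
    return Label.NEGATIVE


def classify_document(
    sentences: Sequence[Sequence[str]],
    params: CnnParameters,
    table: EmbeddingTable,
    tau_pos: float | None = None,
) -> Label:
    """Document-level 3-way label (POSITIVE/NEGATIVE only) from sentence
    token sequences."""
    tau = params.config.tau_pos if tau_pos is None else tau_pos
    return aggregate_document(sentence_scores(sentences, params, table), tau)
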