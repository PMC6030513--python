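"""Convolutional neural text classifier.

The architecture is the standard single-layer sentence-classification CNN:
token indices are mapped to word embeddings, banks of linear filters of
widths 1, 3 and 5 slide over adjacent embeddings, each filter's outputs
are rectified and max-pooled to one scalar, the pooled scalars are
concatenated into a document vector, and a softmax output layer yields the
probability that the document reports a randomized trial.

Training minimizes class-weighted cross-entropy with Adam, dropout on the
pooled vector, and a max-norm constraint on the output-layer class weight
vectors applied after every optimizer step. The shipped defaults are the
tuned operating configuration for this task: dropout 0.160, filter sizes
(1, 3, 5) with 150 filters each, max-norm 3.33, two epochs, RCT class
weight 3.86, vocabulary capped at 12500 tokens.

Everything here is plain numpy: forward pass, backpropagation (through
max-pooling via argmax routing and scatter-add into the embedding matrix)
and the optimizer, so training is deterministic under a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .corpus import TokenizedDoc, Vocabulary, PAD_INDEX, OOV_INDEX

__all__ = [
    "CnnHyperparams",
    "FAST_CNN",
    "IndexSequence",
    "ConvModel",
    "encode",
    "predict_proba",
    "predict_proba_batch",
    "train_cnn",
    "load_word2vec_text",
]


@dataclass(frozen=True)
class CnnHyperparams:
    """CNN architecture and training settings.

    ``vocab_size`` is the maximum number of content tokens (the embedding
    matrix has two extra rows for padding and OOV). ``l2_maxnorm`` bounds
    the Euclidean norm of each output-layer class weight vector after
    every update. ``class_weight_rct`` scales the loss of a misclassified
    RCT relative to a non-RCT.
    """

    vocab_size: int = 12500
    embed_dim: int = 200
    max_sequence_length: int = 400
    filter_sizes: tuple[int, ...] = (1, 3, 5)
    n_filters: int = 150
    dropout: float = 0.160
    l2_maxnorm: float = 3.33
    epochs: int = 2
    class_weight_rct: float = 3.86
    class_weight_non: float = 1.0
    batch_size: int = 32
    learning_rate: float = 0.001
    seed: int = 0

    @property
    def pooled_dim(self) -> int:
        return len(self.filter_sizes) * self.n_filters


#: Reduced configuration for desk-scale experiments: same regularization
#: settings, smaller embedding/filter banks and shorter sequences.
FAST_CNN = CnnHyperparams(embed_dim=32, max_sequence_length=200, n_filters=64)


@dataclass
class IndexSequence:
    """Fixed-length vector of vocabulary indices plus the true length."""

    indices: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.true_length > self.indices.shape[0]:
            raise ValueError("true_length exceeds sequence length")


def encode(doc: TokenizedDoc, vocab: Vocabulary, max_len: int) -> IndexSequence:
    """Map tokens (title first, then abstract) to a padded index sequence.

    Unknown tokens get the OOV index 1; sequences are right-padded with 0
    or truncated at ``max_len``.
    """
    idx = vocab.encode(doc.tokens)[:max_len]
    true_length = len(idx)
    padded = np.full(max_len, PAD_INDEX, dtype=np.int64)
    padded[:true_length] = idx
    return IndexSequence(indices=padded, true_length=true_length)


class ConvModel:
    """Trained CNN: embedding matrix, filter banks and softmax output layer."""

    def __init__(self, hyperparams: CnnHyperparams, params: dict[str, np.ndarray]):
        self.hyperparams = hyperparams
        self.params = params
        self.history: list[float] = []  # mean training loss per epoch

    @classmethod
    def initialize(
        cls,
        hyperparams: CnnHyperparams,
        rng: np.random.Generator,
        embedding_init: np.ndarray | None = None,
    ) -> "ConvModel":
        hp = hyperparams
        n_rows = hp.vocab_size + 2  # + padding, OOV
        if embedding_init is not None:
            emb = np.array(embedding_init, dtype=np.float64)
            if emb.shape != (n_rows, hp.embed_dim):
                raise ValueError("embedding_init has wrong shape")
        else:
            emb = rng.normal(0.0, 0.01, size=(n_rows, hp.embed_dim))
        emb[PAD_INDEX] = 0.0
        params: dict[str, np.ndarray] = {"emb": emb}
        for k in hp.filter_sizes:
            fan_in = k * hp.embed_dim
            bound = np.sqrt(6.0 / (fan_in + hp.n_filters))
            params[f"W{k}"] = rng.uniform(-bound, bound, size=(fan_in, hp.n_filters))
            params[f"b{k}"] = np.zeros(hp.n_filters)
        bound = np.sqrt(6.0 / (hp.pooled_dim + 2))
        params["Wout"] = rng.uniform(-bound, bound, size=(hp.pooled_dim, 2))
        params["bout"] = np.zeros(2)
        return cls(hp, params)

    # -- forward -----------------------------------------------------------

    def _forward(
        self,
        idx: np.ndarray,
        lengths: np.ndarray,
        dropout_mask: np.ndarray | None = None,
    ):
        """Forward pass for a batch (B, T) of index rows.

        Returns (probs, cache); cache holds intermediates for backprop.
        """
        hp = self.hyperparams
        kmax = max(hp.filter_sizes)
        eff_len = np.maximum(lengths, kmax)  # padding guarantees >= kmax rows
        E = self.params["emb"][idx]  # (B, T, D)
        B, T, D = E.shape
        pooled_parts, cache_parts = [], []
        for k in hp.filter_sizes:
            P = T - k + 1
            win = sliding_window_view(E, k, axis=1)  # (B, P, D, k)
            win = win.transpose(0, 1, 3, 2).reshape(B, P, k * D)
            Z = win @ self.params[f"W{k}"] + self.params[f"b{k}"]  # (B, P, F)
            A = np.maximum(Z, 0.0)
            n_valid = eff_len - k + 1  # >= 1 by construction
            invalid = np.arange(P)[None, :] >= n_valid[:, None]
            A = np.where(invalid[:, :, None], -1.0, A)
            arg = A.argmax(axis=1)  # (B, F)
            pooled = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
            pooled_parts.append(pooled)
            cache_parts.append((k, win, Z, arg))
        x = np.concatenate(pooled_parts, axis=1)  # (B, pooled_dim)
        if dropout_mask is not None:
            xd = x * dropout_mask
        else:
            xd = x
        logits = xd @ self.params["Wout"] + self.params["bout"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        cache = (idx, E, cache_parts, x, xd, dropout_mask, probs)
        return probs, cache

    def _backward(self, cache, y: np.ndarray, sample_weights: np.ndarray):
        """Gradients of the mean weighted cross-entropy for the batch."""
        hp = self.hyperparams
        idx, E, cache_parts, x, xd, dropout_mask, probs = cache
        B, T, D = E.shape
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (sample_weights / B)[:, None]
        grads["Wout"] = xd.T @ dlogits
        grads["bout"] = dlogits.sum(axis=0)
        dxd = dlogits @ self.params["Wout"].T
        dx = dxd * dropout_mask if dropout_mask is not None else dxd
        dE = np.zeros_like(E)
        off = 0
        for k, win, Z, arg in cache_parts:
            F = hp.n_filters
            dpooled = dx[:, off : off + F]
            off += F
            P = Z.shape[1]
            bb = np.arange(B)[:, None]
            ff = np.arange(F)[None, :]
            z_sel = Z[bb, arg, ff]
            dz_sel = dpooled * (z_sel > 0.0)
            dZ = np.zeros_like(Z)
            dZ[bb, arg, ff] = dz_sel
            grads[f"W{k}"] = np.tensordot(win, dZ, axes=([0, 1], [0, 1]))
            grads[f"b{k}"] = dZ.sum(axis=(0, 1))
            dwin = (dZ @ self.params[f"W{k}"].T).reshape(B, P, k, D)
            for j in range(k):
                dE[:, j : j + P, :] += dwin[:, :, j, :]
        gemb = np.zeros_like(self.params["emb"])
        np.add.at(gemb, idx.ravel(), dE.reshape(-1, D))
        gemb[PAD_INDEX] = 0.0  # padding embedding stays fixed at zero
        grads["emb"] = gemb
        return grads

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            format_version=np.array([1]),
            hyperparams=np.array(json.dumps(asdict(self.hyperparams))),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConvModel":
        with np.load(path, allow_pickle=False) as z:
            hp_d = json.loads(str(z["hyperparams"]))
            hp_d["filter_sizes"] = tuple(hp_d["filter_sizes"])
            hp = CnnHyperparams(**hp_d)
            params = {
                k: z[k]
                for k in z.files
                if k not in ("format_version", "hyperparams")
            }
        return cls(hp, params)


def _stack(seqs: Sequence[IndexSequence]) -> tuple[np.ndarray, np.ndarray]:
    idx = np.stack([s.indices for s in seqs])
    lengths = np.array([s.true_length for s in seqs])
    return idx, lengths


def predict_proba(model: ConvModel, seq: IndexSequence) -> float:
    """Probability that one document reports an RCT (dropout disabled)."""
    return float(predict_proba_batch(model, [seq])[0])


def predict_proba_batch(model: ConvModel, seqs: Sequence[IndexSequence]) -> np.ndarray:
    idx, lengths = _stack(seqs)
    probs, _ = model._forward(idx, lengths, dropout_mask=None)
    return probs[:, 1]


def _maxnorm_project(W: np.ndarray, c: float) -> None:
    # constrain each class weight vector (column) to Euclidean norm <= c
    norms = np.linalg.norm(W, axis=0)
    scale = np.minimum(1.0, c / np.maximum(norms, 1e-12))
    W *= scale[None, :]


def train_cnn(
    sequences: Sequence[IndexSequence],
    labels: Sequence[int],
    hyperparams: CnnHyperparams | None = None,
    embedding_init: np.ndarray | None = None,
) -> ConvModel:
    """Train the CNN with Adam on class-weighted cross-entropy.

    Runs ``epochs`` shuffled passes in minibatches; dropout is applied to
    the pooled document vector only; after every optimizer step each
    output-layer class weight vector is rescaled to norm <=
    ``l2_maxnorm``. Deterministic under ``hyperparams.seed``. The returned
    model's ``history`` holds the mean training loss per epoch.
    """
    hp = hyperparams or CnnHyperparams()
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    rng = np.random.default_rng(hp.seed)
    model = ConvModel.initialize(hp, rng, embedding_init)
    idx_all, len_all = _stack(sequences)
    n = idx_all.shape[0]
    w_class = np.array([hp.class_weight_non, hp.class_weight_rct])

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    keep = 1.0 - hp.dropout

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            batch = order[start : start + hp.batch_size]
            bidx, blen, by = idx_all[batch], len_all[batch], y[batch]
            if hp.dropout > 0.0:
                mask = (rng.random((len(batch), hp.pooled_dim)) < keep) / keep
            else:
                mask = None
            probs, cache = model._forward(bidx, blen, dropout_mask=mask)
            sw = w_class[by]
            p_true = np.clip(probs[np.arange(len(batch)), by], 1e-12, None)
            losses.append(float(np.mean(sw * -np.log(p_true))))
            grads = model._backward(cache, by, sw)
            t += 1
            lr_t = hp.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                model.params[key] -= lr_t * m[key] / (np.sqrt(v[key]) + eps)
            model.params["emb"][PAD_INDEX] = 0.0
            _maxnorm_project(model.params["Wout"], hp.l2_maxnorm)
        model.history.append(float(np.mean(losses)))
    return model


def load_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    """Read a word2vec text-format embedding file (header ``count dim``)."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected 'count dim' header line")
        _, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"bad embedding row for token {parts[0]!r}")
            vectors[parts[0]] = np.array(parts[1:], dtype=np.float64)
    return vectors


def embedding_matrix_from_word2vec(
    vocab: Vocabulary,
    hyperparams: CnnHyperparams,
    vectors: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial embedding matrix with pretrained rows for matching tokens."""
    hp = hyperparams
    emb = rng.normal(0.0, 0.01, size=(hp.vocab_size + 2, hp.embed_dim))
    emb[PAD_INDEX] = 0.0
    for tok, i in vocab.token_to_index.items():
        vec = vectors.get(tok)
        if vec is not None and vec.shape[0] == hp.embed_dim and i < emb.shape[0]:
            emb[i] = vec
    return emb
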