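"""Bag-of-words linear SVM scorer.

Documents are represented as sparse term-count vectors over a fixed
vocabulary (optionally tf-idf weighted, optionally with a disjoint block
of binary title-presence indicators) and classified by a linear SVM
trained with stochastic gradient descent on the class-weighted hinge loss
with L2 regularization. The shipped default hyperparameters are the tuned
operating configuration for this task: RCT class weight 12.4, alpha
0.00092, 66 epochs, unigrams, hinge loss.

The model's raw output is an unconstrained decision score
``w . x + b``; mean and standard deviation of the training-set scores are
stored on the model so the ensemble layer can z-normalize them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import SGDClassifier

from .corpus import TokenizedDoc, Vocabulary

__all__ = [
    "FeatureConfig",
    "SvmHyperparams",
    "LinearModel",
    "ngram_tokens",
    "vectorize",
    "vectorize_all",
    "fit_idf",
    "train_svm",
    "decision_score",
    "decision_scores",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature extraction settings for the linear path.

    ngram_order : include n-grams up to this order (joined with ``_``);
    the vocabulary must have been built over the same n-gram stream.
    title_indicators : append a disjoint block of binary flags for
    vocabulary terms appearing in the title.
    tfidf : reweight counts by smoothed log inverse document frequency
    (requires idf weights fitted on the training corpus).
    """

    ngram_order: int = 1
    title_indicators: bool = False
    tfidf: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.ngram_order <= 3:
            raise ValueError("ngram_order must be 1, 2 or 3")


@dataclass(frozen=True)
class SvmHyperparams:
    class_weight_rct: float = 12.4
    class_weight_non: float = 1.0
    l2_alpha: float = 0.00092
    n_iterations: int = 66
    loss: str = "hinge"
    shuffle_seed: int = 42


@dataclass
class LinearModel:
    """Trained linear SVM: weight vector, bias and training-score stats."""

    weights: np.ndarray
    bias: float
    hyperparams: SvmHyperparams
    feature_config: FeatureConfig
    training_score_stats: tuple[float, float]  # (mean, sd) of decision scores

    @property
    def n_features(self) -> int:
        return int(self.weights.shape[0])

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            format_version=np.array([1]),
            weights=self.weights,
            bias=np.array([self.bias]),
            stats=np.array(self.training_score_stats),
            hyperparams=np.array(json.dumps(asdict(self.hyperparams))),
            feature_config=np.array(json.dumps(asdict(self.feature_config))),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                weights=z["weights"],
                bias=float(z["bias"][0]),
                hyperparams=SvmHyperparams(**json.loads(str(z["hyperparams"]))),
                feature_config=FeatureConfig(**json.loads(str(z["feature_config"]))),
                training_score_stats=tuple(z["stats"]),
            )


def ngram_tokens(tokens: Sequence[str], order: int) -> list[str]:
    """Unigrams through *order*-grams, n-grams joined with underscores."""
    out = list(tokens)
    for n in range(2, order + 1):
        out.extend("_".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
    return out


def _feature_dim(vocab: Vocabulary, config: FeatureConfig) -> int:
    n = len(vocab)
    return 2 * n if config.title_indicators else n


def vectorize(
    doc: TokenizedDoc,
    vocab: Vocabulary,
    config: FeatureConfig | None = None,
    idf: np.ndarray | None = None,
) -> dict[int, float]:
    """Sparse index->value feature map for one document.

    Column ``vocab_index - 2`` carries the (n-gram) term count; tokens
    outside the vocabulary contribute nothing (the linear path has no OOV
    feature). With ``title_indicators`` a second block of the same width
    holds binary flags for title terms. With ``tfidf``, counts are
    multiplied by the fitted idf weights.
    """
    config = config or FeatureConfig()
    if len(doc) == 0:
        raise ValueError("cannot vectorize an empty document")
    if config.tfidf and idf is None:
        raise ValueError("tfidf requested but no idf weights supplied")
    n = len(vocab)
    vec: dict[int, float] = {}
    for tok in ngram_tokens(doc.tokens, config.ngram_order):
        idx = vocab.token_to_index.get(tok)
        if idx is not None:
            col = idx - 2
            vec[col] = vec.get(col, 0.0) + 1.0
    if config.tfidf:
        for col in list(vec):
            vec[col] *= float(idf[col])
    if config.title_indicators:
        title_tokens = [t for t, flag in zip(doc.tokens, doc.in_title) if flag]
        for tok in ngram_tokens(title_tokens, config.ngram_order):
            idx = vocab.token_to_index.get(tok)
            if idx is not None:
                vec[n + idx - 2] = 1.0
    return vec


def vectorize_all(
    docs: Sequence[TokenizedDoc],
    vocab: Vocabulary,
    config: FeatureConfig | None = None,
    idf: np.ndarray | None = None,
) -> sp.csr_matrix:
    """CSR matrix of :func:`vectorize` rows (shape n_docs x n_features)."""
    config = config or FeatureConfig()
    dim = _feature_dim(vocab, config)
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        for col, v in vectorize(doc, vocab, config, idf).items():
            rows.append(i)
            cols.append(col)
            vals.append(v)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(docs), dim))


def fit_idf(
    docs: Sequence[TokenizedDoc], vocab: Vocabulary, config: FeatureConfig | None = None
) -> np.ndarray:
    """Smoothed idf weights ``log((1+N)/(1+df)) + 1`` per count column."""
    config = config or FeatureConfig()
    n_cols = len(vocab)
    df = np.zeros(n_cols)
    for doc in docs:
        seen = set()
        for tok in ngram_tokens(doc.tokens, config.ngram_order):
            idx = vocab.token_to_index.get(tok)
            if idx is not None:
                seen.add(idx - 2)
        for col in seen:
            df[col] += 1
    n = len(docs)
    return np.log((1.0 + n) / (1.0 + df)) + 1.0


def _as_matrix(vectors, dim: int | None = None) -> sp.csr_matrix:
    if sp.issparse(vectors):
        return vectors.tocsr()
    # list of index->value maps
    if dim is None:
        dim = 1 + max((max(v) for v in vectors if v), default=0)
    rows, cols, vals = [], [], []
    for i, v in enumerate(vectors):
        for c, x in v.items():
            rows.append(i)
            cols.append(c)
            vals.append(x)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(vectors), dim))


def train_svm(
    vectors,
    labels: Sequence[int],
    hyperparams: SvmHyperparams | None = None,
    feature_config: FeatureConfig | None = None,
    n_features: int | None = None,
) -> LinearModel:
    """Fit the class-weighted hinge-loss SGD SVM.

    ``vectors`` may be a CSR matrix or a list of sparse index->value maps.
    Runs exactly ``n_iterations`` full passes (no early stopping); a
    misclassified RCT costs ``class_weight_rct / class_weight_non`` times a
    non-RCT error. Reproducible bit-for-bit under ``shuffle_seed``.
    """
    hp = hyperparams or SvmHyperparams()
    X = _as_matrix(vectors, n_features)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    clf = SGDClassifier(
        loss=hp.loss,
        penalty="l2",
        alpha=hp.l2_alpha,
        max_iter=hp.n_iterations,
        tol=None,
        shuffle=True,
        random_state=hp.shuffle_seed,
        class_weight={1: hp.class_weight_rct, 0: hp.class_weight_non},
    )
    clf.fit(X, y)
    scores = clf.decision_function(X)
    sd = float(np.std(scores, ddof=1))
    return LinearModel(
        weights=np.asarray(clf.coef_).ravel().copy(),
        bias=float(clf.intercept_[0]),
        hyperparams=hp,
        feature_config=feature_config or FeatureConfig(),
        training_score_stats=(float(np.mean(scores)), sd),
    )


def decision_score(model: LinearModel, vector) -> float:
    """Raw SVM decision score ``w . x + b`` for one document.

    Accepts a sparse index->value map or a 1 x n_features sparse/dense row.
    Linear and exactly additive over feature decomposition.
    """
    w, b = model.weights, model.bias
    if isinstance(vector, dict):
        if vector and max(vector) >= w.shape[0]:
            raise ValueError("feature index out of range for this model")
        return float(sum(w[i] * v for i, v in vector.items()) + b)
    if sp.issparse(vector):
        if vector.shape[1] != w.shape[0]:
            raise ValueError("feature dimension mismatch")
        return float(vector @ w + b)
    vec = np.asarray(vector).ravel()
    if vec.shape[0] != w.shape[0]:
        raise ValueError("feature dimension mismatch")
    return float(vec @ w + b)


def decision_scores(model: LinearModel, X: sp.spmatrix) -> np.ndarray:
    """Vectorized decision scores for a CSR matrix of documents."""
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError("feature dimension mismatch")
    return np.asarray(X @ model.weights).ravel() + model.bias
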