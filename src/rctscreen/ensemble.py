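"""Balanced-undersample bagging, score normalization and ensembling.

Trial reports are a small minority of any citation corpus. The training
strategy here counters that imbalance by *balanced sampling*: each
training subset keeps every positive and a random subsample of negatives
(a configurable number of non-RCTs per RCT), and the procedure is
repeated to train a bag of models whose consensus is the arithmetic mean
of their scores.

Heterogeneous model families produce scores on different scales (the SVM
an unconstrained decision value, the CNN a probability, the
publication-type tag a 0/1 vote), so each member's scores are z-normalized
with mean and standard deviation computed on the training set, and the
final ensemble score is the sum of normalized member scores. Where the PT
tag exists (present or absent) the with-PT ensemble is used; where the
record carries no PT information at all, scoring falls back to the best
text-only ensemble (hybrid routing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import Citation, PtTag

__all__ = [
    "BaggedEnsemble",
    "ScoreNormalizer",
    "EnsembleSpec",
    "RoutedScore",
    "balanced_subsample",
    "train_bagged",
    "consensus_score",
    "consensus_scores",
    "fit_normalizer",
    "ensemble_score",
    "route_hybrid",
    "pt_vote",
]

#: Default negatives kept per positive in each balanced subsample.
SVM_SAMPLING_RATIO = 9.2
CNN_SAMPLING_RATIO = 6.0

#: Default number of bagged models per family.
DEFAULT_N_MODELS = 25


def balanced_subsample(
    labels: Sequence[int], ratio: float, seed: int
) -> np.ndarray:
    """Indices of all positives plus ``round(ratio * n_pos)`` negatives.

    Negatives are sampled uniformly without replacement; if fewer are
    available than requested, all are kept and a warning is emitted.
    Deterministic under *seed*.
    """
    if ratio <= 0:
        raise ValueError("sampling ratio must be positive")
    y = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    n_neg = round(ratio * len(pos))
    if n_neg > len(neg):
        warnings.warn(
            f"requested {n_neg} negatives but only {len(neg)} available; keeping all",
            stacklevel=2,
        )
        n_neg = len(neg)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(np.concatenate([pos, chosen]))


@dataclass
class BaggedEnsemble:
    """Bag of models of one family trained on balanced subsamples.

    ``score_fn(model, items)`` must return an array of raw scores (decision
    values or probabilities) for a sequence of documents. The consensus
    rule is fixed: the arithmetic mean of component scores.
    """

    components: list
    score_fn: Callable[[object, Sequence], np.ndarray]
    sampling_ratio: float
    component_seeds: list[int] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.components)


def train_bagged(
    trainer: Callable[[np.ndarray, int], object],
    labels: Sequence[int],
    score_fn: Callable[[object, Sequence], np.ndarray],
    n_models: int = DEFAULT_N_MODELS,
    ratio: float = SVM_SAMPLING_RATIO,
    base_seed: int = 0,
) -> BaggedEnsemble:
    """Train ``n_models`` components on balanced subsamples.

    Component *k* is trained by ``trainer(indices, seed)`` on
    ``balanced_subsample(labels, ratio, base_seed + k)`` with seed
    ``base_seed + k``. Trainer failures are re-raised with the component
    index attached.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    components, seeds = [], []
    for k in range(n_models):
        seed = base_seed + k
        idx = balanced_subsample(labels, ratio, seed)
        try:
            components.append(trainer(idx, seed))
        except Exception as exc:  # noqa: BLE001 - context added, then re-raised
            raise RuntimeError(f"training component {k} failed: {exc}") from exc
        seeds.append(seed)
    return BaggedEnsemble(
        components=components,
        score_fn=score_fn,
        sampling_ratio=ratio,
        component_seeds=seeds,
    )


def consensus_scores(ensemble: BaggedEnsemble, items: Sequence) -> np.ndarray:
    """Mean of component scores for each item (the bagging consensus)."""
    if ensemble.n_models == 0:
        raise ValueError("empty ensemble")
    n = items.shape[0] if sp.issparse(items) else len(items)
    acc = np.zeros(n)
    for model in ensemble.components:
        acc += np.asarray(ensemble.score_fn(model, items), dtype=float)
    return acc / ensemble.n_models


def consensus_score(ensemble: BaggedEnsemble, item) -> float:
    return float(consensus_scores(ensemble, [item])[0])


class ScoreNormalizer:
    """Per-member z-normalization statistics fitted on training scores."""

    def __init__(self, stats: dict[str, tuple[float, float]]):
        for member, (_, sd) in stats.items():
            if not sd > 0:
                raise ValueError(f"member {member!r} has zero score variance")
        self.stats = stats

    def normalize(self, member: str, score: float) -> float:
        mean, sd = self.stats[member]
        return (score - mean) / sd

    def members(self) -> set[str]:
        return set(self.stats)


def fit_normalizer(training_scores: Mapping[str, Sequence[float]]) -> ScoreNormalizer:
    """Fit per-member (mean, sample sd) from training-set score streams.

    The PT tag stream is normalized from its 0/1 training values like any
    other member. A member with fewer than two distinct scores has zero
    variance and is rejected by name.
    """
    stats: dict[str, tuple[float, float]] = {}
    for member, scores in training_scores.items():
        arr = np.asarray(scores, dtype=float)
        if arr.size < 2:
            raise ValueError(f"member {member!r} needs at least 2 scores")
        sd = float(np.std(arr, ddof=1))
        if sd == 0.0:
            raise ValueError(f"member {member!r} has zero score variance")
        stats[member] = (float(np.mean(arr)), sd)
    return ScoreNormalizer(stats)


@dataclass
class EnsembleSpec:
    """Which members vote, and the normalizer that puts them on one scale."""

    members: tuple[str, ...]
    normalizer: ScoreNormalizer

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        missing = set(self.members) - self.normalizer.members()
        if missing:
            raise ValueError(f"normalizer lacks stats for members: {sorted(missing)}")


def ensemble_score(spec: EnsembleSpec, member_scores: Mapping[str, float]) -> float:
    """Sum of z-normalized member scores.

    ``member_scores`` must cover exactly ``spec.members``; monotone
    increasing in each raw member score.
    """
    if set(member_scores) != set(spec.members):
        raise ValueError(
            f"member scores {sorted(member_scores)} do not match spec members "
            f"{sorted(spec.members)}"
        )
    return float(
        sum(spec.normalizer.normalize(m, member_scores[m]) for m in spec.members)
    )


def pt_vote(tag: PtTag) -> float:
    """The PT tag as a binary classifier vote: present=1, absent=0."""
    if tag is PtTag.PRESENT:
        return 1.0
    if tag is PtTag.ABSENT:
        return 0.0
    raise ValueError("PT vote undefined for UNKNOWN tag; use route_hybrid")


@dataclass
class RoutedScore:
    """Hybrid-routing outcome: the score and which ensemble produced it."""

    score: float
    path: str  # "with_pt" or "text_only"


def route_hybrid(
    citation: Citation,
    with_pt_spec: EnsembleSpec,
    text_only_spec: EnsembleSpec,
    text_scores: Mapping[str, float],
) -> RoutedScore:
    """Score one citation, using PT information where it exists.

    A record whose PT status is known (tag present *or* absent — absence
    of the tag on an indexed record is an informative 0-vote) is scored by
    the with-PT ensemble; a record with no PT information at all falls
    back to the text-only ensemble. ``text_scores`` supplies the raw
    scores of the text members (e.g. ``{"svm": ..., "cnn": ...}``).
    """
    if citation.pt_rct_tag is PtTag.UNKNOWN:
        scores = {m: text_scores[m] for m in text_only_spec.members}
        return RoutedScore(score=ensemble_score(text_only_spec, scores), path="text_only")
    scores = {
        m: (pt_vote(citation.pt_rct_tag) if m == "pt_tag" else text_scores[m])
        for m in with_pt_spec.members
    }
    return RoutedScore(score=ensemble_score(with_pt_spec, scores), path="with_pt")
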