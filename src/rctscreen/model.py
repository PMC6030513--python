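"""High-level screening model: fit once, inspect, predict, persist.

:class:`RCTScreeningModel` wraps the full training pipeline — tokenize,
build vocabulary, train bagged SVM and CNN ensembles on balanced
subsamples, fit the score normalizer (with the publication-type tag as an
extra binary voter where tags exist), and calibrate use-case thresholds
on a held-out split. :meth:`RCTScreeningModel.fit` returns an
:class:`RCTScreeningResults` carrying the fitted components, held-out
AUROC estimates with DeLong confidence intervals, the calibrated
operating points, a :meth:`~RCTScreeningResults.summary` table, and
prediction/persistence methods.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import conv, ensemble as ens, evaluation as ev, linear
from .corpus import (
    Citation,
    Label,
    PtTag,
    TokenizedDoc,
    Vocabulary,
    build_vocabulary,
    read_ris,
    tokenize,
)

__all__ = ["UseCasePreset", "PRESETS", "ScreeningConfig", "RCTScreeningModel", "RCTScreeningResults"]


@dataclass(frozen=True)
class UseCasePreset:
    """A named screening use case and its operating target.

    ``systematic_review`` fixes a sensitivity floor of 0.985 (miss
    essentially nothing, at the price of more manual screening);
    ``rapid_review`` fixes a specificity floor of 0.975 (high precision,
    accepting modestly lower sensitivity).
    """

    name: str
    target_kind: str  # "sensitivity" or "specificity"
    target: float


PRESETS = {
    "systematic_review": UseCasePreset("systematic_review", "sensitivity", 0.985),
    "rapid_review": UseCasePreset("rapid_review", "specificity", 0.975),
}


@dataclass
class ScreeningConfig:
    """Everything that governs a training run.

    The defaults are the tuned operating configuration: 25 bagged models
    per family, sampling ratios 9.2 (SVM) and 6.0 (CNN) negatives per
    positive, vocabulary capped at 12500 tokens. ``fast()`` returns a
    desk-scale preset (7 CNN components — bagging gains plateau around
    6-7 models — and the reduced CNN architecture).
    """

    svm: linear.SvmHyperparams = field(default_factory=linear.SvmHyperparams)
    cnn: conv.CnnHyperparams = field(default_factory=conv.CnnHyperparams)
    features: linear.FeatureConfig = field(default_factory=linear.FeatureConfig)
    vocab_size: int = 12500
    n_models_svm: int = ens.DEFAULT_N_MODELS
    n_models_cnn: int = ens.DEFAULT_N_MODELS
    ratio_svm: float = ens.SVM_SAMPLING_RATIO
    ratio_cnn: float = ens.CNN_SAMPLING_RATIO
    holdout_fraction: float = 0.2
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0) -> "ScreeningConfig":
        return cls(cnn=conv.FAST_CNN, n_models_cnn=7, n_models_svm=10, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cnn"]["filter_sizes"] = list(d["cnn"]["filter_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningConfig":
        d = dict(d)
        d["svm"] = linear.SvmHyperparams(**d["svm"])
        cnn_d = dict(d["cnn"])
        cnn_d["filter_sizes"] = tuple(cnn_d["filter_sizes"])
        d["cnn"] = conv.CnnHyperparams(**cnn_d)
        d["features"] = linear.FeatureConfig(**d["features"])
        return cls(**d)


def _binary_labels(citations: Sequence[Citation]) -> np.ndarray:
    labels = []
    for c in citations:
        if c.label is Label.UNLABELED:
            raise ValueError(f"citation {c.record_id} is unlabeled; cannot train")
        labels.append(1 if c.label is Label.RCT else 0)
    return np.array(labels, dtype=int)


class RCTScreeningModel:
    """Trial-report screening classifier, built from a labeled corpus."""

    def __init__(self, citations: Sequence[Citation], config: ScreeningConfig | None = None):
        self.citations = list(citations)
        self.config = config or ScreeningConfig()
        self.labels = _binary_labels(self.citations)
        if self.labels.sum() == 0 or self.labels.sum() == len(self.labels):
            raise ValueError("training corpus must contain both classes")

    @classmethod
    def from_ris(cls, path: str | Path, config: ScreeningConfig | None = None) -> "RCTScreeningModel":
        """Build from an RIS file whose records carry gold labels."""
        return cls(read_ris(path), config=config)

    def fit(self) -> "RCTScreeningResults":
        """Train everything and return the fitted results object."""
        cfg = self.config
        n = len(self.citations)
        idx_all = np.arange(n)
        train_idx, hold_idx = train_test_split(
            idx_all,
            test_size=cfg.holdout_fraction,
            stratify=self.labels,
            random_state=cfg.seed,
        )
        train_idx = np.sort(train_idx)
        hold_idx = np.sort(hold_idx)

        docs = [tokenize(c) for c in self.citations]
        empty = [self.citations[i].record_id for i, d in enumerate(docs) if len(d) == 0]
        if empty:
            raise ValueError(f"empty documents after tokenization: {empty[:5]}")
        vocab = build_vocabulary([docs[i] for i in train_idx], cfg.vocab_size)

        y_train = self.labels[train_idx]

        # --- linear family ---
        idf = (
            linear.fit_idf([docs[i] for i in train_idx], vocab, cfg.features)
            if cfg.features.tfidf
            else None
        )
        X = linear.vectorize_all(docs, vocab, cfg.features, idf)
        X_train = X[train_idx]

        def svm_trainer(sub_idx: np.ndarray, seed: int):
            hp = replace(cfg.svm, shuffle_seed=seed)
            return linear.train_svm(
                X_train[sub_idx], y_train[sub_idx], hp, cfg.features
            )

        svm_bag = ens.train_bagged(
            svm_trainer,
            y_train,
            score_fn=linear.decision_scores,
            n_models=cfg.n_models_svm,
            ratio=cfg.ratio_svm,
            base_seed=cfg.seed,
        )

        # --- convolutional family ---
        cnn_hp = replace(cfg.cnn, vocab_size=len(vocab))
        seqs = [conv.encode(d, vocab, cnn_hp.max_sequence_length) for d in docs]
        seqs_train = [seqs[i] for i in train_idx]

        def cnn_trainer(sub_idx: np.ndarray, seed: int):
            hp = replace(cnn_hp, seed=seed)
            return conv.train_cnn(
                [seqs_train[i] for i in sub_idx], y_train[sub_idx], hp
            )

        cnn_bag = ens.train_bagged(
            cnn_trainer,
            y_train,
            score_fn=conv.predict_proba_batch,
            n_models=cfg.n_models_cnn,
            ratio=cfg.ratio_cnn,
            base_seed=cfg.seed + 1000,
        )

        # --- normalizer from training-set consensus scores ---
        train_streams: dict[str, np.ndarray] = {
            "svm": ens.consensus_scores(svm_bag, X_train),
            "cnn": ens.consensus_scores(cnn_bag, seqs_train),
        }
        pt_known = [
            self.citations[i].pt_rct_tag is not PtTag.UNKNOWN for i in train_idx
        ]
        has_pt = any(pt_known)
        if has_pt:
            votes = [
                ens.pt_vote(self.citations[i].pt_rct_tag)
                for i, known in zip(train_idx, pt_known)
                if known
            ]
            train_streams["pt_tag"] = np.asarray(votes)
        normalizer = ens.fit_normalizer(train_streams)

        text_spec = ens.EnsembleSpec(members=("svm", "cnn"), normalizer=normalizer)
        with_pt_spec = (
            ens.EnsembleSpec(members=("svm", "cnn", "pt_tag"), normalizer=normalizer)
            if has_pt
            else text_spec
        )

        results = RCTScreeningResults(
            config=cfg,
            vocab=vocab,
            idf=idf,
            svm_bag=svm_bag,
            cnn_bag=cnn_bag,
            normalizer=normalizer,
            text_spec=text_spec,
            with_pt_spec=with_pt_spec,
            train_idx=train_idx,
            holdout_idx=hold_idx,
            model=self,
        )
        results._evaluate_holdout()
        return results


@dataclass
class RCTScreeningResults:
    """Fitted screening pipeline plus held-out diagnostics."""

    config: ScreeningConfig
    vocab: Vocabulary
    idf: np.ndarray | None
    svm_bag: ens.BaggedEnsemble
    cnn_bag: ens.BaggedEnsemble
    normalizer: ens.ScoreNormalizer
    text_spec: ens.EnsembleSpec
    with_pt_spec: ens.EnsembleSpec
    train_idx: np.ndarray | None = None
    holdout_idx: np.ndarray | None = None
    model: RCTScreeningModel | None = None
    auroc_: dict[str, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    operating_points_: dict[str, ev.OperatingPoint] = field(default_factory=dict)

    # -- scoring -----------------------------------------------------------

    def member_scores(self, citations: Sequence[Citation]) -> dict[str, np.ndarray]:
        """Raw consensus scores of each text member for new citations."""
        docs = [tokenize(c) for c in citations]
        for c, d in zip(citations, docs):
            if len(d) == 0:
                raise ValueError(f"citation {c.record_id} is empty after tokenization")
        X = linear.vectorize_all(docs, self.vocab, self.config.features, self.idf)
        seqs = [
            conv.encode(d, self.vocab, self.config.cnn.max_sequence_length)
            for d in docs
        ]
        return {
            "svm": ens.consensus_scores(self.svm_bag, X),
            "cnn": ens.consensus_scores(self.cnn_bag, seqs),
        }

    def predict(self, citations: Sequence[Citation]) -> list[ens.RoutedScore]:
        """Hybrid-routed ensemble score for each citation."""
        member = self.member_scores(citations)
        out = []
        for i, c in enumerate(citations):
            out.append(
                ens.route_hybrid(
                    c,
                    self.with_pt_spec,
                    self.text_spec,
                    {"svm": member["svm"][i], "cnn": member["cnn"][i]},
                )
            )
        return out

    def scores(self, citations: Sequence[Citation]) -> np.ndarray:
        return np.array([r.score for r in self.predict(citations)])

    # -- evaluation --------------------------------------------------------

    def _evaluate_holdout(self) -> None:
        if self.model is None or self.holdout_idx is None:
            return
        cits = [self.model.citations[i] for i in self.holdout_idx]
        y = self.model.labels[self.holdout_idx]
        member = self.member_scores(cits)
        streams: dict[str, np.ndarray] = dict(member)
        routed = self.predict(cits)
        streams["hybrid"] = np.array([r.score for r in routed])
        for name, s in streams.items():
            _, auc = ev.roc_and_auroc(s, y)
            ci = ev.auroc_ci(s, y)
            self.auroc_[name] = (auc, ci)
        hybrid = streams["hybrid"]
        for preset in PRESETS.values():
            kwargs = {f"target_{preset.target_kind}": preset.target}
            self.operating_points_[preset.name] = ev.calibrate_threshold(
                hybrid, y, **kwargs
            )

    def evaluate(self, citations: Sequence[Citation]) -> dict:
        """AUROC (with CI) and preset operating points on a labeled set."""
        y = _binary_labels(citations)
        s = self.scores(citations)
        _, auc = ev.roc_and_auroc(s, y)
        ci = ev.auroc_ci(s, y)
        points = {}
        for preset in PRESETS.values():
            kwargs = {f"target_{preset.target_kind}": preset.target}
            op = ev.calibrate_threshold(s, y, **kwargs)
            points[preset.name] = dataclasses.asdict(op)
        return {"auroc": auc, "auroc_ci": list(ci), "operating_points": points}

    def threshold_for(self, preset_name: str) -> float:
        return self.operating_points_[preset_name].threshold

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text fit report: data sizes, held-out AUROCs, presets."""
        cfg = self.config
        lines = ["RCT screening model", "=" * 52]
        if self.model is not None:
            n = len(self.model.citations)
            n_pos = int(self.model.labels.sum())
            lines += [
                f"Corpus: {n} citations ({n_pos} RCTs, prevalence {n_pos / n:.1%})",
                f"Train/holdout: {len(self.train_idx)}/{len(self.holdout_idx)}",
            ]
        lines += [
            f"Vocabulary: {len(self.vocab)} tokens (cap {cfg.vocab_size})",
            f"SVM bag: {self.svm_bag.n_models} models, ratio {self.svm_bag.sampling_ratio}",
            f"CNN bag: {self.cnn_bag.n_models} models, ratio {self.cnn_bag.sampling_ratio}",
            "",
            f"{'Held-out AUROC':<16}{'estimate':>10}{'95% CI':>22}",
            "-" * 48,
        ]
        for name, (auc, (lo, hi)) in self.auroc_.items():
            lines.append(f"{name:<16}{auc:>10.3f}{f'({lo:.3f}-{hi:.3f})':>22}")
        if self.operating_points_:
            lines += [
                "",
                f"{'Use case':<20}{'thresh':>9}{'sens':>7}{'spec':>7}{'prec':>7}{'NNS':>7}",
                "-" * 57,
            ]
            for name, op in self.operating_points_.items():
                lines.append(
                    f"{name:<20}{op.threshold:>9.3f}{op.sensitivity:>7.3f}"
                    f"{op.specificity:>7.3f}{op.precision:>7.3f}{op.nns:>7.1f}"
                )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a model bundle (manifest + component weight files)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        ranked = sorted(self.vocab.token_to_index.items(), key=lambda kv: kv[1])
        manifest = {
            "format_version": 1,
            "config": self.config.to_dict(),
            "vocab": [tok for tok, _ in ranked],
            "vocab_max_size": self.vocab.max_size,
            "normalizer": {k: list(v) for k, v in self.normalizer.stats.items()},
            "text_members": list(self.text_spec.members),
            "with_pt_members": list(self.with_pt_spec.members),
            "svm_seeds": self.svm_bag.component_seeds,
            "cnn_seeds": self.cnn_bag.component_seeds,
            "auroc": {k: [v[0], list(v[1])] for k, v in self.auroc_.items()},
            "operating_points": {
                k: dataclasses.asdict(v) for k, v in self.operating_points_.items()
            },
            "has_idf": self.idf is not None,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2), "utf-8")
        if self.idf is not None:
            np.savez(d / "idf.npz", idf=self.idf)
        for i, m in enumerate(self.svm_bag.components):
            m.save(d / f"svm_{i:02d}.npz")
        for i, m in enumerate(self.cnn_bag.components):
            m.save(d / f"cnn_{i:02d}.npz")

    @classmethod
    def load(cls, directory: str | Path) -> "RCTScreeningResults":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text("utf-8"))
        cfg = ScreeningConfig.from_dict(manifest["config"])
        vocab = Vocabulary(
            {tok: i + 2 for i, tok in enumerate(manifest["vocab"])},
            max_size=manifest["vocab_max_size"],
        )
        idf = None
        if manifest.get("has_idf"):
            with np.load(d / "idf.npz") as z:
                idf = z["idf"]
        svm_models = [
            linear.LinearModel.load(d / f"svm_{i:02d}.npz")
            for i in range(len(manifest["svm_seeds"]))
        ]
        cnn_models = [
            conv.ConvModel.load(d / f"cnn_{i:02d}.npz")
            for i in range(len(manifest["cnn_seeds"]))
        ]
        svm_bag = ens.BaggedEnsemble(
            components=svm_models,
            score_fn=linear.decision_scores,
            sampling_ratio=cfg.ratio_svm,
            component_seeds=manifest["svm_seeds"],
        )
        cnn_bag = ens.BaggedEnsemble(
            components=cnn_models,
            score_fn=conv.predict_proba_batch,
            sampling_ratio=cfg.ratio_cnn,
            component_seeds=manifest["cnn_seeds"],
        )
        normalizer = ens.ScoreNormalizer(
            {k: tuple(v) for k, v in manifest["normalizer"].items()}
        )
        text_spec = ens.EnsembleSpec(tuple(manifest["text_members"]), normalizer)
        with_pt_spec = ens.EnsembleSpec(tuple(manifest["with_pt_members"]), normalizer)
        results = cls(
            config=cfg,
            vocab=vocab,
            idf=idf,
            svm_bag=svm_bag,
            cnn_bag=cnn_bag,
            normalizer=normalizer,
            text_spec=text_spec,
            with_pt_spec=with_pt_spec,
        )
        results.auroc_ = {
            k: (v[0], tuple(v[1])) for k, v in manifest["auroc"].items()
        }
        results.operating_points_ = {
            k: ev.OperatingPoint(**v) for k, v in manifest["operating_points"].items()
        }
        return results
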