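"""ROC/AUROC statistics, calibration, NNS and burden arithmetic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rctscreen.evaluation import (
    BurdenTree,
    ConfusionCounts,
    UndefinedMetricError,
    auroc_ci,
    bootstrap_auroc,
    calibrate_threshold,
    confusion_at,
    metrics,
    operating_point_table,
    paired_diff_ci,
    rank_by_score,
    roc_and_auroc,
    screening_burden,
)


def mann_whitney_auroc(scores, labels) -> float:
    """Independent pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionAndMetrics:
    def test_threshold_below_min_retrieves_everything(self):
        c = confusion_at([0.1, 0.5, 0.9], [0, 1, 1], threshold=0.0)
        assert (c.fn, c.tn) == (0, 0)
        assert (c.tp, c.fp) == (2, 1)

    def test_threshold_above_max_retrieves_nothing(self):
        c = confusion_at([0.1, 0.5, 0.9], [0, 1, 1], threshold=1.5)
        assert (c.tp, c.fp) == (0, 0)

    def test_threshold_is_inclusive(self):
        c = confusion_at([0.5, 0.4], [1, 0], threshold=0.5)
        assert c.tp == 1 and c.fp == 0

    def test_hand_counted_fixture(self):
        c = confusion_at([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0], threshold=0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_at([0.1], [0, 1], 0.5)

    @pytest.mark.parametrize(
        "tp,fp,nns_1dp",
        [
            (125, 875, 8.0),   # precision 12.5%
            (104, 896, 9.6),   # precision 10.4%
            (78, 922, 12.8),   # precision 7.8%
            (525, 475, 1.9),   # precision 52.5%
        ],
    )
    def test_nns_is_reciprocal_precision(self, tp, fp, nns_1dp):
        c = ConfusionCounts(tp=tp, fp=fp, fn=1, tn=1)
        m = metrics(c)
        assert m.precision == pytest.approx(tp / (tp + fp))
        assert round(m.nns, 1) == nns_1dp

    def test_perfect_precision_gives_nns_one(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, fn=1, tn=3))
        assert m.nns == 1.0

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=0, fp=0, fn=1, tn=1))
        with pytest.raises(UndefinedMetricError):
            metrics(ConfusionCounts(tp=1, fp=0, fn=0, tn=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestRocAuroc:
    def test_perfect_separation(self):
        _, auc = roc_and_auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = roc_and_auroc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_known_fixture(self):
        _, auc = roc_and_auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        curve, _ = roc_and_auroc(s, y)
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)
        assert curve.sensitivity[0] == 0 and curve.fpr[0] == 0
        assert curve.sensitivity[-1] == 1 and curve.fpr[-1] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auroc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_trapezoid_equals_mann_whitney(self, data):
        n = data.draw(st.integers(4, 40))
        # coarse grid of score values forces plenty of ties
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ys: 0 < sum(ys) < len(ys)
            )
        )
        _, auc = roc_and_auroc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auroc(scores, labels), abs=1e-12)


class TestAurocCi:
    def test_perfect_separation_collapses(self):
        lo, hi = auroc_ci([4.0, 3.0, 2.0, 1.0], [1, 1, 0, 0])
        assert lo == pytest.approx(1.0)
        assert hi == 1.0

    def test_midpoint_equals_point_estimate(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        s[y == 1] += 0.8
        _, auc = roc_and_auroc(s, y)
        lo, hi = auroc_ci(s, y)
        assert (lo + hi) / 2 == pytest.approx(auc, abs=1e-12)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            auroc_ci([1.0] * 10, [0, 1] * 5)

    def test_matches_stratified_bootstrap(self):
        # DeLong variance cross-checked against a 2000-replicate stratified
        # bootstrap on a 200-point fixture: normal intervals built from the
        # two variance estimates must agree closely at both endpoints
        rng = np.random.default_rng(3)
        y = np.array([1] * 60 + [0] * 140)
        s = rng.normal(y * 1.2, 1.0)
        lo, hi = auroc_ci(s, y)
        _, auc = roc_and_auroc(s, y)
        _, boot_se, _ = bootstrap_auroc(s, y, n_boot=2000, seed=0)
        z = 1.959963984540054
        assert lo == pytest.approx(auc - z * boot_se, abs=0.005)
        assert hi == pytest.approx(auc + z * boot_se, abs=0.005)


class TestPairedDiffCi:
    def test_symmetric_when_discordants_equal(self):
        lo, hi = paired_diff_ci(10, 10, 100)
        assert lo == pytest.approx(-hi)

    def test_truncated_at_one(self):
        lo, hi = paired_diff_ci(50, 0, 50)
        assert hi <= 1.0

    def test_matches_formula_oracle(self):
        # adjusted cells: b'=20.5, c'=5.5, n'=1001
        b, c, n = 20.5, 5.5, 1001.0
        d = (b - c) / n
        se = np.sqrt(b + c - (b - c) ** 2 / n) / n
        z = 1.959963984540054
        lo, hi = paired_diff_ci(20, 5, 1000)
        assert lo == pytest.approx(d - z * se, abs=1e-12)
        assert hi == pytest.approx(d + z * se, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            paired_diff_ci(-1, 0, 10)


class TestCalibrateThreshold:
    def test_sensitivity_one_retrieves_all_positives(self):
        s = [0.9, 0.7, 0.5, 0.3, 0.1]
        y = [1, 0, 1, 0, 0]
        op = calibrate_threshold(s, y, target_sensitivity=1.0)
        assert op.sensitivity == 1.0
        assert op.threshold == 0.5  # the minimum positive-class score

    def test_specificity_one_on_separated_data(self):
        s = [0.9, 0.8, 0.2, 0.1]
        y = [1, 1, 0, 0]
        op = calibrate_threshold(s, y, target_specificity=1.0)
        assert op.specificity == 1.0
        assert op.sensitivity == 1.0

    def test_dominates_all_qualifying_thresholds(self):
        rng = np.random.default_rng(4)
        s = rng.integers(0, 10, size=10).astype(float)
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        target = 0.66
        op = calibrate_threshold(s, y, target_sensitivity=target)
        # exhaustive enumeration oracle over every distinct threshold
        best_spec = -1.0
        for t in np.unique(s):
            pred = s >= t
            sens = pred[y == 1].mean()
            spec = (~pred[y == 0]).mean()
            if sens >= target:
                best_spec = max(best_spec, spec)
        assert op.sensitivity >= target
        assert op.specificity == pytest.approx(best_spec)

    def test_requires_exactly_one_target(self):
        with pytest.raises(ValueError):
            calibrate_threshold([1, 0], [1, 0])
        with pytest.raises(ValueError):
            calibrate_threshold([1, 0], [1, 0], target_sensitivity=0.9, target_specificity=0.9)


class TestScreeningBurden:
    def test_corpus_scale_projection(self):
        """High-sensitivity filter over a 26.6M-article corpus with 1.6%
        positives: the burden tree reproduces the published arithmetic."""
        tree = screening_burden(26_600_000, 423_000, 0.984, 0.779)
        assert tree.tp == 416_232
        assert tree.retrieved_total == 6_201_349
        assert round(100 * tree.precision, 1) == 6.7

    def test_perfect_filter(self):
        tree = screening_burden(1000, 16, 1.0, 1.0)
        assert tree.retrieved_total == 16
        assert tree.precision == 1.0

    def test_zero_sensitivity_leaves_precision_undefined(self):
        tree = screening_burden(1000, 16, 0.0, 1.0)
        assert tree.tp == 0
        with pytest.raises(UndefinedMetricError):
            _ = tree.precision

    def test_count_conservation(self):
        tree = screening_burden(10_000, 300, 0.9, 0.8)
        assert tree.tp + tree.fp + tree.fn + tree.tn == 10_000

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            screening_burden(10, 20, 0.9, 0.9)
        with pytest.raises(ValueError):
            screening_burden(100, 10, 1.2, 0.9)


class TestRankByScore:
    def test_descending_order(self):
        out = rank_by_score(["a", "b", "c"], [0.1, 0.9, 0.5])
        assert out == ["b", "c", "a"]

    def test_stability_under_ties(self):
        out = rank_by_score(["a", "b", "c"], [0.5, 0.5, 0.5])
        assert out == ["a", "b", "c"]

    def test_agrees_with_sorted_oracle(self):
        rng = np.random.default_rng(6)
        scores = rng.random(50)
        items = list(range(50))
        out = rank_by_score(items, scores)
        oracle = [i for _, i in sorted(zip(-scores, items))]
        assert out == oracle


def test_operating_point_table_columns_and_monotonicity():
    rng = np.random.default_rng(7)
    s = rng.random(40)
    y = (rng.random(40) < 0.3).astype(int)
    table = operating_point_table(s, y)
    assert list(table.columns) == ["threshold", "sensitivity", "specificity", "precision", "nns"]
    assert table["sensitivity"].is_monotonic_increasing
    assert (table["specificity"].diff().dropna() <= 0).all()
    defined = table.dropna()
    assert np.allclose(defined["nns"], 1.0 / defined["precision"])
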