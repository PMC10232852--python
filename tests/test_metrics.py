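"""Confusion metrics against independent loop-based oracles; curve properties."""

import math
import warnings

import numpy as np
import pytest

from m5ukit.metrics import (ConfusionCounts, accuracy, aupr, auroc,
                            confusion, evaluate, f_value, mcc, pr_curve,
                            precision, recall, roc_curve)


def _loop_confusion(labels, preds):
    tp = fp = tn = fn = 0
    for y, p in zip(labels, preds):
        if y == 1 and p == 1:
            tp += 1
        elif y == 0 and p == 1:
            fp += 1
        elif y == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def _loop_metrics(tp, fp, tn, fn):
    """Independent plain-python implementation of the five count metrics."""
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    den = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    m = (tp * tn - fn * fp) / math.sqrt(den) if den else 0.0
    return acc, pre, rec, f, m


def _pair_auroc(labels, scores):
    """Concordance-probability oracle: P(s+ > s-) + 0.5 P(tie), all pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_direct_count_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)

    def test_all_correct_has_no_errors(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.FP == c.FN == 0

    def test_matches_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 30)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            c = confusion(y, p)
            assert (c.TP, c.FP, c.TN, c.FN) == _loop_confusion(y, p)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [0, 1])


class TestCountMetrics:
    def test_printed_worked_example_36_of_41(self):
        c = ConfusionCounts(TP=36, FP=0, TN=0, FN=5)
        assert accuracy(c) == 36 / 41
        assert round(accuracy(c) * 100, 2) == 87.80

    def test_perfect_classifier(self):
        c = ConfusionCounts(TP=10, FP=0, TN=10, FN=0)
        assert (accuracy(c), precision(c), recall(c), f_value(c), mcc(c)) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_chance_level_symmetric_table(self):
        c = ConfusionCounts(TP=25, FP=25, TN=25, FN=25)
        assert mcc(c) == 0.0
        assert accuracy(c) == 0.5

    def test_matches_loop_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            expected = _loop_metrics(tp, fp, tn, fn)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = (accuracy(c), precision(c), recall(c), f_value(c), mcc(c))
            assert np.allclose(got, expected, atol=1e-12)

    def test_degenerate_denominator_returns_zero_with_warning(self):
        c = ConfusionCounts(TP=0, FP=0, TN=5, FN=3)
        with pytest.warns(UserWarning, match="degenerate"):
            assert precision(c) == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            assert mcc(ConfusionCounts(TP=0, FP=0, TN=0, FN=5)) == 0.0

    def test_mcc_antisymmetric_under_prediction_flip(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 2, 60)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert mcc(confusion(y, p)) == pytest.approx(-mcc(confusion(y, 1 - p)), abs=1e-12)

    def test_accuracy_invariant_under_class_exchange(self):
        c = ConfusionCounts(TP=7, FP=3, TN=11, FN=2)
        swapped = ConfusionCounts(TP=11, FP=2, TN=7, FN=3)
        assert accuracy(c) == accuracy(swapped)


class TestCurves:
    def test_perfect_separation_hits_corner(self):
        c = roc_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert any(np.isclose(x, 0) and np.isclose(y, 1) for x, y in zip(c.x, c.y))
        assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_are_chance(self):
        c = roc_curve([0, 1, 0, 1], [0.5] * 4)
        assert len(c.x) == 2  # single threshold group: the two endpoints
        assert auroc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_point_count_bounded_by_unique_scores(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.choice([0.1, 0.3, 0.5, 0.9], 40)
        c = roc_curve(y, s)
        assert len(c.x) <= len(np.unique(s)) + 1

    def test_inverted_labels_give_zero_area(self):
        assert auroc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9]) == 0.0

    def test_auroc_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(4, 51)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert abs(auroc(y, s) - _pair_auroc(y, s)) < 1e-12

    def test_pr_curve_and_area(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        c = pr_curve(y, s)
        assert c.kind == "pr"
        assert aupr(y, s) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            roc_curve([1, 1], [0.2, 0.8])

    def test_curve_csv_round_trip(self, tmp_path):
        c = roc_curve([0, 1, 0, 1], [0.2, 0.9, 0.4, 0.6])
        path = tmp_path / "roc.csv"
        c.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.allclose(data[:, 0], c.x)
        assert np.allclose(data[:, 1], c.y)


class TestEvaluate:
    def test_full_report_fields_and_ranges(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = np.clip(y * 0.6 + rng.normal(0.2, 0.25, 200), 0, 1)
        report = evaluate(y, s)
        d = report.to_dict()
        for key in ("acc", "pre", "f_value", "recall", "auroc", "aupr"):
            assert 0.0 <= d[key] <= 1.0
        assert -1.0 <= d["mcc"] <= 1.0
        assert report.counts.total == report.n == 200
        assert "ACC" in str(report)
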