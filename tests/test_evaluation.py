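import math
import random

import numpy as np
import pytest

from thermotriage.evaluation import (
    ConfusionCounts,
    confusion_from_predictions,
    confusion_metrics,
    evaluate_scores,
    optimize_threshold,
    pr_curve_auc,
    roc_curve_auc,
    subsample_evaluate,
)


def auc_pairwise_oracle(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def metrics_by_hand(tp, fp, tn, fn):
    def div(a, b):
        return a / b if b else 0.0

    q2 = div(tp + tn, tp + fp + tn + fn)
    tpr, tnr = div(tp, tp + fn), div(tn, tn + fp)
    ppv, npv = div(tp, tp + fp), div(tn, tn + fn)
    f1 = div(2 * ppv * tpr, ppv + tpr)
    mcc = div(tp * tn - fp * fn,
              math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    return q2, tnr, npv, tpr, ppv, mcc, f1


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        r = confusion_metrics(ConfusionCounts(5, 0, 5, 0))
        assert (r.q2, r.mcc, r.f1) == (1.0, 1.0, 1.0)

    def test_hand_formula_example(self):
        r = confusion_metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=0))
        assert r.mcc == pytest.approx(6 / math.sqrt(72))

    def test_degenerate_all_negative_predictor(self):
        r = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert r.ppv == 0.0 and r.mcc == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_1000_random_tables_match_hand_formulas(self):
        rng = random.Random(77)
        for _ in range(1000):
            tp, fp, tn, fn = (rng.randint(0, 40) for _ in range(4))
            if tp + fp + tn + fn == 0:
                continue
            r = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            exp = metrics_by_hand(tp, fp, tn, fn)
            got = (r.q2, r.tnr, r.npv, r.tpr, r.ppv, r.mcc, r.f1)
            assert got == pytest.approx(exp, abs=1e-12)

    def test_label_swap_negates_mcc(self):
        rng = random.Random(5)
        for _ in range(100):
            tp, fp, tn, fn = (rng.randint(0, 20) for _ in range(4))
            if tp + fp + tn + fn == 0:
                continue
            m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn)).mcc
            # inverting predictions swaps tp<->fn and tn<->fp
            m_inv = confusion_metrics(ConfusionCounts(fn, tn, fp, tp)).mcc
            assert m_inv == pytest.approx(-m, abs=1e-12)


class TestRocAuc:
    def test_four_point_example(self):
        _, auc = roc_curve_auc([3, 1, 2, 0], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        _, auc = roc_curve_auc([5, 4, 1, 0], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_curve_auc([2, 2, 2, 2], [1, 1, 0, 0])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([1, 2], [1, 1])

    def test_agrees_with_pairwise_oracle_up_to_n200(self):
        rng = random.Random(123)
        for trial in range(200):
            n = rng.randint(4, 200)
            scores = [rng.randint(-3, 8) for _ in range(n)]
            labels = [rng.random() < 0.5 for _ in range(n)]
            if all(labels) or not any(labels):
                continue
            _, auc = roc_curve_auc(scores, labels)
            assert auc == pytest.approx(auc_pairwise_oracle(scores, labels),
                                        abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.integers(-3, 9, size=150).astype(float)
        labels = rng.random(150) < 0.4
        _, auc = roc_curve_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def aupr_sweep_oracle(scores, labels):
    """Brute-force threshold enumeration with step-wise area."""
    n_pos = sum(labels)
    area, prev_r = 0.0, 0.0
    for th in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= th and y)
        fp = sum(1 for s, y in zip(scores, labels) if s >= th and not y)
        r = tp / n_pos
        p = tp / (tp + fp) if tp + fp else 0.0
        area += (r - prev_r) * p
        prev_r = r
    return area


class TestPrAupr:
    def test_perfect_separation(self):
        _, aupr = pr_curve_auc([5, 4, 1, 0], [1, 1, 0, 0])
        assert aupr == 1.0

    def test_all_ties_gives_prevalence(self):
        _, aupr = pr_curve_auc([2, 2, 2, 2], [1, 1, 0, 0])
        assert aupr == pytest.approx(0.5)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve_auc([1, 2], [0, 0])

    def test_four_point_example_vs_sweep_oracle(self):
        scores, labels = [3, 1, 2, 0], [1, 1, 0, 0]
        _, aupr = pr_curve_auc(scores, labels)
        assert aupr == pytest.approx(aupr_sweep_oracle(scores, labels), abs=1e-12)
        assert aupr == pytest.approx(5 / 6)

    def test_random_instances_vs_sweep_oracle(self):
        rng = random.Random(31)
        for _ in range(100):
            n = rng.randint(3, 60)
            scores = [rng.randint(0, 6) for _ in range(n)]
            labels = [rng.random() < 0.5 for _ in range(n)]
            if not any(labels):
                continue
            _, aupr = pr_curve_auc(scores, labels)
            assert aupr == pytest.approx(aupr_sweep_oracle(scores, labels),
                                         abs=1e-12)


class TestOptimizeThreshold:
    def test_smallest_perfect_threshold(self):
        th, res = optimize_threshold([5, 4, 1, 0], [1, 1, 0, 0])
        assert th == 4 and res.mcc == 1.0

    def test_constant_scores_no_discrimination(self):
        th, res = optimize_threshold([3, 3, 3, 3], [1, 0, 1, 0])
        assert res.mcc == 0.0

    def test_inseparable_pair(self):
        _, res = optimize_threshold([3, 3], [1, 0])
        assert res.mcc == 0.0

    def test_returned_mcc_dominates_all_candidates(self):
        rng = random.Random(42)
        for _ in range(50):
            n = rng.randint(4, 50)
            scores = [rng.randint(-2, 8) for _ in range(n)]
            labels = [rng.random() < 0.5 for _ in range(n)]
            if all(labels) or not any(labels):
                continue
            th, res = optimize_threshold(scores, labels)
            for cand in set(scores):
                cand_mcc = confusion_metrics(
                    confusion_from_predictions(scores, labels, cand)
                ).mcc
                assert res.mcc >= cand_mcc - 1e-12


class TestSubsampleEvaluate:
    def test_balanced_draws_and_band(self):
        rng = np.random.default_rng(1)
        pos = rng.integers(3, 9, size=40).astype(float)
        pool = rng.integers(0, 3, size=200).astype(float)
        out = subsample_evaluate(pos, pool, threshold=3.0, n_repeats=10, seed=0)
        mean, lo, hi = out["mcc"]
        assert lo <= mean <= hi
        assert mean == 1.0  # separated by construction

    def test_deterministic_under_seed(self):
        pos = [4.0, 5.0, 6.0]
        pool = list(map(float, range(10)))
        a = subsample_evaluate(pos, pool, threshold=4.0, seed=7)
        b = subsample_evaluate(pos, pool, threshold=4.0, seed=7)
        assert a == b


def test_evaluate_scores_includes_curves():
    res = evaluate_scores([3, 1, 2, 0], [1, 1, 0, 0], threshold=2)
    assert res.auc is not None and res.aupr is not None
    assert res.roc_points[0] == (0.0, 0.0) and res.roc_points[-1] == (1.0, 1.0)
    assert res.threshold == 2
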