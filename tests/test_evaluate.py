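"""Metric implementations against brute-force oracles and printed formulas."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from ppipred.evaluate import (
    ConfusionCounts,
    auc50,
    confusion,
    metrics,
    positives_ratio,
    precision_recall,
    rank_correlation,
    report,
    roc_auc,
)
from ppipred.pairs import MISSING


def auc_by_pair_counting(scores, labels):
    """Oracle: (#concordant + 0.5 * #tied) / (P * N) over all pos-neg pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def auc50_by_step_curve(scores, labels, cutoff=50):
    """Oracle: walk the ranked list one item at a time, averaging tied
    blocks, and accumulate trapezoids in (FP, TP) count space."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    P = sum(labels)
    N = len(labels) - P
    cutoff = min(cutoff, N)
    points = [(0.0, 0.0)]
    i = 0
    while i < len(order):
        j = i
        dtp = dfp = 0
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                dtp += 1
            else:
                dfp += 1
            j += 1
        points.append((points[-1][0] + dfp, points[-1][1] + dtp))
        i = j
    area = 0.0
    for (f0, t0), (f1, t1) in zip(points, points[1:]):
        if f0 >= cutoff:
            break
        if f1 > cutoff:
            t1 = t0 + (t1 - t0) * (cutoff - f0) / (f1 - f0)
            f1 = cutoff
        area += (f1 - f0) * (t0 + t1) / 2
    if points[-1][0] < cutoff:
        area += (cutoff - points[-1][0]) * P
    return area / (cutoff * P)


def random_instance(rng, n, tie_prob=0.3):
    scores = [round(rng.random(), 1) if rng.random() < tie_prob else rng.random()
              for _ in range(n)]
    labels = [rng.randint(0, 1) for _ in range(n)]
    if len(set(labels)) < 2:
        labels[0], labels[1] = 0, 1
    return scores, labels


class TestConfusion:
    def test_basic_tally(self):
        c = confusion([0.9, 0.2], [1, 0], 0.5)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_zero_threshold_predicts_everything_positive(self):
        c = confusion([0.1, 0.0, 0.9], [0, 1, 1], 0.0)
        assert c.FN == 0 and c.TN == 0

    def test_missing_scores_excluded(self):
        c = confusion([0.9, MISSING, 0.1], [1, 1, 0], 0.5)
        assert c.total == 2

    def test_matches_brute_force_tally(self):
        rng = random.Random(0)
        scores, labels = random_instance(rng, 50)
        t = 0.5
        c = confusion(scores, labels, t)
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        tn = sum(1 for s, y in zip(scores, labels) if s < t and y == 0)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


class TestThresholdMetrics:
    def test_go_complex_printed_counts(self):
        # 28,771 within-complex and 1,374,879 cross-complex pairs; 14,720
        # and 1,191,506 confirmed at threshold 0.5 by both learners.
        counts = ConfusionCounts(
            TP=14_720, FN=28_771 - 14_720,
            TN=1_191_506, FP=1_374_879 - 1_191_506,
        )
        rep = metrics(counts)
        assert rep.precision == pytest.approx(0.07, abs=0.005)
        assert rep.accuracy == pytest.approx(0.86, abs=0.005)

    def test_perfect_counts(self):
        rep = metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert rep.accuracy == rep.sensitivity == rep.specificity == rep.precision == 1.0
        assert rep.fpr == 0.0

    def test_formulas_match_independent_arithmetic(self):
        rng = random.Random(1)
        for _ in range(20):
            tp, tn, fp, fn = (rng.randint(0, 100) for _ in range(4))
            if tp + tn + fp + fn == 0:
                continue
            rep = metrics(ConfusionCounts(tp, tn, fp, fn))
            total = tp + tn + fp + fn
            assert rep.accuracy == pytest.approx((tp + tn) / total)
            if tp + fn:
                assert rep.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert rep.specificity == pytest.approx(tn / (tn + fp))
                assert rep.fpr == pytest.approx(fp / (fp + tn))
                assert rep.specificity + rep.fpr == pytest.approx(1.0)
            if tp + fp:
                assert rep.precision == pytest.approx(tp / (tp + fp))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_independent_scores_near_half(self):
        rng = random.Random(2)
        scores = [rng.random() for _ in range(4000)]
        labels = [rng.randint(0, 1) for _ in range(4000)]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_pair_counting_oracle(self, seed):
        rng = random.Random(seed)
        scores, labels = random_instance(rng, 20)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = random.Random(11)
        scores, labels = random_instance(rng, 200)
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = random.Random(12)
        scores, labels = random_instance(rng, 100, tie_prob=0.0)
        _, auc1 = roc_auc(scores, labels)
        _, auc2 = roc_auc([math.tanh(3 * s) for s in scores], labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)


class TestAuc50:
    def test_perfect_separation_is_one(self):
        rng = random.Random(3)
        scores = [0.9 + 0.1 * rng.random() for _ in range(30)]
        scores += [0.1 * rng.random() for _ in range(80)]
        labels = [1] * 30 + [0] * 80
        assert auc50(scores, labels) == pytest.approx(1.0)

    def test_reversed_ranking_is_zero(self):
        # every negative outscores every positive: no true positive is
        # retrieved before the 50-false-positive cutoff
        scores = list(np.linspace(0.0, 0.4, 30)) + list(np.linspace(0.5, 1.0, 80))
        labels = [1] * 30 + [0] * 80
        assert auc50(scores, labels) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_step_curve(self, seed):
        rng = random.Random(seed)
        scores = [rng.random() for _ in range(230)]
        labels = [1] * 30 + [0] * 200
        rng.shuffle(labels)
        assert auc50(scores, labels) == pytest.approx(
            auc50_by_step_curve(scores, labels), abs=1e-12
        )

    def test_fewer_negatives_than_cutoff_uses_all(self):
        scores = [0.9, 0.8, 0.3, 0.2]
        labels = [1, 1, 0, 0]
        assert auc50(scores, labels) == pytest.approx(1.0)

    def test_monotone_in_cutoff(self):
        rng = random.Random(7)
        scores = [rng.random() for _ in range(300)]
        labels = [1] * 50 + [0] * 250
        rng.shuffle(labels)
        areas = [auc50(scores, labels, max_fp=c) for c in (10, 50, 100, 250)]
        # normalized partial area can only grow as the cutoff relaxes for a
        # better-than-random ranker; assert the documented ordering vs AUC
        _, full = roc_auc(scores, labels)
        assert areas[-1] == pytest.approx(full, abs=1e-12)


class TestPrecisionRecall:
    def test_perfect_separation_precision_one_at_full_recall(self):
        curve = precision_recall([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        at_full_recall = curve[np.isclose(curve[:, 0], 1.0)]
        assert at_full_recall[0, 1] == 1.0

    def test_random_scores_precision_near_prevalence_at_high_recall(self):
        rng = random.Random(8)
        n = 4000
        scores = [rng.random() for _ in range(n)]
        labels = [1 if rng.random() < 0.2 else 0 for _ in range(n)]
        curve = precision_recall(scores, labels)
        tail = curve[curve[:, 0] > 0.9]
        assert tail[:, 1].mean() == pytest.approx(0.2, abs=0.03)

    def test_matches_brute_force_sweep(self):
        rng = random.Random(9)
        scores, labels = random_instance(rng, 40)
        curve = precision_recall(scores, labels)
        P = sum(labels)
        for t in sorted(set(scores), reverse=True):
            tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
            fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
            match = curve[np.isclose(curve[:, 0], tp / P) &
                          np.isclose(curve[:, 1], tp / (tp + fp))]
            assert len(match) >= 1


class TestRankCorrelation:
    def test_identical_rankings(self):
        rho, _ = rank_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_reversed_rankings(self):
        rho, _ = rank_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_pearson_on_midranks(self):
        rng = random.Random(10)
        a = [rng.random() for _ in range(10)]
        b = [rng.choice(a) for _ in range(10)]  # force some ties
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        rho, p = rank_correlation(a, b)
        assert rho == pytest.approx(oracle, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_agrees_with_scipy_for_larger_n(self):
        rng = random.Random(13)
        a = [rng.random() for _ in range(40)]
        b = [x + 0.3 * rng.random() for x in a]
        rho, p = rank_correlation(a, b)
        ref = stats.spearmanr(a, b)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPositivesRatio:
    def test_imbalanced_test_composition(self):
        assert positives_ratio(204, 32_482) == pytest.approx(0.006, abs=0.0005)

    def test_edge_cases(self):
        assert positives_ratio(0, 10) == 0.0
        assert positives_ratio(10, 0) == 1.0
        with pytest.raises(ValueError):
            positives_ratio(0, 0)


def test_report_bundles_consistent_metrics():
    rng = random.Random(14)
    scores = [rng.random() for _ in range(120)]
    labels = [1 if rng.random() < 0.4 else 0 for _ in range(120)]
    rep = report(scores, labels, threshold=0.5)
    c = rep.counts
    assert rep.accuracy == pytest.approx((c.TP + c.TN) / c.total)
    assert rep.roc_curve is not None and rep.pr_curve is not None
    assert 0.0 <= rep.auc50 <= 1.0
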