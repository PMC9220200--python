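import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from mhclstm.metrics import (
    ConfusionMatrix,
    ScoredLabels,
    auc,
    aupr,
    basic_metrics,
    confusion_from_scores,
    metrics_report,
    scored,
)


def brute_force_auc(scores, labels):
    """Exhaustive positive/negative pair counting, ties credited 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMatrix:
    def test_simple_split(self):
        cm = confusion_from_scores(scored([0.9, 0.1], [1, 0]), 0.5)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 0, 0)

    def test_all_below_threshold(self):
        cm = confusion_from_scores(scored([0.1, 0.2, 0.3], [1, 0, 1]), 0.5)
        assert cm.tp == 0 and cm.fp == 0 and cm.fn == 2 and cm.tn == 1

    def test_threshold_is_inclusive(self):
        cm = confusion_from_scores(scored([0.5], [1]), 0.5)
        assert cm.tp == 1

    def test_matches_manual_count(self, rng):
        for _ in range(20):
            s = rng.random(6)
            y = rng.integers(0, 2, size=6)
            if len(np.unique(y)) < 2:
                continue
            cm = confusion_from_scores(scored(s, y), 0.5)
            tp = sum(1 for si, yi in zip(s, y) if si >= 0.5 and yi == 1)
            fp = sum(1 for si, yi in zip(s, y) if si >= 0.5 and yi == 0)
            fn = sum(1 for si, yi in zip(s, y) if si < 0.5 and yi == 1)
            tn = sum(1 for si, yi in zip(s, y) if si < 0.5 and yi == 0)
            assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
            assert cm.n == 6


class TestBasicMetrics:
    def test_published_class1_row(self):
        """Counts reconstructed from the printed class-I sensitivity 0.371 and
        specificity 0.959 with 197 positives / 123 negatives."""
        rep = basic_metrics(ConfusionMatrix(tp=73, tn=118, fp=5, fn=124))
        r = rep.rounded()
        assert r["accuracy"] == 0.597
        assert r["f1"] == 0.531
        assert r["mcc"] == 0.374
        assert r["precision"] == 0.936
        assert r["sensitivity"] == 0.371
        assert r["specificity"] == 0.959

    def test_published_class2_row(self):
        rep = basic_metrics(ConfusionMatrix(tp=6, tn=109, fp=4, fn=12))
        r = rep.rounded()
        assert r["accuracy"] == 0.878
        assert r["f1"] == 0.429
        assert r["mcc"] == 0.386
        assert r["precision"] == 0.600

    def test_zero_sensitivity_gives_na_f1(self):
        """With no predicted or true positives among hits, precision +
        sensitivity is zero, so F1 is NA while MCC is still defined."""
        rep = basic_metrics(ConfusionMatrix(tp=0, tn=110, fp=3, fn=18))
        assert rep.f1 is None
        assert rep.rounded()["mcc"] == -0.061
        assert rep.precision == 0.0 and rep.sensitivity == 0.0

    def test_perfect_classifier(self):
        rep = basic_metrics(ConfusionMatrix(tp=7, tn=9, fp=0, fn=0))
        for f in ("accuracy", "sensitivity", "specificity", "f1", "mcc", "precision"):
            assert getattr(rep, f) == 1.0

    def test_zero_marginal_mcc_is_na(self):
        rep = basic_metrics(ConfusionMatrix(tp=0, tn=0, fp=0, fn=5))
        assert rep.mcc is None and rep.specificity is None

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            basic_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_accuracy_is_convex_combination(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 40, size=4)
            rep = basic_metrics(ConfusionMatrix(int(tp), int(tn), int(fp), int(fn)))
            P, N = tp + fn, tn + fp
            expected = (P * rep.sensitivity + N * rep.specificity) / (P + N)
            assert rep.accuracy == pytest.approx(expected, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert auc(scored([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_null_behavior(self, rng):
        s = rng.random(4000)
        y = rng.integers(0, 2, size=4000)
        assert auc(scored(s, y)) == pytest.approx(0.5, abs=0.05)

    def test_ties_get_half_credit(self):
        data = scored([0.5, 0.5, 0.5, 0.9, 0.1, 0.5, 0.3, 0.7], [1, 0, 1, 1, 0, 0, 0, 1])
        assert auc(data) == pytest.approx(brute_force_auc(data.scores, data.labels))

    def test_single_class_is_na(self):
        assert auc(scored([0.3, 0.6], [1, 1])) is None

    def test_exhaustive_pair_oracle_small_n(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            y = rng.integers(0, 2, size=n)
            expected = brute_force_auc(s, y)
            got = auc(scored(s, y))
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        s = rng.random(300)
        y = rng.integers(0, 2, size=300)
        assert auc(scored(s, y)) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAUPR:
    def test_perfect_separation(self):
        assert aupr(scored([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])) == 1.0

    def test_constant_scores_equal_prevalence(self):
        data = scored([0.4] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert aupr(data) == pytest.approx(0.3, abs=1e-12)

    def test_hand_computed_step_curve(self):
        # sorted desc: (0.9,+), (0.8,-), (0.7,+), (0.6,+), (0.4,-), (0.3,-), (0.2,+), (0.1,-)
        # recall steps at the positives: 1/4*1 + 1/4*(2/3) + 1/4*(3/4) + 1/4*(4/7)
        data = scored([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1],
                      [1, 0, 1, 1, 0, 0, 1, 0])
        expected = 0.25 * (1.0 + 2.0 / 3.0 + 3.0 / 4.0 + 4.0 / 7.0)
        assert aupr(data) == pytest.approx(expected, abs=1e-12)

    def test_no_positives_is_na(self):
        assert aupr(scored([0.2, 0.8], [0, 0])) is None

    def test_agrees_with_sklearn(self, rng):
        for _ in range(10):
            s = np.round(rng.random(200), 2)
            y = rng.integers(0, 2, size=200)
            if y.sum() == 0:
                continue
            assert aupr(scored(s, y)) == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )


class TestMetricsReport:
    def test_combines_all_eight(self):
        rep = metrics_report(scored([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]), 0.5)
        for f in rep.FIELDS:
            assert getattr(rep, f) == 1.0
        assert rep.n_positive == 2 and rep.n_negative == 2

    def test_label_swap_symmetry(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, size=40)
        # swapping labels and reflecting scores around the threshold
        # exchanges sensitivity/specificity and preserves |MCC|
        a = metrics_report(scored(s, y), 0.5)
        b = metrics_report(scored([1.0 - x - 1e-12 for x in s], 1 - y), 0.5)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
        assert abs(a.mcc) == pytest.approx(abs(b.mcc))

    def test_monotone_transform_invariance(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, size=30)
        t = 0.4
        a = metrics_report(scored(s, y), t)
        g = lambda x: 1.0 / (1.0 + math.exp(-3.0 * (x - 0.2)))  # strictly increasing
        b = metrics_report(scored([g(x) for x in s], y), g(t))
        for f in a.FIELDS:
            va, vb = getattr(a, f), getattr(b, f)
            assert (va is None) == (vb is None)
            if va is not None:
                assert va == pytest.approx(vb, abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False), st.integers(0, 1)),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_fields_within_declared_ranges(self, pairs):
        s = [p for p, _ in pairs]
        y = [l for _, l in pairs]
        rep = metrics_report(scored(s, y), 0.5)
        for f in ("accuracy", "sensitivity", "specificity", "f1", "precision",
                  "auc", "aupr"):
            v = getattr(rep, f)
            assert v is None or 0.0 <= v <= 1.0
        assert rep.mcc is None or -1.0 <= rep.mcc <= 1.0
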