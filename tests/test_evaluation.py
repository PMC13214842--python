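"""ROC/AUC, screening thresholds, McNemar, permutation importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from oculocog.evaluation import (
    confusion_at,
    evaluate_classifier,
    mcnemar,
    moca_as_classifier,
    permutation_importance,
    roc_auc,
    screening_threshold,
)
from oculocog.modeling import run_classifier


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        auc, _ = roc_auc(scores, labels)
        assert auc == 1.0

    def test_constant_scores_chance(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        auc, _ = roc_auc(np.full(6, 0.5), labels)
        assert auc == 0.5

    def test_reversed_scores_zero(self):
        labels = np.array([0, 0, 1, 1])
        auc, _ = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels)
        assert auc == 0.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(0, 1, 200)
        labels = (scores + rng.normal(0, 1, 200) > 0).astype(int)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestMocaAsClassifier:
    def test_self_consistent_labels_give_perfect_auc(self):
        rng = np.random.default_rng(1)
        moca = rng.integers(16, 31, 200).astype(float)
        labels = (moca < 26).astype(int)
        report = moca_as_classifier(moca, labels)
        assert report.auc == 1.0
        cm = report.confusion
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == labels.sum() and cm.tn == (1 - labels).sum()

    def test_independent_labels_give_chance_auc(self):
        aucs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            moca = rng.integers(16, 31, 500).astype(float)
            labels = rng.integers(0, 2, 500)
            aucs.append(moca_as_classifier(moca, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_no_low_scores_means_zero_sensitivity(self):
        moca = np.full(50, 28.0)
        labels = np.zeros(50, dtype=int)
        labels[:10] = 1
        report = moca_as_classifier(moca, labels)
        assert report.confusion.sensitivity == 0.0

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            moca_as_classifier(np.array([35.0, 20.0]), np.array([0, 1]))


class TestScreeningThreshold:
    def test_perfect_scores_hit_both_targets(self):
        labels = np.array([0] * 5 + [1] * 5)
        scores = np.array([0.1] * 5 + [0.9] * 5)
        thr, cm = screening_threshold(scores, labels)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_constant_scores_degenerate_threshold(self):
        labels = np.array([0, 1, 0, 1])
        thr, cm = screening_threshold(np.full(4, 0.3), labels)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_matches_exhaustive_enumeration(self):
        """Six-point score set: selection agrees with brute force over
        every candidate threshold."""
        scores = np.array([0.15, 0.3, 0.42, 0.55, 0.7, 0.88])
        labels = np.array([0, 1, 0, 1, 1, 1])
        thr, cm = screening_threshold(scores, labels, min_sensitivity=0.85)

        best = None
        for cand in np.concatenate([scores, [1.5]]):
            c = confusion_at(scores, labels, cand)
            if c.sensitivity >= 0.85:
                if best is None or c.specificity > best[1].specificity:
                    best = (cand, c)
        assert best is not None
        assert cm.sensitivity == best[1].sensitivity
        assert cm.specificity == best[1].specificity

    def test_fallback_maximizes_sensitivity(self):
        # no threshold reaches 0.85 sensitivity except predict-all
        scores = np.array([0.9, 0.1, 0.8, 0.2])
        labels = np.array([0, 1, 0, 1])
        thr, cm = screening_threshold(scores, labels, min_sensitivity=0.85)
        assert cm.sensitivity == 1.0


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        pred = np.array([0, 1, 1, 1, 0])
        chi2, p = mcnemar(pred, pred, y)
        assert chi2 == 0.0 and p == 1.0

    def test_continuity_corrected_closed_form(self):
        # b=10, c=2 -> chi2 = (8-1)^2/12 = 49/12
        y = np.zeros(40, dtype=int)
        pred_a = np.zeros(40, dtype=int)
        pred_b = np.zeros(40, dtype=int)
        pred_b[:10] = 1          # A correct, B wrong (b=10)
        pred_a[10:12] = 1        # B correct, A wrong (c=2)
        chi2, p = mcnemar(pred_a, pred_b, y, exact_below=0)
        assert chi2 == pytest.approx(49.0 / 12.0)

    def test_small_sample_exact_binomial(self):
        # b=4, c=0 -> exact two-sided p = 2 * (1/2)^4 = 0.125
        y = np.zeros(10, dtype=int)
        pred_a = np.zeros(10, dtype=int)
        pred_b = np.zeros(10, dtype=int)
        pred_b[:4] = 1
        _, p = mcnemar(pred_a, pred_b, y)
        assert p == pytest.approx(0.125)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        pa = rng.integers(0, 2, 100)
        pb = rng.integers(0, 2, 100)
        assert mcnemar(pa, pb, y) == mcnemar(pb, pa, y)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        pa = (rng.random(200) < 0.6).astype(int)
        pb = (rng.random(200) < 0.6).astype(int)
        a_ok = pa == y
        b_ok = pb == y
        table = [
            [np.sum(a_ok & b_ok), np.sum(a_ok & ~b_ok)],
            [np.sum(~a_ok & b_ok), np.sum(~a_ok & ~b_ok)],
        ]
        ref = sm_mcnemar(table, exact=False, correction=True)
        chi2, p = mcnemar(pa, pb, y, exact_below=0)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestConfusionMatrix:
    def test_row_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        cm = confusion_at(scores, labels, 0.5)
        rows = cm.row_percentages()
        assert rows.sum(axis=1).round(9).eq(100.0).all()
        assert cm.n == 100


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(4)
    n = 300
    signal = rng.normal(0, 1, n)
    X = pd.DataFrame(
        {"signal": signal, "noise1": rng.normal(0, 1, n), "noise2": rng.normal(0, 1, n)}
    )
    y = (signal + 0.5 * rng.normal(0, 1, n) > 0).astype(int)
    res = run_classifier(X, y, model="rf", params={"n_estimators": 100}, seed=4)
    return X, y, res


class TestPermutationImportance:

    def test_null_feature_near_zero(self, planted):
        X, y, res = planted
        imp = permutation_importance(res, X, y, n_perm=30, seed=0).set_index("feature")
        assert abs(imp.loc["noise1", "importance"]) < 0.05
        assert abs(imp.loc["noise2", "importance"]) < 0.05

    def test_informative_feature_dominates(self, planted):
        X, y, res = planted
        imp = permutation_importance(res, X, y, n_perm=30, seed=0).set_index("feature")
        assert imp.loc["signal", "importance"] > 0.2
        permuted_auc = imp.loc["signal", "baseline_auc"] - imp.loc["signal", "importance"]
        assert permuted_auc < 0.65  # collapses toward chance

    def test_duplicated_signal_dilutes_each_copy(self):
        rng = np.random.default_rng(5)
        n = 300
        signal = rng.normal(0, 1, n)
        y = (signal + 0.5 * rng.normal(0, 1, n) > 0).astype(int)
        X1 = pd.DataFrame({"signal": signal, "noise": rng.normal(0, 1, n)})
        X2 = X1.copy()
        X2["signal_copy"] = signal
        r1 = run_classifier(X1, y, model="rf", params={"n_estimators": 100}, seed=5)
        r2 = run_classifier(X2, y, model="rf", params={"n_estimators": 100}, seed=5)
        i1 = permutation_importance(r1, X1, y, n_perm=25, seed=1).set_index("feature")
        i2 = permutation_importance(r2, X2, y, n_perm=25, seed=1).set_index("feature")
        unique = i1.loc["signal", "importance"]
        assert i2.loc["signal", "importance"] < unique
        assert i2.loc["signal_copy", "importance"] < unique


def test_evaluation_report_summary_is_consistent():
    rng = np.random.default_rng(6)
    scores = rng.random(120)
    labels = (scores + rng.normal(0, 0.3, 120) > 0.5).astype(int)
    report = evaluate_classifier(scores, labels, model="demo")
    s = report.summary()
    cm = report.confusion
    assert s["tp"] + s["fp"] + s["fn"] + s["tn"] == 120
    assert s["sensitivity"] == pytest.approx(cm.tp / (cm.tp + cm.fn), abs=1e-4)
    assert report.confusion.sensitivity >= 0.85 or report.threshold == min(scores)
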