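"""Screening-oriented classifier evaluation.

Pooled out-of-fold class scores are summarized by ROC/AUC and
precision-recall curves; an operating threshold is chosen to guarantee
a minimum sensitivity of 0.85 (screening criterion) while maximizing
specificity; paired classifiers are compared with McNemar's test on
discordant errors; and predictor contributions are quantified by
permutation feature importance (mean AUC decrease over 50 permutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .modeling import CVResult


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """AUC (trapezoidal / normalized Mann-Whitney U) plus the ROC curve.

    Ties in the scores are handled by the midrank convention, so a
    constant score yields exactly 0.5. Raises when only one class is
    present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return float(auc(fpr, tpr)), curve


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    def row_percentages(self) -> pd.DataFrame:
        """Counts normalized within each actual class, in percent."""
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        return pd.DataFrame(
            {
                "pred_altered": [100.0 * self.tp / pos if pos else math.nan,
                                 100.0 * self.fp / neg if neg else math.nan],
                "pred_not_altered": [100.0 * self.fn / pos if pos else math.nan,
                                     100.0 * self.tn / neg if neg else math.nan],
            },
            index=["actual_altered", "actual_not_altered"],
        )


def confusion_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionMatrix:
    """Confusion counts predicting altered when score >= threshold."""
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
    )


def screening_threshold(
    scores: np.ndarray, labels: np.ndarray, min_sensitivity: float = 0.85
) -> tuple[float, ConfusionMatrix]:
    """Operating threshold for a screening test.

    Among all thresholds achieving sensitivity >= ``min_sensitivity``,
    return the one maximizing specificity. If none attains it, return
    the threshold with maximal sensitivity (ties broken by higher
    specificity).
    """
    scores = np.asarray(scores, dtype=float)
    candidates = np.unique(scores)
    candidates = np.concatenate([candidates, [candidates.max() + 1.0]])
    best, best_cm = None, None
    fallback, fallback_cm = None, None
    for thr in candidates:
        cm = confusion_at(scores, labels, thr)
        sens, spec = cm.sensitivity, cm.specificity
        if sens >= min_sensitivity:
            if best is None or spec > best_cm.specificity:
                best, best_cm = thr, cm
        key = (sens, spec)
        if fallback is None or key > (fallback_cm.sensitivity, fallback_cm.specificity):
            fallback, fallback_cm = thr, cm
    if best is not None:
        return float(best), best_cm
    return float(fallback), fallback_cm


def mcnemar(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    labels: np.ndarray,
    exact_below: int = 25,
) -> tuple[float, float]:
    """McNemar's test on paired classification errors.

    b = cases A classifies correctly and B misclassifies; c = the
    reverse. Continuity-corrected chi-square (|b-c|-1)^2/(b+c) with 1 df;
    an exact two-sided binomial test when b + c < ``exact_below``; and
    (chi2=0, p=1) by convention when there are no discordant pairs.
    """
    labels = np.asarray(labels).astype(bool)
    a_ok = np.asarray(pred_a).astype(bool) == labels
    b_ok = np.asarray(pred_b).astype(bool) == labels
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return 0.0, 1.0
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    if b + c < exact_below:
        p = float(stats.binomtest(min(b, c), b + c, 0.5).pvalue)
    else:
        p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def permutation_importance(
    cv_result: CVResult,
    X: pd.DataFrame,
    labels: np.ndarray,
    n_perm: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean AUC decrease (+/- SD) when each feature is permuted.

    Uses the pipeline's out-of-fold protocol: for every permutation the
    shuffled matrix is re-scored by each fold's fitted model on its own
    held-out participants, and the AUC of the pooled scores is compared
    with the unpermuted baseline.
    """
    labels = np.asarray(labels).astype(int)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    baseline = float(roc_auc_score(labels, cv_result.predictions))

    rows = []
    for j, feature in enumerate(X.columns):
        drops = []
        for _ in range(n_perm):
            Xp = Xv.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            scores = np.full(len(labels), np.nan)
            for est, test_idx in cv_result.fitted_models:
                scores[test_idx] = est.predict_proba(Xp[test_idx])[:, 1]
            drops.append(baseline - float(roc_auc_score(labels, scores)))
        rows.append(
            {"feature": feature, "importance": float(np.mean(drops)),
             "sd": float(np.std(drops)), "baseline_auc": baseline}
        )
    return pd.DataFrame(rows).sort_values("importance", ascending=False, ignore_index=True)


@dataclass
class EvaluationReport:
    """Everything reported for one classifier on one outcome."""

    model: str
    auc: float
    roc: pd.DataFrame
    pr: pd.DataFrame
    average_precision: float
    threshold: float
    confusion: ConfusionMatrix
    mcnemar_vs: dict[str, tuple[float, float]] = field(default_factory=dict)
    importances: pd.DataFrame | None = None

    def summary(self) -> dict[str, float]:
        return {
            "model": self.model,
            "auc": round(self.auc, 4),
            "average_precision": round(self.average_precision, 4),
            "threshold": float(self.threshold),
            "sensitivity": round(self.confusion.sensitivity, 4),
            "specificity": round(self.confusion.specificity, 4),
            "tp": self.confusion.tp, "fp": self.confusion.fp,
            "fn": self.confusion.fn, "tn": self.confusion.tn,
        }


def evaluate_classifier(
    scores: np.ndarray,
    labels: np.ndarray,
    model: str = "classifier",
    min_sensitivity: float = 0.85,
    fixed_threshold: float | None = None,
) -> EvaluationReport:
    """Full screening report from pooled out-of-fold scores."""
    labels = np.asarray(labels).astype(int)
    auc_val, curve = roc_auc(scores, labels)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    pr = pd.DataFrame({"precision": precision, "recall": recall})
    ap = float(average_precision_score(labels, scores))
    if fixed_threshold is None:
        thr, cm = screening_threshold(scores, labels, min_sensitivity)
    else:
        thr, cm = fixed_threshold, confusion_at(scores, labels, fixed_threshold)
    return EvaluationReport(
        model=model, auc=auc_val, roc=curve, pr=pr, average_precision=ap,
        threshold=thr, confusion=cm,
    )


def moca_as_classifier(
    moca: np.ndarray, labels: np.ndarray, cutoff: int = 26
) -> EvaluationReport:
    """MoCA as a standalone screener.

    Lower MoCA means greater impairment, so scores are negated for the
    ROC; the confusion matrix uses the fixed clinical cutoff (< 26
    predicts altered).
    """
    moca = np.asarray(moca, dtype=float)
    if np.any((moca < 0) | (moca > 30)):
        raise ValueError("MoCA scores must lie in [0, 30]")
    report = evaluate_classifier(-moca, labels, model="moca",
                                 fixed_threshold=-(cutoff - 0.5))
    return report
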