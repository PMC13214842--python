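"""Headline synthetic-data analyses: calibration, recovery and ordering.

Each function runs one complete experiment from scratch — generating
its own cohorts or traces, running the pipeline stages, and measuring
the result — and returns plain numbers. They power the numbered
analysis drivers and the acceptance summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import cohort as sc
from .config import ET_FEATURES, CohortConfig, NoiseParams, TaskSpec
from .evaluation import moca_as_classifier, roc_auc
from .features import partial_spearman
from .modeling import run_classifier, run_regression
from .normative import fit_normative, label_cohort
from .preprocessing import preprocess


def _spawn(seed: int, k: int) -> int:
    return int((seed * 9973 + k * 7919 + 1) % (2**31))


def moca_self_classification_auc(seed: int = 0) -> float:
    """AUC of inverted MoCA against its own cutoff label (analytically 1)."""
    _, primary = sc.generate_cohort(CohortConfig(seed=_spawn(seed, 0)))
    moca = primary["moca"].to_numpy(dtype=float)
    labels = (moca < 26).astype(int)
    if labels.min() == labels.max():  # degenerate draw; resample
        return moca_self_classification_auc(seed + 1)
    return float(moca_as_classifier(moca, labels).auc)


def chance_auc(seed: int = 0, n: int = 500) -> float:
    """AUC of a constant score under midrank tie handling (analytically 0.5)."""
    rng = np.random.default_rng(_spawn(seed, 1))
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    value, _ = roc_auc(np.full(n, 0.5), labels)
    return float(value)


def partial_spearman_recovery(
    n_seeds: int = 20, seed: int = 0, effect_rho: float = 0.25
) -> dict[str, float]:
    """Mean |partial Spearman| between each planted feature and the
    cognitive composite (controlling age/education) over seeds, at the
    study's primary sample size."""
    per_feature = {f: [] for f in ET_FEATURES}
    for k in range(n_seeds):
        cfg = CohortConfig(seed=_spawn(seed, 10 + k), effect_rho=effect_rho)
        _, primary = sc.generate_cohort(cfg)
        feats = sc.planted_feature_values(primary, cfg, _spawn(seed, 200 + k))
        comp = sc.composite_score(primary).to_numpy()
        cov = primary[["age", "education"]].to_numpy()
        for f in ET_FEATURES:
            rho, _ = partial_spearman(feats[f].to_numpy(), comp, cov)
            per_feature[f].append(abs(rho))
    means = {f: float(np.mean(v)) for f, v in per_feature.items()}
    means["overall"] = float(np.mean([v for vals in per_feature.values() for v in vals]))
    means["n_seeds"] = n_seeds
    return means


def saccade_detector_performance(
    n_traces: int = 20,
    seed: int = 0,
    duration: float = 10.0,
    sample_rate: float = 1000.0,
    tolerance_ms: float = 10.0,
) -> dict[str, float]:
    """Recall/precision of the adaptive detector against planted event
    logs (events >= 2 deg, >= 20 ms), pooled over traces at generator
    default noise."""
    spec = TaskSpec("fixation_distractors", duration, sample_rate)
    n_hit = n_planted = n_det = n_matched_det = 0
    for k in range(n_traces):
        rec, _, truth = sc.generate_trace(None, spec, NoiseParams(), _spawn(seed, 300 + k))
        _, _, detected, _ = preprocess(rec)
        planted = [e for e in truth.saccades if e.amplitude >= 2.0 and e.duration >= 20.0]
        for p in planted:
            if any(
                d.onset <= p.onset + tolerance_ms and d.offset >= p.offset - tolerance_ms
                for d in detected
            ):
                n_hit += 1
        n_planted += len(planted)
        for d in detected:
            if any(
                d.onset <= p.offset + tolerance_ms and d.offset >= p.onset - tolerance_ms
                for p in truth.saccades
            ):
                n_matched_det += 1
        n_det += len(detected)
    return {
        "recall": n_hit / n_planted if n_planted else float("nan"),
        "precision": n_matched_det / n_det if n_det else float("nan"),
        "n_planted": n_planted,
        "n_detected": n_det,
    }


def null_calibration(
    n_seeds: int = 20, seed: int = 0, n_estimators: int = 100
) -> dict[str, float]:
    """With zero planted signal: pooled out-of-fold classification AUC
    (global composite) and linear-regression R^2 on outcome-permuted
    scores."""
    aucs, r2s = [], []
    for k in range(n_seeds):
        cfg = CohortConfig(seed=_spawn(seed, 400 + k), effect_rho=0.0)
        normative, primary = sc.generate_cohort(cfg)
        feats = sc.planted_feature_values(primary, cfg, _spawn(seed, 500 + k))
        labels = label_cohort(fit_normative(normative), primary)
        y = labels["global"].to_numpy().astype(int)
        X = feats[ET_FEATURES + ["age"]]
        res = run_classifier(X, y, model="rf", params={"n_estimators": n_estimators},
                             seed=_spawn(seed, 600 + k))
        aucs.append(roc_auc_score(y, res.predictions))
        rng = np.random.default_rng(_spawn(seed, 700 + k))
        y_null = rng.permutation(primary["digit_symbol"].to_numpy())
        _, metrics = run_regression(X, y_null, model="ols", seed=_spawn(seed, 800 + k))
        r2s.append(metrics["r2"])
    return {
        "auc_mean": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs)),
        "r2_mean": float(np.mean(r2s)),
        "n_seeds": n_seeds,
    }


def multimodal_ordering(
    n_seeds: int = 20,
    seed: int = 0,
    n: int = 172,
    moca_weight: int = 2,
    n_estimators: int = 200,
) -> dict[str, float]:
    """Independent MoCA-borne and ET-borne signals: fraction of seeds
    with AUC(ET+MoCA) > AUC(MoCA) > AUC(ET), plus mean AUCs."""
    ordered = 0
    aucs = []
    params = {"n_estimators": n_estimators}
    for k in range(n_seeds):
        s = _spawn(seed, 900 + k)
        X, moca, y = sc.generate_multimodal_dataset(n=n, seed=s)
        a_et = roc_auc_score(y, run_classifier(X, y, model="rf", params=params, seed=s).predictions)
        a_mm = roc_auc_score(
            y,
            run_classifier(X, y, model="rf", moca=moca, moca_weight=moca_weight,
                           params=params, seed=s).predictions,
        )
        a_mo = roc_auc_score(y, -moca)
        aucs.append((a_et, a_mo, a_mm))
        ordered += int(a_mm > a_mo > a_et)
    arr = np.asarray(aucs)
    return {
        "ordering_fraction": ordered / n_seeds,
        "auc_et": float(arr[:, 0].mean()),
        "auc_moca": float(arr[:, 1].mean()),
        "auc_et_moca": float(arr[:, 2].mean()),
        "n_seeds": n_seeds,
    }


def normative_calibration(seed: int = 0) -> dict[str, float]:
    """In-sample z-score calibration of the normative model: worst-case
    |mean z| and z SD across the battery."""
    cfg = CohortConfig(seed=_spawn(seed, 2))
    normative, _ = sc.generate_cohort(cfg)
    model = fit_normative(normative)
    from .normative import z_scores

    zs = z_scores(model, normative)
    cols = [c for c in zs.columns if c.startswith("z_")]
    mean_abs = max(abs(float(zs[c].mean())) for c in cols)
    sds = [float(zs[c].std()) for c in cols]
    return {"max_abs_mean_z": mean_abs, "mean_z_sd": float(np.mean(sds))}
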