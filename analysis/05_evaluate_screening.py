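#!/usr/bin/env python
"""Screening evaluation of the multimodal classifier condition.

On the independently planted multimodal dataset (MoCA-borne and ET-borne
signals), compares RF-ET, standalone MoCA and the weighted RF-ET+MoCA:
ROC curves, sensitivity>=0.85 operating points, confusion matrices in
the counts + row-percentage layout, McNemar comparisons, and permutation
feature importance (50 permutations per feature). Writes plots and a
JSON report.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import oculocog.cohort as sc
from oculocog.evaluation import (
    evaluate_classifier,
    mcnemar,
    moca_as_classifier,
    permutation_importance,
)
from oculocog.modeling import build_classification_matrix, run_classifier

OUT = Path("results/analysis")
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    X, moca, y = sc.generate_multimodal_dataset(seed=SEED)
    params = {"n_estimators": 300}

    res_et = run_classifier(X, y, model="rf", params=params, seed=SEED)
    res_mm = run_classifier(X, y, model="rf", moca=moca, moca_weight=2,
                            params=params, seed=SEED)
    rep_et = evaluate_classifier(res_et.predictions, y, model="rf_et")
    rep_mm = evaluate_classifier(res_mm.predictions, y, model="rf_et_moca")
    rep_mo = moca_as_classifier(moca, y)

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep, label in ((rep_et, "RF-ET"), (rep_mo, "MoCA"), (rep_mm, "RF-ET+MoCA")):
        ax.plot(rep.roc["fpr"], rep.roc["tpr"],
                label=f"{label} (AUC={rep.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(OUT / "roc_global.png", dpi=150)

    print("operating points (threshold chosen for sensitivity >= 0.85):")
    for rep, label in ((rep_et, "RF-ET"), (rep_mm, "RF-ET+MoCA"), (rep_mo, "MoCA @ <26")):
        cm = rep.confusion
        print(f"  {label}: AUC={rep.auc:.3f} sens={cm.sensitivity:.2f} "
              f"spec={cm.specificity:.2f}")
        print(cm.row_percentages().round(1).to_string())

    pred_et = res_et.predictions >= rep_et.threshold
    pred_mm = res_mm.predictions >= rep_mm.threshold
    pred_mo = moca < 26
    tests = {
        "rf_et_vs_moca": mcnemar(pred_et, pred_mo, y),
        "rf_et_moca_vs_moca": mcnemar(pred_mm, pred_mo, y),
    }
    print("\nMcNemar comparisons (chi2, p):")
    for k, (chi2, p) in tests.items():
        print(f"  {k}: chi2={chi2:.2f}, p={p:.4f}")

    X_mm = build_classification_matrix(X, moca, 2)
    imp = permutation_importance(res_mm, X_mm, y, n_perm=50, seed=SEED)
    imp.to_csv(OUT / "permutation_importance.csv", index=False)
    fig2, ax2 = plt.subplots(figsize=(6, 4))
    ax2.barh(imp["feature"], imp["importance"], xerr=imp["sd"])
    ax2.set_xlabel("mean AUC decrease (50 permutations)")
    fig2.tight_layout()
    fig2.savefig(OUT / "permutation_importance.png", dpi=150)
    print("\npermutation importance ranking:", ", ".join(imp["feature"]))

    report = {
        "auc": {"rf_et": rep_et.auc, "moca": rep_mo.auc, "rf_et_moca": rep_mm.auc},
        "operating_points": {r.model: r.summary() for r in (rep_et, rep_mm, rep_mo)},
        "mcnemar": {k: {"chi2": v[0], "p": v[1]} for k, v in tests.items()},
    }
    (OUT / "screening_report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
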