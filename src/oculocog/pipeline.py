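"""End-to-end orchestration: synthesize -> preprocess -> features ->
labels -> models -> evaluation, from a single serializable config.

Stages run in DAG order and write plain-text artifacts (CSV/JSON) plus
a manifest with SHA-256 checksums; re-running with the same config and
seed reproduces every artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as sc
from .config import ET_FEATURES, CohortConfig, TaskSpec, default_task_specs
from .containers import events_to_frame
from .evaluation import evaluate_classifier, mcnemar, moca_as_classifier, permutation_importance
from .features import extract_features, screen_features
from .modeling import run_classifier, run_regression_bank
from .normative import fit_normative, label_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Complete description of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sample_rate: float = 1000.0
    feature_source: str = "traces"        # "traces" or "direct"
    outcome: str = "global"
    blink_margin: float = 200.0
    min_sensitivity: float = 0.85
    n_permutations: int = 50
    moca_weight: int = 1
    folds: int = 5
    rf_params: dict = field(default_factory=lambda: {"n_estimators": 300})
    run_regressions: bool = False
    regression_models: tuple = ("ols", "rf")
    seed: int = 0
    output_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_cfg = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort_cfg, **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["regression_models"] = list(self.regression_models)
        payload["cohort"]["missing_rates"] = dict(self.cohort.missing_rates)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def synthesize_stage(config: RunConfig, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    normative, primary = sc.generate_cohort(config.cohort)
    normative.to_csv(out / "cohort_normative.csv", index=False)
    primary.to_csv(out / "cohort_primary.csv", index=False)
    return normative, primary


def trace_features_stage(
    config: RunConfig, primary: pd.DataFrame, out: Path
) -> pd.DataFrame:
    """Synthesize raw traces per participant/task and extract features."""
    specs = default_task_specs(config.sample_rate)
    trace_dir = out / "traces"
    trace_dir.mkdir(exist_ok=True)
    rows = []
    for i, row in enumerate(primary.itertuples(index=False)):
        pseed = (config.cohort.seed * 100003 + i * 7919) % (2**31)
        noise_by_task = sc.participant_noise_params(
            pd.Series(row._asdict()), config.cohort, pseed
        )
        recordings = {}
        for t_i, (task, spec) in enumerate(specs.items()):
            rec, target, truth = sc.generate_trace(
                None, spec, noise_by_task[task], (pseed + 31 * t_i) % (2**31)
            )
            recordings[task] = (rec, target)
            if i < 2:  # archive a couple of example traces, not the cohort
                rec.to_csv(trace_dir / f"{row.participant_id}_{task}.csv")
                events_to_frame(truth.saccades).to_csv(
                    trace_dir / f"{row.participant_id}_{task}_events.csv", index=False
                )
        feats = extract_features(recordings, specs, age=row.age,
                                 blink_margin=config.blink_margin)
        feats["participant_id"] = row.participant_id
        rows.append(feats)
    features = pd.DataFrame(rows)[["participant_id"] + ET_FEATURES + ["age"]]
    return features


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns a summary dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    logger.info("stage: synthesize cohorts")
    try:
        normative, primary = synthesize_stage(config, out)
    except Exception as exc:  # pragma: no cover - error surface
        raise RuntimeError(f"stage 'synthesize' failed: {exc}") from exc

    logger.info("stage: features (%s)", config.feature_source)
    if config.feature_source == "traces":
        features = trace_features_stage(config, primary, out)
    else:
        features = sc.planted_feature_values(primary, config.cohort, config.cohort.seed)
        features = features[["participant_id"] + ET_FEATURES + ["age"]]
    features = sc.apply_missingness(
        features, dict(config.cohort.missing_rates), seed=config.cohort.seed
    )
    features.to_csv(out / "features.csv", index=False)

    logger.info("stage: screening")
    screen = screen_features(features, primary, tests=sc.TEST_NAMES)
    screen.to_csv(out / "screening.csv", index=False)

    logger.info("stage: normative labels")
    model = fit_normative(normative)
    model.to_json(out / "normative_model.json")
    labels = label_cohort(model, primary)
    labels.to_csv(out / "labels.csv", index=False)

    y = labels[config.outcome].to_numpy().astype(int)
    X = features[ET_FEATURES + ["age"]]
    moca = primary["moca"].to_numpy(dtype=float)
    seed = config.seed

    summary: dict = {"outcome": config.outcome, "n": int(len(y)),
                     "prevalence": float(y.mean())}

    if config.run_regressions:
        logger.info("stage: regression bank")
        reg = run_regression_bank(
            X, primary[sc.TEST_NAMES], models=config.regression_models,
            folds=config.folds, seed=seed,
        )
        reg.to_csv(out / "regression_metrics.csv", index=False)
        summary["regression"] = reg.to_dict("records")

    logger.info("stage: classifiers")
    res_et = run_classifier(X, y, model="rf", params=config.rf_params,
                            folds=config.folds, seed=seed)
    res_multi = run_classifier(X, y, model="rf", moca=moca,
                               moca_weight=config.moca_weight,
                               params=config.rf_params, folds=config.folds, seed=seed)

    logger.info("stage: evaluation")
    rep_et = evaluate_classifier(res_et.predictions, y, model="rf_et",
                                 min_sensitivity=config.min_sensitivity)
    rep_multi = evaluate_classifier(res_multi.predictions, y, model="rf_et_moca",
                                    min_sensitivity=config.min_sensitivity)
    rep_moca = moca_as_classifier(moca, y)

    thr = rep_et.threshold
    pred_et = res_et.predictions >= thr
    pred_multi = res_multi.predictions >= rep_multi.threshold
    pred_moca = moca < 26
    comparisons = {
        "rf_et_vs_moca": mcnemar(pred_et, pred_moca, y),
        "rf_et_moca_vs_moca": mcnemar(pred_multi, pred_moca, y),
        "rf_et_vs_rf_et_moca": mcnemar(pred_et, pred_multi, y),
    }

    from .modeling import build_classification_matrix

    X_multi = build_classification_matrix(X, moca, config.moca_weight)
    X_multi_imputed = X_multi.fillna(X_multi.mean())
    importances = permutation_importance(
        res_multi, X_multi_imputed, y, n_perm=config.n_permutations, seed=seed
    )
    importances.to_csv(out / "permutation_importance.csv", index=False)

    summary["classifiers"] = {
        "rf_et": rep_et.summary(),
        "rf_et_moca": rep_multi.summary(),
        "moca": rep_moca.summary(),
    }
    summary["mcnemar"] = {k: {"chi2": v[0], "p": v[1]} for k, v in comparisons.items()}
    summary["importance_ranking"] = importances["feature"].tolist()
    (out / "evaluation.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        str(p.relative_to(out)): _checksum(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary["manifest"] = manifest
    return summary
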