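"""Imputation, cross-validated regression/classification banks, tuning.

All model evaluation follows an out-of-fold protocol: 5-fold
cross-validation (shuffled; stratified for classification) where each
participant is predicted exactly once, by a model trained on the folds
that exclude it, and metrics are computed on the pooled out-of-fold
predictions. Missing features are completed with chained-equations
multiple imputation; by default the imputer is fitted inside each
training fold so no test-fold statistics leak into training (a flag
restores global pre-CV imputation). The multimodal classifier controls
the weight of the MoCA predictor by duplicating its column k times in
the feature pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import BayesianRidge, LinearRegression, SGDRegressor
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .config import ConfigurationError

REGRESSION_MODELS = ("ols", "sgd", "xgb", "rf", "mlp")
CLASSIFIER_MODELS = ("lda", "rf")


# ---------------------------------------------------------------------------
# Imputation


def make_imputer(seed: int = 0, estimator: str = "bayesian_ridge",
                 max_iter: int = 25) -> IterativeImputer:
    est = LinearRegression() if estimator == "linear" else BayesianRidge()
    return IterativeImputer(estimator=est, max_iter=max_iter, random_state=seed,
                            sample_posterior=False)


def impute(table: pd.DataFrame, seed: int = 0, estimator: str = "bayesian_ridge",
           max_iter: int = 25) -> pd.DataFrame:
    """Chained-equations imputation of a numeric feature table.

    Each missing column is iteratively regressed on the others; observed
    cells are left untouched and the result is deterministic for a given
    seed. Raises when a column has fewer than two observed values.
    """
    numeric = table.select_dtypes(include=[np.number])
    for col in numeric.columns:
        if numeric[col].notna().sum() < 2:
            raise ConfigurationError(f"column '{col}' has fewer than 2 observed values")
    if not numeric.isna().any().any():
        return table.copy()
    imputer = make_imputer(seed=seed, estimator=estimator, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        completed = imputer.fit_transform(numeric.to_numpy(dtype=float))
    out = table.copy()
    out[numeric.columns] = completed
    return out


# ---------------------------------------------------------------------------
# Cross-validation bookkeeping


@dataclass
class CVResult:
    """Pooled out-of-fold predictions plus full fold bookkeeping."""

    model: str
    predictions: np.ndarray            # regression: yhat; classification: P(class 1)
    fold_assignment: np.ndarray
    train_indices: list[np.ndarray]
    hyperparameters: dict[str, Any]
    seed: int
    fitted_models: list[Any] = field(default_factory=list)

    def assert_out_of_fold(self) -> None:
        """Every participant's prediction comes from a model that never saw it."""
        for fold_id, train_idx in enumerate(self.train_indices):
            test_idx = np.flatnonzero(self.fold_assignment == fold_id)
            if np.intersect1d(train_idx, test_idx).size:
                raise AssertionError(f"fold {fold_id} leaks test participants into training")
        covered = np.concatenate(
            [np.flatnonzero(self.fold_assignment == f) for f in range(len(self.train_indices))]
        )
        if len(np.unique(covered)) != len(self.fold_assignment):
            raise AssertionError("folds do not partition the cohort")


def _build_regressor(model: str, params: dict[str, Any], seed: int):
    if model == "ols":
        return LinearRegression(**params)
    if model == "sgd":
        return SGDRegressor(random_state=seed, max_iter=2000, **params)
    if model == "xgb":
        from xgboost import XGBRegressor

        defaults = dict(n_estimators=100, max_depth=3, learning_rate=0.1,
                        subsample=1.0, reg_lambda=1.0, verbosity=0)
        defaults.update(params)
        return XGBRegressor(random_state=seed, **defaults)
    if model == "rf":
        defaults = dict(n_estimators=200)
        defaults.update(params)
        return RandomForestRegressor(random_state=seed, **defaults)
    if model == "mlp":
        defaults = dict(hidden_layer_sizes=(16,), max_iter=500, early_stopping=False)
        defaults.update(params)
        return MLPRegressor(random_state=seed, **defaults)
    raise ConfigurationError(f"unknown regression model '{model}'")


def _build_classifier(model: str, params: dict[str, Any], seed: int):
    if model == "lda":
        return LinearDiscriminantAnalysis(**params)
    if model == "rf":
        defaults = dict(n_estimators=200)
        defaults.update(params)
        return RandomForestClassifier(random_state=seed, **defaults)
    raise ConfigurationError(f"unknown classifier '{model}'")


_SCALED_MODELS = {"sgd", "mlp", "lda"}


def _cv_predict(
    X: pd.DataFrame,
    y: np.ndarray,
    build: Callable[[], Any],
    model_name: str,
    folds: int,
    seed: int,
    stratified: bool,
    classification: bool,
    impute_within_fold: bool = True,
    impute_seed: int | None = None,
) -> CVResult:
    Xv = X.to_numpy(dtype=float)
    n = len(Xv)
    if stratified:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xv, y)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xv)

    impute_seed = seed if impute_seed is None else impute_seed
    has_missing = np.isnan(Xv).any()
    if has_missing and not impute_within_fold:
        Xv = (
            make_imputer(seed=impute_seed)
            .fit_transform(Xv)
        )
        has_missing = False

    preds = np.full(n, np.nan)
    fold_assignment = np.full(n, -1, dtype=int)
    train_indices: list[np.ndarray] = []
    fitted = []
    for fold_id, (tr, te) in enumerate(split_iter):
        Xtr, Xte = Xv[tr], Xv[te]
        if has_missing:
            imp = make_imputer(seed=impute_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Xtr = imp.fit_transform(Xtr)
                Xte = imp.transform(Xte)
        if model_name in _SCALED_MODELS:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        est = build()
        if classification and len(np.unique(y[tr])) < 2:
            raise ConfigurationError(f"fold {fold_id} has a single training class")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xtr, y[tr])
            if classification:
                preds[te] = est.predict_proba(Xte)[:, 1]
            else:
                preds[te] = est.predict(Xte)
        fold_assignment[te] = fold_id
        train_indices.append(np.asarray(tr))
        fitted.append((est, np.asarray(te)))
    result = CVResult(
        model=model_name,
        predictions=preds,
        fold_assignment=fold_assignment,
        train_indices=train_indices,
        hyperparameters={},
        seed=seed,
        fitted_models=fitted,
    )
    result.assert_out_of_fold()
    return result


# ---------------------------------------------------------------------------
# Regression bank


def rmspe(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared percentage error, in percent.

    Observations with y = 0 are excluded (with a warning) because the
    percentage error is undefined there.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    keep = y != 0
    if not keep.all():
        warnings.warn(f"{(~keep).sum()} zero outcomes excluded from RMSPE")
    if not keep.any():
        return float("nan")
    rel = (y[keep] - yhat[keep]) / y[keep]
    return float(100.0 * np.sqrt(np.mean(rel * rel)))


def run_regression(
    X: pd.DataFrame,
    y: np.ndarray,
    model: str = "ols",
    params: dict[str, Any] | None = None,
    folds: int = 5,
    seed: int = 0,
    impute_within_fold: bool = True,
) -> tuple[CVResult, dict[str, float]]:
    """Out-of-fold regression of one continuous outcome.

    Returns the CV result and pooled metrics (R^2 and RMSPE).
    """
    params = params or {}
    result = _cv_predict(
        X, np.asarray(y, dtype=float),
        build=lambda: _build_regressor(model, params, seed),
        model_name=model, folds=folds, seed=seed, stratified=False,
        classification=False, impute_within_fold=impute_within_fold,
    )
    result.hyperparameters = params
    metrics = {
        "r2": float(r2_score(y, result.predictions)),
        "rmspe": rmspe(y, result.predictions),
    }
    return result, metrics


def run_regression_bank(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    models: tuple[str, ...] = REGRESSION_MODELS,
    params: dict[str, dict[str, Any]] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Every regression model against every outcome column.

    Returns a tidy table (model, outcome, r2, rmspe) of pooled
    out-of-fold metrics.
    """
    params = params or {}
    rows = []
    for model in models:
        for outcome in outcomes.columns:
            _, metrics = run_regression(
                X, outcomes[outcome].to_numpy(), model=model,
                params=params.get(model, {}), folds=folds, seed=seed,
            )
            rows.append({"model": model, "outcome": outcome, **metrics})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classification


def build_classification_matrix(
    et_features: pd.DataFrame,
    moca: np.ndarray | None = None,
    moca_weight: int = 0,
) -> pd.DataFrame:
    """Assemble the predictor matrix, duplicating MoCA ``moca_weight`` times.

    ``moca_weight=0`` yields the ET-only matrix; k >= 1 appends k copies
    of the MoCA column, which raises its selection probability during
    random-forest tree construction.
    """
    X = et_features.copy()
    if moca_weight > 0:
        if moca is None:
            raise ConfigurationError("moca_weight > 0 requires MoCA scores")
        for i in range(moca_weight):
            X[f"moca_{i}" if i else "moca"] = np.asarray(moca, dtype=float)
    return X


def run_classifier(
    et_features: pd.DataFrame,
    y: np.ndarray,
    model: str = "rf",
    moca: np.ndarray | None = None,
    moca_weight: int = 0,
    params: dict[str, Any] | None = None,
    folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
    impute_within_fold: bool = True,
) -> CVResult:
    """Out-of-fold binary classification with pooled class-1 scores."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("both classes must be present")
    params = params or {}
    X = build_classification_matrix(et_features, moca, moca_weight)
    try:
        result = _cv_predict(
            X, y, build=lambda: _build_classifier(model, params, seed),
            model_name=model, folds=folds, seed=seed, stratified=stratified,
            classification=True, impute_within_fold=impute_within_fold,
        )
    except ConfigurationError:
        # single-class fold: retry once with a stratified refold
        result = _cv_predict(
            X, y, build=lambda: _build_classifier(model, params, seed),
            model_name=model, folds=folds, seed=seed + 1, stratified=True,
            classification=True, impute_within_fold=impute_within_fold,
        )
    result.hyperparameters = dict(params, moca_weight=moca_weight)
    return result


# ---------------------------------------------------------------------------
# Hyperparameter search

RF_CLASSIFIER_SPACE = {
    "n_estimators": lambda rng: int(rng.choice([100, 200, 300, 500])),
    "max_depth": lambda rng: rng.choice([None, 3, 5, 8, 12]),
    "max_features": lambda rng: rng.choice(["sqrt", "log2", None]),
    "min_samples_leaf": lambda rng: int(rng.choice([1, 2, 4, 8])),
    "class_weight": lambda rng: rng.choice([None, "balanced"]),
}

RF_REGRESSOR_SPACE = {
    "n_estimators": lambda rng: int(rng.choice([100, 200, 300, 500])),
    "max_depth": lambda rng: rng.choice([None, 3, 5, 8, 12]),
    "max_features": lambda rng: rng.choice(["sqrt", "log2", None]),
    "min_samples_leaf": lambda rng: int(rng.choice([1, 2, 4, 8])),
}

XGB_SPACE = {
    "n_estimators": lambda rng: int(rng.choice([50, 100, 200, 400])),
    "max_depth": lambda rng: int(rng.choice([2, 3, 4, 6])),
    "learning_rate": lambda rng: float(10 ** rng.uniform(-2.5, -0.5)),
    "subsample": lambda rng: float(rng.uniform(0.5, 1.0)),
    "reg_lambda": lambda rng: float(10 ** rng.uniform(-2, 2)),
}

SGD_SPACE = {
    "loss": lambda rng: rng.choice(["squared_error", "huber"]),
    "penalty": lambda rng: rng.choice(["l2", "l1", "elasticnet"]),
    "alpha": lambda rng: float(10 ** rng.uniform(-6, 0)),
}

MLP_SPACE = {
    "hidden_layer_sizes": lambda rng: tuple(
        int(rng.choice([8, 16, 32, 64])) for _ in range(int(rng.integers(1, 4)))
    ),
    # sklearn's MLP offers relu/tanh; tanh stands in for the smooth option
    "activation": lambda rng: str(rng.choice(["relu", "tanh"])),
    "alpha": lambda rng: float(10 ** rng.uniform(-6, -1)),
    "learning_rate_init": lambda rng: float(10 ** rng.uniform(-4, -1.5)),
    "batch_size": lambda rng: int(rng.choice([16, 32, 64])),
    "early_stopping": lambda rng: bool(rng.choice([True, False])),
    "n_iter_no_change": lambda rng: int(rng.choice([5, 10, 20])),
}

LDA_SPACE = {
    "solver": lambda rng: str(rng.choice(["svd", "lsqr"])),
    "shrinkage": lambda rng: rng.choice([None, "auto"]),
}

SEARCH_SPACES = {
    ("classification", "rf"): RF_CLASSIFIER_SPACE,
    ("classification", "lda"): LDA_SPACE,
    ("regression", "rf"): RF_REGRESSOR_SPACE,
    ("regression", "xgb"): XGB_SPACE,
    ("regression", "sgd"): SGD_SPACE,
    ("regression", "mlp"): MLP_SPACE,
}


def sample_configuration(space: dict[str, Callable], rng: np.random.Generator) -> dict[str, Any]:
    cfg = {k: sampler(rng) for k, sampler in space.items()}
    if cfg.get("solver") == "svd":
        cfg.pop("shrinkage", None)
    return cfg


def tune(
    objective: Callable[[dict[str, Any]], float],
    space: dict[str, Callable],
    budget: int = 80,
    seed: int = 0,
    maximize: bool = True,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Seeded random search over a sampler space.

    Evaluates ``budget`` sampled configurations with the caller's
    cross-validated objective and returns the best one plus the full
    search history. Deterministic for a given seed.
    """
    if budget < 1:
        raise ConfigurationError("search budget must be at least 1")
    if not space:
        raise ConfigurationError("empty search space")
    rng = np.random.default_rng(seed)
    history = []
    best_cfg, best_val = None, -np.inf
    for i in range(budget):
        cfg = sample_configuration(space, rng)
        val = objective(cfg)
        signed = val if maximize else -val
        history.append({"trial": i, "value": val, **{k: str(v) for k, v in cfg.items()}})
        if signed > best_val:
            best_val, best_cfg = signed, cfg
    return best_cfg, pd.DataFrame(history)


def tune_classifier(
    et_features: pd.DataFrame,
    y: np.ndarray,
    model: str = "rf",
    moca: np.ndarray | None = None,
    moca_weight: int = 0,
    budget: int = 80,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """ROC-AUC-maximizing random search for one classification outcome."""

    def objective(cfg: dict[str, Any]) -> float:
        res = run_classifier(
            et_features, y, model=model, moca=moca, moca_weight=moca_weight,
            params=cfg, folds=folds, seed=seed,
        )
        return float(roc_auc_score(y, res.predictions))

    return tune(objective, SEARCH_SPACES[("classification", model)],
                budget=budget, seed=seed, maximize=True)


def tune_regressor(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    model: str,
    budget: int = 80,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict[str, Any], pd.DataFrame]:
    """Random search minimizing the mean out-of-fold error across outcomes."""

    def objective(cfg: dict[str, Any]) -> float:
        errs = []
        for outcome in outcomes.columns:
            y = outcomes[outcome].to_numpy(dtype=float)
            res, _ = run_regression(X, y, model=model, params=cfg, folds=folds, seed=seed)
            errs.append(float(np.sqrt(np.mean((y - res.predictions) ** 2)) / (np.std(y) or 1.0)))
        return float(np.mean(errs))

    return tune(objective, SEARCH_SPACES[("regression", model)],
                budget=budget, seed=seed, maximize=False)
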