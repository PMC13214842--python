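"""Imputation, out-of-fold model banks, MoCA weighting, random search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import oculocog.cohort as sc
from oculocog.config import ConfigurationError
from oculocog.modeling import (
    RF_CLASSIFIER_SPACE,
    build_classification_matrix,
    impute,
    rmspe,
    run_classifier,
    run_regression,
    run_regression_bank,
    tune,
    tune_classifier,
)


class TestImpute:
    def test_complete_table_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        pd.testing.assert_frame_equal(impute(df), df)

    def test_perfectly_correlated_pair_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        df = pd.DataFrame({"a": a, "b": 2.0 * a})
        df.loc[7, "b"] = np.nan
        out = impute(df, estimator="linear")
        assert out.loc[7, "b"] == pytest.approx(2.0 * a[7], abs=1e-6)
        # observed cells untouched
        assert np.allclose(out.drop(index=7)["b"], np.delete(2.0 * a, 7))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (60, 4)), columns=list("abcd"))
        df.iloc[::7, 2] = np.nan
        pd.testing.assert_frame_equal(impute(df, seed=3), impute(df, seed=3))

    def test_beats_mean_imputation_on_correlated_data(self):
        """Chained-equations RMSE below mean-imputation RMSE over 10 seeds."""
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            z = rng.normal(0, 1, 300)
            df = pd.DataFrame(
                {
                    "a": z + rng.normal(0, 0.3, 300),
                    "b": z + rng.normal(0, 0.3, 300),
                    "c": z + rng.normal(0, 0.3, 300),
                }
            )
            truth = df["a"].copy()
            mask = rng.random(300) < 0.15
            df.loc[mask, "a"] = np.nan
            out = impute(df, seed=s)
            rmse_mi = np.sqrt(np.mean((out.loc[mask, "a"] - truth[mask]) ** 2))
            rmse_mean = np.sqrt(np.mean((truth[~mask].mean() - truth[mask]) ** 2))
            wins += int(rmse_mi < rmse_mean)
        assert wins == 10

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ConfigurationError):
            impute(df)


class TestRegression:
    def _matrix(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("wxyz"))

    def test_noiseless_linear_outcome_near_perfect_ols(self):
        X = self._matrix()
        y = 2.0 * X["w"] - 1.0 * X["x"] + 0.5 * X["y"] + 3.0
        _, metrics = run_regression(X, y.to_numpy(), model="ols", seed=0)
        assert metrics["r2"] > 0.99

    def test_independent_outcome_mean_r2_nonpositive(self):
        """Permuted outcomes: the linear model cannot beat the fold-mean
        baseline, so pooled out-of-fold R^2 averages below zero."""
        r2s = []
        for s in range(20):
            X = self._matrix(seed=s)
            rng = np.random.default_rng(1000 + s)
            y = rng.normal(50, 10, len(X))
            _, metrics = run_regression(X, y, model="ols", seed=s)
            r2s.append(metrics["r2"])
        assert np.mean(r2s) <= 0.0

    def test_constant_predictors_hit_mean_baseline(self):
        X = pd.DataFrame({"c": np.ones(100)})
        rng = np.random.default_rng(2)
        y = rng.normal(10, 2, 100)
        _, metrics = run_regression(X, y, model="ols", seed=2)
        assert -0.2 < metrics["r2"] <= 0.01

    def test_rmspe_closed_form_and_zero_exclusion(self):
        y = np.array([10.0, 20.0, 0.0])
        yhat = np.array([11.0, 18.0, 5.0])
        with pytest.warns(UserWarning):
            val = rmspe(y, yhat)
        expected = 100.0 * np.sqrt(np.mean([(1 / 10) ** 2, (2 / 20) ** 2]))
        assert val == pytest.approx(expected)

    def test_bank_covers_models_and_outcomes(self):
        X = self._matrix(n=60)
        rng = np.random.default_rng(3)
        outcomes = pd.DataFrame({"s1": rng.normal(30, 5, 60), "s2": rng.normal(60, 9, 60)})
        table = run_regression_bank(X, outcomes, models=("ols", "rf"),
                                    params={"rf": {"n_estimators": 20}}, seed=3)
        assert set(table["model"]) == {"ols", "rf"}
        assert set(table["outcome"]) == {"s1", "s2"}
        assert table["r2"].notna().all()


class TestClassifier:
    def test_separable_labels_perfect_auc(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(0, 1, 120)})
        y = (X["a"] > 0).astype(int).to_numpy()
        res = run_classifier(X, y, model="lda", seed=0)
        assert roc_auc_score(y, res.predictions) == 1.0

    def test_shuffled_labels_chance_auc(self):
        aucs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(0, 1, (150, 4)), columns=list("abcd"))
            y = rng.integers(0, 2, 150)
            res = run_classifier(X, y, model="rf", params={"n_estimators": 50}, seed=s)
            aucs.append(roc_auc_score(y, res.predictions))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_out_of_fold_integrity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (80, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 80)
        res = run_classifier(X, y, model="rf", params={"n_estimators": 20}, seed=1)
        res.assert_out_of_fold()
        assert (res.fold_assignment >= 0).all()
        assert np.isfinite(res.predictions).all()

    def test_moca_duplication_matrix_shape(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        out = build_classification_matrix(X, moca=np.array([26.0, 24.0]), moca_weight=3)
        assert list(out.columns) == ["a", "moca", "moca_1", "moca_2"]
        with pytest.raises(ConfigurationError):
            build_classification_matrix(X, moca=None, moca_weight=1)

    def test_moca_weighting_helps_when_moca_carries_the_signal(self):
        """Planted MoCA-only signal: including the duplicated MoCA column
        raises pooled AUC over the ET-only model, averaged over seeds."""
        gains = []
        for s in range(12):
            X, moca, y = sc.generate_multimodal_dataset(seed=s, et_strength=0.0)
            p = {"n_estimators": 100}
            a0 = roc_auc_score(y, run_classifier(X, y, model="rf", params=p, seed=s).predictions)
            a1 = roc_auc_score(
                y,
                run_classifier(X, y, model="rf", moca=moca, moca_weight=1,
                               params=p, seed=s).predictions,
            )
            gains.append(a1 - a0)
        assert np.mean(gains) > 0.05

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ConfigurationError):
            run_classifier(X, np.zeros(10, dtype=int), model="lda")


class TestTune:
    def test_budget_one_returns_that_configuration(self):
        calls = []

        def objective(cfg):
            calls.append(cfg)
            return 1.0

        best, history = tune(objective, RF_CLASSIFIER_SPACE, budget=1, seed=0)
        assert len(calls) == 1 and best == calls[0]
        assert len(history) == 1

    def test_deterministic_selection(self):
        def objective(cfg):
            return float(cfg["n_estimators"]) - 10.0 * (cfg["min_samples_leaf"] or 0)

        b1, _ = tune(objective, RF_CLASSIFIER_SPACE, budget=15, seed=7)
        b2, _ = tune(objective, RF_CLASSIFIER_SPACE, budget=15, seed=7)
        assert b1 == b2

    def test_empty_space_and_budget_rejected(self):
        with pytest.raises(ConfigurationError):
            tune(lambda c: 0.0, {}, budget=5)
        with pytest.raises(ConfigurationError):
            tune(lambda c: 0.0, RF_CLASSIFIER_SPACE, budget=0)

    def test_search_approaches_known_good_configuration(self):
        """On a planted problem the searched objective reaches >= 95% of a
        known strong configuration's objective."""
        X, moca, y = sc.generate_multimodal_dataset(n=120, seed=5)
        space = {
            "n_estimators": lambda rng: int(rng.choice([25, 50])),
            "max_depth": lambda rng: rng.choice([2, 5, None]),
        }

        def objective(cfg):
            res = run_classifier(X, y, model="rf", moca=moca, moca_weight=1,
                                 params=cfg, folds=5, seed=5)
            return float(roc_auc_score(y, res.predictions))

        best, history = tune(objective, space, budget=6, seed=5)
        oracle = objective({"n_estimators": 50, "max_depth": None})
        assert history["value"].max() >= 0.95 * oracle

    def test_classifier_tuner_runs_end_to_end(self):
        X, moca, y = sc.generate_multimodal_dataset(n=100, seed=2)
        best, history = tune_classifier(X, y, model="lda", budget=4, seed=2)
        assert len(history) == 4
        assert "solver" in best
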