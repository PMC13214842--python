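"""Normative expected-score model, z-scores, alteration labels, composites."""

import numpy as np
import pandas as pd
import pytest

import oculocog.cohort as sc
from oculocog.config import CohortConfig, ConfigurationError
from oculocog.normative import (
    COMPOSITES,
    NormativeModel,
    binarize,
    composites,
    fit_normative,
    label_cohort,
    moca_label,
    z_scores,
)


def _toy_normative(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(30, 65, n)
    edu = rng.uniform(8, 20, n)
    female = rng.random(n) < 0.7
    score = 90.0 - 0.8 * age + 1.5 * edu + 2.0 * female + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "participant_id": [f"T{i}" for i in range(n)],
            "age": age,
            "education": edu,
            "gender": np.where(female, "female", "male"),
            "digit_symbol": score,
            "tmt_a": 100.0 + 0.5 * age - edu + rng.normal(0, noise, n),
            "tmt_b": 200.0 + 0.5 * age - edu + rng.normal(0, noise, n),
        }
    )


class TestFitNormative:
    def test_noiseless_linear_scores_recovered_exactly(self):
        model = fit_normative(_toy_normative(), tests=["digit_symbol"])
        beta = model.coefficients["digit_symbol"]
        assert np.allclose(beta, [90.0, -0.8, 1.5, 2.0], atol=1e-8)
        assert model.sigma["digit_symbol"] < 1e-6

    def test_row_permutation_invariance(self):
        df = _toy_normative(noise=3.0)
        m1 = fit_normative(df, tests=["digit_symbol"])
        m2 = fit_normative(df.sample(frac=1.0, random_state=1), tests=["digit_symbol"])
        assert np.allclose(m1.coefficients["digit_symbol"], m2.coefficients["digit_symbol"])

    def test_parameter_recovery_within_three_se(self):
        """Known coefficients with noise sigma=5 at n=133: estimates within
        3 SE and sigma-hat within 20%, averaged over 20 seeds."""
        true = np.array([90.0, -0.8, 1.5, 2.0])
        cover = 0
        sigma_ratios = []
        for s in range(20):
            df = _toy_normative(n=133, seed=s, noise=5.0)
            model = fit_normative(df, tests=["digit_symbol"])
            beta = np.asarray(model.coefficients["digit_symbol"])
            female = (df["gender"] == "female").astype(float)
            X = np.column_stack([np.ones(133), df["age"], df["education"], female])
            cov = 5.0**2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(np.diag(cov))
            cover += int(np.all(np.abs(beta - true) <= 3 * se))
            sigma_ratios.append(model.sigma["digit_symbol"] / 5.0)
        assert cover >= 18
        assert abs(np.mean(sigma_ratios) - 1.0) < 0.2

    def test_collinear_design_names_predictor(self):
        df = _toy_normative()
        df["education"] = df["age"]  # perfectly collinear
        with pytest.raises(ConfigurationError, match="age|education"):
            fit_normative(df, tests=["digit_symbol"])

    def test_serialization_round_trip(self, tmp_path):
        model = fit_normative(_toy_normative(noise=2.0), tests=["digit_symbol", "tmt_a"])
        path = tmp_path / "norm.json"
        model.to_json(path)
        loaded = NormativeModel.from_json(path)
        for test in model.tests:
            assert np.allclose(loaded.coefficients[test], model.coefficients[test])
            assert loaded.sigma[test] == pytest.approx(model.sigma[test])


class TestZScores:
    def test_observed_equals_expected_gives_zero(self):
        df = _toy_normative()
        model = fit_normative(df, tests=["digit_symbol"])
        model.sigma["digit_symbol"] = 4.0
        zs = z_scores(model, df)
        assert np.allclose(zs["z_digit_symbol"], 0.0, atol=1e-8)

    def test_two_sigma_deviation_gives_z_two(self):
        df = _toy_normative()
        model = fit_normative(df, tests=["digit_symbol"])
        model.sigma["digit_symbol"] = 4.0
        shifted = df.copy()
        shifted["digit_symbol"] += 8.0
        zs = z_scores(model, shifted)
        assert np.allclose(zs["z_digit_symbol"], 2.0, atol=1e-8)

    def test_in_sample_calibration(self, default_config):
        """Applying the model to its own normative sample: mean z ~ 0,
        SD ~ 1 for every test."""
        normative, _ = sc.generate_cohort(default_config)
        model = fit_normative(normative)
        zs = z_scores(model, normative)
        for test in model.tests:
            col = zs[f"z_{test}"]
            assert abs(col.mean()) < 0.05
            assert abs(col.std() - 1.0) < 0.1

    def test_missing_demographics_propagate(self):
        df = _toy_normative()
        model = fit_normative(df, tests=["digit_symbol"])
        df2 = df.copy()
        df2.loc[df2.index[0], "education"] = np.nan
        zs = z_scores(model, df2)
        assert np.isnan(zs["z_digit_symbol"].iloc[0])
        assert np.isfinite(zs["z_digit_symbol"].iloc[1:]).all()


class TestBinarize:
    @pytest.mark.parametrize(
        "z,test,expected",
        [
            (-1.5, "digit_symbol", True),
            (+1.5, "tmt_a", True),
            (+1.5, "digit_symbol", False),
            (-1.5, "tmt_a", False),
            (-1.0, "digit_symbol", False),   # strict inequality at |z| = 1
            (+1.0, "tmt_a", False),
            (-0.99, "digit_symbol", False),
        ],
    )
    def test_direction_and_strictness(self, z, test, expected):
        assert binarize(z, test) is expected

    def test_unknown_direction_uses_explicit_set(self):
        assert binarize(1.5, "tmt_b_minus_a") is True


class TestMocaLabel:
    @pytest.mark.parametrize("score,expected", [(25, True), (26, False), (30, False), (16, True)])
    def test_cutoff(self, score, expected):
        assert moca_label(score) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            moca_label(31)
        with pytest.raises(ValueError):
            moca_label(-1)


class TestComposites:
    def _flags(self, altered_tests):
        all_tests = sorted({m for ms in COMPOSITES.values() for m in ms} | set(sc.NON_MOCA_TESTS))
        return pd.DataFrame([{t: t in altered_tests for t in all_tests}])

    def test_no_altered_members_not_altered(self):
        out = composites(self._flags(set()))
        assert not out.iloc[0].any()

    def test_two_altered_members_trigger_composite(self):
        out = composites(self._flags({"digit_span_backward", "stroop_color_word"}))
        assert out.iloc[0]["exec_fn_1"] and out.iloc[0]["exec_fn_2"]

    def test_single_altered_member_insufficient(self):
        out = composites(self._flags({"digit_span_forward"}))
        assert not out.iloc[0]["attention"]

    def test_monotone_in_members(self):
        rng = np.random.default_rng(0)
        all_tests = sorted({m for ms in COMPOSITES.values() for m in ms} | set(sc.NON_MOCA_TESTS))
        for _ in range(30):
            base_set = {t for t in all_tests if rng.random() < 0.3}
            extra = rng.choice([t for t in all_tests if t not in base_set]) if len(base_set) < len(all_tests) else None
            out1 = composites(self._flags(base_set)).iloc[0]
            out2 = composites(self._flags(base_set | ({extra} if extra else set()))).iloc[0]
            assert (out2 | ~out1).all()  # no composite flips altered -> not

    def test_global_invariant_to_moca(self, default_config):
        normative, primary = sc.generate_cohort(default_config)
        model = fit_normative(normative)
        labels1 = label_cohort(model, primary)
        shifted = primary.copy()
        shifted["moca"] = np.clip(shifted["moca"] - 5, 16, 30)
        labels2 = label_cohort(model, shifted)
        assert labels1["global"].equals(labels2["global"])

    def test_slower_tmt_never_lowers_altered_rate(self, default_config):
        normative, primary = sc.generate_cohort(default_config)
        model = fit_normative(normative)
        base = label_cohort(model, primary)["tmt_b"].mean()
        slower = primary.copy()
        slower["tmt_b"] += 40.0
        worse = label_cohort(model, slower)["tmt_b"].mean()
        assert worse >= base
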