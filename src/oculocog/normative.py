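"""Demographically adjusted impairment labels.

Expected test scores are modeled on the normative sample by OLS with
age, years of education and gender as predictors; a participant's
z-score is (observed - expected) / sigma_normative, with sigma the
residual SD of the normative fit (n - p denominator). A test is
"altered" when the z-score exceeds 1 in the direction of impairment:
z < -1 for higher-is-better tests, z > +1 for time-based tests (TMT).
MoCA is labeled by its conventional raw cutoff (< 26). Domain
composites are altered when two or more member tests are altered; the
global composite pools all tests except MoCA.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import NON_MOCA_TESTS, TIME_BASED_TESTS
from .config import ConfigurationError

logger = logging.getLogger(__name__)

MOCA_CUTOFF = 26

COMPOSITES: dict[str, list[str]] = {
    "attention": ["digit_span_forward", "tmt_a"],
    "exec_fn_1": ["digit_span_backward", "tmt_b_minus_a", "stroop_color_word",
                  "phonological_fluency"],
    "exec_fn_2": ["digit_span_backward", "tmt_b", "stroop_color_word",
                  "phonological_fluency"],
    "proc_speed_1": ["digit_symbol", "tmt_a", "stroop_word", "stroop_color"],
    "proc_speed_2": ["digit_symbol", "stroop_word", "stroop_color"],
}

PREDICTORS = ["age", "education", "gender_female"]


def _design(cohort: pd.DataFrame) -> np.ndarray:
    female = (cohort["gender"].astype(str) == "female").astype(float).to_numpy()
    return np.column_stack(
        [np.ones(len(cohort)), cohort["age"].to_numpy(dtype=float),
         cohort["education"].to_numpy(dtype=float), female]
    )


def derive_tmt_difference(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add the TMT B-minus-A contrast (seconds, time-based direction)."""
    out = cohort.copy()
    if "tmt_a" in out.columns and "tmt_b" in out.columns:
        out["tmt_b_minus_a"] = out["tmt_b"] - out["tmt_a"]
    return out


@dataclass
class NormativeModel:
    """Per-test OLS expected-score models fitted on the normative sample."""

    coefficients: dict[str, list[float]]   # intercept, age, education, female
    sigma: dict[str, float]
    time_based: set[str] = field(default_factory=lambda: set(TIME_BASED_TESTS))
    predictors: list[str] = field(default_factory=lambda: list(PREDICTORS))

    @property
    def tests(self) -> list[str]:
        return list(self.coefficients)

    def expected(self, cohort: pd.DataFrame, test: str) -> np.ndarray:
        return _design(cohort) @ np.asarray(self.coefficients[test])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "predictors": ["intercept"] + self.predictors,
            "time_based": sorted(self.time_based),
            "tests": {
                t: {"coefficients": self.coefficients[t], "sigma": self.sigma[t]}
                for t in self.tests
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            coefficients={t: v["coefficients"] for t, v in payload["tests"].items()},
            sigma={t: v["sigma"] for t, v in payload["tests"].items()},
            time_based=set(payload["time_based"]),
        )


def fit_normative(
    normative: pd.DataFrame, tests: list[str] | None = None
) -> NormativeModel:
    """Fit the per-test expected-score OLS on the normative sample.

    ``sigma`` is the residual SD with an n - p denominator (p = 4).
    Raises on missing scores, insufficient sample or a collinear design.
    """
    normative = derive_tmt_difference(normative)
    if tests is None:
        tests = [c for c in normative.columns if c in set(NON_MOCA_TESTS) | {"moca", "tmt_b_minus_a"}]
    if len(normative) < 10:
        raise ConfigurationError("normative sample must have at least 10 rows")
    X = _design(normative)
    p = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending predictor for the error message
        for j, name in enumerate(["intercept"] + PREDICTORS):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ConfigurationError(f"collinear predictor in normative design: {name}")
        raise ConfigurationError("rank-deficient normative design")

    coefs, sigmas = {}, {}
    for test in tests:
        y = normative[test].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ConfigurationError(f"missing scores in normative test {test}")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma = float(np.sqrt(resid @ resid / (len(y) - p)))
        if sigma <= 0:
            sigma = np.finfo(float).tiny
        coefs[test] = beta.tolist()
        sigmas[test] = sigma
    return NormativeModel(coefficients=coefs, sigma=sigmas)


def z_scores(model: NormativeModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Standardized deviations from demographically expected scores."""
    cohort = derive_tmt_difference(cohort)
    out = pd.DataFrame({"participant_id": cohort["participant_id"].to_numpy()})
    demo_ok = cohort[["age", "education", "gender"]].notna().all(axis=1).to_numpy()
    for test in model.tests:
        expected = model.expected(cohort, test)
        observed = cohort[test].to_numpy(dtype=float)
        z = (observed - expected) / model.sigma[test]
        z[~demo_ok] = np.nan
        out[f"z_{test}"] = z
    return out


def binarize(z: float, test: str, time_based: set[str] | None = None) -> bool:
    """Altered flag from a z-score: strict one-sided |z| > 1 by direction."""
    if time_based is None:
        time_based = set(TIME_BASED_TESTS) | {"tmt_b_minus_a"}
    if isinstance(test, str) and test.startswith("z_"):
        test = test[2:]
    if not isinstance(z, (int, float)) or not math.isfinite(z):
        return False
    return z > 1.0 if test in time_based else z < -1.0


def moca_label(score: float) -> bool:
    """Altered by the conventional clinical cutoff: raw MoCA < 26."""
    if not math.isfinite(score) or not 0 <= score <= 30:
        raise ValueError(f"MoCA score out of range: {score}")
    return score < MOCA_CUTOFF


def composites(altered: pd.DataFrame) -> pd.DataFrame:
    """Domain composites: altered when >= 2 member tests are altered.

    ``altered`` holds per-test boolean columns. Missing member columns
    count as not-altered (with a logged warning). The global composite
    uses every non-MoCA test (the raw TMT times, not the B-A contrast).
    """
    out = pd.DataFrame(index=altered.index)
    for name, members in COMPOSITES.items():
        present = [m for m in members if m in altered.columns]
        absent = set(members) - set(present)
        if absent:
            logger.warning("composite %s missing member tests %s; treated as not altered",
                           name, sorted(absent))
        counts = altered[present].fillna(False).sum(axis=1) if present else 0
        out[name] = counts >= 2
    global_members = [t for t in NON_MOCA_TESTS if t in altered.columns]
    out["global"] = altered[global_members].fillna(False).sum(axis=1) >= 2
    return out


def label_cohort(model: NormativeModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Full label table: z per test, per-test altered flags, MoCA flag,
    and the six composite labels."""
    zs = z_scores(model, cohort)
    time_based = model.time_based | {"tmt_b_minus_a"}
    flags = pd.DataFrame({"participant_id": zs["participant_id"]})
    for test in model.tests:
        if test == "moca":
            continue
        flags[test] = [
            binarize(z, test, time_based) for z in zs[f"z_{test}"]
        ]
    flags["moca_altered"] = [moca_label(s) for s in cohort["moca"]]
    comp = composites(flags.drop(columns=["participant_id", "moca_altered"]))
    return pd.concat([zs, flags.drop(columns="participant_id"), comp], axis=1)
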