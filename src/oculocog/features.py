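"""Scalar oculomotor features and the partial-Spearman feature screen.

Four features summarize each participant: fixation RMS error under
distractors, smooth-pursuit RMS error for the sinusoidal and vertical
trajectories, and the relative pupil-area reduction to a light step.
RMS is the root-mean-square Euclidean gaze-target distance over all
valid samples of a trial (saccades included; blink margins excluded).
The pupil feature is (B - C) / B with B the mean area over the 1 s
before LED onset and C the mean over the 1 s from the first qualifying
post-onset local minimum (at least a 10% drop from baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ET_FEATURES, TaskSpec
from .containers import GazeRecording, TargetTrace

FEATURE_TASK_MAP = {
    "fix_rms_distractors": "fixation_distractors",
    "sp_rms_sinusoidal": "pursuit_sinusoidal",
    "sp_rms_vertical": "pursuit_vertical",
}


def rms_error(gaze: GazeRecording, target: TargetTrace) -> float:
    """RMS Euclidean gaze-target distance over valid samples, degrees.

    Computed across the full trial: every valid sample contributes, with
    the target taken at the gaze timestamp by nearest-sample lookup.
    Returns NaN when no valid samples remain.
    """
    valid = gaze.valid
    if not valid.any():
        return math.nan
    tx, ty = target.at(gaze.time[valid])
    dx = gaze.x[valid] - tx
    dy = gaze.y[valid] - ty
    return float(np.sqrt(np.mean(dx * dx + dy * dy)))


@dataclass
class PupilTrial:
    """A pupil light-reflex recording and its derived quantities."""

    trace: GazeRecording
    led_onset: float                 # ms
    baseline: float = math.nan       # B, device units
    constriction: float = math.nan   # C, device units
    t_min: float | None = None       # ms


def pupil_baseline(
    trial: PupilTrial, window_ms: float = 1000.0, min_valid_frac: float = 0.5
) -> float:
    """Mean pupil area over the 1 s interval preceding LED onset.

    NaN when fewer than ``min_valid_frac`` of the window's nominal
    samples are valid.
    """
    rec = trial.trace
    sel = (rec.time >= trial.led_onset - window_ms) & (rec.time < trial.led_onset)
    nominal = max(int(window_ms * rec.sample_rate / 1000.0), 1)
    good = sel & rec.valid
    if good.sum() == 0 or good.sum() < min_valid_frac * min(nominal, sel.sum()):
        return math.nan
    b = float(rec.pupil_area[good].mean())
    trial.baseline = b
    return b


def pupil_constriction(
    trial: PupilTrial,
    smooth_ms: float = 50.0,
    window_ms: float = 1000.0,
    min_valid_frac: float = 0.5,
    criterion: float = 0.10,
) -> float:
    """Mean pupil area over 1 s from the first qualifying local minimum.

    The minimum must fall after LED onset and represent at least a
    ``criterion`` (default 10%) decrease from baseline; the search runs
    on a ``smooth_ms`` moving average so raw sampling noise does not
    create spurious minima. NaN (feature missing) when no minimum
    qualifies.
    """
    rec = trial.trace
    b = trial.baseline
    if not math.isfinite(b):
        b = pupil_baseline(trial, window_ms=window_ms, min_valid_frac=min_valid_frac)
        if not math.isfinite(b):
            return math.nan

    area = np.where(rec.valid, rec.pupil_area, np.nan)
    k = max(int(round(smooth_ms * rec.sample_rate / 1000.0)), 1)
    kernel = np.ones(k) / k
    filled = pd.Series(area).interpolate(limit_direction="both").to_numpy()
    smoothed = np.convolve(filled, kernel, mode="same")

    after = rec.time > trial.led_onset
    cutoff = (1.0 - criterion) * b
    idx = np.flatnonzero(after)
    t_min_idx = None
    for i in idx[1:-1]:
        if (
            smoothed[i] <= cutoff
            and smoothed[i] <= smoothed[i - 1]
            and smoothed[i] <= smoothed[i + 1]
        ):
            t_min_idx = i
            break
    if t_min_idx is None:
        return math.nan
    t_min = rec.time[t_min_idx]

    sel = (rec.time >= t_min) & (rec.time < t_min + window_ms) & rec.valid
    nominal = max(int(window_ms * rec.sample_rate / 1000.0), 1)
    n_window = ((rec.time >= t_min) & (rec.time < t_min + window_ms)).sum()
    if sel.sum() == 0 or sel.sum() < min_valid_frac * min(nominal, n_window):
        return math.nan
    c = float(rec.pupil_area[sel].mean())
    trial.constriction = c
    trial.t_min = float(t_min)
    return c


def pupil_reduction(baseline: float, constriction: float) -> float:
    """Relative pupil-area decrease (B - C) / B; NaN when C is missing."""
    if not (math.isfinite(baseline) and math.isfinite(constriction)):
        return math.nan
    if baseline <= 0:
        raise ValueError("baseline pupil area must be positive")
    return (baseline - constriction) / baseline


def extract_pupil_feature(rec: GazeRecording, spec: TaskSpec, **kwargs) -> float:
    trial = PupilTrial(trace=rec, led_onset=spec.led_onset * 1000.0)
    b = pupil_baseline(trial)
    if not math.isfinite(b):
        return math.nan
    c = pupil_constriction(trial, **kwargs)
    return pupil_reduction(b, c)


def extract_features(
    recordings: dict[str, tuple[GazeRecording, TargetTrace]],
    specs: dict[str, TaskSpec],
    age: float,
    blink_margin: float = 200.0,
) -> dict[str, float]:
    """Compute the four-model features (+ age) from one participant's tasks.

    ``recordings`` maps task name to ``(GazeRecording, TargetTrace)``;
    tasks absent from the dict yield missing features.
    """
    from .preprocessing import mask_blinks

    out: dict[str, float] = {}
    for feature, task in FEATURE_TASK_MAP.items():
        if task in recordings:
            rec, target = recordings[task]
            out[feature] = rms_error(mask_blinks(rec, blink_margin), target)
        else:
            out[feature] = math.nan
    if "pupil_light" in recordings:
        rec, _ = recordings["pupil_light"]
        out["pupil_reduction"] = extract_pupil_feature(
            mask_blinks(rec, blink_margin), specs["pupil_light"]
        )
    else:
        out["pupil_reduction"] = math.nan
    out["age"] = age
    return out


# ---------------------------------------------------------------------------
# Partial Spearman screening


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (midrank ties), the ranks of x
    and y are residualized on the covariate ranks (plus intercept) by
    least squares, and the Pearson correlation of the residuals is
    returned with its t-based p-value on n - k - 2 degrees of freedom.
    Complete cases only; constant x or y raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(cov), axis=1)
    x, y, cov = x[keep], y[keep], cov[keep]
    n, k = len(x), cov.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] + [stats.rankdata(c) for c in cov.T])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    r = float(np.corrcoef(ex, ey)[0, 1])

    dof = n - k - 2
    r_clip = min(max(r, -0.9999999), 0.9999999)
    tstat = r_clip * math.sqrt(dof / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return r, p


def screen_features(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    tests: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial Spearman screen of each feature against each test score,
    controlling age and years of education (no multiplicity correction;
    raw p < alpha marks retention)."""
    merged = features.merge(
        cohort[["participant_id", "age", "education"] + tests],
        on="participant_id",
        suffixes=("", "_cohort"),
    )
    rows = []
    for feature in ET_FEATURES:
        for test in tests:
            sub = merged[[feature, test, "age", "education"]].dropna()
            rho, p = partial_spearman(
                sub[feature].to_numpy(),
                sub[test].to_numpy(),
                sub[["age", "education"]].to_numpy(),
            )
            rows.append(
                {"feature": feature, "test": test, "rho": rho, "p": p,
                 "significant": p < alpha, "n": len(sub)}
            )
    return pd.DataFrame(rows)
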