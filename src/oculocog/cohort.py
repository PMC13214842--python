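"""Synthetic cohorts and gaze traces with a planted cognition signal.

The generator emulates the study design the pipeline targets: a primary
cohort (n=172, age 49.69 +/- 7.58, 79% female) assessed with both eye
tracking and an 11-test neuropsychological battery, and an independent
normative sample (n=133) used only to calibrate expected scores.

A single latent ability factor ``g`` drives everything: test scores load
on it (with demographic main effects), and the four eye-tracking features
are coupled to it with a configurable target partial Spearman correlation
(``effect_rho``). Raw gaze/pupil traces are synthesized so that the
feature-extraction path recovers the planted per-participant values, and
every trace carries a ground-truth event log for detector validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ET_FEATURES,
    CohortConfig,
    ConfigurationError,
    NoiseParams,
    TaskSpec,
)
from .containers import GazeRecording, SaccadeEvent, TargetTrace

# ---------------------------------------------------------------------------
# Neuropsychological battery: primary-cohort calibration targets
# (min, max, mean, sd, integer-valued, time-based i.e. higher = worse)


@dataclass(frozen=True)
class TestDef:
    name: str
    lo: float
    hi: float
    mean: float
    sd: float
    integer: bool
    time_based: bool


TEST_BATTERY: list[TestDef] = [
    TestDef("moca", 16, 30, 26.14, 2.67, True, False),
    TestDef("digit_span_forward", 3, 9, 5.52, 1.21, True, False),
    TestDef("digit_span_backward", 2, 8, 4.35, 1.15, True, False),
    TestDef("digit_symbol", 17, 102, 63.44, 16.07, True, False),
    TestDef("tmt_a", 10, 180, 39.61, 19.62, False, True),
    TestDef("tmt_b", 10, 360, 87.07, 46.09, False, True),
    TestDef("stroop_word", 12, 144, 86.51, 24.61, True, False),
    TestDef("stroop_color", 7, 94, 59.23, 15.12, True, False),
    TestDef("stroop_color_word", 4, 96, 36.02, 12.16, True, False),
    TestDef("phonological_fluency", 10, 72, 39.90, 12.01, True, False),
    TestDef("semantic_fluency", 8, 38, 20.23, 5.73, True, False),
]

TEST_NAMES = [t.name for t in TEST_BATTERY]
TIME_BASED_TESTS = {t.name for t in TEST_BATTERY if t.time_based}
NON_MOCA_TESTS = [t.name for t in TEST_BATTERY if t.name != "moca"]

# standardized demographic loadings of performance (shared across tests)
BETA_AGE = 0.30        # older -> worse
BETA_EDU = 0.20        # more education -> better
BETA_GENDER = 0.05

# feature marginals: (log-median, log-sd) for RMS features (lognormal)
_FEATURE_MARGINALS = {
    "fix_rms_distractors": (math.log(0.45), 0.45),
    "sp_rms_sinusoidal": (math.log(1.30), 0.35),
    "sp_rms_vertical": (math.log(1.00), 0.35),
}
_PUPIL_MEAN, _PUPIL_SD = 0.36, 0.09
BETA_AGE_FEATURE = 0.15


@dataclass
class ParticipantRecord:
    """One participant: demographics, hidden ability, raw test scores."""

    id: str
    age: float
    gender: str
    education: float
    latent_g: float
    scores: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cohort generation


def _standardized_performance(
    rng: np.random.Generator,
    g: np.ndarray,
    age_std: np.ndarray,
    edu_std: np.ndarray,
    female: np.ndarray,
    loading: float,
) -> np.ndarray:
    """Unit-variance performance index: ability + demographics + noise."""
    resid_var = 1.0 - loading**2 - BETA_AGE**2 - BETA_EDU**2 - BETA_GENDER**2
    if resid_var <= 0:
        raise ConfigurationError("score loadings leave no residual variance")
    eps = rng.standard_normal(len(g))
    return (
        loading * g
        - BETA_AGE * age_std
        + BETA_EDU * edu_std
        + BETA_GENDER * (female - female.mean() if len(g) > 1 else female)
        + math.sqrt(resid_var) * eps
    )


def _draw_sample(
    rng: np.random.Generator,
    n: int,
    config: CohortConfig,
    g_shift: float,
    prefix: str,
) -> pd.DataFrame:
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 65.0)
    education = np.clip(
        rng.normal(config.education_mean, config.education_sd, n), 5.0, 22.0
    )
    female = (rng.random(n) < config.prop_female).astype(float)
    g = rng.standard_normal(n) + g_shift

    age_std = (age - config.age_mean) / config.age_sd
    edu_std = (education - config.education_mean) / config.education_sd

    rows: dict[str, np.ndarray] = {
        "participant_id": np.array([f"{prefix}{i:04d}" for i in range(n)]),
        "age": age,
        "gender": np.where(female == 1.0, "female", "male"),
        "education": education,
        "latent_g": g,
    }
    for t in TEST_BATTERY:
        v = _standardized_performance(
            rng, g, age_std, edu_std, female, config.score_loading
        )
        # center the primary cohort's marginal on the battery's reference
        # mean/SD regardless of the ability shift it was drawn with
        centered = v - config.score_loading * g_shift
        raw = t.mean + t.sd * (-centered if t.time_based else centered)
        raw = np.clip(raw, t.lo, t.hi)
        if t.integer:
            raw = np.round(raw)
        rows[t.name] = raw
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the normative and primary cohorts.

    Returns ``(normative, primary)`` tables with demographics, the hidden
    ability factor (retained for recovery tests) and all 11 raw scores.
    The normative sample's ability is drawn from the standard reference
    distribution; the primary cohort's is shifted by ``primary_g_shift``.
    """
    rng = np.random.default_rng(config.seed)
    normative = _draw_sample(rng, config.n_normative, config, 0.0, "N")
    primary = _draw_sample(rng, config.n_primary, config, config.primary_g_shift, "P")
    return normative, primary


def cohort_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    """View a cohort table as a list of participant records."""
    return [
        ParticipantRecord(
            id=row.participant_id,
            age=row.age,
            gender=row.gender,
            education=row.education,
            latent_g=row.latent_g,
            scores={t: getattr(row, t) for t in TEST_NAMES},
        )
        for row in df.itertuples(index=False)
    ]


def composite_score(cohort: pd.DataFrame) -> pd.Series:
    """Mean standardized, direction-aligned performance over non-MoCA tests."""
    parts = []
    for t in TEST_BATTERY:
        if t.name == "moca":
            continue
        z = (cohort[t.name] - t.mean) / t.sd
        parts.append(-z if t.time_based else z)
    return pd.concat(parts, axis=1).mean(axis=1)


# ---------------------------------------------------------------------------
# Eye-tracking feature table with calibrated effect size


def _pearson_from_spearman(rho_s: float) -> float:
    """Bivariate-normal conversion: the Pearson r whose Spearman is rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _composite_g_correlation(config: CohortConfig) -> float:
    """Partial correlation (age/education removed) between the non-MoCA
    composite and latent ability, implied by the score model."""
    lam = config.score_loading / math.sqrt(1.0 - BETA_AGE**2 - BETA_EDU**2)
    m = len(NON_MOCA_TESTS)
    return lam * math.sqrt(m) / math.sqrt(1.0 + (m - 1) * lam**2)


def planted_feature_loading(config: CohortConfig, feature: str) -> float:
    """Loading of a feature's latent score on g such that the partial
    Spearman between the feature and the cognitive composite hits the
    configured ``effect_rho`` for that feature."""
    rho_target = _pearson_from_spearman(config.rho_map()[feature])
    lam_c = _composite_g_correlation(config)
    loading = rho_target / lam_c * math.sqrt(1.0 - BETA_AGE_FEATURE**2)
    if abs(loading) >= 0.95:
        raise ConfigurationError(f"effect_rho for {feature} too large to plant")
    return loading


def planted_feature_values(
    cohort: pd.DataFrame, config: CohortConfig, seed: int
) -> pd.DataFrame:
    """Per-participant planted values of the four eye-tracking features.

    RMS features load negatively on ability (worse cognition -> larger
    gaze error); pupil constriction depth loads positively (worse
    cognition -> blunted light reflex). Marginals are lognormal for RMS
    and truncated normal for the pupil reduction fraction. Monotone
    marginal transforms preserve the planted Spearman structure.
    """
    rng = np.random.default_rng(seed)
    g = cohort["latent_g"].to_numpy()
    age_std = (cohort["age"].to_numpy() - config.age_mean) / config.age_sd
    out = pd.DataFrame(index=cohort.index)
    out["participant_id"] = cohort["participant_id"].to_numpy()
    for feature in ET_FEATURES:
        loading = planted_feature_loading(config, feature)
        sign = +1.0 if feature == "pupil_reduction" else -1.0
        resid = 1.0 - loading**2 - BETA_AGE_FEATURE**2
        z = (
            sign * loading * g
            + BETA_AGE_FEATURE * age_std
            + math.sqrt(resid) * rng.standard_normal(len(g))
        )
        if feature == "pupil_reduction":
            out[feature] = np.clip(_PUPIL_MEAN + _PUPIL_SD * z, 0.10, 0.95)
        else:
            mu, sig = _FEATURE_MARGINALS[feature]
            out[feature] = np.exp(mu + sig * z)
    out["age"] = cohort["age"].to_numpy()
    return out


def generate_multimodal_dataset(
    n: int = 172,
    seed: int = 0,
    moca_strength: float = 1.0,
    et_strength: float = 1.0,
    feature_loading: float = 0.55,
    noise: float = 0.8,
    moca_obs_noise: float = 0.25,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Cohort with independent MoCA-borne and ET-borne impairment signals.

    Two independent latent components drive the altered label: one is
    observed (noisily) through MoCA, the other through the four
    eye-tracking features. Setting ``et_strength=0`` plants a
    MoCA-only signal; ``moca_strength=0`` an ET-only signal. Returns
    ``(et_features_with_age, moca, labels)``.
    """
    rng = np.random.default_rng(seed)
    u1 = rng.standard_normal(n)   # MoCA-borne component
    u2 = rng.standard_normal(n)   # ET-borne component
    liability = -moca_strength * u1 - et_strength * u2 + noise * rng.standard_normal(n)
    y = (liability > np.quantile(liability, 0.5)).astype(int)

    moca = np.clip(
        np.round(26.0 + 2.2 * (u1 + moca_obs_noise * rng.standard_normal(n))), 16, 30
    )

    age = np.clip(rng.normal(49.69, 7.58, n), 18.0, 65.0)
    c = feature_loading
    X = pd.DataFrame({"age": age})
    for feature in ET_FEATURES:
        eps = rng.standard_normal(n)
        z = c * (u2 if feature == "pupil_reduction" else -u2) + math.sqrt(1 - c * c) * eps
        if feature == "pupil_reduction":
            X[feature] = np.clip(_PUPIL_MEAN + _PUPIL_SD * z, 0.10, 0.95)
        else:
            mu, sig = _FEATURE_MARGINALS[feature]
            X[feature] = np.exp(mu + sig * z)
    X = X[ET_FEATURES + ["age"]]
    return X, moca, y


# ---------------------------------------------------------------------------
# Raw trace synthesis


def participant_noise_params(
    participant: ParticipantRecord | pd.Series,
    config: CohortConfig,
    seed: int,
) -> dict[str, NoiseParams]:
    """Per-task noise parameters realizing one participant's planted
    feature values, derived from the calibrated feature model."""
    frame = pd.DataFrame(
        {
            "participant_id": [getattr(participant, "id", None) or participant["participant_id"]],
            "age": [participant.age if hasattr(participant, "age") else participant["age"]],
            "latent_g": [
                participant.latent_g
                if hasattr(participant, "latent_g")
                else participant["latent_g"]
            ],
        }
    )
    planted = planted_feature_values(frame, config, seed).iloc[0]
    base = NoiseParams()

    def _gaze_params(rms: float, ref: float) -> NoiseParams:
        # intrusion rate scales with the planted error level so the
        # saccadic contribution to RMS grows with it rather than
        # swamping it with a constant offset
        return NoiseParams(
            rms_target=rms,
            intrusion_rate=base.intrusion_rate * (rms / ref) ** 2,
        )

    return {
        "fixation_distractors": _gaze_params(float(planted["fix_rms_distractors"]), 0.45),
        "pursuit_horizontal": _gaze_params(float(planted["sp_rms_vertical"]), 1.0),
        "pursuit_vertical": _gaze_params(float(planted["sp_rms_vertical"]), 1.0),
        "pursuit_sinusoidal": _gaze_params(float(planted["sp_rms_sinusoidal"]), 1.3),
        "pupil_light": NoiseParams(
            rms_target=0.3,
            pupil_reduction=float(planted["pupil_reduction"]),
            pupil_baseline=base.pupil_baseline,
        ),
    }


def _target_trajectory(spec: TaskSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    zeros = np.zeros_like(t)
    if spec.task in ("fixation_distractors", "pupil_light"):
        return zeros, zeros
    amplitude, speed = 8.0, 8.0
    if spec.task == "pursuit_sinusoidal":
        return amplitude * np.sin(2.0 * math.pi * 0.25 * t), zeros
    # constant-velocity ramps with reversals (triangle wave)
    period = 4.0 * amplitude / speed
    phase = np.mod(t + period / 4.0, period) / period
    tri = amplitude * (4.0 * np.abs(phase - 0.5) - 1.0)
    if spec.task == "pursuit_horizontal":
        return tri, zeros
    return zeros, tri


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _ou_noise(rng: np.random.Generator, n: int, dt: float, sd: float, tau: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), n)
    for i in range(1, n):
        out[i] = a * out[i - 1] + innov[i]
    return out


@dataclass
class TraceTruth:
    """Ground truth planted in one synthetic trace."""

    saccades: list[SaccadeEvent]
    blinks: list[tuple[float, float]]
    pupil_reduction: float | None = None


def generate_trace(
    participant: ParticipantRecord | None,
    spec: TaskSpec,
    noise: NoiseParams,
    seed: int,
) -> tuple[GazeRecording, TargetTrace, TraceTruth]:
    """Synthesize one task recording plus its ground-truth event log.

    Gaze = (lagged, gain-scaled) target + slow drift + tremor + saccadic
    intrusions; blinks appear as invalid gaps with zero pupil area. The
    pupil task plants a plateaued constriction of relative depth
    ``noise.pupil_reduction`` after LED onset.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / spec.sample_rate
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) * dt
    time_ms = t * 1000.0

    tx, ty = _target_trajectory(spec, t)
    lagged = np.clip(t - noise.pursuit_latency, 0.0, None)
    gx, gy = _target_trajectory(spec, lagged)
    gx, gy = gx * noise.pursuit_gain, gy * noise.pursuit_gain

    # positional noise: slow drift (OU) + white tremor, split so the
    # total per-sample RMS error lands near the planted target
    per_axis = noise.rms_target / math.sqrt(2.0)
    drift_sd = per_axis * math.sqrt(0.9)
    tremor_sd = per_axis * math.sqrt(0.1)
    gx = gx + _ou_noise(rng, n, dt, drift_sd, 0.25) + rng.normal(0.0, tremor_sd, n)
    gy = gy + _ou_noise(rng, n, dt, drift_sd, 0.25) + rng.normal(0.0, tremor_sd, n)

    # saccadic intrusions: outward jump + corrective return, both logged
    saccades: list[SaccadeEvent] = []
    if noise.intrusion_rate > 0:
        rate = np.full(n, noise.intrusion_rate)
        if spec.task == "fixation_distractors":
            rate[t >= spec.distractor_onset] *= noise.distractor_rate_multiplier
        hazard = rng.random(n) < rate * dt
        onset_idx = np.flatnonzero(hazard)
        last_end = -1.0
        for i0 in onset_idx:
            t0 = t[i0]
            if t0 < last_end + 0.12:
                continue
            amp = max(2.0, rng.normal(noise.intrusion_amplitude, 0.5))
            theta = rng.uniform(0.0, 2.0 * math.pi)
            dur = noise.intrusion_duration
            hold = rng.uniform(0.15, 0.25)
            for s_start, s_sign in ((t0, +1.0), (t0 + dur + hold, -1.0)):
                s_end = s_start + dur
                if s_end >= spec.duration:
                    break
                prof = _smoothstep((t - s_start) / dur)
                step = np.where(t < s_start, 0.0, np.where(t >= s_end, 1.0, prof))
                gx = gx + s_sign * amp * math.cos(theta) * step
                gy = gy + s_sign * amp * math.sin(theta) * step
                peak_v = 1.5 * amp / dur
                saccades.append(
                    SaccadeEvent(
                        onset=s_start * 1000.0,
                        offset=s_end * 1000.0,
                        peak_velocity=peak_v,
                        amplitude=amp,
                    )
                )
            last_end = t0 + 2 * dur + hold

    # pupil trace
    pupil = np.full(n, noise.pupil_baseline)
    truth_reduction = None
    if spec.task == "pupil_light":
        d = noise.pupil_reduction
        truth_reduction = d
        rise, recover = 0.8, 1.5
        t0 = spec.led_onset + 0.25          # constriction latency
        t_off = spec.led_onset + spec.led_duration
        response = _smoothstep((t - t0) / rise)
        rebound = np.where(t > t_off, 1.0 - np.exp(-(t - t_off) / recover), 0.0)
        pupil = noise.pupil_baseline * (1.0 - d * response * (1.0 - 0.9 * rebound))
    if noise.pupil_noise > 0:
        pupil = pupil + rng.normal(0.0, noise.pupil_noise, n)

    # blinks: invalid gaps with lost pupil signal
    valid = np.ones(n, dtype=bool)
    blinks: list[tuple[float, float]] = []
    if noise.blink_rate > 0:
        n_blinks = rng.poisson(noise.blink_rate * spec.duration)
        for t0 in np.sort(rng.uniform(0.0, spec.duration, n_blinks)):
            t1 = min(t0 + noise.blink_duration, spec.duration)
            sel = (t >= t0) & (t < t1)
            valid[sel] = False
            pupil[sel] = 0.0
            blinks.append((t0 * 1000.0, t1 * 1000.0))

    rec = GazeRecording(
        time=time_ms, x=gx, y=gy, pupil_area=pupil, valid=valid,
        sample_rate=spec.sample_rate,
    )
    target = TargetTrace(time=time_ms, x_stim=tx, y_stim=ty)
    return rec, target, TraceTruth(saccades=saccades, blinks=blinks,
                                   pupil_reduction=truth_reduction)


# ---------------------------------------------------------------------------
# Missingness


def apply_missingness(
    features: pd.DataFrame,
    rates: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mask feature cells completely at random at per-column rates.

    Emulates technical signal loss (poor tracking, eyelid closure); the
    mechanism is independent of every variable in the table.
    """
    from .config import DEFAULT_MISSING_RATES

    if rates is None:
        rates = DEFAULT_MISSING_RATES
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"missing rate for {col} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = features.copy()
    for col, rate in rates.items():
        if col not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out
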