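"""Configuration objects: cohort parameters, task specifications, trace noise.

Defaults reproduce the study conditions the pipeline is designed around:
a primary cohort of 172 middle-aged, predominantly female participants
recorded binocularly at 1000 Hz, an independent normative sample of 133,
eye-tracking/cognition partial correlations in the 0.21-0.29 band, and
per-feature technical missingness of 2.9-14.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

ET_FEATURES = [
    "fix_rms_distractors",
    "sp_rms_sinusoidal",
    "sp_rms_vertical",
    "pupil_reduction",
]

DEFAULT_MISSING_RATES = {
    "fix_rms_distractors": 0.029,
    "sp_rms_sinusoidal": 0.0465,
    "sp_rms_vertical": 0.0465,
    "pupil_reduction": 0.1453,
}

TASK_NAMES = [
    "fixation_distractors",
    "pursuit_horizontal",
    "pursuit_vertical",
    "pursuit_sinusoidal",
    "pupil_light",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_rho`` is the target partial Spearman correlation between each
    eye-tracking feature and composite cognitive performance (controlling
    age and education); it may be a scalar applied to all four features or
    a per-feature mapping.
    """

    n_primary: int = 172
    n_normative: int = 133
    age_mean: float = 49.69
    age_sd: float = 7.58
    prop_female: float = 0.79
    education_mean: float = 13.5
    education_sd: float = 3.2
    effect_rho: float | Mapping[str, float] = 0.25
    score_loading: float = 0.5
    primary_g_shift: float = -0.6
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 2 or self.n_normative < 2:
            raise ConfigurationError("cohort sizes must be at least 2")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female must lie in [0, 1]")
        for name, rate in self.rho_map().items():
            if not -1.0 < rate < 1.0:
                raise ConfigurationError(f"effect_rho[{name}] outside (-1, 1)")
        for name, rate in dict(self.missing_rates).items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missing rate for {name} outside [0, 1]")
        if not 0 < self.score_loading < 1:
            raise ConfigurationError("score_loading must lie in (0, 1)")

    def rho_map(self) -> dict[str, float]:
        if isinstance(self.effect_rho, Mapping):
            unknown = set(self.effect_rho) - set(ET_FEATURES)
            if unknown:
                raise ConfigurationError(f"unknown features in effect_rho: {unknown}")
            return {f: float(self.effect_rho.get(f, 0.25)) for f in ET_FEATURES}
        return {f: float(self.effect_rho) for f in ET_FEATURES}


@dataclass
class TaskSpec:
    """One recording task: trajectory family, duration and sampling rate.

    The fixation task runs 10 s of plain fixation followed by 30 s with
    peripheral distractors; the pupil task illuminates an LED for 5 s.
    """

    task: str
    duration: float
    sample_rate: float = 1000.0
    led_onset: float = 3.0
    led_duration: float = 5.0
    distractor_onset: float = 10.0

    def __post_init__(self) -> None:
        if self.task not in TASK_NAMES:
            raise ConfigurationError(f"unknown task '{self.task}'")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.task == "pupil_light" and self.led_onset + self.led_duration > self.duration:
            raise ConfigurationError("LED interval must fit inside the task duration")


def default_task_specs(sample_rate: float = 1000.0) -> dict[str, TaskSpec]:
    """The five recording tasks at their study durations."""
    return {
        "fixation_distractors": TaskSpec("fixation_distractors", 40.0, sample_rate),
        "pursuit_horizontal": TaskSpec("pursuit_horizontal", 30.0, sample_rate),
        "pursuit_vertical": TaskSpec("pursuit_vertical", 30.0, sample_rate),
        "pursuit_sinusoidal": TaskSpec("pursuit_sinusoidal", 30.0, sample_rate),
        "pupil_light": TaskSpec("pupil_light", 12.0, sample_rate, led_onset=3.0),
    }


@dataclass
class NoiseParams:
    """Oculomotor noise model for one synthetic trace.

    ``rms_target`` sets the Gaussian positional noise so the measured
    gaze-target RMS error lands near it; ``pupil_reduction`` plants the
    relative constriction depth recovered by the pupil feature.
    """

    rms_target: float = 0.5
    intrusion_rate: float = 0.3          # saccadic intrusions per second
    intrusion_amplitude: float = 2.5     # degrees, mean planted amplitude
    intrusion_duration: float = 0.030    # seconds
    distractor_rate_multiplier: float = 2.0
    blink_rate: float = 0.08             # blinks per second
    blink_duration: float = 0.15         # seconds
    pupil_baseline: float = 1000.0       # device units
    pupil_reduction: float = 0.35        # fraction of baseline
    pupil_noise: float = 2.0             # device units, additive
    pursuit_latency: float = 0.100       # seconds of tracking lag
    pursuit_gain: float = 0.95

    @classmethod
    def noiseless(cls, **overrides) -> "NoiseParams":
        base = dict(
            rms_target=0.0,
            intrusion_rate=0.0,
            blink_rate=0.0,
            pupil_noise=0.0,
            pursuit_latency=0.0,
            pursuit_gain=1.0,
        )
        base.update(overrides)
        return cls(**base)
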