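import numpy as np
import pytest

from oculocog.config import CohortConfig
from oculocog.containers import GazeRecording


@pytest.fixture
def small_config() -> CohortConfig:
    return CohortConfig(n_primary=40, n_normative=40, seed=11)


@pytest.fixture
def default_config() -> CohortConfig:
    return CohortConfig(seed=11)


def make_recording(
    x: np.ndarray,
    y: np.ndarray | None = None,
    sample_rate: float = 1000.0,
    valid: np.ndarray | None = None,
    pupil: np.ndarray | None = None,
) -> GazeRecording:
    n = len(x)
    return GazeRecording(
        time=np.arange(n) * 1000.0 / sample_rate,
        x=np.asarray(x, dtype=float),
        y=np.zeros(n) if y is None else np.asarray(y, dtype=float),
        pupil_area=np.full(n, 500.0) if pupil is None else np.asarray(pupil, dtype=float),
        valid=np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool),
        sample_rate=sample_rate,
    )
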