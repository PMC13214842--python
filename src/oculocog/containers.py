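"""Core in-memory containers for gaze recordings, stimulus traces and events.

A :class:`GazeRecording` holds one task's sampled gaze/pupil trace together
with a validity mask; a :class:`TargetTrace` holds the stimulus position on
the same clock. Both round-trip through plain CSV so synthetic and real
exports share one format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["time_ms", "x_deg", "y_deg", "pupil_area", "valid"]


@dataclass
class GazeRecording:
    """One task's gaze/pupil trace.

    Parameters
    ----------
    time : ndarray
        Sample timestamps in milliseconds, strictly increasing.
    x, y : ndarray
        Gaze position in degrees of visual angle.
    pupil_area : ndarray
        Pupil area in arbitrary device units; positive wherever valid.
    valid : ndarray of bool
        Sample validity mask. Invalid samples are excluded from every
        downstream statistic.
    sample_rate : float
        Nominal sampling rate in Hz.
    blink_masked : bool
        True once blink margins have been applied; makes blink masking
        idempotent.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil_area: np.ndarray
    valid: np.ndarray
    sample_rate: float
    blink_masked: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil_area = np.asarray(self.pupil_area, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time)
        for name in ("x", "y", "pupil_area", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column '{name}' length differs from time")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def copy(self) -> "GazeRecording":
        return replace(
            self,
            time=self.time.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            pupil_area=self.pupil_area.copy(),
            valid=self.valid.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time,
                "x_deg": self.x,
                "y_deg": self.y,
                "pupil_area": self.pupil_area,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_rate: float | None = None) -> "GazeRecording":
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trace table lacks columns {missing}")
        t = df["time_ms"].to_numpy(dtype=float)
        if sample_rate is None:
            dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
            sample_rate = 1000.0 / dt
        return cls(
            time=t,
            x=df["x_deg"].to_numpy(dtype=float),
            y=df["y_deg"].to_numpy(dtype=float),
            pupil_area=df["pupil_area"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy().astype(bool),
            sample_rate=float(sample_rate),
        )

    @classmethod
    def from_csv(cls, path: str | Path, sample_rate: float | None = None) -> "GazeRecording":
        return cls.from_frame(pd.read_csv(path), sample_rate=sample_rate)


@dataclass
class TargetTrace:
    """Stimulus position over time on the gaze recording's clock."""

    time: np.ndarray
    x_stim: np.ndarray
    y_stim: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x_stim = np.asarray(self.x_stim, dtype=float)
        self.y_stim = np.asarray(self.y_stim, dtype=float)
        if not (len(self.time) == len(self.x_stim) == len(self.y_stim)):
            raise ValueError("target trace columns must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    def at(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Target position at arbitrary timestamps by nearest-sample lookup."""
        idx = np.searchsorted(self.time, times)
        idx = np.clip(idx, 0, len(self.time) - 1)
        left = np.clip(idx - 1, 0, len(self.time) - 1)
        use_left = np.abs(self.time[left] - times) < np.abs(self.time[idx] - times)
        idx = np.where(use_left, left, idx)
        return self.x_stim[idx], self.y_stim[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time, "x_stim_deg": self.x_stim, "y_stim_deg": self.y_stim}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetTrace":
        df = pd.read_csv(path)
        return cls(
            time=df["time_ms"].to_numpy(dtype=float),
            x_stim=df["x_stim_deg"].to_numpy(dtype=float),
            y_stim=df["y_stim_deg"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected (or planted) saccade: [onset, offset] in ms."""

    onset: float
    offset: float
    peak_velocity: float = np.nan
    amplitude: float = np.nan

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("saccade onset must precede offset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset_ms": [e.onset for e in events],
            "offset_ms": [e.offset for e in events],
            "peak_velocity_deg_s": [e.peak_velocity for e in events],
            "amplitude_deg": [e.amplitude for e in events],
        }
    )
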