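"""Gaze trace cleaning, velocity smoothing and adaptive saccade detection.

The processing chain mirrors standard oculomotor practice: blink margins
are discarded (200 ms either side of each invalid run), velocity is the
magnitude of a Savitzky-Golay smoothed first derivative (21 ms window,
second order), saccades are found with a noise-adaptive velocity
threshold, and fixation samples are what remains after removing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.signal import savgol_filter

from .config import ConfigurationError
from .containers import GazeRecording, SaccadeEvent

# 17" 1280x1024 display at 60 cm: pixel pitch from the stated diagonal
SCREEN_DIAGONAL_MM = 17.0 * 25.4
SCREEN_RESOLUTION = (1280, 1024)
VIEWING_DISTANCE_MM = 600.0


def pixels_to_degrees(
    px: np.ndarray | float,
    distance_mm: float = VIEWING_DISTANCE_MM,
    diagonal_mm: float = SCREEN_DIAGONAL_MM,
    resolution: tuple[int, int] = SCREEN_RESOLUTION,
) -> np.ndarray | float:
    """Convert screen pixels to degrees of visual angle (small-angle exact)."""
    pitch = diagonal_mm / math.hypot(*resolution)
    return np.degrees(np.arctan(np.asarray(px) * pitch / distance_mm))


def mask_blinks(rec: GazeRecording, margin: float = 200.0) -> GazeRecording:
    """Extend every invalid run by ``margin`` ms on both sides.

    Idempotent: a recording whose margins were already applied is
    returned unchanged.
    """
    if margin < 0:
        raise ConfigurationError("blink margin must be non-negative")
    out = rec.copy()
    if rec.blink_masked or len(rec) == 0 or rec.valid.all():
        out.blink_masked = True
        return out
    margin_samples = int(round(margin * rec.sample_rate / 1000.0))
    invalid = ~rec.valid
    if margin_samples > 0:
        structure = np.ones(2 * margin_samples + 1, dtype=bool)
        invalid = binary_dilation(invalid, structure=structure)
    out.valid = ~invalid
    out.blink_masked = True
    return out


def _window_samples(window_ms: float, sample_rate: float, polyorder: int) -> int:
    w = int(round(window_ms * sample_rate / 1000.0))
    if w % 2 == 0:
        w -= 1
    if w < polyorder + 2:
        raise ConfigurationError(
            f"{window_ms} ms window spans {w} samples at {sample_rate} Hz; "
            f"needs at least {polyorder + 2} for polyorder {polyorder}"
        )
    return w


def smooth_velocity(
    rec: GazeRecording, window: float = 21.0, polyorder: int = 2
) -> np.ndarray:
    """Gaze speed (deg/s) from a Savitzky-Golay smoothed first derivative.

    Velocity is computed independently within each contiguous valid
    segment; samples in segments too short for the filter, and samples
    within half a window of a gap edge, are NaN — the filter never
    interpolates across blinks.
    """
    w = _window_samples(window, rec.sample_rate, polyorder)
    half = w // 2
    dt = 1.0 / rec.sample_rate
    v = np.full(len(rec), np.nan)
    if len(rec) == 0:
        return v

    valid = rec.valid
    edges = np.flatnonzero(np.diff(np.concatenate(([0], valid.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        seg = slice(start, stop)
        if stop - start < w:
            continue
        vx = savgol_filter(rec.x[seg], w, polyorder, deriv=1, delta=dt)
        vy = savgol_filter(rec.y[seg], w, polyorder, deriv=1, delta=dt)
        speed = np.hypot(vx, vy)
        # guard the filter's boundary fit where the segment abuts a gap
        if start > 0:
            speed[:half] = np.nan
        if stop < len(rec):
            speed[-half:] = np.nan
        v[seg] = speed
    return v


@dataclass(frozen=True)
class SaccadeDetectionParams:
    """Constants of the adaptive velocity-threshold detector."""

    initial_threshold: float = 100.0   # deg/s
    peak_multiplier: float = 6.0       # peak threshold = mu + 6 sigma
    onset_multiplier: float = 3.0      # onset/offset threshold = mu + 3 sigma
    convergence_tol: float = 1.0       # deg/s
    min_duration: float = 10.0         # ms
    merge_gap: float = 20.0            # ms
    max_iterations: int = 100


def adaptive_threshold(
    velocity: np.ndarray, params: SaccadeDetectionParams = SaccadeDetectionParams()
) -> tuple[float, float]:
    """Iterate PT <- mu + k*sigma over sub-threshold samples to convergence.

    Returns ``(peak_threshold, onset_threshold)``; both are NaN when no
    finite velocity samples exist.
    """
    v = velocity[np.isfinite(velocity)]
    if v.size == 0:
        return math.nan, math.nan
    pt = params.initial_threshold
    for _ in range(params.max_iterations):
        below = v[v < pt]
        if below.size < 2:
            break
        mu, sigma = float(below.mean()), float(below.std())
        new_pt = mu + params.peak_multiplier * sigma
        if abs(new_pt - pt) < params.convergence_tol:
            pt = new_pt
            break
        pt = new_pt
    below = v[v < pt]
    if below.size < 2:
        return pt, pt
    mu, sigma = float(below.mean()), float(below.std())
    return pt, mu + params.onset_multiplier * sigma


def detect_saccades(
    velocity: np.ndarray,
    sample_rate: float,
    params: SaccadeDetectionParams = SaccadeDetectionParams(),
    time: np.ndarray | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades by an adaptive, noise-driven velocity threshold.

    Candidate events are runs exceeding the converged peak threshold;
    onsets/offsets are refined outward to the lower onset threshold,
    events closer than ``merge_gap`` ms are merged, and events shorter
    than ``min_duration`` ms are dropped. NaN (invalid) velocity samples
    never participate, so events cannot span a blink's interior.
    """
    velocity = np.asarray(velocity, dtype=float)
    n = len(velocity)
    if time is None:
        time = np.arange(n) * 1000.0 / sample_rate
    pt, onset_thr = adaptive_threshold(velocity, params)
    if not math.isfinite(pt):
        return []

    above_peak = np.flatnonzero(np.nan_to_num(velocity, nan=-np.inf) > pt)
    if above_peak.size == 0:
        return []
    above_onset = np.nan_to_num(velocity, nan=-np.inf) > onset_thr

    # expand each supra-peak run outward while velocity stays above the
    # onset threshold (and remains finite)
    intervals: list[list[int]] = []
    for i in above_peak:
        if intervals and i <= intervals[-1][1]:
            continue
        lo = i
        while lo > 0 and above_onset[lo - 1]:
            lo -= 1
        hi = i
        while hi < n - 1 and above_onset[hi + 1]:
            hi += 1
        if intervals and lo <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], hi)
        else:
            intervals.append([lo, hi])

    # merge events separated by short gaps
    merge_samples = params.merge_gap * sample_rate / 1000.0
    merged: list[list[int]] = []
    for lo, hi in intervals:
        if merged and lo - merged[-1][1] < merge_samples:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])

    min_dur_samples = params.min_duration * sample_rate / 1000.0
    events = []
    for lo, hi in merged:
        if hi - lo + 1 < min_dur_samples:
            continue
        seg = velocity[lo : hi + 1]
        peak = float(np.nanmax(seg))
        amp = float(np.nansum(seg) / sample_rate)  # integral of speed, deg
        events.append(
            SaccadeEvent(
                onset=float(time[lo]),
                offset=float(time[hi]),
                peak_velocity=peak,
                amplitude=amp,
            )
        )
    return events


def fixation_samples(
    rec: GazeRecording, saccades: list[SaccadeEvent]
) -> GazeRecording:
    """Restrict a recording to valid, non-saccadic samples.

    The returned recording keeps the full time base with the validity
    mask narrowed to ``valid AND outside every saccade interval``.
    """
    out = rec.copy()
    mask = rec.valid.copy()
    for ev in saccades:
        mask &= ~((rec.time >= ev.onset) & (rec.time <= ev.offset))
    out.valid = mask
    return out


def preprocess(
    rec: GazeRecording,
    blink_margin: float = 200.0,
    window: float = 21.0,
    polyorder: int = 2,
    params: SaccadeDetectionParams = SaccadeDetectionParams(),
) -> tuple[GazeRecording, np.ndarray, list[SaccadeEvent], GazeRecording]:
    """Full chain: blink margins -> velocity -> saccades -> fixation samples."""
    clean = mask_blinks(rec, margin=blink_margin)
    velocity = smooth_velocity(clean, window=window, polyorder=polyorder)
    saccades = detect_saccades(velocity, clean.sample_rate, params, time=clean.time)
    fixations = fixation_samples(clean, saccades)
    return clean, velocity, saccades, fixations
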