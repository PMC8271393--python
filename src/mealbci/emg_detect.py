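"""Chewing detection from the temporal channels (T7, T8).

Chewing produces broadband scalp EMG far larger than the EEG background.
The envelope is ``MA(|diff(MA(|x|))|)``: rectify, smooth with a moving
average, differentiate (first difference scaled by the sampling rate),
rectify and smooth again.  The differentiation step suppresses slow
baseline wander so the envelope responds to fast burst activity only.
Detection counts samples above the subject's threshold (half the median of
a calibration envelope); chewing is reported when more than 2 s worth of
samples exceed it (1024 samples at 512 Hz, 256 at 128 Hz).  The real-time
path additionally requires three such window-level detections before the
meal cycle is allowed to end (spoon descent is the hazard case).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "EmgThreshold",
    "ChewDecision",
    "emg_envelope",
    "calibrate_emg_threshold",
    "detect_chewing",
    "realtime_chew_confirm",
]


@dataclass(frozen=True)
class EmgThreshold:
    value: float  # envelope units
    source: Literal["calibration", "manual"] = "manual"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise CalibrationError("EMG threshold must be positive")


@dataclass(frozen=True)
class ChewDecision:
    detected: bool
    supra_count: int
    required_count: int
    per_channel_counts: tuple[int, ...] = ()


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    return np.convolve(x, np.ones(n) / n, mode="same")


def emg_envelope(x: np.ndarray, fs: float, ma_window_s: float = 0.25) -> np.ndarray:
    """Rectify-smooth-differentiate-rectify-smooth envelope, same length as x."""
    if ma_window_s <= 0:
        raise ConfigurationError("ma_window_s must be positive")
    x = np.asarray(x, dtype=float)
    n = max(1, int(round(ma_window_s * fs)))
    if x.size <= 2 * n:
        raise ConfigurationError(f"signal too short ({x.size} samples) for {ma_window_s} s smoothing")
    smoothed = _moving_average(np.abs(x), n)
    deriv = np.diff(smoothed, prepend=smoothed[0]) * fs
    return _moving_average(np.abs(deriv), n)


def calibrate_emg_threshold(calibration_envelope: np.ndarray) -> EmgThreshold:
    """Per-subject threshold: 50 % of the median calibration envelope value."""
    env = np.asarray(calibration_envelope, dtype=float)
    if env.size == 0:
        raise CalibrationError("empty calibration envelope")
    return EmgThreshold(value=float(0.5 * np.median(env)), source="calibration")


def detect_chewing(
    envelope: np.ndarray,
    fs: float,
    thr: EmgThreshold,
    min_duration_s: float = 2.0,
) -> ChewDecision:
    """Report chewing when strictly more than ``min_duration_s`` worth of
    envelope samples exceed the threshold.

    ``envelope`` may be one channel (1-D) or a channel stack (2-D); with
    two channels the per-sample maximum combines them, so either temporal
    electrode can carry the detection and the rule is symmetric in T7/T8.
    """
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    if np.any(env < 0):
        raise ConfigurationError("envelope must be non-negative")
    per_channel = tuple(int(np.sum(ch > thr.value)) for ch in env)
    combined = env.max(axis=0)
    supra = int(np.sum(combined > thr.value))
    required = int(round(min_duration_s * fs))
    return ChewDecision(
        detected=supra > required,
        supra_count=supra,
        required_count=required,
        per_channel_counts=per_channel,
    )


def realtime_chew_confirm(
    window_decisions: Sequence[ChewDecision | bool],
    n_required: int = 3,
    rule: Literal["consecutive", "any"] = "consecutive",
) -> bool:
    """Stricter online criterion: chewing confirmed after three detections.

    ``consecutive`` (default) requires a run of ``n_required`` detected
    windows on the 1 s sliding grid; ``any`` accepts any three since
    monitoring began.
    """
    flags = [d.detected if isinstance(d, ChewDecision) else bool(d) for d in window_decisions]
    if rule == "any":
        return sum(flags) >= n_required
    if rule == "consecutive":
        run = 0
        for f in flags:
            run = run + 1 if f else 0
            if run >= n_required:
                return True
        return False
    raise ConfigurationError(f"unknown confirmation rule {rule!r}")
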