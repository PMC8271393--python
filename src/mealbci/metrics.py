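"""Performance metrics: accuracy, Wolpaw information transfer rate, FPR.

The Wolpaw ITR for an N-class selection with accuracy P and selection time
T seconds is

    ITR = (60/T) * [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))]  bit/min,

with 0*log0 taken as 0.  The selection time used here is the analysis
epoch length (3 or 4 s).  The false-positive rate is the number of
detections outside designated task windows divided by the session length
in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .events import EventLog

__all__ = [
    "MetricsReport",
    "ItrInputs",
    "itr_wolpaw",
    "accuracy",
    "false_positive_rate",
    "summarize",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Table-style rounding: half-up at ``ndigits`` decimals."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ItrInputs:
    P: float
    N: int = 5
    T: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ConfigurationError("P must lie in [0, 1]")
        if self.N < 2:
            raise ConfigurationError("need at least two classes")
        if self.T <= 0:
            raise ConfigurationError("selection time must be positive")


@dataclass
class MetricsReport:
    """Per-subject (or averaged) performance summary."""

    accuracy_pct: dict[str, float] = field(default_factory=dict)  # per modality
    itr_bit_per_min: float = 0.0
    fpr_per_min: dict[str, float] = field(default_factory=dict)  # {"eb": ..., "emg": ...}
    n_cycles: int = 0
    session_minutes: float = 0.0


def itr_wolpaw(P: float, N: int = 5, T_seconds: float = 4.0) -> float:
    """Wolpaw ITR in bit/min; signed (not clamped below chance)."""
    inputs = ItrInputs(P=float(P), N=int(N), T=float(T_seconds))
    p, n = inputs.P, inputs.N
    bits = math.log2(n)
    if p > 0:
        bits += p * math.log2(p)
    if p < 1:
        bits += (1 - p) * math.log2((1 - p) / (n - 1))
    return (60.0 / inputs.T) * bits


def _windows_of(truth: EventLog, label: str | None) -> list[tuple[float, float]]:
    events = truth if label is None else truth.filter(label)
    return [(ev.onset_s, ev.end_s) for ev in events]


def accuracy(pred, truth, modality: str) -> float:
    """Percentage of cycles scored correct against ground truth.

    * ``ssvep``: ``pred`` is a sequence of chosen stimulus indices (or an
      EventLog of classification events carrying ``index`` in their info),
      compared elementwise with the cued indices in ``truth`` (a sequence
      or an EventLog of ``stimulus`` events).
    * ``eb`` / ``emg``: ``pred`` is an EventLog of detections; a ground
      truth window counts correct when a detection onset falls inside it.
    """
    if modality == "ssvep":
        pred_idx = (
            [ev.info["index"] for ev in pred] if isinstance(pred, EventLog) else list(pred)
        )
        truth_idx = (
            [ev.info["index"] for ev in truth.filter("stimulus")]
            if isinstance(truth, EventLog)
            else list(truth)
        )
        if len(pred_idx) != len(truth_idx):
            raise ConfigurationError(
                f"{len(pred_idx)} predictions for {len(truth_idx)} cued cycles"
            )
        if not truth_idx:
            raise ConfigurationError("accuracy undefined for zero cycles")
        correct = sum(int(p == t) for p, t in zip(pred_idx, truth_idx))
        return 100.0 * correct / len(truth_idx)
    if modality in ("eb", "emg"):
        label = {"eb": "eb", "emg": "chew"}[modality]
        windows = _windows_of(truth, label) if isinstance(truth, EventLog) else list(truth)
        if not windows:
            raise ConfigurationError("accuracy undefined for zero cycles")
        onsets = [ev.onset_s for ev in pred]
        correct = sum(
            int(any(a <= t <= b for t in onsets)) for a, b in windows
        )
        return 100.0 * correct / len(windows)
    raise ConfigurationError(f"unknown modality {modality!r}")


def false_positive_rate(
    detections: EventLog | Sequence[float],
    allowed_windows: Sequence[tuple[float, float]],
    session_minutes: float,
) -> float:
    """Detections outside every allowed window, per minute of session."""
    if session_minutes <= 0:
        raise ConfigurationError("session length must be positive")
    onsets = (
        [ev.onset_s for ev in detections]
        if isinstance(detections, EventLog)
        else list(detections)
    )
    false = sum(
        int(not any(a <= t <= b for a, b in allowed_windows)) for t in onsets
    )
    return false / session_minutes


def summarize(per_subject_reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of every field across subjects.

    The average ITR is the mean of per-subject ITRs, not the ITR of the
    mean accuracy (the two differ because the ITR is nonlinear in P).
    """
    if not per_subject_reports:
        raise ConfigurationError("no reports to summarize")
    acc_keys = {k for r in per_subject_reports for k in r.accuracy_pct}
    fpr_keys = {k for r in per_subject_reports for k in r.fpr_per_min}
    n = len(per_subject_reports)
    return MetricsReport(
        accuracy_pct={
            k: float(np.mean([r.accuracy_pct[k] for r in per_subject_reports if k in r.accuracy_pct]))
            for k in sorted(acc_keys)
        },
        itr_bit_per_min=float(np.mean([r.itr_bit_per_min for r in per_subject_reports])),
        fpr_per_min={
            k: float(np.mean([r.fpr_per_min[k] for r in per_subject_reports if k in r.fpr_per_min]))
            for k in sorted(fpr_keys)
        },
        n_cycles=int(round(np.mean([r.n_cycles for r in per_subject_reports]))),
        session_minutes=float(np.mean([r.session_minutes for r in per_subject_reports])),
    )
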