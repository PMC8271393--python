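"""Offline session scoring: run all three detectors against ground truth.

Reproduces the offline evaluation workflow on a (synthetic or recorded)
session: per-modality elliptic filtering, per-subject threshold
calibration, per-cycle detection — blink triples in the blink windows,
stimulus classification on start-aligned epochs of the gaze windows,
chewing in the chew windows — plus whole-session false-positive scans on
the 4 s / 1 s sliding grid.  Returns a :class:`~mealbci.metrics.MetricsReport`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eb_detect import (
    BlinkThreshold,
    calibrate_blink_threshold,
    detect_triple_blink,
    scan_stream_for_eb,
)
from .emg_detect import EmgThreshold, calibrate_emg_threshold, detect_chewing, emg_envelope
from .errors import ConfigurationError
from .events import EventLog
from .metrics import MetricsReport, false_positive_rate, itr_wolpaw
from .preprocess import CHANNEL_ROLES, Recording, apply_filter, make_filter, rereference, sliding_windows
from .ssvep_emsi import StimulusSet, classify_ssvep

__all__ = ["SessionScores", "score_session"]


@dataclass
class SessionScores:
    """Detailed per-cycle outcomes behind a MetricsReport."""

    report: MetricsReport
    eb_detected: list[bool]
    ssvep_chosen: list[int]
    ssvep_cued: list[int]
    emg_detected: list[bool]
    eb_threshold: BlinkThreshold
    emg_threshold: EmgThreshold


def _segment(x: np.ndarray, fs: float, start_s: float, len_s: float) -> np.ndarray:
    i0 = int(round(start_s * fs))
    return x[..., i0 : i0 + int(round(len_s * fs))]


def score_session(
    rec: Recording,
    truth: EventLog,
    epoch_s: float = 4.0,
    n_channels: int = 3,
    n_harmonics: int = 2,
    estimator: str = "emsi",
    stimuli: StimulusSet = StimulusSet(),
    session_minutes: float | None = None,
) -> SessionScores:
    """Score one session offline.

    ``epoch_s`` (3 or 4) and ``n_channels`` (1 = Oz only, 3 = O1/Oz/O2)
    select the analysis condition; epochs are start-aligned within each
    5 s gaze window.  Thresholds are calibrated from the session itself:
    blink threshold from the peaks inside the blink windows, chewing
    threshold from the envelope median inside the chew windows.
    """
    fs = rec.fs
    eb_windows = [(ev.onset_s, ev.end_s) for ev in truth.filter("eb")]
    gaze = list(truth.filter("stimulus"))
    chew_windows = [(ev.onset_s, ev.end_s) for ev in truth.filter("chew")]
    if not (eb_windows and gaze and chew_windows):
        raise ConfigurationError("ground truth must contain eb, stimulus and chew events")
    if session_minutes is None:
        session_minutes = rec.duration_s / 60.0

    # --- blink path -------------------------------------------------------
    fpz = apply_filter(rec.channel(CHANNEL_ROLES["eb"]), make_filter("eb", fs))
    calib = np.concatenate(
        [_segment(fpz, fs, a - 0.5, (b - a) + 1.0) for a, b in eb_windows]
    )
    eb_thr = calibrate_blink_threshold(calib, fs)
    eb_detected = []
    for a, b in eb_windows:
        # evaluate the 3 s response window around the instructed triple
        pad = max(0.0, (3.0 - (b - a)) / 2.0 + 0.3)
        epoch = _segment(fpz, fs, max(a - pad, 0.0), (b - a) + 2 * pad)
        eb_detected.append(detect_triple_blink(epoch, fs, eb_thr).detected)

    # --- SSVEP path -------------------------------------------------------
    occ_all = CHANNEL_ROLES["ssvep"]
    occ = ["Oz"] if n_channels == 1 else list(occ_all)
    reref = rereference(rec, occ, CHANNEL_ROLES["ssvep_ref"])
    ssvep_spec = make_filter("ssvep", fs)
    occ_filt = apply_filter(reref.samples, ssvep_spec)
    chosen, cued = [], []
    for ev in gaze:
        epoch = _segment(occ_filt, fs, ev.onset_s, epoch_s)
        dec = classify_ssvep(epoch, stimuli, n_harmonics=n_harmonics, fs=fs,
                             estimator=estimator)
        chosen.append(dec.chosen_index)
        cued.append(int(ev.info["index"]))

    # --- chewing path -----------------------------------------------------
    emg_spec = make_filter("emg", fs)
    envs = np.stack(
        [emg_envelope(apply_filter(rec.channel(ch), emg_spec), fs)
         for ch in CHANNEL_ROLES["emg"]]
    )
    # calibration envelope must contain chewing: use the chew windows
    combined = envs.max(axis=0)
    calib_env = np.concatenate([_segment(combined, fs, a, b - a) for a, b in chew_windows])
    emg_thr = calibrate_emg_threshold(calib_env)
    emg_detected = []
    for a, b in chew_windows:
        seg = _segment(envs, fs, a, b - a)
        emg_detected.append(detect_chewing(seg, fs, emg_thr).detected)

    # --- false-positive scans over the whole session ----------------------
    eb_events = _scan_eb(fpz, fs, eb_thr)
    eb_fp_windows = [(a - 1.0, b + 1.0) for a, b in eb_windows]
    eb_fpr = false_positive_rate(eb_events, eb_fp_windows, session_minutes)

    emg_events = _scan_emg(envs, fs, emg_thr)
    chew_fp_windows = [(a - 4.0, b + 1.0) for a, b in chew_windows]
    emg_fpr = false_positive_rate(emg_events, chew_fp_windows, session_minutes)

    n_cycles = len(gaze)
    acc_ssvep = 100.0 * float(np.mean([c == t for c, t in zip(chosen, cued)]))
    report = MetricsReport(
        accuracy_pct={
            "eb": 100.0 * float(np.mean(eb_detected)),
            "ssvep": acc_ssvep,
            "emg": 100.0 * float(np.mean(emg_detected)),
        },
        itr_bit_per_min=itr_wolpaw(acc_ssvep / 100.0, len(stimuli), epoch_s),
        fpr_per_min={"eb": eb_fpr, "emg": emg_fpr},
        n_cycles=n_cycles,
        session_minutes=session_minutes,
    )
    return SessionScores(
        report=report,
        eb_detected=eb_detected,
        ssvep_chosen=chosen,
        ssvep_cued=cued,
        emg_detected=emg_detected,
        eb_threshold=eb_thr,
        emg_threshold=emg_thr,
    )


def _scan_eb(fpz: np.ndarray, fs: float, thr: BlinkThreshold) -> EventLog:
    """Sliding 4 s / 1 s triple-blink scan on an already filtered trace."""
    rec = Recording(fpz[None, :], fs, ("FPz",))
    return scan_stream_for_eb(list(sliding_windows(rec, 4.0, 1.0)), thr)


def _scan_emg(envs: np.ndarray, fs: float, thr: EmgThreshold) -> EventLog:
    """Sliding-window chewing scan; runs of detected windows merge into one event."""
    log = EventLog()
    nwin, nstep = int(4.0 * fs), int(1.0 * fs)
    prev_detected = False
    for start in range(0, envs.shape[1] - nwin + 1, nstep):
        dec = detect_chewing(envs[:, start : start + nwin], fs, thr)
        if dec.detected and not prev_detected:
            log.add(start / fs, 4.0, "chew_window", supra_count=dec.supra_count)
        prev_detected = dec.detected
    return log
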