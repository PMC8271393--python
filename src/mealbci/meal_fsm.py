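"""The meal-cycle controller: detector events in, robot commands out.

One meal cycle: a triple eye-blink activates the system (LED flickers turn
on), the synchronization-index classifier selects the food, the robot
grabs and feeds it, chewing is monitored, and the cycle ends either on a
triple-confirmed chewing detection or after a 10 s timeout, upon which the
spoon returns and the system is ready for the next cycle.  Blink events
are honoured only while idle — the activation switch is locked out during
a meal.  Robot actions are simulated as timed log events; there is no
hardware interface here.

``run_session`` replays a recording through the real-time contract: a
common causal 0.5-55 Hz elliptic bandpass, 4 s windows sliding by 1 s,
with the blink, synchrony and chewing detectors gated by the controller
phase.  Replay is deterministic: the same recording and configuration
always produce the identical event log.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np

from .eb_detect import BlinkThreshold, detect_triple_blink
from .emg_detect import EmgThreshold, detect_chewing, emg_envelope
from .errors import ConfigurationError, SequencingError
from .events import EventLog
from .preprocess import (
    CHANNEL_ROLES,
    Recording,
    make_filter,
    filter_recording,
    sliding_windows,
)
from .ssvep_emsi import ClassDecision, StimulusSet, classify_ssvep

__all__ = [
    "Phase",
    "FsmState",
    "FsmConfig",
    "RobotCommand",
    "Tick",
    "BlinkEvent",
    "SelectionEvent",
    "ChewWindowEvent",
    "step",
    "run_session",
]


class Phase(enum.Enum):
    IDLE = "IDLE"
    STIMULATING = "STIMULATING"
    SELECTING = "SELECTING"
    FEEDING = "FEEDING"
    CHEW_MONITOR = "CHEW_MONITOR"
    RETURNING = "RETURNING"


@dataclass(frozen=True)
class FsmConfig:
    """Controller timings, seconds."""

    min_stimulation_s: float = 4.0  # ignore classifier output earlier than this
    grab_s: float = 2.0  # simulated grab-arm motion
    feed_s: float = 2.0  # simulated spoon-arm feed
    return_s: float = 1.0  # simulated spoon return
    chew_timeout_s: float = 10.0  # meal considered over without chewing
    chew_confirms_required: int = 3
    chew_rule: str = "consecutive"


@dataclass(frozen=True)
class FsmState:
    phase: Phase = Phase.IDLE
    entered_at: float = 0.0
    selection: int | None = None
    chew_confirm_count: int = 0
    clock: float = 0.0


@dataclass(frozen=True)
class RobotCommand:
    kind: str  # LED_ON | LED_OFF | GRAB_FOOD | FEED | RETURN_SPOON
    issued_at: float
    food_index: int | None = None


@dataclass(frozen=True)
class Tick:
    t: float


@dataclass(frozen=True)
class BlinkEvent:
    t: float


@dataclass(frozen=True)
class SelectionEvent:
    t: float
    decision: ClassDecision


@dataclass(frozen=True)
class ChewWindowEvent:
    t: float
    detected: bool


FsmInput = Union[Tick, BlinkEvent, SelectionEvent, ChewWindowEvent]


def step(
    state: FsmState, event: FsmInput, config: FsmConfig = FsmConfig()
) -> tuple[FsmState, list[RobotCommand]]:
    """Advance the controller by one event or clock tick.

    Pure function: returns the successor state and the commands issued.
    Events must arrive in non-decreasing time order.
    """
    t = event.t
    if t < state.clock:
        raise SequencingError(f"event at t={t} before clock {state.clock}")
    state = replace(state, clock=t)
    cmds: list[RobotCommand] = []

    if isinstance(event, BlinkEvent):
        if state.phase is Phase.IDLE:
            state = replace(state, phase=Phase.STIMULATING, entered_at=t,
                            selection=None, chew_confirm_count=0)
            cmds.append(RobotCommand("LED_ON", t))
        # any other phase: activation locked out, event discarded
        return state, cmds

    if isinstance(event, SelectionEvent):
        if state.phase is Phase.STIMULATING and t - state.entered_at >= config.min_stimulation_s:
            idx = event.decision.chosen_index
            state = replace(state, phase=Phase.SELECTING, entered_at=t, selection=idx)
            cmds.append(RobotCommand("GRAB_FOOD", t, food_index=idx))
            cmds.append(RobotCommand("FEED", t, food_index=idx))
            cmds.append(RobotCommand("LED_OFF", t))
        return state, cmds

    if isinstance(event, ChewWindowEvent):
        if state.phase is Phase.CHEW_MONITOR:
            if event.detected:
                count = state.chew_confirm_count + 1
            else:
                count = 0 if config.chew_rule == "consecutive" else state.chew_confirm_count
            state = replace(state, chew_confirm_count=count)
            if count >= config.chew_confirms_required:
                state = replace(state, phase=Phase.RETURNING, entered_at=t)
                cmds.append(RobotCommand("RETURN_SPOON", t))
        return state, cmds

    if isinstance(event, Tick):
        # timed progress of the simulated robot actions
        if state.phase is Phase.SELECTING and t - state.entered_at >= config.grab_s:
            state = replace(state, phase=Phase.FEEDING, entered_at=state.entered_at + config.grab_s)
        if state.phase is Phase.FEEDING and t - state.entered_at >= config.feed_s:
            state = replace(state, phase=Phase.CHEW_MONITOR,
                            entered_at=state.entered_at + config.feed_s,
                            chew_confirm_count=0)
        if state.phase is Phase.CHEW_MONITOR and t - state.entered_at >= config.chew_timeout_s:
            state = replace(state, phase=Phase.RETURNING, entered_at=t)
            cmds.append(RobotCommand("RETURN_SPOON", t))
        if state.phase is Phase.RETURNING and t - state.entered_at >= config.return_s:
            state = replace(state, phase=Phase.IDLE, entered_at=t,
                            selection=None, chew_confirm_count=0)
        return state, cmds

    raise ConfigurationError(f"unknown FSM input {event!r}")


@dataclass(frozen=True)
class SessionRunConfig:
    """Everything the streaming replay needs besides the recording."""

    eb_threshold: BlinkThreshold
    emg_threshold: EmgThreshold
    stimuli: StimulusSet = StimulusSet()
    window_s: float = 4.0
    step_s: float = 1.0
    n_harmonics: int = 2
    estimator: str = "emsi"
    ma_window_s: float = 0.25
    chew_min_duration_s: float = 2.0
    fsm: FsmConfig = FsmConfig()


def run_session(rec: Recording, config: SessionRunConfig) -> EventLog:
    """Replay a recording through the full online pipeline.

    Returns the merged event log: detections (``eb``, ``classification``,
    ``chew_window``), robot commands (log label = command kind) and phase
    transitions (``state``).  Every command is preceded in the log by the
    detection that licensed it.
    """
    eb_ch = CHANNEL_ROLES["eb"]
    occ = list(CHANNEL_ROLES["ssvep"])
    ref = CHANNEL_ROLES["ssvep_ref"]
    emg_chs = list(CHANNEL_ROLES["emg"])
    rec.require_channels([eb_ch, ref, *occ, *emg_chs])

    common = make_filter("realtime_common", rec.fs)
    filtered = filter_recording(rec, common, mode="causal")

    log = EventLog()
    state = FsmState()
    cfg = config.fsm

    def emit(cmds: Sequence[RobotCommand]) -> None:
        for cmd in cmds:
            info = {} if cmd.food_index is None else {"index": cmd.food_index}
            log.add(cmd.issued_at, 0.0, cmd.kind, **info)

    def record_phase(prev: Phase, new_state: FsmState) -> None:
        if new_state.phase is not prev:
            log.add(new_state.clock, 0.0, "state", phase=new_state.phase.value)

    for win in sliding_windows(filtered, config.window_s, config.step_s):
        t_end = win.window_end_s
        prev = state.phase
        state, cmds = step(state, Tick(t_end), cfg)
        emit(cmds)
        record_phase(prev, state)

        if state.phase is Phase.IDLE:
            dec = detect_triple_blink(win.channel(eb_ch), win.fs, config.eb_threshold)
            if dec.detected:
                times = [win.window_start_s + pt for pt in dec.peak_times]
                log.add(times[0], times[-1] - times[0], "eb",
                        peak_times=times, rescued_by_cwt=dec.rescued_by_cwt)
                prev = state.phase
                state, cmds = step(state, BlinkEvent(t_end), cfg)
                emit(cmds)
                record_phase(prev, state)
        elif state.phase is Phase.STIMULATING:
            if t_end - state.entered_at >= cfg.min_stimulation_s:
                ref_sig = win.channel(ref)
                data = np.stack([win.channel(ch) - ref_sig for ch in occ])
                decision = classify_ssvep(
                    data, config.stimuli, n_harmonics=config.n_harmonics,
                    fs=win.fs, estimator=config.estimator,
                )
                log.add(t_end, 0.0, "classification",
                        index=decision.chosen_index,
                        values=[round(v, 6) for v in decision.index_values])
                prev = state.phase
                state, cmds = step(state, SelectionEvent(t_end, decision), cfg)
                emit(cmds)
                record_phase(prev, state)
        elif state.phase is Phase.CHEW_MONITOR:
            envs = np.stack(
                [emg_envelope(win.channel(ch), win.fs, config.ma_window_s) for ch in emg_chs]
            )
            chew = detect_chewing(envs, win.fs, config.emg_threshold,
                                  config.chew_min_duration_s)
            log.add(t_end, 0.0, "chew_window",
                    detected=chew.detected, supra_count=chew.supra_count)
            prev = state.phase
            state, cmds = step(state, ChewWindowEvent(t_end, chew.detected), cfg)
            emit(cmds)
            record_phase(prev, state)

    return log
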