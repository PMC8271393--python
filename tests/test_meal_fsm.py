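"""Meal-cycle controller: transitions, lockout, timeout and full replay."""

import numpy as np
import pytest

from mealbci import (
    BlinkEvent,
    BlinkThreshold,
    ChewWindowEvent,
    ClassDecision,
    EmgThreshold,
    FsmConfig,
    FsmState,
    Phase,
    Recording,
    SelectionEvent,
    SequencingError,
    SessionRunConfig,
    SynthesisParams,
    Tick,
    calibrate_emg_threshold,
    emg_envelope,
    run_session,
    step,
    synth_blink_train,
    synth_chew_burst,
    synth_ssvep,
)
from mealbci.preprocess import STANDARD_CHANNELS

CFG = FsmConfig()


def decision(idx=2):
    vals = [0.1] * 5
    vals[idx] = 0.9
    return ClassDecision(chosen_index=idx, index_values=tuple(vals))


class TestStep:
    def test_idle_blink_starts_stimulation(self):
        state, cmds = step(FsmState(), BlinkEvent(5.0), CFG)
        assert state.phase is Phase.STIMULATING
        assert [c.kind for c in cmds] == ["LED_ON"]

    def test_blink_locked_out_outside_idle(self):
        state, _ = step(FsmState(), BlinkEvent(5.0), CFG)
        state2, cmds = step(state, BlinkEvent(6.0), CFG)
        assert state2.phase is Phase.STIMULATING and cmds == []

    def test_selection_commits_after_min_stimulation(self):
        state, _ = step(FsmState(), BlinkEvent(5.0), CFG)
        # too early: ignored
        state, cmds = step(state, SelectionEvent(7.0, decision()), CFG)
        assert state.phase is Phase.STIMULATING and cmds == []
        state, cmds = step(state, SelectionEvent(9.0, decision()), CFG)
        assert state.phase is Phase.SELECTING
        assert [c.kind for c in cmds] == ["GRAB_FOOD", "FEED", "LED_OFF"]
        assert cmds[0].food_index == 2

    def test_timed_progress_to_chew_monitor(self):
        state, _ = step(FsmState(), BlinkEvent(0.0), CFG)
        state, _ = step(state, SelectionEvent(4.0, decision()), CFG)
        state, _ = step(state, Tick(4.0 + CFG.grab_s + CFG.feed_s), CFG)
        assert state.phase is Phase.CHEW_MONITOR

    def _to_chew_monitor(self):
        state, _ = step(FsmState(), BlinkEvent(0.0), CFG)
        state, _ = step(state, SelectionEvent(4.0, decision()), CFG)
        state, _ = step(state, Tick(8.0), CFG)
        assert state.phase is Phase.CHEW_MONITOR
        return state

    def test_three_consecutive_chews_end_meal(self):
        state = self._to_chew_monitor()
        for t in (9.0, 10.0):
            state, cmds = step(state, ChewWindowEvent(t, True), CFG)
            assert cmds == []
        state, cmds = step(state, ChewWindowEvent(11.0, True), CFG)
        assert state.phase is Phase.RETURNING
        assert [c.kind for c in cmds] == ["RETURN_SPOON"]

    def test_missed_window_resets_consecutive_count(self):
        state = self._to_chew_monitor()
        for t, det in ((9.0, True), (10.0, True), (11.0, False), (12.0, True), (13.0, True)):
            state, cmds = step(state, ChewWindowEvent(t, det), CFG)
            assert cmds == []
        assert state.phase is Phase.CHEW_MONITOR
        assert state.chew_confirm_count == 2

    def test_timeout_returns_spoon(self):
        state = self._to_chew_monitor()
        entered = state.entered_at
        state, cmds = step(state, Tick(entered + CFG.chew_timeout_s), CFG)
        assert state.phase is Phase.RETURNING
        assert [c.kind for c in cmds] == ["RETURN_SPOON"]
        state, _ = step(state, Tick(entered + CFG.chew_timeout_s + CFG.return_s), CFG)
        assert state.phase is Phase.IDLE

    def test_out_of_order_events_rejected(self):
        state, _ = step(FsmState(), Tick(5.0), CFG)
        with pytest.raises(SequencingError):
            step(state, BlinkEvent(4.0), CFG)

    def test_no_feed_without_selection(self):
        # chew events before any selection leave IDLE untouched, no commands
        state, cmds = step(FsmState(), ChewWindowEvent(1.0, True), CFG)
        assert state.phase is Phase.IDLE and cmds == []


def single_cycle_recording(fs=128.0, with_chew=True, stim_freq=9.8, seed=0):
    """Blink triple at ~2 s, stimulus 4-12 s, chewing 13-17.5 s."""
    dur = 26.0
    n = int(dur * fs)
    params = SynthesisParams(fs=fs, seed=seed, emg_burst_band=(15.0, 55.0))
    rng = np.random.default_rng(seed + 1)
    data = {}
    for i, lb in enumerate(STANDARD_CHANNELS):
        p = SynthesisParams(fs=fs, seed=seed + 10 + i, emg_burst_band=(15.0, 55.0))
        data[lb], _ = synth_blink_train(0, 0.5, p, dur)
    # blink triple on FPz, centred at 2 s
    blink, _ = synth_blink_train(3, 0.5, SynthesisParams(fs=fs, seed=seed + 2), 4.0)
    data["FPz"][: len(blink)] = blink
    # stimulus on the occipital channels from 4 to 12 s (high SNR)
    stim = synth_ssvep(stim_freq, SynthesisParams(fs=fs, seed=seed + 3, ssvep_snr=8.0), 8.0, 3)
    i0, i1 = int(4 * fs), int(12 * fs)
    for k, lb in enumerate(("O1", "Oz", "O2")):
        data[lb][i0:i1] = stim[k]
    if with_chew:
        chew = synth_chew_burst(
            dur, [(13.0, 17.5)], SynthesisParams(fs=fs, seed=seed + 4, emg_burst_band=(15.0, 55.0))
        )
        for lb in ("T7", "T8"):
            data[lb] = chew
    return Recording(np.stack([data[lb] for lb in STANDARD_CHANNELS]), fs, STANDARD_CHANNELS)


def run_config(rec):
    chew_env = emg_envelope(rec.channel("T7")[int(13.2 * rec.fs) : int(17.2 * rec.fs)], rec.fs)
    emg_thr = calibrate_emg_threshold(chew_env)
    return SessionRunConfig(
        eb_threshold=BlinkThreshold(40.0),
        emg_threshold=emg_thr,
        fsm=FsmConfig(grab_s=1.0, feed_s=1.0),
    )


COMMANDS = ("LED_ON", "GRAB_FOOD", "FEED", "RETURN_SPOON")


class TestRunSession:
    def test_single_cycle_command_sequence(self):
        rec = single_cycle_recording()
        log = run_session(rec, run_config(rec))
        seq = [ev for ev in log if ev.label in COMMANDS]
        assert [ev.label for ev in seq] == list(COMMANDS)
        assert seq[1].info["index"] == 2  # 9.8 Hz is the third stimulus
        # chew-confirmed ending arrives before the 10 s timeout would
        feed_t = next(ev.onset_s for ev in log if ev.label == "FEED")
        ret_t = next(ev.onset_s for ev in log if ev.label == "RETURN_SPOON")
        assert ret_t - feed_t < FsmConfig().chew_timeout_s + 2.0
        assert sum(1 for ev in log if ev.label == "LED_OFF") == 1

    def test_no_blink_no_commands(self):
        rec = single_cycle_recording()
        quiet = rec.copy_with(np.vstack([rec.samples[0] * 0.01, rec.samples[1:]]))
        log = run_session(quiet, run_config(rec))
        assert [ev for ev in log if ev.label in COMMANDS] == []

    def test_timeout_when_chew_omitted(self):
        rec = single_cycle_recording(with_chew=False)
        ref = single_cycle_recording()  # for a valid chew threshold
        log = run_session(rec, run_config(ref))
        seq = [ev for ev in log if ev.label in COMMANDS]
        assert [ev.label for ev in seq] == list(COMMANDS)
        feed_t = next(ev.onset_s for ev in log if ev.label == "FEED")
        ret_t = next(ev.onset_s for ev in log if ev.label == "RETURN_SPOON")
        cfg = FsmConfig(grab_s=1.0, feed_s=1.0)
        expected = cfg.grab_s + cfg.feed_s + cfg.chew_timeout_s
        assert ret_t - feed_t == pytest.approx(expected, abs=1.1)  # one window slide

    def test_replay_byte_identical(self, tmp_path):
        rec = single_cycle_recording()
        cfg = run_config(rec)
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        run_session(rec, cfg).to_jsonl(p1)
        run_session(rec, cfg).to_jsonl(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_command_preceded_by_licensing_detection(self):
        rec = single_cycle_recording()
        log = run_session(rec, run_config(rec))
        labels = [ev.label for ev in log]
        assert labels.index("eb") < labels.index("LED_ON")
        assert labels.index("classification") < labels.index("GRAB_FOOD")
        chew_hits = [i for i, ev in enumerate(log) if ev.label == "chew_window" and ev.info["detected"]]
        assert chew_hits and chew_hits[0] < labels.index("RETURN_SPOON")

    def test_missing_channel_rejected(self):
        rec = single_cycle_recording()
        partial = Recording(rec.samples[:5], rec.fs, rec.labels[:5])
        from mealbci import NamedChannelError

        with pytest.raises(NamedChannelError):
            run_session(partial, run_config(rec))
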