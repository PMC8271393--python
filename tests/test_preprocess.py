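"""Filtering, re-referencing, windowing and recording I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mealbci import (
    ConfigurationError,
    FormatError,
    NamedChannelError,
    Recording,
    SamplingError,
    apply_filter,
    make_filter,
    read_recording,
    rereference,
    sliding_windows,
    write_recording_csv,
)


def _recording(n_ch=3, fs=512.0, dur=2.0, labels=("O1", "Oz", "Cz"), seed=0):
    rng = np.random.default_rng(seed)
    return Recording(rng.standard_normal((n_ch, int(fs * dur))), fs, labels)


class TestMakeFilter:
    @pytest.mark.parametrize(
        "modality,fs,kind,low,high",
        [
            ("eb", 512, "bandpass", 0.5, 5.0),
            ("ssvep", 512, "bandpass", 2.0, 54.0),
            ("emg", 512, "highpass", 0.5, None),
            ("realtime_common", 128, "bandpass", 0.5, 55.0),
        ],
    )
    def test_band_edges_per_modality(self, modality, fs, kind, low, high):
        spec = make_filter(modality, fs)
        assert (spec.kind, spec.low_hz, spec.high_hz) == (kind, low, high)

    def test_fs_too_low_for_band(self):
        with pytest.raises(SamplingError):
            make_filter("ssvep", 64)  # 54 Hz edge above 32 Hz Nyquist

    def test_unknown_modality(self):
        with pytest.raises(ConfigurationError):
            make_filter("ecg", 512)


class TestApplyFilter:
    def test_dc_rejected(self):
        spec = make_filter("eb", 512)
        y = apply_filter(np.full(4096, 10.0), spec)
        assert np.max(np.abs(y)) < 0.1  # µV, from a 10 µV constant

    def test_passband_amplitude_preserved(self):
        spec = make_filter("ssvep", 512)
        t = np.arange(8192) / 512
        y = apply_filter(np.sin(2 * np.pi * 9.8 * t), spec)
        mid = y[2048:-2048]
        # zero-phase => ripple applies twice; allow 2x passband ripple (0.5 dB each)
        assert np.max(np.abs(mid)) == pytest.approx(1.0, abs=0.12)

    def test_mains_attenuated_by_stopband_spec(self):
        # 60 Hz line noise must sit in the designed stopband of the 2-54 Hz filter
        spec = make_filter("ssvep", 512)
        h = spec.frequency_response(np.array([60.0]))
        atten_db = -20 * np.log10(np.abs(h[0]))
        assert atten_db >= spec.stopband_atten_db

    def test_linearity(self, rng):
        spec = make_filter("ssvep", 512)
        x, y = rng.standard_normal((2, 4096))
        lhs = apply_filter(2.5 * x - 1.5 * y, spec)
        rhs = 2.5 * apply_filter(x, spec) - 1.5 * apply_filter(y, spec)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_causal_mode_differs_from_zero_phase(self, rng):
        spec = make_filter("eb", 512)
        x = rng.standard_normal(4096)
        assert not np.allclose(
            apply_filter(x, spec, mode="causal"), apply_filter(x, spec)
        )

    def test_too_short_signal_rejected(self):
        with pytest.raises(ConfigurationError):
            apply_filter(np.zeros(10), make_filter("eb", 512))


class TestRereference:
    def test_channel_equal_to_ref_goes_to_zero(self):
        rec = _recording()
        rec.samples[0] = rec.samples[2]  # O1 := Cz
        out = rereference(rec, ["O1"], "Cz")
        np.testing.assert_array_equal(out.channel("O1"), 0.0)

    def test_exact_linear_recovery(self, rng):
        rec = _recording()
        s = rng.standard_normal(rec.n_samples)
        rec.samples[0] = rec.samples[2] + s  # O1 = Cz + s
        out = rereference(rec, ["O1"], "Cz")
        np.testing.assert_allclose(out.channel("O1"), s, atol=1e-12)

    def test_idempotent_once_ref_zeroed(self):
        rec = _recording()
        once = rereference(rec, ["O1", "Oz"], "Cz")
        rec2 = Recording(
            np.vstack([once.samples, np.zeros(rec.n_samples)]),
            rec.fs,
            ("O1", "Oz", "Cz"),
        )
        twice = rereference(rec2, ["O1", "Oz"], "Cz")
        np.testing.assert_array_equal(once.samples, twice.samples)

    def test_self_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            rereference(_recording(), ["O1", "Cz"], "Cz")

    def test_missing_channel(self):
        with pytest.raises(NamedChannelError):
            rereference(_recording(), ["O2"], "Cz")


class TestSlidingWindows:
    @pytest.mark.parametrize("dur,window,step,expected", [(10, 4, 1, 7), (4, 4, 1, 1), (9.5, 4, 2, 3)])
    def test_window_count(self, dur, window, step, expected):
        rec = _recording(dur=dur)
        wins = list(sliding_windows(rec, window, step))
        assert len(wins) == expected

    def test_starts_step_spaced_and_sized(self):
        rec = _recording(dur=10)
        wins = list(sliding_windows(rec, 4.0, 1.0))
        starts = [w.window_start_s for w in wins]
        np.testing.assert_allclose(np.diff(starts), 1.0)
        assert all(w.samples.shape[1] == int(4.0 * rec.fs) for w in wins)
        assert all(w.window_end_s <= rec.duration_s + 1e-9 for w in wins)

    def test_short_recording_warns_and_yields_nothing(self):
        rec = _recording(dur=2)
        with pytest.warns(UserWarning):
            assert list(sliding_windows(rec, 4.0, 1.0)) == []


class TestRecordingIO:
    def test_csv_round_trip(self, tmp_path, rng):
        rec = Recording(rng.standard_normal((7, 512)), 512.0,
                        ("FPz", "T7", "T8", "O1", "Oz", "O2", "Cz"))
        path = tmp_path / "rec.csv"
        write_recording_csv(rec, path)
        back = read_recording(path)
        assert back.labels == rec.labels
        assert back.fs == rec.fs
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-9)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(FormatError):
            read_recording(p)

    def test_missing_channel_for_pipeline(self, rng):
        rec = Recording(rng.standard_normal((2, 512)), 512.0, ("O1", "Oz"))
        with pytest.raises(NamedChannelError):
            rec.require_channels(["O1", "Oz", "Cz"])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            Recording(np.zeros((2, 10)), 512.0, ("Oz", "Oz"))


@given(scale=st.floats(0.1, 100.0), offset=st.floats(-50, 50))
def test_filter_dc_rejection_is_amplitude_independent(scale, offset):
    """Any constant input is annihilated by the blink bandpass."""
    spec = make_filter("eb", 512)
    y = apply_filter(np.full(2048, offset) * scale, spec)
    assert np.max(np.abs(y)) < 1e-3 * max(abs(offset * scale), 1.0)
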