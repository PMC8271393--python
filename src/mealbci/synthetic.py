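"""Synthetic scalp recordings with ground truth for the meal-cycle protocol.

Emulates the five-subject session design: per cycle, an instruction screen
(3 s), a triple-eye-blink window (3 s), a food cue (3 s), a gaze window with
a flickering stimulus at one of 7.4 / 8.43 / 9.8 / 11.7 / 13.7 Hz (5 s), a
chew cue (3 s) and a chewing window (5 s); five cycles per trial in random
stimulus order, six trials, 10 s rest between trials.  Blinks appear as
smooth positive deflections on FPz, the visual response as narrowband
occipital oscillations over 1/f background, chewing as broadband bursts on
T7/T8.  Everything is driven by a single seed and is bit-reproducible.

The generator is deliberately phenomenological: no volume conduction, no
eye movements other than blinks, no inter-subject variability unless the
caller varies the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, SamplingError
from .events import EventLog
from .preprocess import STANDARD_CHANNELS, Recording

__all__ = [
    "SessionProtocol",
    "SynthesisParams",
    "background_noise",
    "blink_pulse",
    "synth_blink_train",
    "synth_ssvep",
    "synth_chew_burst",
    "synth_session",
]

#: Stimulus frequencies of the five food targets (rice + four side dishes).
DEFAULT_STIMULUS_FREQS: tuple[float, ...] = (7.4, 8.43, 9.8, 11.7, 13.7)


@dataclass
class SessionProtocol:
    """Timeline of one recording session.

    Durations are seconds.  ``stimulus_order`` may pre-specify, per trial, a
    permutation of the stimulus indices; left ``None`` it is drawn from the
    synthesis seed.
    """

    n_trials: int = 6
    cycles_per_trial: int = 5
    instruction_s: float = 3.0
    eb_window_s: float = 3.0
    food_cue_s: float = 3.0
    gaze_s: float = 5.0
    chew_cue_s: float = 3.0
    chew_s: float = 5.0
    rest_s: float = 10.0
    stimulus_order: list[list[int]] | None = None

    def __post_init__(self) -> None:
        durations = (
            self.instruction_s,
            self.eb_window_s,
            self.food_cue_s,
            self.gaze_s,
            self.chew_cue_s,
            self.chew_s,
            self.rest_s,
        )
        if any(d <= 0 for d in durations):
            raise ConfigurationError("all protocol durations must be positive")
        if self.n_trials < 1 or self.cycles_per_trial < 1:
            raise ConfigurationError("need at least one trial and one cycle")
        if self.stimulus_order is not None:
            if len(self.stimulus_order) != self.n_trials:
                raise ConfigurationError("stimulus_order needs one permutation per trial")
            want = set(range(self.cycles_per_trial))
            for order in self.stimulus_order:
                if set(order) != want or len(order) != self.cycles_per_trial:
                    raise ConfigurationError(
                        f"each trial order must be a permutation of {sorted(want)}"
                    )

    @property
    def cycle_s(self) -> float:
        """Duration of one cycle (no rest): 3+3+3+5+3+5 = 22 s by default."""
        return (
            self.instruction_s
            + self.eb_window_s
            + self.food_cue_s
            + self.gaze_s
            + self.chew_cue_s
            + self.chew_s
        )

    @property
    def n_cycles(self) -> int:
        return self.n_trials * self.cycles_per_trial

    def total_s(self) -> float:
        """Session length: cycles plus the rests between trials."""
        return self.n_cycles * self.cycle_s + (self.n_trials - 1) * self.rest_s


@dataclass
class SynthesisParams:
    """Signal-level knobs of the generator.

    ``ssvep_snr`` is the ratio of narrowband stimulus power to background
    power within a 1 Hz band around the stimulus frequency (``np.inf`` means
    noise-free, ``0`` means no stimulus-locked component at all).
    ``noise_rms_uv`` sets the background amplitude on every channel;
    ``emg_burst_rms_uv`` the chewing-burst amplitude, which dominates the
    background as scalp EMG does.
    """

    fs: float = 512.0
    blink_amplitude: float = 100.0  # µV
    blink_width_s: float = 0.2
    ssvep_snr: float = 1.0
    n_harmonics_emitted: int = 1
    emg_burst_band: tuple[float, float] = (15.0, 60.0)
    noise_spectrum: Literal["white", "one_over_f"] = "one_over_f"
    noise_rms_uv: float = 10.0
    emg_burst_rms_uv: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        lo, hi = self.emg_burst_band
        if not 0 < lo < hi < self.fs / 2:
            raise SamplingError(f"emg_burst_band {self.emg_burst_band} invalid at fs={self.fs}")
        if self.blink_width_s <= 0 or self.blink_amplitude <= 0:
            raise ConfigurationError("blink pulse must have positive width and amplitude")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def background_noise(
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    spectrum: str = "one_over_f",
    rms: float = 10.0,
) -> np.ndarray:
    """Background activity: white or 1/f-power-shaped noise at a target RMS."""
    white = rng.standard_normal(n_samples)
    if spectrum == "white":
        x = white
    elif spectrum == "one_over_f":
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        freqs[0] = freqs[1] if n_samples > 1 else 1.0
        spec /= np.sqrt(freqs)  # amplitude ~ f^-1/2  =>  power ~ 1/f
        x = np.fft.irfft(spec, n=n_samples)
    else:
        raise ConfigurationError(f"unknown noise spectrum {spectrum!r}")
    x -= x.mean()
    s = x.std()
    return x * (rms / s) if s > 0 else x


def blink_pulse(width_s: float, fs: float) -> np.ndarray:
    """Unit-amplitude raised-cosine (Hann) pulse; smooth and unimodal."""
    n = max(int(round(width_s * fs)), 3) | 1  # odd length => peak exactly 1
    return np.hanning(n)


def synth_blink_train(
    n_blinks: int,
    interval_s: float,
    params: SynthesisParams,
    duration_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-channel signal with ``n_blinks`` evenly spaced blink pulses.

    Returns ``(signal, peak_times)``; the train is centred in the record,
    superposed on background noise.
    """
    if n_blinks < 0:
        raise ConfigurationError("n_blinks must be non-negative")
    n = int(round(duration_s * params.fs))
    x = background_noise(n, params.fs, params.rng(), params.noise_spectrum, params.noise_rms_uv)
    if n_blinks == 0:
        return x, np.array([])
    if n_blinks > 1 and interval_s <= params.blink_width_s:
        raise ConfigurationError(
            f"blink interval {interval_s} s too small for width {params.blink_width_s} s"
        )
    span = (n_blinks - 1) * interval_s
    if span + params.blink_width_s > duration_s:
        raise ConfigurationError("blink train does not fit in the requested duration")
    first = (duration_s - span) / 2.0
    peak_times = first + interval_s * np.arange(n_blinks)
    pulse = params.blink_amplitude * blink_pulse(params.blink_width_s, params.fs)
    half = len(pulse) // 2
    for t in peak_times:
        c = int(round(t * params.fs))
        lo, hi = c - half, c - half + len(pulse)
        x[max(lo, 0) : min(hi, n)] += pulse[max(-lo, 0) : len(pulse) - max(hi - n, 0)]
    return x, peak_times


def _band_power(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    freqs, pxx = sps.periodogram(x, fs=fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():
        return 0.0
    return float(np.trapezoid(pxx[band], freqs[band]))


def synth_ssvep(
    freq: float,
    params: SynthesisParams,
    duration_s: float,
    n_channels: int = 3,
) -> np.ndarray:
    """Multichannel oscillation at ``freq`` (plus optional harmonics) in noise.

    Each channel gets an independent random phase; the sinusoid amplitude is
    set so that its power over the background power in a 1 Hz band around
    the stimulus frequency equals ``params.ssvep_snr``.
    """
    if freq <= 0:
        raise ConfigurationError("stimulus frequency must be positive")
    if freq >= params.fs / 2:
        raise SamplingError(f"stimulus {freq} Hz at or above Nyquist for fs={params.fs}")
    if duration_s < 1:
        raise ConfigurationError("need at least 1 s of signal")
    if params.n_harmonics_emitted * freq >= params.fs / 2:
        raise SamplingError("highest emitted harmonic exceeds Nyquist")
    n = int(round(duration_s * params.fs))
    t = np.arange(n) / params.fs
    rng = params.rng()
    out = np.empty((n_channels, n))
    noiseless = np.isinf(params.ssvep_snr)
    for ch in range(n_channels):
        if noiseless:
            noise = np.zeros(n)
            amp = 10.0  # µV; arbitrary in the noise-free limit
        else:
            noise = background_noise(
                n, params.fs, rng, params.noise_spectrum, params.noise_rms_uv
            )
            p_band = _band_power(noise, params.fs, freq - 0.5, freq + 0.5)
            amp = float(np.sqrt(2.0 * params.ssvep_snr * p_band))
        sig = np.zeros(n)
        if params.ssvep_snr > 0:
            for h in range(1, params.n_harmonics_emitted + 1):
                phase = rng.uniform(0, 2 * np.pi)
                sig += (amp / h) * np.sin(2 * np.pi * h * freq * t + phase)
        out[ch] = noise + sig
    return out


def synth_chew_burst(
    duration_s: float,
    burst_windows: Sequence[tuple[float, float]],
    params: SynthesisParams,
) -> np.ndarray:
    """Single-channel record: broadband bursts inside the windows, noise elsewhere."""
    windows = sorted((float(a), float(b)) for a, b in burst_windows)
    for a, b in windows:
        if not 0 <= a < b <= duration_s:
            raise ConfigurationError(f"burst window ({a}, {b}) outside record of {duration_s} s")
    for (_, b0), (a1, _) in zip(windows, windows[1:]):
        if a1 < b0:
            raise ConfigurationError("burst windows overlap")
    n = int(round(duration_s * params.fs))
    rng = params.rng()
    x = background_noise(n, params.fs, rng, params.noise_spectrum, params.noise_rms_uv)
    lo, hi = params.emg_burst_band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")
    for a, b in windows:
        i0, i1 = int(round(a * params.fs)), int(round(b * params.fs))
        m = i1 - i0
        if m < 8:
            raise ConfigurationError(f"burst ({a}, {b}) too short at fs={params.fs}")
        burst = sps.sosfiltfilt(sos, rng.standard_normal(m))
        burst *= params.emg_burst_rms_uv / burst.std()
        burst *= sps.windows.tukey(m, alpha=0.1)  # soft onset/offset
        x[i0:i1] += burst
    return x


def synth_session(
    protocol: SessionProtocol,
    params: SynthesisParams,
    stimulus_freqs: Sequence[float] = DEFAULT_STIMULUS_FREQS,
) -> tuple[Recording, EventLog]:
    """Render a full session on the seven-channel montage with ground truth.

    Ground-truth labels: ``cycle`` (one per meal cycle), ``eb`` (the blink
    triple; peak times in info), ``stimulus`` (gaze window; stimulus index
    and frequency in info) and ``chew`` (burst extent).  Blink triples are
    centred in the blink window with 0.5 s spacing; chew bursts span the
    chew window minus a 0.25 s guard at each edge.
    """
    if len(stimulus_freqs) < protocol.cycles_per_trial:
        raise ConfigurationError("need at least one stimulus frequency per cycle of a trial")
    fs = params.fs
    rng = params.rng()

    order = protocol.stimulus_order
    if order is None:
        order = [
            list(rng.permutation(protocol.cycles_per_trial)) for _ in range(protocol.n_trials)
        ]

    n_total = int(round(protocol.total_s() * fs))
    n_ch = len(STANDARD_CHANNELS)
    data = np.empty((n_ch, n_total))
    for c in range(n_ch):
        data[c] = background_noise(
            n_total, fs, rng, params.noise_spectrum, params.noise_rms_uv
        )

    idx = {lb: i for i, lb in enumerate(STANDARD_CHANNELS)}
    truth = EventLog()
    blink = params.blink_amplitude * blink_pulse(params.blink_width_s, fs)
    half = len(blink) // 2
    t_cursor = 0.0
    for trial, trial_order in enumerate(order):
        for cycle_in_trial, stim in enumerate(trial_order):
            t0 = t_cursor
            truth.add(t0, protocol.cycle_s, "cycle", trial=trial, cycle=cycle_in_trial,
                      stimulus_index=int(stim))

            # --- blink triple, centred in the EB window, 0.5 s spacing
            eb_start = t0 + protocol.instruction_s
            spacing = 0.5
            centre = eb_start + protocol.eb_window_s / 2.0
            peaks = centre + spacing * (np.arange(3) - 1)
            for tp in peaks:
                c = int(round(tp * fs))
                data[idx["FPz"], c - half : c - half + len(blink)] += blink
            truth.add(peaks[0], peaks[-1] - peaks[0], "eb", peak_times=list(peaks))

            # --- SSVEP in the gaze window on the occipital channels
            gaze_start = eb_start + protocol.eb_window_s + protocol.food_cue_s
            freq = float(stimulus_freqs[stim])
            g0 = int(round(gaze_start * fs))
            g1 = int(round((gaze_start + protocol.gaze_s) * fs))
            t = np.arange(g1 - g0) / fs
            for lb in ("O1", "Oz", "O2"):
                noise_seg = data[idx[lb], g0:g1]
                if np.isinf(params.ssvep_snr):
                    amp = 10.0
                elif params.ssvep_snr > 0:
                    p_band = _band_power(noise_seg, fs, freq - 0.5, freq + 0.5)
                    amp = float(np.sqrt(2.0 * params.ssvep_snr * p_band))
                else:
                    amp = 0.0
                for h in range(1, params.n_harmonics_emitted + 1):
                    phase = rng.uniform(0, 2 * np.pi)
                    noise_seg += (amp / h) * np.sin(2 * np.pi * h * freq * t + phase)
            truth.add(gaze_start, protocol.gaze_s, "stimulus",
                      index=int(stim), freq_hz=freq)

            # --- chewing burst on both temporal channels
            chew_start = gaze_start + protocol.gaze_s + protocol.chew_cue_s
            guard = 0.25
            b0 = int(round((chew_start + guard) * fs))
            b1 = int(round((chew_start + protocol.chew_s - guard) * fs))
            lo, hi = params.emg_burst_band
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            for lb in ("T7", "T8"):
                burst = sps.sosfiltfilt(sos, rng.standard_normal(b1 - b0))
                burst *= params.emg_burst_rms_uv / burst.std()
                burst *= sps.windows.tukey(b1 - b0, alpha=0.1)
                data[idx[lb], b0:b1] += burst
            truth.add(chew_start + guard, protocol.chew_s - 2 * guard, "chew")

            t_cursor += protocol.cycle_s
        if trial < protocol.n_trials - 1:
            t_cursor += protocol.rest_s

    rec = Recording(data, fs, STANDARD_CHANNELS)
    return rec, truth
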