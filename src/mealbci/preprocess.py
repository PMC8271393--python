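"""Recording I/O, elliptic IIR filtering, re-referencing and windowing.

The pipeline works on seven scalp channels.  Their roles are fixed by the
montage: FPz carries eye blinks, O1/Oz/O2 carry the steady-state visual
evoked potential (re-referenced against Cz), and T7/T8 carry the chewing
electromyogram.  Offline recordings are sampled at 512 Hz; the real-time
path runs at 128 Hz with a single common 0.5-55 Hz bandpass, a 4 s analysis
window and a 1 s slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, FormatError, NamedChannelError, SamplingError

__all__ = [
    "CHANNEL_ROLES",
    "STANDARD_CHANNELS",
    "Recording",
    "FilterSpec",
    "Epoch",
    "read_recording",
    "write_recording_csv",
    "make_filter",
    "apply_filter",
    "rereference",
    "sliding_windows",
]

#: Channel-role mapping used by the detectors.
CHANNEL_ROLES: dict[str, object] = {
    "eb": "FPz",
    "ssvep": ["O1", "Oz", "O2"],
    "ssvep_ref": "Cz",
    "emg": ["T7", "T8"],
}

#: Montage order used by the synthetic generator and the session runner.
STANDARD_CHANNELS: tuple[str, ...] = ("FPz", "T7", "T8", "O1", "Oz", "O2", "Cz")

#: Band edges (low_hz, high_hz) per processing modality.  ``None`` marks a
#: highpass.  EB: blink band; SSVEP: keeps stimulation fundamentals and
#: harmonics below the 60 Hz mains line; EMG: DC removal only;
#: realtime_common: the single shared band of the 128 Hz online system.
MODALITY_BANDS: dict[str, tuple[float, float | None]] = {
    "eb": (0.5, 5.0),
    "ssvep": (2.0, 54.0),
    "emg": (0.5, None),
    "realtime_common": (0.5, 55.0),
}


@dataclass
class Recording:
    """Multichannel scalp time series in microvolts.

    ``samples`` is channels x time; ``labels`` names each row.
    """

    samples: np.ndarray
    fs: float
    labels: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = tuple(self.labels)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be a 2-D channels x time array")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("channel labels must be unique")
        if self.samples.shape[0] != len(self.labels):
            raise ConfigurationError(
                f"{self.samples.shape[0]} sample rows but {len(self.labels)} labels"
            )
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples; raise if the label is absent."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise NamedChannelError(
                f"channel {label!r} not in recording (has {list(self.labels)})"
            ) from None
        return self.samples[idx]

    def pick(self, labels: Sequence[str]) -> "Recording":
        rows = np.stack([self.channel(lb) for lb in labels])
        return Recording(rows, self.fs, tuple(labels), self.start_time)

    def require_channels(self, labels: Iterable[str]) -> None:
        missing = [lb for lb in labels if lb not in self.labels]
        if missing:
            raise NamedChannelError(f"recording lacks required channel(s) {missing}")

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return Recording(np.asarray(samples, float), self.fs, self.labels, self.start_time)


@dataclass(frozen=True)
class FilterSpec:
    """An elliptic IIR filter design.

    ``high_hz is None`` denotes a highpass.  ``sos`` holds the designed
    second-order sections; stability is checked at design time.
    """

    kind: Literal["bandpass", "highpass"]
    low_hz: float
    high_hz: float | None
    fs: float
    order: int = 6
    passband_ripple_db: float = 0.5
    stopband_atten_db: float = 40.0
    sos: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        nyq = self.fs / 2.0
        if self.kind == "bandpass":
            if not (0 < self.low_hz < self.high_hz < nyq):  # type: ignore[operator]
                raise SamplingError(
                    f"bandpass {self.low_hz}-{self.high_hz} Hz invalid at fs={self.fs}"
                )
            wn = [self.low_hz / nyq, self.high_hz / nyq]  # type: ignore[operator]
            btype = "bandpass"
        elif self.kind == "highpass":
            if not 0 < self.low_hz < nyq:
                raise SamplingError(f"highpass edge {self.low_hz} Hz invalid at fs={self.fs}")
            wn = self.low_hz / nyq
            btype = "highpass"
        else:
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        sos = sps.ellip(
            self.order,
            self.passband_ripple_db,
            self.stopband_atten_db,
            wn,
            btype=btype,
            output="sos",
        )
        # all poles strictly inside the unit circle, else refuse the design
        _, poles, _ = sps.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ConfigurationError("unstable filter design")
        object.__setattr__(self, "sos", sos)

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response at the given frequencies (Hz)."""
        _, h = sps.sosfreqz(self.sos, worN=np.asarray(freqs_hz, float), fs=self.fs)
        return h


@dataclass(frozen=True)
class Epoch:
    """A fixed-length analysis window cut from a recording."""

    samples: np.ndarray
    fs: float
    window_start_s: float
    window_len_s: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.atleast_2d(np.asarray(self.samples, float)))
        expected = self.window_len_s * self.fs
        if abs(self.samples.shape[1] - expected) > 1:
            raise ConfigurationError(
                f"epoch has {self.samples.shape[1]} samples, expected ~{expected:.0f}"
            )

    @property
    def window_end_s(self) -> float:
        return self.window_start_s + self.window_len_s

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError:
            raise NamedChannelError(f"epoch lacks channel {label!r}") from None


# ---------------------------------------------------------------------------
# I/O


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF/BDF (via mne) or labelled CSV.

    CSV layout: one column per channel; the header row holds channel labels,
    and the sampling rate is carried in a ``# fs=<Hz>`` comment on the first
    line (as written by :func:`write_recording_csv`).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format in ("edf", "bdf"):
        import mne

        try:
            if format == "edf":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            else:
                raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
        except Exception as exc:  # corrupt header, truncated file ...
            raise FormatError(f"could not parse {path} as {format.upper()}: {exc}") from exc
        data = raw.get_data() * 1e6  # mne returns volts
        return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))
    if format == "csv":
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("#"):
                raise FormatError(f"{path}: missing '# fs=' header line")
            try:
                fs = float(dict(kv.split("=") for kv in first.lstrip("# ").split())["fs"])
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}: malformed header {first!r}") from exc
            df = pd.read_csv(fh)
        return Recording(df.to_numpy().T, fs, tuple(df.columns))
    raise FormatError(f"unknown recording format {format!r}")


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording as labelled CSV with a ``# fs=`` header line."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        pd.DataFrame(rec.samples.T, columns=list(rec.labels)).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Filtering


def make_filter(
    modality: str,
    fs: float,
    order: int = 6,
    passband_ripple_db: float = 0.5,
    stopband_atten_db: float = 40.0,
) -> FilterSpec:
    """Build the elliptic IIR filter for one processing modality.

    Band edges per modality: eb 0.5-5 Hz bandpass, ssvep 2-54 Hz bandpass,
    emg 0.5 Hz highpass, realtime_common 0.5-55 Hz bandpass.
    """
    try:
        low, high = MODALITY_BANDS[modality]
    except KeyError:
        raise ConfigurationError(
            f"unknown modality {modality!r}; expected one of {sorted(MODALITY_BANDS)}"
        ) from None
    kind = "highpass" if high is None else "bandpass"
    return FilterSpec(
        kind=kind,
        low_hz=low,
        high_hz=high,
        fs=fs,
        order=order,
        passband_ripple_db=passband_ripple_db,
        stopband_atten_db=stopband_atten_db,
    )


def apply_filter(
    x: np.ndarray,
    spec: FilterSpec,
    mode: Literal["offline_zero_phase", "causal"] = "offline_zero_phase",
) -> np.ndarray:
    """Filter a signal (1-D) or channel stack (2-D, channels x time).

    ``offline_zero_phase`` runs the filter forward and backward (no phase
    distortion; used for offline analysis); ``causal`` runs a single forward
    pass as the real-time system must.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= 3 * spec.order:
        raise ConfigurationError(f"signal too short ({n} samples) for order-{spec.order} filter")
    if mode == "offline_zero_phase":
        return sps.sosfiltfilt(spec.sos, x, axis=-1)
    if mode == "causal":
        return sps.sosfilt(spec.sos, x, axis=-1)
    raise ConfigurationError(f"unknown filter mode {mode!r}")


def filter_recording(
    rec: Recording,
    spec: FilterSpec,
    mode: Literal["offline_zero_phase", "causal"] = "offline_zero_phase",
) -> Recording:
    """Apply one filter to every channel of a recording."""
    return rec.copy_with(apply_filter(rec.samples, spec, mode=mode))


# ---------------------------------------------------------------------------
# Re-referencing and windowing


def rereference(rec: Recording, channels: Sequence[str], ref: str) -> Recording:
    """Subtract the reference channel from each requested channel.

    Returns a recording holding only ``channels`` (in the given order), each
    with the reference waveform removed; used to re-reference the occipital
    channels against Cz before synchrony estimation.
    """
    if ref in channels:
        raise ConfigurationError(f"reference {ref!r} listed among target channels")
    rec.require_channels(list(channels) + [ref])
    ref_sig = rec.channel(ref)
    rows = np.stack([rec.channel(ch) - ref_sig for ch in channels])
    return Recording(rows, rec.fs, tuple(channels), rec.start_time)


def sliding_windows(
    rec: Recording, window_s: float = 4.0, step_s: float = 1.0
) -> Iterator[Epoch]:
    """Yield half-open [start, start+window) epochs on a step_s grid.

    Yields ``floor((T - window)/step) + 1`` epochs; a recording shorter than
    one window yields nothing (with a warning), matching the streaming
    contract of the 4 s / 1 s online analysis.
    """
    if window_s <= 0 or step_s <= 0:
        raise ConfigurationError("window_s and step_s must be positive")
    nwin = int(round(window_s * rec.fs))
    nstep = int(round(step_s * rec.fs))
    if nwin > rec.n_samples:
        warnings.warn(
            f"recording ({rec.duration_s:.2f} s) shorter than window ({window_s} s); no epochs",
            stacklevel=2,
        )
        return
    for start in range(0, rec.n_samples - nwin + 1, nstep):
        yield Epoch(
            rec.samples[:, start : start + nwin],
            rec.fs,
            rec.start_time + start / rec.fs,
            window_s,
            rec.labels,
        )
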