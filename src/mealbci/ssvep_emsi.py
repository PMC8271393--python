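"""SSVEP frequency recognition via the multivariate synchronization index.

The attended flicker frequency is recognized by measuring the synchrony
between the occipital channels (O1/Oz/O2, re-referenced to Cz) and a set of
sine/cosine reference signals at each candidate frequency and its
harmonics.  Synchrony is quantified with the S-estimator: stack channels
and references, form their joint correlation matrix, whiten each auto-block
to identity so that only cross-correlation structure remains, and map the
eigenvalue entropy of the result onto [0, 1] — 0 for independent signals,
1 for perfect synchrony.  The stimulus with the largest index wins.  The
method needs no training data.

Two estimator variants are exposed: ``msi`` applies the S-estimator to the
raw channel block, while ``emsi`` first augments each channel with a copy
delayed by a quarter cycle of the candidate frequency (a minimal temporal
embedding that adds the quadrature component of the response and improves
robustness to the unknown response phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError, SamplingError
from .preprocess import Epoch

__all__ = [
    "StimulusSet",
    "ReferenceSet",
    "ClassDecision",
    "make_references",
    "sync_index",
    "classify_ssvep",
]

DEFAULT_FREQS: tuple[float, ...] = (7.4, 8.43, 9.8, 11.7, 13.7)
DEFAULT_LABELS: tuple[str, ...] = ("rice", "side dish 1", "side dish 2", "side dish 3", "side dish 4")

#: Relative eigenvalue cutoff for the auto-block whitening.
WHITEN_EPS = 1e-10


@dataclass(frozen=True)
class StimulusSet:
    """Ordered flicker frequencies and the food target each selects."""

    freqs_hz: tuple[float, ...] = DEFAULT_FREQS
    target_labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(set(self.freqs_hz)) != len(self.freqs_hz):
            raise ConfigurationError("stimulus frequencies must be distinct")
        if any(f <= 0 for f in self.freqs_hz):
            raise ConfigurationError("stimulus frequencies must be positive")
        if len(self.target_labels) != len(self.freqs_hz):
            raise ConfigurationError("one target label per frequency required")

    def __len__(self) -> int:
        return len(self.freqs_hz)


@dataclass(frozen=True)
class ReferenceSet:
    """Sine/cosine reference block for one candidate frequency."""

    freq: float
    n_harmonics: int
    fs: float
    matrix: np.ndarray = field(repr=False)  # (2H, M)


@dataclass(frozen=True)
class ClassDecision:
    chosen_index: int
    index_values: tuple[float, ...]


def make_references(
    freq: float, n_harmonics: int, n_samples: int, fs: float, strict: bool = False
) -> ReferenceSet:
    """Build sin/cos rows at h*freq for h = 1..H on the epoch time grid.

    Harmonics at or above Nyquist are dropped with a warning (or rejected
    when ``strict``).
    """
    if freq <= 0 or n_harmonics < 1:
        raise ConfigurationError("need a positive frequency and at least one harmonic")
    h_max = n_harmonics
    while h_max >= 1 and h_max * freq >= fs / 2:
        h_max -= 1
    if h_max < n_harmonics:
        if strict or h_max == 0:
            raise SamplingError(
                f"harmonic {n_harmonics}x{freq} Hz at or above Nyquist for fs={fs}"
            )
        warnings.warn(
            f"dropping harmonics above Nyquist: using H={h_max} for {freq} Hz at fs={fs}",
            stacklevel=2,
        )
    t = np.arange(n_samples) / fs
    rows = []
    for h in range(1, h_max + 1):
        rows.append(np.sin(2 * np.pi * h * freq * t))
        rows.append(np.cos(2 * np.pi * h * freq * t))
    return ReferenceSet(freq=freq, n_harmonics=h_max, fs=fs, matrix=np.stack(rows))


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    std = a.std(axis=1, keepdims=True)
    bad = std.ravel() == 0
    if bad.any():
        warnings.warn("constant channel encountered; leaving it zero", stacklevel=3)
        std[std == 0] = 1.0
    return a / std

def _inv_sqrt(block: np.ndarray) -> np.ndarray:
    """Pseudo-inverse square root: directions with eigenvalues below
    WHITEN_EPS of the largest are dropped (rank-deficient blocks, e.g. a
    constant channel or identical-frequency sinusoids, stay numerically
    stable instead of amplifying round-off in the near-null space)."""
    w, v = np.linalg.eigh(block)
    keep = w > WHITEN_EPS * np.max(w)
    inv = np.where(keep, 1.0 / np.sqrt(np.where(keep, w, 1.0)), 0.0)
    return (v * inv) @ v.T

def _s_estimator(x: np.ndarray, y: np.ndarray) -> float:
    """Eigenvalue-entropy synchronization of two signal blocks, in [0, 1]."""
    n, m = x.shape
    k = y.shape[0]
    if m <= n + k:
        raise ConfigurationError(f"epoch too short ({m} samples) for {n + k} joint dimensions")
    z = np.vstack([_standardize_rows(x), _standardize_rows(y)])
    c = (z @ z.T) / m
    u = np.zeros_like(c)
    u[:n, :n] = _inv_sqrt(c[:n, :n])
    u[n:, n:] = _inv_sqrt(c[n:, n:])
    r = u @ c @ u.T
    lam = np.linalg.eigvalsh(r)
    lam = np.clip(lam, 0.0, None)
    lam_n = lam / lam.sum()
    p = n + k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(lam_n > 0, lam_n * np.log(lam_n), 0.0)
    s = 1.0 + terms.sum() / np.log(p)
    return float(min(max(s, 0.0), 1.0))


def sync_index(
    epoch: np.ndarray,
    refs: ReferenceSet,
    estimator: Literal["msi", "emsi"] = "emsi",
) -> float:
    """Synchrony between an N-channel epoch and one frequency's references.

    Scale-invariant (rows are variance-normalized) and symmetric in channel
    order.  ``emsi`` augments the channel block with a quarter-cycle
    delayed copy before estimation.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    y = refs.matrix
    if x.shape[1] != y.shape[1]:
        raise ConfigurationError(
            f"epoch has {x.shape[1]} samples but references have {y.shape[1]}"
        )
    if estimator == "msi":
        return _s_estimator(x, y)
    if estimator == "emsi":
        d = max(1, int(round(refs.fs / (4.0 * refs.freq))))
        if x.shape[1] <= 2 * d:
            raise ConfigurationError("epoch too short for delay embedding")
        x_aug = np.vstack([x[:, d:], x[:, :-d]])
        return _s_estimator(x_aug, y[:, d:])
    raise ConfigurationError(f"unknown estimator {estimator!r}")


def classify_ssvep(
    epoch: Epoch | np.ndarray,
    stimuli: StimulusSet = StimulusSet(),
    n_harmonics: int = 2,
    fs: float | None = None,
    estimator: Literal["msi", "emsi"] = "emsi",
) -> ClassDecision:
    """Pick the attended stimulus: argmax of the synchronization index.

    Accepts a 1- or 3-channel occipital epoch (already re-referenced to
    Cz).  Ties break deterministically toward the lowest stimulus index.
    """
    if isinstance(epoch, Epoch):
        data = epoch.samples
        fs = epoch.fs
    else:
        data = np.atleast_2d(np.asarray(epoch, dtype=float))
        if fs is None:
            raise ConfigurationError("fs required when passing a bare array")
    m = data.shape[1]
    values = []
    for f in stimuli.freqs_hz:
        refs = make_references(f, n_harmonics, m, fs)
        values.append(sync_index(data, refs, estimator=estimator))
    values_arr = np.asarray(values)
    if not np.all(np.isfinite(values_arr)):
        raise ConfigurationError("non-finite synchronization index")
    return ClassDecision(chosen_index=int(np.argmax(values_arr)), index_values=tuple(values))
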