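# Methods

`mealbci` implements the signal-processing core of a hybrid brain–computer
interface for a meal-assist robot.  Three scalp signals, all recorded with
the same EEG montage, drive one meal cycle: a voluntary triple eye-blink
(prefrontal channel FPz) arms the system, a steady-state visual evoked
potential (SSVEP; occipital channels O1/Oz/O2 against a Cz reference)
selects one of five foods marked by LEDs flickering at 7.4, 8.43, 9.8, 11.7
and 13.7 Hz, and chewing electromyogram (EMG; temporal channels T7/T8) — or
a 10 s timeout — closes the cycle.  Offline analysis runs at 512 Hz; the
online contract is 128 Hz with a 4 s analysis window sliding by 1 s.

## Signal model and synthetic sessions

The generator (`mealbci.synthetic`) renders the session protocol used for
performance measurement: per cycle, instruction (3 s), blink window (3 s),
food cue (3 s), gaze window (5 s), chew cue (3 s), chew window (5 s) —
22 s per cycle; five cycles per trial in a seed-driven random permutation
of the five stimuli; six trials (30 cycles) with 10 s rests between trials,
≈11.8 min in total.

* **Background**: 1/f-power-shaped Gaussian noise (white optional) at
  10 µV RMS on every channel — the canonical EEG spectral shape; amplitude
  chosen at the low end of typical scalp EEG so detector margins are not
  trivially large.
* **Blinks**: raised-cosine (Hann) pulses, 200 ms wide, 100 µV, in triples
  spaced 0.5 s and centred in the blink window.  Real blinks are
  asymmetric; only amplitude, width and timing matter to the detector
  under test, so a symmetric smooth unimodal pulse suffices.
* **SSVEP**: a sinusoid at the cued frequency with an independent random
  phase per occipital channel.  Its amplitude is set per channel so that
  sinusoid power over background power *within a 1 Hz band around the
  stimulus frequency* equals `ssvep_snr`.  The default `ssvep_snr = 1`
  ("moderate") puts 4 s classification accuracy in the 65–80 % range —
  comparable to the mid-range of real subjects; `ssvep_snr = 4` ("high")
  saturates it.  Only the fundamental is emitted by default so the
  classifier's harmonic handling stays an independent choice.
* **Chewing**: 15–60 Hz bandpassed Gaussian bursts at 50 µV RMS with soft
  Tukey edges, on both temporal channels, spanning the chew window minus a
  0.25 s guard.

Everything derives from one `numpy` generator seeded by
`SynthesisParams.seed`; identical inputs give bit-identical recordings and
event logs.  The generator is phenomenological: no volume conduction, no
channel cross-talk, no eye movements other than blinks, no alpha rhythm,
no electrode drift, and a *stationary* noise floor.  Passing tests
therefore demonstrate algorithmic correctness against a known ground
truth, not clinical performance on real recordings.

## Preprocessing

All filters are elliptic IIR designs (`scipy.signal.ellip`, second-order
sections): blink band 0.5–5 Hz, SSVEP band 2–54 Hz (the upper edge keeps
the 60 Hz South-Korean mains line in the stopband), EMG 0.5 Hz highpass
(DC removal only), and the shared online band 0.5–55 Hz at 128 Hz.
Defaults: order 6, 0.5 dB passband ripple, 40 dB stopband attenuation —
order 6 rather than a lower order because the 54 → 60 Hz transition must
actually reach the stopband specification (an order-4 design attenuates
60 Hz by only ~6 dB; order 6 gives ~42 dB) and the design is stable at
both 128 and 512 Hz.  Offline filtering is zero-phase
(forward–backward); the streaming path is strictly causal.  Stability is
checked at design time (all poles inside the unit circle) and an unstable
design raises instead of returning garbage.

Event times are seconds from recording start; windows are half-open
`[start, start + len)`; a sliding scan of a record of length `T` yields
`floor((T − window)/step) + 1` epochs.

## Triple-blink detection

On the 0.5–5 Hz filtered FPz trace, candidate peaks are local maxima with
a minimum separation of 0.3 s and height above the subject's threshold,
defined as half the mean amplitude of instructed calibration blinks.  A
triple is accepted iff **exactly three** supra-threshold peaks exist in
the epoch (a fourth voids the detection) and **both** inter-peak gaps lie
strictly inside (0.3, 0.8) s — faster repeats are "mistake blinks",
slower ones are unrelated spontaneous blinks.  If the direct pass fails,
the trace is re-screened on a continuous-wavelet enhanced version: a
Ricker (Mexican-hat) filter bank at scales matched to 100–400 ms blink
widths, each scale gain-normalized so a unit-amplitude blink of the
matching width responds with ~1, then reduced by a maximum across scales.
The µV threshold thus carries over to the enhanced trace, and the same
two conditions are re-applied.  In streaming mode, detections whose
middle peaks fall within 1 s are merged (the same physical triple seen
through overlapping 4 s windows), and windows flagged as locked out (any
non-idle controller phase) never emit.

## SSVEP recognition — multivariate synchronization index

For each candidate frequency `f`, reference signals are
`sin(2π h f t), cos(2π h f t)` for harmonics `h = 1..H` (default `H = 2`,
bounded by the passband/Nyquist).  The channel block `X` (N×M) and
reference block `Y` (2H×M) are centred and variance-normalized per row,
stacked, and their joint correlation matrix `C` is formed.  The two
auto-blocks are whitened to identity with inverse square roots, leaving
only cross-block structure in `R = U C Uᵀ`.  With normalized eigenvalues
`λ'ᵢ = λᵢ/Σλ` and joint dimension `P = N + 2H`, the synchronization index
is the linearized eigenvalue entropy

    S = 1 + Σᵢ λ'ᵢ log λ'ᵢ / log P  ∈ [0, 1],

0 for mutually independent signals (all `λ'ᵢ` equal) and approaching 1 as
the joint matrix collapses toward rank 1.  The stimulus with the largest
S wins; ties break toward the lowest index.  Because rows are
variance-normalized, S is exactly scale-invariant and symmetric under
channel permutation; the single-channel case is the same formula with
N = 1.  No training data is used.

Two estimator variants sit behind one interface.  `msi` is the plain
S-estimator above.  `emsi` (default) first augments the channel block
with a copy of each channel delayed by a quarter cycle of the candidate
frequency — a minimal temporal embedding that supplies the quadrature
component of the response and removes sensitivity to the unknown response
phase.  On the synthetic benchmark both variants perform within a few
percent of each other; the embedding choice is the package's own, since
only the estimator family is fixed by the method's lineage.

Whitening uses a pseudo-inverse square root: eigenvalue directions below
`1e−10` of the block's largest eigenvalue are dropped rather than
regularized away.  Rank-deficient blocks (a constant channel, or three
channels carrying the same noiseless sinusoid) then stay numerically
stable; an additive-epsilon regularization amplifies round-off in the
near-null space and visibly breaks scale invariance (~1e−7), while the
pseudo-inverse keeps it below 1e−12.

## Chewing detection

The envelope is `MA(|d/dt MA(|x|)|)`: rectify, smooth with a 250 ms
moving average, differentiate (first difference × fs), rectify, smooth
again.  Differentiation suppresses slow baseline wander so only fast
broadband bursts survive.  The threshold is 50 % of the median envelope
over a calibration segment *that contains chewing* — over a mostly quiet
record the baseline exceeds half its own median almost everywhere and
the rule would degenerate, hence the calibration precondition.  Chewing
is reported when strictly more than 2 s worth of samples exceed the
threshold (1024 samples at 512 Hz, 256 at 128 Hz; exactly 1024 is *not*
a detection).  With two channels the per-sample maximum of the T7 and T8
envelopes is counted, so either electrode can carry the detection and
the rule is symmetric.  The online path is stricter: three consecutive
window-level detections on the 1 s grid are required before the cycle
may end (a falsely ending meal lowers the spoon — the hazard case); a
relaxed any-three rule is available.

## Metrics

Wolpaw's information transfer rate for `N` classes at accuracy `P` and
selection time `T` seconds:

    ITR = (60/T) · [log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))]  bit/min,

with `0·log 0 ≡ 0`.  `T` is the analysis epoch length (3 or 4 s): this
identification reproduces every per-subject ITR of the published
five-subject benchmark from its printed accuracies to ±0.01 bit/min,
which fixes the convention.  The bracket is a Kullback–Leibler
divergence, hence non-negative with a single zero at chance `P = 1/N`;
the signed value is returned unclamped.  Averages across subjects are
means of per-subject ITRs, *not* the ITR of the mean accuracy (the
formula is nonlinear in `P`; only the former reproduces the printed
condition averages).  The false-positive rate counts detections outside
designated task windows per minute of session.  Report rounding is
half-up at two decimals, matching tabulated values.

One benchmark inconsistency is reproduced as printed rather than
resolved: the five per-subject EMG false-positive rates average to 0.078
→ 0.08 times/min, while the running text of the source study quotes
0.09; this package reports 0.08 from the per-subject values.

## Meal-cycle controller

A pure-function finite-state machine over phases IDLE → STIMULATING →
SELECTING → FEEDING → CHEW_MONITOR → RETURNING → IDLE.  Blink events are
honoured only in IDLE (activation lock-out during meals); classifier
decisions are honoured only in STIMULATING and only after a minimum
stimulation time (default 4 s — the first full analysis window), at
which point `GRAB_FOOD(index)`, `FEED` and `LED_OFF` are issued and the
simulated robot motions advance the phase on clock ticks (grab 2 s, feed
2 s, return 1 s; all configurable).  CHEW_MONITOR exits on the third
consecutive chew-detected window or after 10 s without one, both via
`RETURN_SPOON`.  Out-of-order timestamps raise.  Robot actions are timed
log events only; no hardware interface is modelled.  `run_session`
replays a recording through the online contract (causal common filter,
4 s/1 s windows, detectors gated by phase) and is deterministic: the
same recording and configuration yield byte-identical JSON-lines logs.
Whether the LEDs keep flickering after the selection commits is not
fixed by the source material; the controller switches them off at
commit.

## Problem sizes and defaults

The bundled evaluation scales are chosen to characterize the algorithms
tightly at desk scale: full synthetic benchmark sessions are 30 cycles
(≈11.8 min at 512 Hz, seven channels); Monte-Carlo accuracy estimates
use 100 epochs per condition; the null distribution of S uses 200 noise
epochs; the blink screen is validated on an exhaustive 4 × 10 grid of
peak counts × spacings at a grid-aligned 500 Hz (every 0.1 s spacing an
exact sample count, keeping the open-interval boundary unambiguous).
Epoch placement inside the 5 s gaze window is start-aligned.

## Known limitations

Real-data effects the synthetic benchmark cannot expose: inter-subject
variability, non-stationary noise, eye-movement and muscle artifacts
outside the modelled bands, LED-reflection interference between
stimulus channels, volume-conducted cross-talk between FPz/T7/T8/O*
and food-dependent EMG morphology.  EDF/BDF recordings are read (via
`mne`); recordings are written as labelled CSV only.  Thresholds are
per-subject inputs by design — the package calibrates them from
designated segments but does not adapt them online.
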