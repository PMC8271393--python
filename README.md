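# mealbci

Signal processing for a hybrid brain–computer-interface meal-assist robot:
every control signal comes from the same scalp EEG montage, so a user who
cannot operate a joystick can run an entire meal cycle hands-free.

1. **Activation** — a voluntary *triple eye-blink* on the prefrontal
   channel (FPz) arms the system: three supra-threshold peaks with both
   inter-peak intervals strictly inside (0.3, 0.8) s, with a
   continuous-wavelet rescue pass for low-amplitude triples.
2. **Food selection** — five LEDs flicker at 7.4, 8.43, 9.8, 11.7 and
   13.7 Hz; the attended one is decoded from the occipital channels
   (O1/Oz/O2, re-referenced to Cz) with the multivariate synchronization
   index

   S = 1 + Σᵢ λ'ᵢ log λ'ᵢ / log P ∈ [0, 1],

   the eigenvalue entropy of the whitened joint correlation matrix of the
   EEG block and sine/cosine references at each candidate frequency.  No
   training session is needed; argmax over the five S values picks the food.
3. **Cycle end** — chewing EMG on the temporal channels (T7/T8), detected
   by a rectify–smooth–differentiate–rectify–smooth envelope exceeding a
   per-subject threshold for more than 2 s; three consecutive detections
   (or a 10 s timeout) return the spoon and re-arm the system.

The package provides the detectors, a synthetic session generator with
ground-truth event logs (so the full pipeline is testable without any
recordings), evaluation metrics (accuracy, Wolpaw information transfer
rate, false-positive rate), the meal-cycle finite-state machine with a
deterministic streaming replay, and a CLI.  It is aimed at BCI/assistive
robotics researchers and students who need a reproducible reference
implementation of this class of hybrid pipeline.

## Worked example

Generate a 30-cycle synthetic session (six trials of five cycles, the
protocol used for performance measurement) at high stimulus SNR, score it
offline, and compute the transfer rate:

```python
from mealbci import SessionProtocol, SynthesisParams, synth_session, itr_wolpaw
from mealbci.analysis import score_session

rec, truth = synth_session(SessionProtocol(), SynthesisParams(seed=5, ssvep_snr=4.0))
scores = score_session(rec, truth, epoch_s=4.0, n_channels=3)
r = scores.report
print("accuracy (%)     :", {k: round(v, 2) for k, v in r.accuracy_pct.items()})
print("ITR (bit/min)    :", round(r.itr_bit_per_min, 2))
print("FPR (times/min)  :", {k: round(v, 3) for k, v in r.fpr_per_min.items()})
print("ITR at 83.33 %/4 s:", round(itr_wolpaw(0.8333, 5, 4), 2))
```

prints

```
accuracy (%)     : {'eb': 100.0, 'ssvep': 100.0, 'emg': 100.0}
ITR (bit/min)    : 34.83
FPR (times/min)  : {'eb': 0.0, 'emg': 0.0}
ITR at 83.33 %/4 s: 20.08
```

All 30 blink triples, cued stimuli and chew bursts are recovered
(synthetic high-SNR conditions are deliberately easy); a perfect 5-class
selection every 4 s corresponds to 15·log₂5 ≈ 34.83 bit/min, and 83.33 %
accuracy — the average reported for real subjects under the 3-channel/4-s
condition — corresponds to 20.08 bit/min.  At the default moderate SNR
(`ssvep_snr=1`) classification lands in the 65–80 % range and grows with
epoch length, mirroring the behaviour seen on real recordings.

The same steps are available from the shell:

```sh
mealbci simulate --seed 5 --out session/
mealbci detect-eb --in session/recording.csv --threshold auto --out eb.tsv
mealbci classify-ssvep --in session/recording.csv --epoch 4
mealbci evaluate --pred eb.tsv --truth session/truth.tsv --report report.json
mealbci run-session --in session/recording.csv --config cfg.yaml --log run.jsonl
```

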