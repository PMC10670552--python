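# Methods

## Problem and pipeline

`ecgqual` classifies 10-second single-lead ECG segments as *acceptable* or
*unacceptable* for diagnostic use. The pipeline is:

1. **Ingest** — delimited-text columns (one per lead) or WAV; every lead from
   one file shares a `group_id` so splits can avoid leaking leads of the same
   source recording across partitions.
2. **Conform** — polyphase resampling to the working rate (500 Hz), cutting
   labeled regions into non-overlapping 10-s windows (regions shorter than one
   window, and any tail remainder, are discarded), then per-segment min-max
   normalization to [-1, 1].
3. **Spectrogram** — Hann-windowed short-time Fourier transform, magnitude of
   the one-sided spectrum. Defaults: frame length 256, frame step 128, no
   padding, so a 5000-sample segment becomes a 38 x 129 matrix
   (38 = floor((5000-256)/128)+1 frames, 129 = 256/2+1 bins). The defaults are
   the unique conventional power-of-two pair producing that input geometry.
4. **Classifier** — a CNN-LSTM (below) emitting the probability that a segment
   is acceptable. A segment is called acceptable iff p > threshold (default
   0.5); exact ties go to unacceptable, the conservative call for a screening
   tool.
5. **Evaluation** — confusion matrix with *acceptable* as the positive class
   (configurable, since sensitivity/specificity swap meaning under the other
   convention), reported as sensitivity, specificity, accuracy and F1 in
   percent to two decimals. Zero-denominator metrics are flagged undefined
   rather than reported as 0.

## Spectrogram conventions

- **Periodic Hann**: w[k] = 0.5 - 0.5 cos(2 pi k / N) with denominator N, so
  w[0] = 0 and w[N/2] = 1 for even N. The symmetric (N-1) variant is not used.
- **Magnitude, not power, no logarithm**: the classifier's input-normalization
  layer standardizes each frequency bin on training statistics, which removes
  the scale argument for a log transform; magnitude keeps the transform linear
  in the signal (an all-zero segment maps to an all-zero spectrogram).
- **No end padding**: the final partial frame is dropped, consistent with the
  frame-count formula above.

## Classifier

Topology, in order: input (38 frames x 129 bins) -> per-bin normalization
(mean/std adapted on the training set) -> [Conv1D -> ReLU -> max-pool ->
dropout] x 2 -> time-distributed dense -> LSTM -> dropout -> dense -> output
head. The 38-frame axis is the sequence dimension; frequency bins are the
per-step features. Defaults: conv blocks (64 filters, kernel 3) then
(128, kernel 3), pool 2, dropout 0.3, dense 64, LSTM 64 units, dense 32 —
all exposed in `ModelConfig` because only the input shape, optimizer, and
loss of the reference design are fixed; layer widths are configuration.

Two output heads are supported: the default 2-unit softmax with sparse
categorical cross-entropy, and a 1-unit sigmoid with binary cross-entropy.
The two pairings describe the same binary decision; the softmax form is the
default because it matches the configured loss, and the sigmoid form is kept
as a switch rather than silently merged — the source design names both and
they are not interchangeable as printed. Labels are encoded unacceptable = 0,
acceptable = 1.

Training: Adam at learning rate 1e-4 (the conventional 1e-3 converges too
aggressively on this task), batch 32, up to 50 epochs with early stopping on
validation loss (patience 10, best weights restored). The backend is a small
NumPy implementation (valid-mode 1-D convolution via strided windows, BPTT
through the LSTM, inverted dropout, float64 throughout) with every random
draw — weight init, shuffling, dropout masks — taken from seeded generators,
so identical seeds and data reproduce identical histories bit for bit on a
fixed BLAS. There is no GPU path; the largest training run in the test suite
(2000 segments, 50 epochs) takes well under a minute on one CPU core.

Model archives are a single file: a canonical JSON header (format, version,
config, history, array manifest) followed by the raw little-endian float64
weight blob. The encoding has no timestamps, so saving the same model twice
is byte-identical, and load/save round-trips reproduce predictions exactly.

## Corpus construction and splitting

- **Ratio construction** keeps all of the limiting class and uniformly
  subsamples the other to hit the requested acceptable fraction within one
  item, yielding the largest corpus achievable without duplication.
  Oversampling is deliberately absent: duplicating segments fabricates data
  and inflates apparent performance.
- **Splits** use largest-remainder rounding (ties resolved toward the test
  partition) over a seeded shuffle. `group_aware=True` assigns whole groups
  greedily, largest first, to the partition with the largest remaining
  deficit; it errors if a single group exceeds the training partition. The
  default is group-unaware (a plain random split), with the group-aware mode
  provided because random splits of multi-lead recordings are a known
  leakage risk.

## Synthetic data: what it emulates and what it does not

The generator exists so the full pipeline is testable without downloads; its
defaults define the test conditions used throughout.

- **Clean morphology**: five Gaussian bumps per beat (P, Q, R, S, T) with
  fixed timings/amplitudes as fractions of the RR interval (R amplitude 1),
  RR jitter uniform within +-5%, heart rate drawn uniformly from 50–100 bpm
  per record. Adequate for a quality classifier; it is not an arrhythmia or
  vectorcardiographic simulator.
- **Contamination palette**: baseline wander (sinusoid, 0.15–0.5 Hz),
  powerline (pure 50/60 Hz tone), EMG (white noise band-passed 20–120 Hz),
  electrode motion (random soft steps and exponentially decaying spikes), and
  a composite Dirichlet-weighted mixture. Noise is scaled so the realized
  SNR equals the target exactly (tested to +-0.5 dB over [-10, 30] dB).
- **Class boundary**: acceptable records are clean (probability 0.5) or
  contaminated at 15 dB; unacceptable records are contaminated at -5 dB.
  These sit inside the nominal acceptable >= 10 dB / unacceptable <= 0 dB
  bands with margin and realize a 20 dB class gap. The 20 dB default makes
  the classes nearly separable, which is intentional: the end-to-end tests
  verify the *pipeline* (training converges, metrics computed correctly,
  ratios honored), not robustness to borderline real-world noise. Passing
  them says nothing about performance on clinical recordings, where noise is
  nonstationary and label boundaries are soft.

## The class-ratio experiment

`ecgqual experiment` trains two models from the same record pools — one on an
85:15 acceptable:unacceptable corpus, one on 50:50 — and evaluates both on a
shared balanced test set, emitting one report row per configuration. Only the
experiment *design* is reproduced on synthetic data; the direction and size of
the F1 difference between the two training ratios depends on the data source
and is not asserted. Every run writes its resolved configuration, corpus
manifests, model archives and report next to each other, sufficient to re-run
bit-identically.

## Numerical and scale choices

- Sizes in the test suite: the end-to-end check trains on 2000 segments
  (90:10 train/validation) and evaluates 400 held-out segments; the ratio
  experiment and CLI tests run at 120–300 segments with 6–12 epochs. These
  are the package's own desk-scale choices — large enough that held-out F1
  at the default gap exceeds 95%, small enough to keep the suite around a
  minute.
- The SNR-gap monotonicity check (gaps 5/10/20 dB, fixed seeds) asserts
  non-decreasing held-out F1 with a 2-percentage-point slack: F1 on a few
  hundred segments is quantized at ~0.5 points per segment, so a strict
  assertion would flag single-segment jitter rather than a real violation.
- Resampling uses rational polyphase filtering; output length is forced to
  round(n x target/fs) (trim or edge-pad by at most one sample) so duration
  bookkeeping stays exact.
- Min-max normalization maps constant segments to all zeros instead of
  dividing by zero; the corresponding spectrogram is all zeros.

## Known limitations

- Synthetic noise is stationary within each family and additive; real
  electrode artifacts are neither. External validation on clinical corpora
  (optional loaders for public datasets) is out of scope of the test suite.
- Determinism is guaranteed within one NumPy/BLAS build; cross-platform
  bit-identity of trained weights is best-effort.
- Only single-channel WAV/text ingestion is supported per lead; vendor ECG
  formats (SCP-ECG, HL7 aECG, DICOM) are not parsed.
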