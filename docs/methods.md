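# Methods

This note documents the models and procedures implemented in
`snorescreen`, the parameters that matter, the numerical choices that were
genuinely open, and what the synthetic benchmarks do and do not show.

## Problem setting

Obstructive sleep apnea–hypopnea syndrome (OSAHS) screening from nocturnal
audio proceeds in two stages: (1) locate the onset and offset of every
snore event in a long ambient-microphone recording (endpoint detection),
and (2) classify each extracted snore clip as normal or OSAHS-related.
`snorescreen` implements both stages plus a seeded synthetic-audio module
that makes the whole pipeline testable without clinical recordings.

## Preprocessing

Recordings are mono float signals. Denoising uses magnitude spectral
subtraction with zero clamping:

    |X̂(k, l)| = max(|Y(k, l)| − |N̂(k)|, 0)

with the noisy phase reused and the waveform rebuilt by overlap-add with
window-sum normalization (an exact inverse for unmodified spectra; the
periodic Hamming window is strictly positive). The STFT shares the
detector's framing — 25 ms frames, 10 ms hop, Hamming window — with the
FFT length rounded to the next power of two.

**Noise spectrum N̂.** Estimated per 2-minute analysis window as the mean
magnitude spectrum of the lowest-energy half of the frames
(`noise_fraction = 0.5`). The lowest-energy *decile* was considered and
rejected: selecting only the quietest frames biases the estimate low, and
the residual background left after subtraction then fluctuates enough to
trigger false detections on event-free recordings. The median-energy half
estimates the stationary background nearly unbiasedly while still
excluding snore frames, which occupy roughly 10% of a typical window. A
`leading_seconds` method is available for recordings known to start in
silence.

## Frame features

Every 25 ms frame is scored with four features: short-time energy
E = Σ x², spectral entropy H = −Σ P log(P + ε) over the normalized
one-sided power spectrum (natural log, ε = 1e−10; bounds 0 ≤ H ≤ log K
enforced by clipping, since the ε inside the logarithm otherwise yields a
slightly negative value for a one-bin spectrum), zero-crossing rate with
sgn(0) = +1, and the magnitude-weighted spectral centroid in Hz over the
one-sided spectrum. An all-zero frame takes H = log K (maximally
uncertain), C = 0, and is flagged invalid; invalid frames never vote.

Snoring frames, relative to ambient background, show elevated energy, a
compact spectrum (low H), a smooth waveform (low ZCR) and energy
concentrated at low-to-mid frequencies (low C). These four directions
drive the detector.

## Endpoint detection (AMFF-ED)

The recording is processed in 2-minute windows (window length = step, so
windows tile the recording). Within each window, per-feature thresholds
are derived from that window's own feature distribution, every frame is
voted on, frame masks are concatenated across windows, and two
post-processing rules run globally: segments separated by less than
0.3 s are merged, then segments shorter than 0.3 s are discarded
(inclusive boundaries, with a 1e−12 s guard against float rounding).
Events straddling a window boundary survive because post-processing is
global. Segment times always refer to the original timeline.

**Thresholds (default `discriminative` convention).**

* `T_E = 5 × median(E_raw)` — an SNR-style floor 7 dB above the window's
  median frame energy. The median is taken over the *pre-subtraction*
  energies when denoising is enabled, because subtraction rescales the
  background arbitrarily (its residual median is an artifact of the
  cancellation depth, not a noise level). A percentile-based energy gate
  was rejected because it presumes a fixed snore duty cycle: an upper
  decile misses snores when interference is abundant, and a lower decile
  passes nearly all background.
* `T_H = μ_H − 0.5 σ_H`, `T_ZCR = μ_ZCR − 0.5 σ_ZCR` — half a (population)
  standard deviation below the window mean, on the snore side of each
  distribution.
* `T_C` = lower quartile of the centroid distribution.

An `as_printed` convention (energy at the lower decile with the same
inclusive comparisons, spread offsets *added* to the means, centroid at
the upper quartile) is retained for comparison. Measured on synthetic
nights, those gates individually pass ~70–90% of background frames and
jointly mark most of the recording, so the discriminative convention is
the default.

**Voting.** A frame's vote count is

    S = I(E ≥ T_E) + I(H ≤ T_H) + I(ZCR ≤ T_ZCR) + I(C ≤ T_C)

and a frame is a snore candidate when `S ≥ 3` **and** the energy
criterion itself holds (`energy_mandatory`, default on). The energy
requirement exists because the three spectral features are strongly
mutually correlated on low-frequency ambient noise (a hum-like moment is
simultaneously low-entropy, low-ZCR and low-centroid), so without it they
can outvote the energy cue and mark sustained stretches of quiet
background. Inclusive comparisons at the boundary throughout.

**Raw-run floor.** Candidate runs shorter than `min_raw_run_s = 0.1 s`
are dropped *before* gap merging. Scattered single-frame marks otherwise
chain through the 0.3 s merge rule: with a few percent of isolated marks,
the typical gap between them is below 0.3 s and merging welds them into
long spurious segments. 0.1 s is well below any plausible snore event and
well above feature flicker.

**Baseline detector.** The conventional short-time-energy + ZCR
comparison detector is expressed in the same machinery
(`BASELINE_ENERGY_ZCR`): features {E, ZCR} with either cue sufficient
(vote threshold 1), matching classical dual-cue endpoint detection in
which energy is the primary cue and the ZCR extends boundaries through
low-energy stretches. Its characteristic failures — boundary drift and
background sounds marked as snoring — emerge on the synthetic benchmark.

**Invariances.** Scaling the waveform by a positive constant leaves the
frame mask unchanged (energy thresholds scale quadratically with the
signal; the other features are scale-free). Window statistics are
strictly per-window: content in one 2-minute window never influences
another window's mask.

## Mel spectrograms

Snore clips are mapped to 128×128 log-Mel images: STFT power
(n_fft = 2048 at 16 kHz, 10 ms hop, Hamming), a 128-filter triangular Mel
bank, log(1 + S) compression, and linear interpolation of the time axis
to 128 columns (clips shorter than 128 hops are zero-padded and flagged
instead). Two Mel mappings are provided, m(f) = 2595 log10(1 + f/700)
(`htk_standard`, the default and the field's convention) and a variant
with denominator 100 (`paper`); both are monotone and only the filter
edge placement differs. On coarse FFT grids a narrow low-frequency filter
can cover no bin; such a filter is given unit weight at its nearest bin
so no row is all-zero.

## Classifier (ERBG-Net)

A ResNet18 backbone (1-channel stem, no pretraining) with efficient
channel attention (ECA) inserted after the second convolution of each
residual block in the conv4_x and conv5_x stages, before the residual
addition — the standard ECA placement inside a block. ECA computes a
per-channel global average, convolves across the channel axis with an
adaptive odd kernel

    k = | log2(C)/γ + b |_odd ,  γ = 2, b = 1 (the original ECA defaults)

(nearest integer, ties to even per numpy, bumped to the next odd; floor
at 1), applies a sigmoid and rescales the channels. For C = 256, k = 5;
for C = 512, k = 7 — attention adds only 24 parameters to ResNet18.

The final feature map (C × H′ × W′, with W′ the spectrogram's time axis)
is unfolded along W′ into a sequence of C·H′-dimensional vectors and fed
to a single-layer bidirectional GRU (hidden size 128). The GRU update is

    z = σ(x Wxz + h Whz + bz),  r = σ(x Wxr + h Whr + br)
    c = tanh(x Wxc + r ⊙ (h Whc) + bc),  h′ = (1 − z) ⊙ h + z ⊙ c

with the reset gate applied to the hidden-to-candidate product. The
concatenated last forward and last backward states pass through one
linear layer to the class logits; hidden states are tanh-bounded in
(−1, 1). The ablation variants — plain ResNet18, ResNet18+BiGRU,
ECA-ResNet18, ECA-ResNet34+BiGRU — are reachable purely through
`ModelConfig`.

**Compute core.** No deep-learning framework is part of the runtime; the
network runs on an in-package reverse-mode autodiff core over numpy with
im2col convolution, batch normalization and max pooling backward passes
written explicitly. Gradients were verified against central finite
differences in float64 at 1e−4 relative tolerance through the full
architecture. Parameters are float32; on a single CPU thread training is
bit-reproducible for a fixed seed.

**Training.** Stratified 6:2:2 train/validation/test split, Adam
(lr 1e−3, β = 0.9/0.999), cross-entropy, batch size 8, early stopping on
validation loss (patience 10), best-validation checkpoint returned, and
an optional `stop_at_train_acc` convergence exit. All randomness (init,
split, shuffling) derives from the config seed. These training
hyperparameters are package choices; they are deliberately ordinary.

## Synthetic data

`synth_recording` renders nights at 16 kHz (all detector features live
below 8 kHz; the rate is configurable): pink-noise background at a
reference RMS of 0.01, mains hum (50/100/150 Hz) at a preset-dependent
level, snore events as amplitude-modulated glottal pulse trains
(f0 ∈ 60–180 Hz, second-order band-pass resonance over 100–800 Hz, a
15%/25% raised-cosine attack/decay envelope and a small breathy noise
component) scaled to the requested SNR (default 10 dB) and placed by a
renewal process (default 6 events/min, durations 0.6–1.5 s, ≥ 1 s gaps),
plus optional broadband transients (doors, call bells) and speech-band
chatter (300–3000 Hz, 4 Hz syllabic modulation, talk/pause gating) at
+5 dB over the background. Presets: `original` (hum −6 dB,
2 transients/min), `denoised` (hum −20 dB, no transients), `speech`
(`original` plus chatter). Ground-truth intervals are returned exactly;
events are ≥ 0.3 s with ≥ 0.3 s gaps, so a perfect detector can score
100%.

`synth_spectrogram_dataset` builds balanced two-class clip sets: regular
low-band harmonic bursts (normal surrogate) versus longer, irregular,
band-shifted bursts with silence gaps (OSAHS surrogate). In `easy` mode
the class bands (100–500 vs 300–900 Hz) make a single band-energy-ratio
threshold sufficient for perfect separation; `hard` mode overlaps them.

**What passing these benchmarks shows — and does not.** The synthetic
nights realize exactly the acoustic premises the detector assumes, with
stationary backgrounds and stylized interference; they contain no
breathing sounds, bed noise, room reverberation, inter-patient
variability or annotation ambiguity. Results on them validate the
algorithmic machinery (thresholding, voting, post-processing, training
dynamics), not clinical performance. The spectrogram surrogates likewise
test that the classifier can learn spectro-temporal class structure, not
that it distinguishes real OSAHS snoring.

## Benchmark problem sizes

The packaged studies use 10-minute nights (≈ 60 events each) across 20
seeds for detection and 40-clip datasets for classifier smoke training,
sizes at which the full suite runs in minutes on one CPU while the
binomial noise on the reported rates stays at the percent level. The
acceptance script uses 10 nights per condition.

## Known limitations

* Hard spectral subtraction produces sparse residual spectra ("musical
  noise"); after denoising, the background's spectral entropy drops below
  the snores' and the entropy cue inverts. The detector tolerates this
  (3-of-4 voting with mandatory energy), but entropy contributes little
  on denoised signals.
* Eq.-style plain zero-clamping subtraction is kept deliberately; no
  over-subtraction factor or spectral floor is applied.
* The endpoint accuracy metric is precision-style (correct/total
  detections); recall is reported alongside since precision alone hides
  misses. Matching is greedy one-to-one by descending IoU with a 0.3
  threshold — a standard, explicit choice.
* Single-layer BiGRU only; multi-layer stacks are out of scope.
* Offline processing only; no streaming guarantees.
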