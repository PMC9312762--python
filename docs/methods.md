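# Methods

## Problem and model

Silent speech produces articulatory muscle activity but no sound. Given
5-channel facial surface EMG recorded at 2000 Hz in *silent* mode, the
package reconstructs the audible speech of the same sentence as it would
have been spoken, using *vocal*-mode recordings (simultaneous EMG + 16 kHz
audio) as training supervision. Mandarin is the target language, so the
model must carry lexical tone as well as segmental content.

The central difficulty is length: an N-frame silent recording corresponds
to an M-frame vocal realization with N ≠ M and no annotated correspondence.
The pipeline resolves this with explicit durations:

1. **Duration extraction.** Silent EMG features X₁:N are aligned to vocal
   EMG features x₁:M by dynamic time warping with cost
   ‖X[i] − x[j]‖₂ (steps →, ↓, ↘; ties prefer the diagonal). The path is
   collapsed to a frame assignment A₁:M (first source frame visiting each
   target column), and durations d[i] = #{j : A[j] = i}, so Σd = M.
   Source frames crossed only by vertical steps get duration 0.
   A *refined* cost adds λ_align · ‖Ŷ*[i] − Y[j]‖₂, where Ŷ*₁:N is the
   model's own mel prediction bypassing the length regulator and Y₁:M the
   true mel; λ_align = 10.
2. **Sequence model.** Encoder: linear + ReLU projection of 355-dim EMG
   features to the model width, additive sinusoidal positional encoding
   with a learned scale, then a stack of feed-forward-transformer (FFT)
   blocks (multi-head self-attention + two 1-D convolutions, residual +
   layer norm). A **length regulator** repeats encoder frame i exactly
   d[i] times. Decoder: FFT blocks, a linear projection to 80 mel bands
   (Ŷ⁻), and a 5-layer convolutional postnet whose output is added as a
   residual (Ŷ⁺ = Ŷ⁻ + residual). A 2-layer convolutional **duration
   predictor** with a ReLU-clamped linear head estimates d̂ from the
   encoder output for inference, where output length is Σ round(d̂)
   (at least one frame is forced).
3. **Joint optimization.** Two linear heads read the regulated hidden
   states (by default before the decoder): a frame-level toneme
   classifier over the inventory plus a silence class, and a vocal-EMG
   reconstruction head. Both train jointly and are discarded at inference.

The joint loss is

    L = MAE(Ŷ⁺, Y) + MAE(Ŷ⁻, Y) + MSE(d̂, d)
        + λ_tm · CE(t̂m, tm) + λ_recons · MSE(x̂, x)

with λ_tm = λ_recons = 0.5. The learning rate follows the Noam schedule
lr = d_model^−0.5 · min(step^−0.5, step · step_w^−1.5) (peak at
step = step_w). Ground-truth durations are computed once from the plain
EMG DTW before training, used for the first four epochs, and refreshed
every fifth epoch with the refined cost using the current model's
unregulated predictions. Checkpoint selection uses validation total loss;
a scorer hook accepts any external criterion (e.g. an ASR-based character
error rate) instead.

## Front end

* EMG conditioning: 4th-order Butterworth bandpass 4–400 Hz and an IIR
  notch cascade at 50, 100, …, 400 Hz (Q = 30), both applied zero-phase
  (forward–backward); this is an offline pipeline, so causal filtering is
  not attempted.
* EMG features per 64 ms frame (16 ms hop): per channel, six time-domain
  descriptors — with w the double 9-point running mean (low-frequency
  part), h = signal − w the high-frequency residual and r = |h|: mean(w),
  power(w), mean(r), power(r), the sign-change count of h, and mean(|raw|)
  (power = mean of squares; the zero-crossing count is taken on the signed
  residual because a rectified signal has no sign changes) — plus 65
  one-sided STFT magnitudes (128-sample Hann window). Total
  5 × (6 + 65) = 355 per frame.
* Audio features: 80-band log₁₀ mel spectrogram over 80–7600 Hz
  (1024-sample window, 256-sample hop at 16 kHz, magnitude floored at
  1e-10). Mel filters are triangles equally spaced on the HTK mel scale,
  area-normalized.
* Framing is center-aligned for both streams (frame i centered at
  i · 16 ms, reflect padding, frame count = ceil(T / hop)), so EMG and mel
  sequences are index-aligned.
* Normalization: per-corpus z-score of EMG features (silent and vocal
  pooled) and of mel targets; statistics come from the training split and
  are stored in checkpoints. Alignment costs are computed on normalized
  features so λ_align = 10 is meaningful across scales.

## Tonemes

Tone-numbered Pinyin syllables split into onset / nucleus / coda with the
tone digit attached to the nucleus (maximal vowel-letter run, glides
included): `teng2 → t e2 ng`, `guang1 → g ua1 ng`. The neutral tone is
encoded as tone 5. The inventory is the sorted, de-duplicated toneme set
of the corpus plus `sil` (id 0). Frame labels come from interval
annotations (Praat TextGrid long/short form, or two-column label files);
a frame takes the label of the interval covering its center, half-open on
the right, `sil` when uncovered. Edge syllables such as syllabic "er" are
not special-cased.

## Synthesis

Griffin-Lim is the self-contained mel-to-waveform path: the log-mel is
inverted through a non-negative clamped pseudo-inverse of the filterbank,
and 60 iterations of STFT-consistency projection recover phase with the
same 1024/256 analysis parameters; output length is exactly M · 256
samples. The initial phase is seeded, so synthesis is deterministic. An
adapter slot accepts an externally trained neural vocoder checkpoint and
raises a clear error (naming the fallback) when none is present; training
such a vocoder is out of scope.

## Evaluation

* CER = Levenshtein(ref, hyp) / len(ref), unbounded above; edit distance
  is delegated to edlib. Transcripts are accepted as input — no speech
  recognizer is bundled.
* MCD: 13 mel-cepstral coefficients (DCT-II of the log-mel, c0 excluded),
  DTW-aligned, mean of (10/ln 10)·√2·‖Δc‖₂ over path pairs.
* STOI: the standard short-time objective intelligibility measure,
  implemented in-repo (10 kHz resampling, removal of frames more than
  40 dB below the loudest, 15 one-third-octave bands from 150 Hz, 384 ms
  segments, −15 dB signal-to-distortion clipping, mean band-envelope
  correlation). On this package's synthetic audio, which contains exact
  digital silence between tonemes, the clipping step lets even white noise
  reach ≈ 0.6; STOI separates *degrees* of degradation here rather than
  hitting the very low absolute scores typical of real speech-vs-noise
  comparisons.
* Toneme confusion: frames whose true label is silence are dropped;
  consonant, vowel and tone matrices are column-normalized to percentages
  of each true label's frame count (predictions outside the class set fall
  into an "other" row, so columns still sum to 100%). Display copies mask
  entries below 0.5%. The tone matrix uses only frames whose true label is
  a vowel. Tone accuracy is reported both macro- (mean of the tone-matrix
  diagonal) and micro-averaged.

## Synthetic data

The generator emulates the paired corpus structure: a vocal-mode take
(EMG + audio, sample-synchronized) and a silent-mode take related to it by
an unknown monotone time warp.

* Each toneme has a stable template: per-channel gains (onsets biased to
  lip channels, nuclei to jaw/chin, codas to the submental channel) and a
  per-channel passband inside 20–380 Hz (width 40–120 Hz). A segment's
  vocal EMG is per-channel band-limited noise with that template, under a
  double-peaked contraction envelope (the mid-gesture amplitude dip is a
  sharp, warp-covariant landmark), a deterministic onset-to-offset gain
  drift per channel, and a slow common amplitude modulation (low-passed
  at 12 Hz, depth 0.25) emulating recruitment fluctuation. A low-level
  broadband baseline (resting muscle tone, 0.05 of unit burst scale)
  spans the whole recording. These textures make the time warp
  identifiable to the aligner inside long steady gestures and across
  silences, where a flat-envelope design leaves DTW locally ambiguous.
  Broadband noise carriers (rather than tonal or frequency-swept ones)
  are essential: resampling a waveform scales its spectrum, so
  frequency-localized carriers would systematically misalign the warp.
  Syllable sequences avoid immediate repeats — adjacent identical
  gestures make the alignment inherently ambiguous, and phonetically
  balanced prompt sets avoid them anyway. The default inventory is a
  small pilot set of 12 tone-numbered syllables (18 tonemes) covering
  all five tones and varied onsets, nuclei and a nasal coda.
* Audio: vowel nuclei are 8-harmonic complexes whose f0 contour encodes
  the tone (level 230 Hz; rise 170→270; dip 220→150→240; fall 290→160;
  neutral level 200 and short); onsets are 2–6 kHz noise bursts; nasal
  codas a low hum. A slope heuristic on the f0 contour recovers the tone
  class, confirming the corpus carries learnable tone signal.
* The silent take resamples the vocal EMG through a piecewise-linear
  monotone warp (3 segments, slopes drawn from [0.7, 1.4]), scaled to 0.6
  amplitude (silent articulation is weaker), plus independent measurement
  noise at 30 dB SNR on both takes (`noise_snr_db=None` gives noise-free
  pairs). All segment durations are whole multiples of the 16 ms hop, so
  EMG-feature and mel frame counts agree exactly and the warp converts to
  an exact integer duration sequence (vocal frame j is assigned the
  silent frame whose center is nearest the inverse-warped time).
* Corpora split 8:1:1 into train/val/test deterministically by seed.

What the generator does **not** model: EMG biophysics (motor-unit shapes,
electrode crosstalk, impedance drift), speaker identity, coarticulation,
prosody beyond per-syllable tone, or background acoustics. Passing tests
therefore demonstrate that the machinery (alignment, length regulation,
joint training, metrics) works end to end on data with the right
structure — not that the model reaches any particular fidelity on real
silent-speech recordings.

## Numerical and design choices

* Positional encoding is added (with a learned scalar scale) rather than
  concatenated, keeping the hidden width equal to the attention dimension.
* Duration rounding at inference: round-half-away-from-zero after the
  ReLU clamp; if everything rounds to zero the largest-duration frame is
  forced to 1 so synthesis always emits audio.
* No stop-gradient between encoder and duration predictor by default
  (configurable).
* DTW tie-breaks prefer diagonal, then source-advancing, then
  target-advancing steps, making alignments deterministic. The
  path-to-assignment rule is first-visit (smallest source index per
  target column), which keeps A non-decreasing and Σd = M exact. Zero
  durations are allowed and the duration predictor trains on raw counts
  including zeros.
* Distances in alignment costs are Euclidean over the feature vector
  (an L1 option exists).
* Gradient clipping at global norm 1.0; Adam with β = (0.9, 0.98),
  ε = 1e-9. Training processes utterances singly and accumulates
  gradients over `batch_size` (8) utterances per optimizer step — the
  same summed-gradient update as a padded batch, with no padding or
  masking needed in the loss.
* Refresh epochs are 5, 10, 15, …; epochs 1–4 always use the initial
  plain-cost durations; all other epochs reuse the cache.
* Default full-size hyper-parameters: model width 384, 4 attention heads,
  6 + 6 FFT layers with 1536 convolution channels, postnet 5 × 256
  (kernel 5), duration predictor 2 × 384 (kernel 3), dropout 0.1
  (postnet 0.5), warmup 4000 steps. Tests and the acceptance script use a
  scaled-down study: width 32, 2 + 2 layers, 50-utterance corpora,
  warmup 200 (a 4000-step warmup would never complete in a few hundred
  steps), 60–800 epochs depending on the experiment. The paper-mode loss
  weights (λ_align = 10, λ_tm = λ_recons = 0.5) are kept everywhere.
* The model and its training loop run on a small reverse-mode autodiff
  core written on numpy (`ssrnet._autograd`): broadcasting arithmetic,
  batched matmul, softmax, layer norm, 1-D convolution, row repetition
  (the length regulator's gradient sums over repeats), dropout and fused
  softmax cross-entropy, each verified against central differences.

## Known limitations

* Real-time/streaming operation is out of scope (zero-phase filters,
  whole-utterance attention).
* The adaptive mains-notch is a fixed-frequency cascade; center-frequency
  tracking is not implemented.
* Griffin-Lim audio is intelligible but phase-artifacted; a neural
  vocoder checkpoint is needed for natural-sounding output.
* Multi-alignment averaging across repeated silent takes of the same
  sentence is not implemented (each take aligns independently).
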