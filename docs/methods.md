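# Methods

`bcgmixer` implements an end-to-end screening pipeline that classifies
subjects as hypertensive (HPT) or normotensive (NRT) from single-channel
ballistocardiograph (BCG) recordings: robust amplitude normalization, IIR
bandpass filtering, fixed-window segmentation, time-frequency imaging, and a
patch-based convolutional classifier evaluated with k-fold cross-validation.
This note records the model, the parameters that matter, the numerical
choices, and what the synthetic cohort does and does not establish.

## Signal model and synthetic cohort

A BCG records body micro-movements driven by cardiac ejection, sampled here at
fs = 100 Hz.  The generator emulates the statistical structure the pipeline
relies on, not cardiac mechanics:

    x(t) = s · b(t) · [1 + m sin(2π f_r t)] + A_w sin(2π f_w t) + ε(t)

* **Beat train** `b(t)`: one Gaussian-modulated cosine per heartbeat
  (center 5 Hz, envelope σ = 0.15 s), a stand-in for the BCG IJK complex that
  places beat energy inside the 1–50 Hz passband.  Beat onsets form a jittered
  renewal process: intervals are `60/HR · (1 + 0.05 ζ)`, ζ ~ N(0,1), emulating
  heart-rate variability at a typical ~5 % interval CV.
* **Heart rate** is drawn per subject from the class distributions
  HPT ~ N(77.1, 9.2²) BPM and NRT ~ N(73.6, 8.3²) BPM (clipped to 40–120).
  These distributions overlap heavily — class membership is *not* decidable
  from rate alone, which is the realistic regime.
* **Amplitude scale** `s` is log-normal (σ = 0.5, median 1): body-weight
  differences scale BCG amplitude and are what normalization must remove.
* **Baseline wander**: a 0.2 Hz sinusoid (amplitude 0.5) below the 1 Hz
  passband edge, plus a 0.25 Hz respiration-like amplitude modulation
  (depth 0.2); together they exercise the high-pass side of the filter.
* **Noise** ε: white Gaussian (σ = 0.1); an optional mains tone and an
  optional 16-bit full-range quantization emulate the acquisition chain
  (both off by default).

**Easy mode** is a deliberately separable variant for end-to-end checks: the
two classes' beat wavelets sit at disjoint center frequencies (HPT 4 Hz,
NRT 10 Hz) and their heart-rate distributions do not overlap.  Any correctly
wired pipeline must be able to separate easy-mode classes; failure localizes a
defect in the pipeline rather than in the data.  Passing on easy mode says
nothing about accuracy on real recordings — realistic-mode synthetic data is
itself only a structural emulation (no real IJK morphology, no motion
artifacts, no apnea/arrhythmia epochs, stationary noise).

Cohorts are reproducible from one master seed (per-subject generators are
spawned from it), and the default cohort composition is 61 HPT + 67 NRT
subjects of ≥ 50 minutes.

## Preprocessing

**MAD z-score normalization.**  Each whole recording is centered on its median
and divided by its median absolute deviation, `MAD = median |x − median x|`
(no 1.4826 consistency constant), so the output has median 0 and MAD exactly 1.
The MAD is preferred over the standard deviation because BCG amplitude
distributions are heavy-tailed.  Constant signals are rejected as degenerate.
Normalization precedes filtering and is computed per recording (after the
50-minute trim), never per segment.

**Bandpass filter.**  The canonical pipeline applies a fixed transfer
function, stated as a 4th-order Chebyshev type II bandpass (1–50 Hz at
fs = 100 Hz):

    b = (0.028, 0.053, 0.071, 0.053, 0.028)
    a = (1, −2.026, 2.148, −1.159, 0.279)

These constants are carried verbatim as the reproducible contract.  They are
internally inconsistent with the nominal design: their DC gain is
Σb/Σa ≈ 0.963 (a true 1 Hz high-pass edge would suppress DC), and a 50 Hz
upper edge coincides with Nyquist.  No freshly designed Chebyshev II filter at
those specifications reproduces them, so the package treats the constants as
canonical and documents the discrepancy; a configurable designer
(`design_cheby2_bandpass`, stable and verified against its own stopband spec)
exists for users who want a self-consistent filter instead.  Filtering is
single-pass causal (`lfilter`, zero initial state); a `zero_phase` flag
switches to forward–backward filtering.

**Segmentation.**  Non-overlapping 30-s windows (3,000 samples); the trailing
remainder is discarded (floor division), so 50 minutes yield exactly 100
segments per subject and the 61 + 67 cohort yields 12,800 segments
(6,100 HPT / 6,700 NRT).

## Spectrogram imaging

Each segment becomes an RGB heat map:

1. **STFT**: symmetric Hann window of 128 samples, overlap 120 (ratio 15/16,
   hop 8), FFT length 128, one-sided power spectrum (65 rows × 360 frames for
   a 3,000-sample segment; frame f covers samples [8f, 8f + 128)).
2. **dB conversion**: `10 log10(power)` with a −120 dB floor for zeros.
3. **Thresholding**: every value below (per-segment max + threshold_db) is
   clamped to that floor; default **threshold_db = −40 dB**.  The source
   protocol states that low-amplitude points are eliminated but not the value
   used; this is the single most consequential free parameter of the imaging
   stage and is exposed prominently in the configuration.
4. **Rendering**: min–max normalization over the clamped range (hence
   invariant to additive dB offsets), a perceptually ordered colormap
   (viridis by default; the original colormap is unstated), low frequencies at
   the bottom, time left→right, no axes or margins; rasterized at 420 × 560
   and bilinearly resized to 224 × 224 × 3 with 8-bit channels.

The window variant (symmetric vs periodic), dB scale and interpolation method
are all unstated upstream; the defaults here are the common conventions of the
original tooling and each is configurable.

## ConvMixer classifier

Patch-token architecture operating at constant resolution:

* **Stem**: 5 × 5 convolution with stride 5 (valid padding) to h = 32
  channels — 224 × 224 × 3 → 32 × 44 × 44 — then GELU and batch normalization.
* **Mixer blocks** (depth 7): spatial mixing by a depthwise 5 × 5 convolution
  (same padding, one filter per channel) wrapped in a residual connection —
  `u = x + BN(GELU(DWConv(x)))` — followed by channel mixing with a pointwise
  1 × 1 convolution, GELU and BN.  The source prose is ambiguous about whether
  the residual add precedes the activation; a `prose_residual` flag provides
  the literal-prose ordering (`BN(GELU(DWConv(x) + x))`).  The depthwise
  kernel size is unstated upstream; 5 × 5 (the only kernel size mentioned
  anywhere) is the default and a flagged deviation risk.
* **Head**: global average pooling to an h-vector, a linear map to 2 logits,
  softmax.

Default parameter count: 2,432 + 64 (stem) + 7 × 2,016 (blocks) + 66 (head)
= **16,674** trainable scalars.

The implementation is pure NumPy with hand-written backpropagation, verified
against finite differences layer-by-layer and end-to-end.  Exact (erf-based)
GELU is used, not the tanh approximation.  Layers keep persistent, shape-keyed
scratch buffers that are overwritten on every call; on a single core this
buffer reuse — rather than reallocating tens of megabytes per operation —
dominates training throughput.

**Training** uses SGD with momentum 0.9 ('sgdm'; momentum unstated upstream,
0.9 is its common default), minibatch 64, 7 epochs, initial learning rate
0.001, cross-entropy loss, no augmentation, weight decay, schedule or early
stopping (none are specified).  Inputs are per-channel zero-centered with
training-split means; 10 % of each training split is held out to log a
validation curve.  Weights are Glorot-uniform; everything is deterministic
given `random_state`.

**Batch-norm finalization.**  After the last update, batch-norm moments are
recomputed as *population statistics* over the full training split (one extra
forward pass), mirroring the behavior of the trainer the original experiments
used.  This matters enormously at small step counts: with only a handful of
minibatches, an exponential moving average (momentum 0.1) never leaves its
initialization, and inference-mode predictions are garbage even when
training-mode accuracy is perfect.

## Evaluation protocol

K-fold cross-validation (k = 10 by default): a random partition into k folds,
one fold tested per rotation, a fresh model trained each time.  Reported
tables are the *arithmetic mean of per-fold metrics*; the cumulative confusion
matrix is the element-wise sum over fold test confusions.  Accuracy,
precision, recall and F1 are reported in percent, per class (HPT positive) and
macro-averaged; the macro values are the headline numbers.  Zero-denominator
ratios are reported as 0 with a `degenerate` flag.

The default split is **image-level** — segments of one subject can appear in
both train and test — because that is the protocol the published results use.
This leaks subject identity (amplitude scale, beat morphology) and inflates
accuracy; a **subject-level** grouping that never splits a subject across
folds is provided and recommended for honest generalization claims.  The
difference is directly measurable on synthetic cohorts, whose subjects carry
individual amplitude scales by construction.

## Problem sizes used by the test suite

The full published experiments (12,800 images for the equal-count protocol;
~133k for the full-data protocol; headline accuracies 93.84 % / 97.69 %)
require the original figshare recordings and long training runs; they are
documented benchmarks, not tests.  The suite instead checks:

* the **accounting contract** at full cohort size (128 synthetic subjects,
  50 min each → exactly 12,800 images, 6,100/6,700 by class), where only
  counting is asserted;
* the **learning contract** at desk scale: 16 easy-mode subjects, 5 min each
  (160 images), 5-fold CV with the default architecture.  At this scale a
  fold sees ~14 minibatches instead of the ~11,000 of the published protocol,
  so the test uses a learning rate of 0.05 — the standard compensation when
  the step budget shrinks by two orders of magnitude — while the packaged
  default remains 0.001.  The criterion is ≥ 90 % mean accuracy, which the
  separable-by-construction classes must support.

## Known limitations

* The synthetic beat waveform is not physiological; no claim about real-BCG
  accuracy follows from synthetic results.
* The canonical filter constants are reproduced verbatim despite their
  internal inconsistency with the stated band edges (above).
* The spectrogram threshold, depthwise kernel, BN conventions, colormap and
  resize interpolation are all unstated upstream; defaults are documented
  best guesses, each configurable.
* The full-dataset protocol (unequal segments per subject) is out of scope:
  its published image totals are internally inconsistent, and recreating it
  requires the real recording lengths.
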