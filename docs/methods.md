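# Methods

`ecgfusion` classifies single-lead ECG heartbeats into ten cardiovascular
classes (N, MI, VHD, CAD, CHF, DY, MYO, HCM, DCM, BBB) by turning each beat
into a three-channel image and training a small residual attention network
on those images.  This note documents the models, the parameter choices and
their rationale, the synthetic data the package is validated on, and the
known limitations.

## Signal conditioning

All sources are resampled to a uniform 128 Hz (polyphase FIR resampling).
The clinically relevant QRS content sits well below the 64 Hz Nyquist limit
at this rate, and a single rate lets one filter design serve every source.
Resampling happens *before* filtering so the bandpass is designed once for
128 Hz.

Filtering is a two-step chain:

1. **Butterworth bandpass**, 0.5–40 Hz, order 4, applied forward-backward
   (zero phase).  The band edges are conventional ECG choices: 0.5 Hz
   suppresses baseline wander (body movement, respiration), 40 Hz removes
   powerline interference and EMG while leaving QRS morphology intact at a
   128 Hz rate.
2. **Wavelet denoising**: a 5-level db6 decomposition (one approximation
   C5 plus details D1–D5, symmetric signal extension), soft thresholding of
   the detail bands, inverse transform.  The noise scale is estimated from
   the finest band as `sigma = median(|D1|) / 0.6745`.

   The per-level threshold rule is **hybrid SureShrink** by default: each
   detail level uses the threshold minimizing Stein's unbiased risk
   estimate of the soft-threshold estimator, falling back to the universal
   threshold `sigma * sqrt(2 ln N)` when a level is too sparse for SURE to
   be reliable.  The plain universal rule is available
   (`threshold_rule="universal"`) but is not the default for a measured
   reason: ECG detail coefficients are sparse and large at the QRS, and the
   universal threshold's uniform shrinkage biases those coefficients enough
   to *lose* about 2.5 dB SNR on our synthetic noisy-beat benchmark at
   10 dB input SNR, while the SURE rule gains 4–5 dB under the same
   conditions.  Both rules apply the identical sign-symmetric soft
   shrinkage `sgn(c) * max(|c| - thr, 0)`.

   Baseline drift is removed structurally: with `drop_approximation` (the
   default) the C5 band — 0–2 Hz at 128 Hz, which contains the 0.5–0.6 Hz
   drift — is zeroed at reconstruction.  Note this band also contains the
   heart-rate fundamental of a long beat train, so SNR comparisons against
   a clean reference are run with the approximation retained.

## R-peak detection and segmentation

The detector is the classical Hamilton envelope recipe: bandpass 8–16 Hz
(the QRS energy band), differentiate, rectify, 80 ms moving average, then
adaptive thresholding of envelope peaks.  The threshold sits at
`noise + 0.3125 * (qrs - noise)` where both estimates are running means of
the last 8 accepted QRS / noise peaks; a 200 ms refractory period suppresses
double fires, and RR gaps longer than 1.5x the mean RR are revisited at half
threshold (search-back).  Detections are refined to the local maximum of the
input signal within ±40 ms.  Two additions beyond the canonical stages, both
exposed in `DetectorParams`:

* a candidate floor at 10% of the global envelope maximum, which rejects
  filter ringing on nearly-empty signals that would otherwise pass a
  near-zero adaptive threshold;
* zero-phase filtering in the envelope stage, which avoids group-delay
  compensation.

Beats are windows from 240 ms before to 400 ms after each R peak.  At
128 Hz the per-side rounding is fixed at 31 + 51 = **82 samples** so every
segment has identical length; beats whose window crosses a record edge are
dropped (padding would distort the wavelet transform's edge behavior).
Each segment is z-scored, `(x - mu) / sigma`, with the **population**
(N-denominator) standard deviation — either convention normalizes, one is
declared so tests can be exact.  Zero-variance segments are rejected as
degenerate rather than silently passed on.

## Feature images

Each 82-sample z-scored beat becomes a 128x128x3 image in [0, 1]:

* **Channels 1–2, CWT scalograms.**  The continuous wavelet transform is
  computed by direct convolution with the sampled, scaled mother wavelet,
  `coef(s, u) = 1/sqrt(s) * sum_t x[t] psi((t - u)/s)`, for integer scales
  1–64, under symmetric boundary extension.  Channel 1 uses the Mexican Hat
  wavelet (localizes the sharp QRS transient), channel 2 the Morlet wavelet
  (oscillatory structure).  The pixel value is the coefficient magnitude
  (the squared modulus is available by flag; magnitude gives better image
  dynamics after min-max normalization).  The 64x82 scalogram is min-max
  normalized and bilinearly resized to 128x128.
* **Channel 3, SIFT keypoint density.**  A difference-of-Gaussians keypoint
  detector runs over the grayscale (0–255) version of the *resized* Morlet
  channel: incremental Gaussian scale space with base blur sigma0 = 1.6,
  3 intervals per octave (k = 2^(1/3)), no initial upsampling, octaves until
  the smallest level is under 8 px; DoG extrema over the 26-neighborhood;
  up to 5 iterations of quadratic (Taylor) sub-voxel refinement — an
  extremum straddling a voxel boundary (offset oscillating at ±0.5) is
  accepted with a clipped offset on the final iteration rather than
  discarded; rejection of candidates with refined |D| < 0.04 (intensities
  in [0, 1]) and of edge responses with Hessian ratio tr²/det ≥ (r+1)²/r at
  r = 10.  Keypoint locations are histogrammed into a 5x128 map
  (`row = floor(y * 5/128)`, one increment per keypoint; a filled-circle
  variant with radius proportional to the detected scale is available as
  `mode="disk"`), blurred with a 3x3 Gaussian (sigma 1.0, symmetric
  borders), min-max normalized, and nearest-neighbor upsampled to 128x128 —
  each density row spans ~25 image rows, deliberately blocky so counts stay
  localized.  Orientation assignment (36-bin Gaussian-weighted gradient
  histogram, 80% peak duplication) is implemented for completeness but the
  density map uses locations only.

Channel order is (mexh, morl, sift) and configurable.  The whole path is
deterministic: the same segment always yields the bit-identical image.

## Classifier

`LightResAttNet` is implemented from scratch in NumPy (im2col convolutions
as GEMM in float32, explicit backward passes), with layer-by-layer
parameter accounting:

| component | output | params |
|---|---|---|
| 5x5 conv, stride 2, bias | 64x64x32 | 2,432 |
| BN + ReLU | 64x64x32 | 128 |
| pre-act res-block 32→64, stride 1 | 64x64x64 | 57,728 |
| pre-act res-block 64→128, stride 2 | 32x32x128 | 230,144 |
| pre-act res-block 128→256, stride 2 | 16x16x256 | 919,040 |
| spatial attention (7x7) | 16x16x256 | 99 |
| GAP → dropout 0.5 → dense softmax | 10 | 2,570 |

Total 1,212,141 parameters (batch norm counted as four terms per channel:
scale, offset, two running statistics).  Each residual stage is one
pre-activation block — BN→ReLU→conv3x3→BN→ReLU→conv3x3, convolutions
without bias, 1x1 projection shortcut (no bias) when shape or stride
changes, **no activation after the addition** (the post-addition ReLU form
is available via `post_add_relu` for the literal residual formula
`H(X) = ReLU(F(X) + X)`).  The block internals are fixed by requiring the
stage-1 count of 57,728 = 128 + 18,432 + 256 + 36,864 + 2,048; no uniform
block layout reproduces all three stage counts simultaneously, so stage 1
is the pinned contract and stages 2–3 follow the same layout.

Spatial attention is the standard gate that matches its 99-parameter
budget exactly: channel-wise mean and max pooling, a 7x7 convolution
(7·7·2 + 1 = 99) and a sigmoid, multiplied over all channels.

**Focal loss** `-alpha (1 - p_t)^gamma log p_t` with alpha = 0.25,
gamma = 2.0, batch-mean reduction, probabilities clipped at 1e-7; alpha is
a scalar on every class by default (a per-class vector is accepted).
Training uses Adam (lr 0.001), batch size 32, up to 100 epochs, early
stopping when validation accuracy fails to improve for 10 epochs, with
best-epoch weights restored.  Weight init is He-uniform for convolutions
and Glorot-uniform for the dense head, seeded.

## Rebalancing

SMOTE brings every class to the majority count: each synthetic vector is
`x_i + u (x_nn - x_i)`, u ~ U[0,1], with `x_nn` among the k = 5 nearest
same-class neighbors (Euclidean, on flattened 49,152-dimensional image
vectors).  ENN (k = 3, single pass, self excluded, ties keep) then prunes
points whose neighborhood majority label disagrees with their own.  The
hybrid asserts two safety properties: no input class is annihilated and
the imbalance ratio never increases.  Rebalancing runs **inside each
training fold only** (`apply_within_fold`, default on) — balancing before
splitting would leak synthetic copies of test beats into training.

## Evaluation protocol

Stratified 5-fold cross-validation (not subject-wise).  Early stopping
monitors a 10% fold-internal validation split, never the test fold.
Metrics use one-vs-rest confusion counts per class — accuracy
(TP+TN)/n, precision TP/(TP+FP), recall TP/(TP+FN), harmonic F1 — averaged
as unweighted (macro) means, plus micro/macro ROC AUC and per-class average
precision.  Fold confusion matrices are pooled (summed).  A class absent
from the truth set has undefined recall: it is flagged and excluded from
the macro mean with a warning.  Ablation variants feed single channels of
the fused image to a 1-channel-stem model (morl_only / mexh_only /
sift_only vs hybrid).

## Synthetic data

The generator produces quasi-periodic beat trains with exact R-peak ground
truth.  Each beat is a sum of Gaussian bumps for P, Q, R, S, T (amplitude
mV, centre ms relative to R, width ms); the normal template has a 1.1 mV R
wave, 0.15 mV P at −160 ms, 0.35 mV T at +185 ms.  The ten class profiles
are *caricatures* of textbook signatures — widened QRS for BBB and DCM,
inverted T and deep Q for MI, tall R with deep S for HCM, low-amplitude
fast rhythm for CHF, erratic RR (sd 0.22 s) for DY, and so on.  They exist
to give the pipeline separable structure with known ground truth, not to
simulate disease.  RR intervals are truncated normals (minimum 0.4 s so
640 ms windows never swallow a neighbouring QRS).  Noise is additive
baseline wander (0.1 mV at 0.5 Hz), powerline (0.05 mV at 50 Hz) and white
noise (0.03 mV sd) — amplitudes a realistic fraction of the 1.1 mV R wave.
Default class proportions mirror a heavily imbalanced clinical corpus
(majority:minority ≈ 50:1).  Per-record seeds derive from the master seed
through counter-based `SeedSequence` spawn keys, so a class's records do
not depend on which other classes were requested.

What passing tests on this data do **not** show: robustness to motion
artifacts, electrode misplacement, inverted leads, pathological rhythms
outside the caricatured templates, or inter-patient variability — the
morphology within a synthetic class varies only through noise and RR
jitter, which makes classification far easier than on clinical recordings.

## Problem sizes and numerical choices

The scaled validation experiment uses 3 well-separated classes (N, MI,
BBB) x 100 beats, the full denoise→detect→segment→fuse pipeline, one fold
of a stratified 5-fold split, 5 epochs — sizes chosen so the whole suite
runs comfortably on a single CPU while still exercising every stage.
With the suite's fixed seed the hybrid variant separates the held-out
fold perfectly and beats or ties every single-channel ablation on macro
F1; across other seeds the 5-epoch cap leaves a few points of underfit
(held-out accuracy 85–100% observed, training accuracy ≥0.99 with
validation accuracy still climbing at the cap), which is variance of the
short training budget, not of the feature pipeline.  Convolutions run in float32; gradient correctness is verified
against central differences on a narrow model.  WFDB output uses format 32
with the gain spanning the int32 range so write→read round trips are exact
to below 1e-9 mV (format 16 is read but quantizes at ~0.5/gain).  Degenerate
inputs are contracts, not accidents: constant images produce zero grayscale,
zero feature images and no keypoints; empty R-peak sets produce empty
segment lists; zero-variance beats raise.

## Limitations

* The classifier is NumPy-only: training is CPU-bound and practical for
  hundreds to a few thousand images, not for full clinical corpora.
* The detector assumes upright (positive) R waves, as produced by the
  generator; inverted-QRS leads would need a polarity check.
* SMOTE/ENN neighbor searches are exact and O(n²) in memory-bandwidth
  terms on flattened images; they are fine at within-fold sizes but a
  subsampled or projected search would be needed at corpus scale.
* Real-record label extraction from WFDB headers is best-effort pattern
  matching and should be reviewed against each database's conventions.
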