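# Methods

`paravox` implements a complete voice-condition analysis pipeline for
detecting Parkinson's disease (PD) from sustained /a/ phonations: feature
extraction from one second of voiced signal, repeated recursive-feature-
elimination selection, grid-search tuning, and a repeated stratified
holdout evaluation protocol, together with synthetic generators that make
every stage testable without clinical recordings. This note records the
models, the parameter choices that matter, and what the synthetic material
does and does not establish.

## Preprocessing

Recordings are 44.1 kHz mono WAV files. Voicing is decided per 25 ms frame
(10 ms hop) by RMS level relative to the loudest frame; frames above
−40 dB are voiced. The retained segment is exactly one second starting at
the first voiced frame. The criterion is relative to the recording's own
peak, so trimming is invariant to recording gain and is idempotent.
Inputs at other sampling rates are rejected unless explicitly resampled,
since every extractor default is stated at 44.1 kHz.

## Vowel synthesizer

The generator is a source–filter model: a Rosenberg glottal flow pulse
(open quotient 0.6, speed quotient 2) whose derivative excites a cascade
of three two-pole resonators at the /a/ formants (700/1220/2600 Hz with
80/120/160 Hz bandwidths). Per-cycle periods are T0·(1 + j·z/100) and
source gains 1 + s·z′/100 with z, z′ iid standard normal clipped at ±3;
j and s are the jitter and shimmer dials in percent. Gaussian noise is
passed through the same resonators and scaled so the periodic-to-noise
power ratio at the filter output equals the requested HNR. Cycle lengths
are quantized to whole samples and the stored ground truth (onsets,
periods, gains) is exactly what the waveform realizes.

One deliberate choice: the open phase has a fixed duration computed from
the nominal period, so period perturbations live entirely in the closed
phase. This makes every cycle shape-identical, which pins the excitation
landmark at a constant offset from the cycle onset; with a proportionally
scaled pulse, any intra-cycle landmark sits at a proportional offset and
successive landmark differences average adjacent periods, which would make
the generator's own ground truth unrecoverable by *any* waveform-domain
estimator (measured jitter would be biased low by a factor approaching 2).
Real voices are not this clean; the generator is a calibration instrument,
not a vocal-fold model.

## Cycle detection, jitter, shimmer

Mean f0 comes from the global normalized autocorrelation peak between
1/500 and 1/50 s (parabolic refinement); signals whose peak is below 0.3
are rejected as unvoiced. Cycle landmarks are then tracked by waveform
matching: the lag in [0.7, 1.3] running periods that maximizes the
normalized cross-correlation of successive cycle windows, refined to
sub-sample precision on the correlation parabola. The matching template is
0.7 of the running period — long enough to lock onto the pulse response,
short enough never to contain the next pulse (which would drag the
alignment toward an average of adjacent periods).

Jitter and shimmer are the "local" variants: 100·mean|x_{i+1}−x_i|/mean x
over cycle periods and cycle amplitudes respectively. Cycle amplitudes are
measured on the inverse-filtered glottal flow (peak-to-peak within a
period-centered window) rather than on raw waveform peaks: the raw peak
mixes each pulse with the previous cycle's formant ringing, which shrinks
cycle-to-cycle amplitude differences by ~10% systematically; the flow
estimate is unbiased against the generator's ground truth. If inverse
filtering degenerates the extractor falls back to waveform peaks.

## Spectral, noise and glottal features

- **HNR**: per 40 ms frame (10 ms hop), normalized autocorrelation r at the
  local period lag; frame HNR = 10·log10(r/(1−r)), r clipped to
  [0.001, 0.999] (so the ceiling is ≈30 dB); mean over frames.
- **CPP**: per 40 ms Hamming frame (20 ms hop), real cepstrum of the dB log
  power spectrum; the power cepstrum (dB) peak in the 2–20 ms quefrency
  band is measured against a least-squares regression line over that band.
  Quefrency zero is excluded, which makes CPP exactly gain invariant.
- **GNE**: signal downsampled to 10 kHz, frame-wise LPC (order 13, 30 ms)
  inverse filtering, Hilbert envelopes of 1 kHz bands centered every
  500 Hz from 500–4500 Hz, maximum cross-correlation over ±0.3 ms lags
  between bands more than 500 Hz apart, averaged over frames.
- **Glottal quotients**: two-pass LPC inverse filtering (order-1 tilt
  estimate, vocal tract order round(2 + fs/1000), leaky integration of the
  residual) gives a glottal flow estimate; the open phase of a cycle is
  the longest contiguous region above 50% of the cycle's flow range. The
  three dispersion features (5–95 percentile period range, sd of open and
  of closed phase durations) are normalized by the mean period. If more
  than half the cycles have no usable open phase the two phase features
  are flagged missing (NaN).
- **MFCC 1–13**: 25 ms Hamming frames, 10 ms hop, 26 triangular mel
  filters to fs/2, log energies (floored relative to the global maximum so
  the log stays gain-equivariant), orthonormal DCT-II, coefficient 0
  excluded, frame-averaged.

## Nonlinear measures

All nonlinear measures run on a 22.05 kHz downsampled copy (voice content
lives far below the 11 kHz Nyquist; pairwise-distance costs drop 4×), and
all are invariant to positive rescaling because radii, histogram ranges
and thresholds are defined relative to the signal's own scale.

- **RPDE**: embedding m=4, τ=35 samples, ball radius 0.25·sd; first return
  times after leaving the ball, searched up to 50 ms; normalized entropy
  of the return-time histogram. The radius is larger than the fraction
  sometimes quoted for long recordings because at one second of signal a
  smaller ball yields too few recurrences for the return-time histogram to
  fill, biasing the entropy down even for noise.
- **Correlation dimension**: Grassberger–Procaccia with the same embedding,
  Theiler window of one mean period, slope of log C(r) over r between the
  2nd and 20th percentile of pairwise distances (larger radii are in the
  saturation regime and flatten the slope; with this band a sinusoid reads
  ≈1 and iid noise ≳3.5 at m=4).
- **PPE**: per-cycle f0 mapped to log(f0/median), whitened by a
  least-squares AR(2), residual histogram entropy over [−0.5, 0.5] in 30
  bins, normalized by ln 30. Transposition invariant by construction.
- **Hurst exponent**: order-1 DFA, scales 16…n/8 (12 log-spaced), slope of
  log F(s). Windows are taken from both ends of the profile.
- **MFSW**: multifractal DFA over q ∈ {−5…5} (logarithmic mean at q=0);
  α(q) = d[q·h(q)]/dq by finite differences; width = max α − min α.
  Flagged missing when the per-q regressions have R² < 0.9 for more than
  half the q values — a real occurrence on strictly periodic signals,
  which are not scaling.
- **LZ-2**: median binarization, LZ76 exhaustive-history parsing,
  c(n)·log2(n)/n clipped to [0,1]. The parser is verified exhaustively
  against an independent brute-force implementation on all binary strings
  up to length 12.
- **Permutation entropy** (m=3, τ=1, stable-sort tie-break), **amplitude
  Shannon entropy** (64 bins over ±max|x|), **ACF first zero** (linear
  interpolation), and the **first AMI minimum** (32×32 histogram MI). The
  histogram MI of strongly deterministic signals is twitchy lag-to-lag, so
  the AMI profile is stabilized with a deterministic sub-bin dither and
  5-point smoothing, and the reported minimum must be a genuine basin (no
  lower value within the lookahead window); a sinusoid then reads T/4
  within a few percent.

"Shannon's entropy" is implemented as amplitude-histogram entropy (not
spectral entropy); it is isolated behind one function so the alternative
reading can be swapped in.

## Cohort assembly

Per-recording vectors (32 features) carry subject id, recording id, label
(PD/healthy), sex and age. Subjects' recordings are averaged
component-wise (missing values excluded) to one vector per subject — with
the intended three recordings per subject, 180 rows become 60. Sex enters
the feature matrix as a binary indicator (male = 0, female = 1) and is
standardized like every other feature, since it participates in selection
and classification like any feature. Standardization always uses training
set statistics only; constant columns map to zero. Missing entries are
imputed with training-fold column means computed after scaling, inside
each split, so no test-set statistic ever leaks.

## Detection protocol

Six classifier families are supported: logistic regression, random
forest, perceptron, passive-aggressive (PA-I via the SGD implementation),
gradient boosting, and max-margin (SVM, linear or RBF).

**Feature selection** repeats stratified 5-fold cross-validation 100 times
(fold shuffling reseeded per repeat). Within each training fold, features
are eliminated one per step by weakest importance (|coefficient| for
linear families, impurity importance for trees; the SVM family uses its
linear kernel here), and validation accuracy is recorded at every subset
size; a repeat's optimal count maximizes mean CV accuracy, ties going to
fewer features. The final subset size is the **first quartile** of the
per-repeat optima (linear-interpolation percentile, rounded half up,
floored at 1) — a deliberately conservative rule. Features are ranked by
elimination order (rank 1 = last survivor) averaged over all folds and
repeats, ties alphabetical, and the top final-count features are selected.
Selection-stage linear models use moderate regularization (C = 0.1) as
their default: at ~48 training subjects per fold this visibly stabilizes
the importance estimates and the recovered feature sets.

**Hyperparameter tuning** is an exhaustive grid search scored by mean
stratified 5-fold accuracy, ties broken by enumeration order. The default
grids are small and documented in `detection.DEFAULT_GRIDS`
(regularization over {0.01, 0.1, 1, 10}, tree counts {100, 300}, depths
{2, 3, 5}, learning rates {0.05, 0.1}, SVM kernels {linear, RBF} with
widths {scale, 0.1, 1}).

**Evaluation** repeats 1000 stratified 75/25 holdout splits. Per-class
test counts use largest-remainder rounding with the remainder tie
alternating by iteration parity, so a 30/30 cohort alternates {7, 8} PD
subjects in its 15-subject test sets. The scaler and imputation means are
fitted on the training side of each split. Metrics are accuracy,
sensitivity and specificity from the confusion matrix (PD positive) and
AUC from the continuous score (decision value, or positive-class
probability for tree ensembles). AUC is computed by an in-house threshold
sweep with simultaneous tie steps, equal to the Mann–Whitney concordance
(verified to 1e−12 against a brute-force pair count). ROC curves are
vertically averaged on a fixed 101-point FPR grid with a ±1 sd band.

**Transfer** freezes the selected features and hyperparameters from a
source cohort and evaluates on a target cohort. Two readings exist and
both are implemented: retraining on target training splits (the default),
and a fully frozen pipeline that trains on source subsamples and scores
target subsamples with source scaling statistics. The distinction
matters: per-split re-standardization absorbs any purely affine
per-feature shift between cohorts, so degradation under the synthetic
covariate-shift model is only visible in the frozen reading — that is the
reading the degradation experiments use.

**Comparisons** between reports use Student's equal-variance two-sample
t-test per metric (Welch available), significance at p < 0.05.

Reproducibility: one master seed; iteration i derives its split RNG and
classifier seed from seed + i.

## Synthetic cohorts and what the tests show

`synth_cohort` draws class-conditional Gaussians: healthy means 0, PD
means equal to the per-feature effect sizes (in within-class sd units),
unit variances, optional equicorrelation, optional per-feature affine
shift generating a "second database" sibling, optional label noise. The
default design is 30 PD / 30 healthy with 33 features.

Chance calibration spreads the 1000 protocol iterations over independent
null cohorts: repeated splits of one fixed finite null dataset are not
independent experiments — a flexible learner exploits that dataset's
accidental structure in most splits, and a single-cohort mean can sit
0.05–0.1 above one half without any real signal. Across independent null
cohorts the symmetry is exact and the aggregate mean is 0.5.

These synthetic cohorts have Gaussian classes, homogeneous covariance and
exactly known informative sets; passing the calibration and recovery
checks shows the machinery is correct and leakage-free, not that the
achieved accuracies transfer to clinical recordings, where effect sizes,
covariance structure and shift mechanisms are unknown.

## Problem sizes used in the checked experiments

The protocol defaults (100 selection repeats, 1000 evaluation iterations)
are the package defaults. The automated checks run the same code at
reduced but statistically sufficient sizes, chosen once: selection
recovery uses 25 RFECV repeats per seed over 25 seeds; degradation uses
40 evaluation iterations per side over 20 seeds with 50-tree ensembles;
chance calibration keeps the full 1000 iterations per family (50 null
cohorts × 20); the audio end-to-end run uses 60 one-recording subjects,
10 selection repeats and 200 evaluation iterations.

## Known limitations

- The synthesizer produces steady sustained phonation only: no onset or
  offset transients, no tremor, no breaks, no room acoustics. Measured
  jitter/shimmer floors (~0.01–0.1%) come from sample quantization.
- The glottal-quotient definitions are reconstructed from the feature
  names (dispersion of open/closed phases from inverse-filtered flow);
  they are isolated behind one function so an alternative toolbox
  definition can replace them.
- MFSW is regularly flagged missing on nearly periodic signals; the
  pipeline's imputation handles this by design.
- Degradation under covariate shift is demonstrated for the frozen
  pipeline reading; affine shifts are invisible to the retrain reading by
  construction.
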