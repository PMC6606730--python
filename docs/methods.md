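# Methods

This note records the model, the numerical choices and the open design
decisions behind `emofuse`, and what the synthetic-data experiments do and
do not demonstrate.

## Emotion model and task

Emotional state is represented on the valence/arousal circumplex, each axis
quantized to five intensity levels. Perception is posed as two independent
5-class classification problems solved synchronously on the same trials: an
arousal sub-model and a valence sub-model. Nothing couples the two
sub-models; correlations between the dimensions in real data are neither
assumed nor exploited.

## Preprocessing

- **Framing.** Trials are cut into frames of `N` samples with overlap `M`
  (defaults 500/250 at 250 Hz, i.e. 2 s frames, 1 s hop). Frame count is
  `floor((samples − N)/(N − M)) + 1`; trailing samples that do not fill a
  frame are dropped so every frame has exactly `N` columns. Each channel of
  each frame is tapered by the Hamming window
  `w(n) = 0.54 − 0.46·cos(2πn/(N−1))`.
- **FIR band-pass.** 32-order (33-tap) linear-phase windowed-sinc filter
  with Hamming taps, pass band 0.5–60 Hz, applied causally per channel. The
  tap count `order + 1` is forced odd to keep a type-I response. At this
  order the low edge is a gentle shelf, not a wall; the contract tested is
  ±3 dB in the pass band and > 6 dB attenuation at 80 Hz.
- **Artifact screening.** Manual trial screening is replaced by a
  reproducible amplitude criterion: a trial is rejected iff any sample
  exceeds the threshold (default 100 amplitude units) in magnitude.
- **Pupil illumination removal.** The pupil reflects ambient luminance; the
  confound direction is estimated from the covariance of the standardized
  pupil/luminance pair and regressed out with a soft threshold of 0.1 on
  the correlation. The threshold exists because two independent slow series
  of ~55 s share substantial incidental sample correlation (few effective
  degrees of freedom); removing all of it would subtract genuine emotional
  signal. A plain 2-D PCA removal was considered and rejected: with
  standardized inputs both principal components load at exactly 45°, and
  deleting the luminance-aligned component leaves residual correlation
  √((1−r)/2) — about 0.44 at r = 0.6 — which defeats the purpose.

## Features

- **APS** is the mean periodogram PSD over the band's frequency bins,
  computed with a boxcar window because the frame is already
  Hamming-tapered at framing time (no Welch sub-segmentation: frames are
  only 500 samples).
- **AE** is the mean squared sample of the band-filtered frame (4th-order
  Butterworth band-pass, zero-phase). Filtering and spectral summation
  agree within edge-effect tolerance (tested); filtering is the definition.
- **DAPS** is the *signed* left-minus-right APS difference per symmetric
  pair and band (slow α excluded): the sign carries the hemispheric
  asymmetry that tracks valence, so absolute differences would discard the
  payload.
- Per-trial EEG features are the mean of per-frame features; the mean
  preserves dimensionality and suits the stationary synthetic trials. The
  batched extractor stacks all frames and filters them in one call per
  band; it is bit-compatible with the scalar per-frame operators (tested).
- **Eye features** (20 per trial): blink/saccade/fixation duration mean and
  population SD (population, so a single event gives SD 0), mean saccade
  rotation angle, event frequencies, and duration/rotation extrema for
  fixations and saccades. Event types absent from a trial contribute zeros
  with a logged warning. The fixation "rotation angle" is read as the gaze
  dispersion during the fixation. Pupil band PSD/differential-entropy
  features (4 bands × 2) are computed but excluded from the default
  20-dimensional assembly; `include_pupil_spectral=True` appends them.
  Differential entropy uses the Gaussian closed form `0.5·ln(2πe·σ²)` with
  the band variance from periodogram integration and a floor of −20 for
  degenerate series.
- **Normalization** maps each feature to [0,1] by absolute-value min–max:
  `y = (|x| − min|x|)/(max|x| − min|x|)`, per participant when grouping is
  requested. Constant features map to 0 with a warning. Inside
  cross-validation the statistics come from training folds only and test
  values are clipped into [0,1].

## ICA spatial filtering

Per-trial unmixing is estimated with natural-gradient Infomax (logistic
nonlinearity) on PCA-whitened data. Numerical choices: block size
`max(8, √(samples/3))`; initial learning rate `0.01/ln(n_channels + 2)`;
rate × 0.9 whenever successive update directions turn by more than 60°
(near the optimum stochastic updates decorrelate, so this decays the step);
unconditional geometric decay ×0.98 per iteration after iteration 250; the
convergence criterion is scale-invariant (row-normalized weight change
< 1e−5) because row scale keeps adapting to the logistic density long after
the component directions settle; blow-ups restart from identity at half the
rate. Source recovery is cross-checked against FastICA in the tests.

A filter is **valid** when the per-column argmax indices of |A| (A = W⁻¹)
form a permutation of all channels. Valid filters are reordered so
component *i* sits on channel *i*; because ICA rows have arbitrary scale
and sign, aligned rows are unit-normalized with the dominant mixing
coefficient forced positive before the bank is averaged into the mean
filter — without this the mean of filters from different trials is
meaningless. Projecting a trial through the mean filter and taking the SVD
`S = UΣVᵀ` gives spatial features `ES = [λ₁v₁, …, λₙvₙ]`. As the paper-side
description never fixes how the matrix ES feeds a classifier, the package
exposes two fixed-length summaries: the singular-value vector
(`lambda_only`, default) or that vector plus the leading ES column. Spatial
features are kept separate from the time–frequency vector by default
(concatenation is the caller's choice).

## Fusion

Confidence factors are the calibrated per-class probabilities of each
modality's RBF-SVM (C = 1), which lie in [0,1] and sum to 1 — the
confidence map is otherwise unspecified in the source description, and
Platt-style calibration of decision values is the standard choice. The
discrete Choquet integral aggregates the per-class confidences of the
classifiers under a per-class fuzzy measure; it reduces to the arithmetic
mean for the uniform additive measure, to min/max at the extreme measures,
and is monotone and idempotent (all property-tested against a layer-cake
oracle).

**Measure learning.** The squared margin-deficit objective is expanded into
an exact quadratic form over the stacked coefficient vector (per class:
singletons, pairs, …, per the subset ordering), with inequality constraints
for the [0,1] bounds and every cover relation of the subset lattice. Two
points were genuinely open:

- *Multi-class extension.* The printed objective is two-class. Here each
  training example contributes one term: its true class's global confidence
  against the strongest competing class, the competitor fixed beforehand
  using the uniform measure (column means) so the program stays a convex
  QP with m·(2ⁿ−2) variables.
- *Regularization.* The margin target of 1 is generally unreachable
  (confidences sum to 1 over 5 classes), so the raw objective rewards
  whichever classifier happens to emit sharper training confidences — in
  simulation this cost the fusion several accuracy points against the
  better modality. The objective therefore carries a ridge toward the
  uniform measure (weight 0.1 per training example). The shrunk optimum
  provably still satisfies J(learned) ≤ J(uniform), and a clearly better
  classifier still receives the larger coalition importances (tested).

The QP is solved with SLSQP from the uniform starting point; solver failure
or non-improvement falls back to the uniform measure with a warning, and
tiny constraint slack is repaired by clipping plus a bottom-up monotone
pass. Prediction is the argmax of the global confidences, ties to the
lowest class id.

## Evaluation protocol

Repeated stratified k-fold cross-validation (default 10 repeats × 5 folds).
Stratification is used because 5 classes with tens of trials per class make
unstratified folds degenerate. Per split, the scaler, the SVMs and the
fuzzy measures are fitted on the training folds only; a "global"
normalization mode reproduces whole-session scaling when that is wanted.
Reports carry mean accuracy per modality and fused per dimension, fold SDs,
and the row-normalized 5×5 confusion matrix of the fused classifier
averaged over splits. A per-participant driver runs the same protocol
within each participant and returns one report per participant.

## Synthetic data

No recordings accompany the method description, so the generator defines
the study conditions; its defaults are fixed and the interesting ones are:

| parameter | default | why |
|---|---|---|
| trials per level | 40 | 200-trial session, comparable to a 12-participant pooled design |
| sampling rate | 250 Hz | matches 500 samples = 2 s frames |
| montage | 30 channels | the 12 symmetric pairs + 6 midline electrodes |
| trial length | 55 s | stimulus-clip duration |
| arousal gains / level | 0.6…1.8 | broadband amplitude scales with arousal |
| valence asymmetry / level | −0.4…0.4 | left-minus-right amplitude offset on pairs |
| burst-envelope depth | 0.8 | makes band noise super-Gaussian (rhythm bursts) |
| sensor noise SD | 2.0 | white noise per channel |
| blink rate / level | 0.2…0.4 Hz | level 5 doubles level 1 |
| illumination coupling | 0.8 | pupil–luminance confound strength |

Each channel is a single broadband generator: one noise process shaped into
the six rhythm bands and amplitude-modulated by a slow burst envelope
shared across bands. This matters for the ICA stage: when the six band
components of a channel are *independent* processes, the Infomax optimum is
demonstrably not a channel permutation and the validity judgment can never
pass, whereas one coherent super-Gaussian generator per channel makes the
electrode basis the unique independent basis. Level-conditioned parameters
are per-trial draws (log-normal σ 0.2 on gain, Gaussian σ 0.1 on asymmetry,
σ 0.15 on eye rates) — without this inter-trial variability the synthetic
task is separable at ceiling and says nothing about the fusion.

The generator does **not** emulate volume conduction, cross-channel
mixing, non-stationary artifacts, eye–EEG coupling, or participant
heterogeneity. Consequently the tests demonstrate correctness of the
pipeline and the qualitative behaviour of the fusion (it tracks and
typically exceeds the better modality when the modalities are
complementary), not expected accuracy on real recordings.

## Problem sizes used in the shipped runs

The test suite's end-to-end fixture and the acceptance script use a
200-trial session (40 per level) with the default 55 s trials, a 10-trial
ICA bank, a 120-clip rating table, and 10×5 (script) or 3×5 (test)
cross-validation; these sizes give stable accuracy estimates while keeping
a full run within a few minutes on one CPU.

## Known limitations

- The QP competitor is fixed before optimization; a bilevel variant that
  re-selects competitors at the optimum might lower J further.
- The Infomax implementation targets super-Gaussian sources only (no
  extended sub-Gaussian switching).
- `EyeRecord` event streams are assumed non-overlapping and chronological;
  real eye-tracker exports with overlapping events must be cleaned first.
- Five-class probability calibration on small folds is noisy; confidence
  factors inherit that noise.
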