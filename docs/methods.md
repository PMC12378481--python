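# Methods

## Problem and data model

A patient record carries two observation streams sampled on
independent, irregular time grids: sets of multi-channel cell-image
crops (CTCs/CECs from iFISH composites: DAPI nucleus in blue, CEP8
puncta in red, CD31-style membrane signal in green) and six-marker
serum panels. Timestamps are real days since the first treatment
(baseline = day 0); pre-baseline draws have t ≤ 0. Labels are binary
responder / non-responder (CR/PR vs SD/PD). The modelling task is
binary classification from both streams jointly, with the explicit
difficulty that the streams are asynchronous and of variable length
(1–5 visits per modality, median 3).

## Architecture

* **Cell features.** An 18-layer residual CNN (stem conv + eight
  two-conv residual blocks in four stages + linear head) with a
  configurable base width (`cnn_width`, default 16; tests and the
  bundled experiments use 4–8). Normalisation inside the CNN is
  per-sample instance normalisation: no batch statistics, so outputs
  are independent of batch composition and evaluation is exactly
  deterministic. Global average pooling makes the network accept any
  input ≥ 32 px.
* **Set pooling (stage 1).** A learnable aggregation token *queries*
  the cell set (multi-head attention; the token is not among the
  keys). Consequences that are tested exactly: pooling is
  permutation-invariant; duplicating a cell leaves the pooled output
  unchanged; the softmax weights over cells sum to one and double as
  the per-cell importance scores of the interpretability module.
* **Time encoding.** Continuous sinusoidal encodings sin/cos(t/τ)
  over D/2 geometrically spaced timescales τ ∈ [1, 1000] days, added
  to per-visit embeddings before any cross-time attention. Chosen
  because visit times are continuous and irregular; integer position
  indices would discard the actual elapsed time.
* **Cross-time attention (stage 2).** Pre-norm transformer blocks
  with key masking; padded slots are zeroed on output and provably
  inert to real slots (softmax bias −1e30 underflows to exactly 0).
* **TIM.** Cross-attention, cells query markers (the direction is a
  config flag), output added residually to the cellular stream. With
  a zeroed output projection the full model is numerically identical
  to the images-only variant — a tested reduction. Degraded modes: if
  one stream is empty the other is aggregated alone.
* **Temporal aggregator.** Patient token + four stacked
  self-attention layers ("quad-stage"); the token's output is the
  patient vector.
* **Predictor.** Three-layer MLP D → D/2 → D/4 → 2, softmax.

All tensors are float64 on a small in-package reverse-mode autodiff
core (`dam.nn`: conv via gathered-column matmul, attention, layer /
instance norm, Adam). Double precision keeps the exactness claims
above honest at negligible cost for these model sizes; every layer's
gradient is finite-difference-checked in the test suite.

## Training protocol

Stratified random test holdout (17/91 fraction), stratified threefold
split of the remainder; one model per fold; ensemble = arithmetic mean
of softmax probabilities. Loss is cross-entropy weighted by inverse
class frequency (cohorts are ≈59% responders). Optimiser Adam
(lr 3e-3 in the bundled experiments, weight decay 1e-4), patient-level
batches of 8.

**Dynamic longitudinal elimination**: at every training step each
modality is independently thinned to k = max(1, round(0.8·T))
timepoints (banker's rounding, chronological order kept, never
emptied). Resampled per step, not per epoch — the stronger
regularisation of the two readings. Never applied at evaluation.

**Frozen-CNN default.** `TrainConfig.freeze_cnn=True` keeps the
convolutional extractor at its seeded random initialisation and caches
its pooled features once per image (deterministic eval
preprocessing); only the projection, attention, fusion and head
parameters train. Random convolutional features are a classical
random-projection extractor: they preserve the morphological signal
(nucleus extent, punctum count) well enough for the downstream
attention stack to recover the dynamics, and cohorts of ~90 patients
cannot usefully fine-tune a CNN anyway. End-to-end fine-tuning
(`freeze_cnn=False`) is fully implemented — per-step flip/rotate
augmentation, gradients through the CNN — and is the path Grad-CAM
differentiates through; the frozen path is the default for the CV
driver and all bundled experiments. Because all fold models share the
seeded CNN, one feature cache serves training, validation, ensembling
and windowed evaluation.

Augmentation (fine-tuning path): horizontal/vertical flip p = 0.5
each, rotation Uniform(±30°) with bilinear resampling and zero fill,
resize to `out_size`, ImageNet per-channel standardisation — in that
fixed order. Evaluation uses resize + standardisation only.
Standardised arrays are plain floats (they necessarily leave [0, 1]).

## Synthetic cohorts

The generator emulates the study conditions rather than any real
measurement: n = 90 patients by default, responder fraction 0.59,
visits per modality drawn with median 3 (support 1–5, IQR-like
spread), first visit Uniform(0, 90) days and inter-visit gaps
Uniform(15, 90) days (first biopsy early in treatment, follow-ups at
sub-3-month intervals), independent per modality so >90% of
two-visit patients have mismatched grids. Cells per visit are
1 + Poisson(mean−1); each crop renders an elliptical nucleus (blue),
CEP8-like puncta (red), and a membrane ring for CECs (green), with
Gaussian background noise, quantised to the 8-bit grid so PNG
round-trips are exact.

The response signal lives **only in dynamics**: nucleus radius and
punctum count follow exp(±effect_size·t/span) (shrinking for
responders), and markers follow baseline·exp(s·effect_size·t/span+ε)
with lognormal baselines and noise ε ~ N(0, 0.25). Baseline counts
are label-independent by construction, so a counting classifier is
beatable exactly where dynamic modelling should win — this makes the
headline qualitative claim testable, and is also its limit: passing
tests show signal *recovery under the generator's assumptions*, not
clinical performance. The generator does not model assay reference
ranges, imaging artefacts, inter-channel bleed-through, or
informative visit scheduling.

Default problem sizes for the bundled experiments (90 patients, 32-px
crops, width-8 CNN, D = 32, 30 epochs) were chosen as the smallest
scale at which the dynamics signal is reliably recoverable.

## Evaluation and statistics

AUC is the rank-based (Mann–Whitney) statistic with midrank ties,
tested against exhaustive pairwise enumeration. CIs are stratified
percentile bootstraps (2000 resamples, per-class resampling so every
resample keeps both classes). The Mann–Whitney test enumerates the
exact permutation null (ties included) for n ≤ 16 and otherwise uses
the tie-corrected, continuity-corrected normal approximation.
Windowed evaluation restricts inputs to t ≤ 45 d / 3 m (30.44 d/mo) /
6 m / 1 y (365.25 d) / all, always retaining pre-baseline draws, and
re-runs the ensemble; patients left without any usable modality are
flagged and skipped, and a single-class window yields a flagged NaN
report rather than an error.

## Interpretability

Grad-CAM targets the final convolutional layer of the cellular
aggregator: channel weights are spatially averaged gradients of the
responder logit (backpropagated through the full patient-level
pipeline, so every image's map reflects its role in the patient
prediction), maps are rectified and bilinearly upsampled. Focus masks
threshold each map at its own 75th percentile (linear interpolation,
strictly greater), components counted with 8-connectivity. The six
dynamic features follow the stated formulas exactly (sample variance
with 1/(N−1), defined 0 at N = 1; median as mean of middles; DisFA
summed over images, never averaged) and are verified against a naive
brute-force implementation.

A structural caveat, measured and documented here deliberately: a
strict per-map 75th-percentile threshold caps every image's focus
area at ~25% of its pixels, and for the smooth maps produced by
bilinear upsampling of small rectified CAM grids the cap is
essentially attained — AvgFA is then nearly constant across patients,
so between-patient contrasts in AvgFA/MaxFA are not expressible at
this scale unless maps are mostly exact zeros. The size contrast the
generator encodes is directly measurable at the pixel level (nuclear
areas separate the labels strongly), and the tests check it there.

The feature MLP (6 → 16 → 8 → 2, Adam, 400 epochs, features z-scored
per training fold) runs under the identical threefold protocol;
permutation importance reports the mean ± sd ensemble-AUC drop over
column shuffles.

## Numerical choices and degenerate inputs

Masked softmax uses an additive −1e30 key bias (exact zero after
exp); LayerNorm ε = 1e-6, instance-norm ε = 1e-5; Adam ε = 1e-8.
Month/year window boundaries are 30.44/365.25 days; "within 45 days"
is inclusive (t ≤ 45). Missing marker values are NaN through I/O,
imputed with training-fold medians before log1p + z-scoring (per-fold
statistics only; a zero-variance marker column gets unit scale). An
all-missing panel imputes to the median vector. Empty modalities
raise descriptive errors naming mode and modality, except the TIM
degraded modes above. `round()` in elimination is round-half-to-even.

## Known limitations

* No pretrained weights; the full-scale 224-px/width-64 regime is
  supported but not exercised by the bundled experiments.
* The LSTM contrast model is out of scope by design.
* Synthetic fidelity limits are listed above; in particular the
  cohort-level AUC values reported by the reproduction script
  characterise the generator's regime, not any clinical dataset.
* The per-map focus-area caveat above: AvgFA/MaxFA are shape
  statistics at this scale, not activation-level statistics.
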