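# Methods

`octbrain` reimplements, end to end and on synthetic data, an OCT-based
three-way brain-tissue classifier: normal brain (NOR) vs. glioblastoma (GBM)
vs. primary CNS lymphoma (PCNSL). This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Synthetic B-scan model

B-scans are rendered from a single-scattering Beer–Lambert phantom:

    I(z, x) = R(z, x) · exp(−2 Σ_{z′≤z} μ(z′, x) Δz) · G + F

with reflectivity `R` (linear units, 1 inside tissue, 0 in air), attenuation
coefficient `μ` (mm⁻¹; the factor 2 is the round trip), axial pitch `Δz`
(mm), multiplicative unit-mean gamma speckle `G` with shape `k`
(`k = 1` is fully developed intensity speckle, CV = 1/√k; `k = ∞` disables
it) and an additive exponential noise floor of mean `F` (default 10⁻⁴ of the
surface reflectivity). No confocal/sensitivity roll-off, multiple
scattering, dispersion or polarization effects are modeled: the classifier's
target signatures are attenuation rate, lateral attenuation uniformity, and
microstructure, and this is the simplest forward model that produces all
three.

Class-conditional signatures (per-volume `μ_base` covering the class range
by stratified — jittered Latin — sampling across each cohort's volumes; at
cohorts of 5–15 volumes, i.i.d. draws from overlapping class ranges can by
chance produce class-separable attenuation values, and a classifier trained
on such a draw learns the decay rate as a spurious cue instead of the
morphological signatures the classes are defined by — stratification is the
standard design remedy for this small-cohort confound):

| class | μ range (mm⁻¹) | lateral μ field | inclusions |
|-------|----------------|-----------------|------------|
| NOR   | 1.5–2.5        | constant        | none |
| GBM   | 1.5–3.5        | piecewise-constant, 2–4 regions, ±40%, smoothed borders | 5–11 dark ellipses |
| PCNSL | 0.6–1.2        | smooth, ±10%    | none |

The μ ranges are stand-ins chosen to be physiologically plausible for brain
tissue at 1.3 μm; no published per-class attenuation coefficients exist for
this three-way problem, so they are configuration values
(`synthetic.CLASS_MU_RANGES`), not measurements. The PCNSL range sits
strictly below the NOR range (the "slowly attenuating" signature); GBM's
piecewise lateral field produces attenuation cliffs; its elliptical
inclusions (semi-axes 0.05–0.25 mm, reflectivity ×0.1, μ ×0.3, placed
non-overlapping by rejection sampling) emulate microcysts/necrosis/
hemorrhage. Ground-truth inclusion masks are written next to each volume for
localization experiments.

Geometry defaults are desk scale: 256 depth × 512 lateral pixels over
2.5 mm × 5 mm (the emulated instrument acquires 1000×1000 A-scans over
5 mm × 5 mm; axial resolution (2 ln 2/π)·λc²/Δλ = 7.57 μm at λc = 1.31 μm,
Δλ = 100 nm). Inter-frame motion is simulated as circular integer shifts
uniform in [−3, 3]² px so that translational registration is exactly
invertible, and saturation-stripe artifacts (columns forced to the maximum
representable intensity, ~4% of the width in 1–3 stripes) are injected per
frame with a configurable probability.

## Preprocessing

1. **Registration**: integer-pixel translation at the circular
   cross-correlation peak (FFT), moving frames aligned to the first frame of
   each averaging window. Sub-pixel and rotational registration are out of
   scope.
2. **Despeckle**: pixel-wise mean of 10 registered consecutive B-scans,
   sliding window of stride 1 (a 1000-frame volume yields 991 despeckled
   frames, matching the bookkeeping of the emulated study). Averaging runs
   on linear intensity; i.i.d. shape-1 speckle gives the expected ×10
   variance reduction.
3. **Registration-margin crop**: 3 px (the largest expected inter-frame
   shift) are removed from every side of each despeckled frame. Pixels
   inside that margin are not observed in all frames of the window; left in
   place, the shift seam imprints a vertical brightness discontinuity that
   is indistinguishable from a GBM attenuation cliff and attracts both the
   classifier and its attention maps to an acquisition artifact.
4. **Saturation exclusion**: a frame's score is the fraction of columns
   whose column-mean exceeds median + 6·MAD of the column means; frames with
   score ≥ 0.02 are excluded (after despeckling; both the statistic and the
   ordering are package choices — the emulated workflow states only that
   strong-reflection frames were excluded). On strongly nonuniform GBM
   phantoms this robust rule has a small false-positive rate (~5–10% of
   frames), which we accept as the cost of requiring no global calibration.
5. **Log compression**: linear intensity is mapped to dB over a 40 dB window
   below the frame peak before resizing. This is the conventional OCT
   display domain; on a linear scale the exponential depth decay concentrates
   essentially all post-normalization contrast in the first few hundred
   micrometers, hiding the attenuation-rate signature the classifier must
   learn. (`log_scale=False` restores linear-domain standardization.)
6. **Standardization**: depth crop/pad to 2.5 mm, bilinear resize
   (anti-aliased when downsampling) to 128 × 256, per-frame min–max to
   [0, 1]. Constant frames standardize to zeros with a warning.
7. **Augmentation** (training only, applied per frame with probability 0.5):
   random affine with rotation ≤ ±10°, translation ≤ ±5% of extent, and
   shear/zoom hard-capped at ratio 0.1 — exceeding the cap is a
   configuration error, since larger distortions would alter the
   morphological features the classes are defined by.

## Classifier

A 14-layer attention-gated pre-activation ResNet, implemented directly on
numpy (forward and backward passes are hand-written; convolution is im2col +
GEMM with per-layer scratch buffers — on a single CPU, avoiding repeated
large allocations matters more than FLOPs). Counting convention: 1 initial
3×3 conv + 12 convs in six residual units + 1 dense head = 14; projection
shortcuts and attention-branch convs are not counted.

* Stage filters 8, 16, 32, 64 with 1, 2, 2, 1 pre-activation units
  (BN → ReLU → conv, twice per unit); stride-2 downsampling on the first
  unit of stages 2–4, so the deepest map is 16 × 32 × 64.
* Attention gates after the 32- and 64-filter stages:
  `out = trunk ⊙ (1 + α · M(trunk))` with `M ∈ [0,1]` from a 1×1 bottleneck
  conv pair + sigmoid, and a learnable per-gate scalar `α = raw²` (so
  `α ≥ 0` always; `α = 0` is an exact no-op and the gate can only modulate
  the trunk upward). `α` initializes to 0.01: exactly 0 would be a stationary
  point of the square parameterization.
* Global average pooling gives the 64-d embedding used for t-SNE; a dense
  softmax head gives the three class probabilities.
* L2 weight decay 10⁻⁴ on conv/dense kernels.

## Training

SGD with learning rate 5·10⁻⁴, momentum 0.9, batch size 32, class-weighted
categorical cross-entropy with inverse-frequency weights
`w_c = N_total / (3 N_c)` (the worked example: training frame counts
14,517/9,698/4,854 → 0.667/0.999/1.996). Early stopping: training ends when
the validation loss has not reached a new strict minimum for 10 consecutive
epochs, and the best epoch's weights (including batch-norm running
statistics) are restored. Splits are volume-wise and class-stratified; a
shared volume id between a training set and its evaluation set raises a hard
`LeakageError`. Per-epoch shuffling and augmentation derive from the master
seed, so identical seeds give bit-identical trained weights.

## Reference experiment scale

The default synthetic study mirrors the emulated data separation: 15/10/5
training and 2/3/3 holdout volumes (NOR/GBM/PCNSL), fivefold volume-wise
cross-validation within the training pool. Volumes default to 20 frames of
256 × 512 px, which the 10-frame sliding window turns into 11 despeckled
frames per volume (~420 frames in all); the single reference model trains
for at most 30 epochs (~270 SGD steps) with fold 0 of the volume-wise split
as validation. These sizes were fixed from a throughput benchmark of the
numpy engine so the whole experiment runs in under fifteen minutes on one
CPU core; they are deliberate desk-scale choices, not estimates of what the
architecture needs.

## Evaluation and interpretability

* Confusion matrix in fixed class order (NOR, GBM, PCNSL); prediction is
  argmax probability with ties broken by class order. Accuracy = trace/total;
  macro accuracy = mean per-class recall.
* Sensitivity/specificity by one-vs-rest collapse; a class with no true
  instances yields a flagged undefined value, never a silent zero.
* Per-tumor ROC by one-vs-rest threshold sweep; AUC by trapezoid, equal (to
  10⁻¹²) to the pair-counting statistic #(pos > neg) + ½#(ties), which the
  tests verify against a brute-force oracle. Fold-averaged curves
  interpolate sensitivity onto a 101-point specificity grid (step 0.01) and
  report mean ± sd (sample sd, ddof = 1).
* Grad-CAM: channel weights are spatial means of ∂(class logit)/∂(feature
  map), backpropagated from the class logit through everything above the
  target map; heatmap = ReLU of the weighted sum, bilinearly upsampled to
  128 × 256 and max-normalized. The default target map is the 16-filter
  stage output (64 × 128): its 2 px stride still resolves the smallest
  simulated inclusion (~2.5 px on the standard raster), whereas the
  conventional deepest-map choice (16 × 32, 8 px stride) averages such
  lesions below its sampling grid and can only display the large-scale
  attenuation pattern — measured on trained models, its heatmap argmax lands
  on attenuation cliffs, not on microstructure. The deepest post-gate map
  remains available via ``target_stage``. The localization experiment scores
  the fraction of GBM holdout frames whose heatmap argmax falls inside the
  ground-truth inclusion mask resampled to the standard raster and dilated
  by a disk of radius 8 px (covering residual jitter and upsampling blur).
* t-SNE of the 64-d embeddings: PCA initialization, perplexity 30 (clamped
  to (n−1)/3 for small n), fixed seed; plots color by predicted label with
  train/test shading and ring misclassified points rather than drawing any
  class boundary.

## What the synthetic experiments show — and what they do not

Passing the end-to-end check means the implementation can recover the
class-conditional generative structure it was pointed at: preprocessing
preserves the signatures, the network has the capacity and the training
recipe the stability to separate them, and the evaluation stack measures it
honestly. It does **not** certify clinical performance: real tumor OCT
differs from the phantom in speckle statistics (partially developed,
correlated), microstructure shape and density, surface topography,
formalin-fixation optics, vasculature and artifact diversity, and real
class differences are far subtler — the emulated study itself reports ~80%
test accuracy on patient data where this synthetic benchmark saturates above
90%. Transfer of the *pipeline*, not of the accuracy number, is the claim.

A consequence of the class design worth stating plainly: the synthetic GBM
class carries two *redundant* signatures (attenuation cliffs and
microstructural holes), either of which separates it from NOR and PCNSL.
A model at 100% holdout accuracy may therefore have learned either circuit,
and grad-CAM can only show the one it learned — across training seeds the
localization experiment's rate jumps between ~1.0 (hole-attending models)
and ~0 (cliff-attending models) with no change in classification quality.
Interpretability results on this benchmark characterize *a* converged
solution, not *the* solution.

## Degenerate inputs and tie-breaks

* Constant frames: standardize to all zeros, logged.
* All frames excluded by the saturation filter: empty list plus a warning.
* Grad-CAM on an untrained model is allowed (logged) — heatmaps are then
  arbitrary but well-formed.
* Equal cross-correlation peaks (pathological constant frames): argmax takes
  the first index, i.e. shift (0, 0).
* A GBM spec with zero inclusions is allowed (structureless GBM exists) but
  logged.
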