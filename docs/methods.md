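# Methods

`drwnet` implements a joint lesion-segmentation and severity-grading
pipeline for color fundus photographs: classical lesion priors feed a
W-shaped dual-decoder convolutional network through a gated cross-attention
module, trained with a composite objective and evaluated with one-vs-rest
metrics and resampling statistics.  This note records the model, the
parameter choices that matter, and the design decisions taken where the
design was genuinely open.

## Problem setting

Diabetic retinopathy (DR) is graded on the five-level ICDR scale from the
presence and extent of retinal lesions: microaneurysms (MA, small dark
dots), hemorrhages (HEM, larger dark blobs), and exudates (EX, bright
yellowish deposits).  Grade 0 is lesion-free; grade 1 (mild NPDR) shows
microaneurysms only; higher grades add hemorrhages, exudates and vascular
change.  The package performs (a) pixel-level lesion segmentation and (b)
image-level five-class grading in one forward pass.

## Preprocessing

Images are standardized in five steps: a 3x3 local-variance-adaptive Wiener
filter; Gaussian smoothing (sigma = 1.5, 5x5 kernel); Canny edge detection
with hysteresis thresholds 0.1/0.3 on the normalized intensity scale;
border trimming (rows/columns below 5% of the maximum intensity), central
square crop and bicubic resize to the 644 x 644 working resolution;
luminance grayscale conversion with min-max normalization.  All
convolutions use reflect boundaries, so a flat field passes the Wiener
filter unchanged and the border-trim rule is never triggered by padding
artifacts.  The Wiener estimator is implemented directly (local mean /
variance via uniform filters) because the library routine zero-pads and
therefore alters flat regions near the border.

Augmentation: rotations at 90/180/270 degrees, horizontal/vertical flips at
probability 0.5, translations up to +-10%, optional histogram equalization,
Gaussian noise (sd 0.01-0.05) and brightness/contrast jitter (+-20%) —
geometric transforms are applied identically to masks.  Class balancing
replicates severe (3) and proliferative (4) rows fivefold and mild/moderate
(1-2) 1.5-fold, rounding half up; replicas carry distinct augmentation
identifiers.

## Lesion priors

Four classical detectors produce the prior stack P (H x W x 4, channels
ordered vessels/MA/HEM/EX, values in [0, 1]):

* **Vessels** — Frangi vesselness at scales 1-4 px, normalized, thresholded
  at 0.10, components under 30 px removed.  Vessel density is the binary
  mask mean.
* **Microaneurysms** — Laplacian-of-Gaussian blob detection (sigma 1-3 px,
  threshold 0.05) on the disc-inpainted, inverted green channel.  Blobs on
  the disc, on curvilinear vessel components or on the field-of-view rim
  are discarded, and each candidate must be darker than the 80th percentile
  of its surrounding annulus by at least 0.08 — this suppresses vessel
  tips and junctions, which are the dominant dark round confounders.  The
  prior map places a unit-height Gaussian bump at each accepted detection.
* **Hemorrhages** — local-mean adaptive thresholding (31 px window, offset
  0.05) of the inverted green channel, vessel and rim exclusion, component
  filtering by area (20-2000 px), eccentricity (< 0.98) and solidity
  (> 0.40).  Because a blob raises its own local mean, accepted components
  are grown by morphological reconstruction inside a looser dark support
  (offset halved); grown components exceeding the area cap are dropped.
* **Exudates** — grayscale closing (disk 4) to fill thin dark vessels,
  white top-hat (disk 15), Otsu threshold with an absolute floor of 0.10
  on the response (Otsu alone splits unimodal noise when no lesion is
  present), disc and rim exclusion.

Vessel exclusion uses only *curvilinear* components of the vessel mask
(eccentricity > 0.9 or solidity < 0.5, major axis >= 25 px): the Frangi
response also rings on the rims of dark round lesions, and excluding those
rims would erase the lesions themselves.

The optic disc is suppressed by biharmonic inpainting; when no mask is
supplied, a brightest-blob heuristic (top-2% intensity, largest component,
capped at 10% of the image) locates it.

All constants are `PriorConfig` fields, chosen for the 644 working scale
with lesion sizes in absolute pixels.

## Haar pyramid

A four-level 2-D Haar decomposition of the grayscale image provides
frequency-enriched inputs.  The orthonormal convention (divide by 2 per 2-D
level) is used so energy is conserved exactly and the inverse is exact to
machine precision; odd dimensions are edge-padded to even per level with
the padding recorded for inversion.  Detail bands are stored per level
(horizontal, vertical, diagonal).  PyWavelets is used in the test suite as
an independent oracle only.

## Network

The W-shaped network has one encoder and two heads.  The encoder is four
convolutional stages (3x3, stride 1, same padding, ReLU) of widths
128/256/512 plus a 1024-channel context stage, each followed by 2x2
max-pooling.  644 is not repeatedly halvable to the nominal printed sizes,
so pooling is ceil-mode (644 -> 322 -> 161 -> 81 -> 41) and decoder stages
double the size and center-crop/pad to their skip; the printed feature-map
sizes are treated as nominal.

**Lesion-Prior Cross Attention (LPCA)** sits on each of the three encoder
skips.  With encoder features F and the prior stack P resized to the skip
resolution:

    g   = sigmoid(W_a [F || P])                      (1x1 convolution)
    Q   = W_q F,  K = W_k P  (1x1),  V = W_v F (2x2, cropped back)
    Phi = g * softmax(Q K^T / sqrt(d)) V + (1 - g) * F

Attention runs over flattened spatial positions; to bound memory both
streams are average-pooled to at most `attention_grid_max` (48) cells per
side and the attended output is nearest-upsampled back.  The gate is
computed at full skip resolution.  d equals the channel count of F at that
scale; weights are per-scale.  A pooled mode (`attention_mode="pooled"`)
replaces spatial attention with a GAP-descriptor channel attention; the
spatial form is the default.  Pixel attention `F_pa = sigmoid(W_p * F) ⊙ F`
is applied to the final decoder feature map.

The **segmentation decoder** upsamples from the 41-cell bottleneck with 4x4
stride-2 transposed convolutions, concatenates the LPCA-fused skip at each
scale, and emits a sigmoid probability map at input resolution (644 x 644
x 1).  The **classification branch** pools the deepest LPCA-fused skip
(h = GAP(Phi)) — with the prior channels concatenated at that scale — and
passes h through two 256-unit dense layers with ReLU and dropout 0.75 into
a five-way softmax.

Two conditioning steps precede the pooling: each channel's spatial mean is
subtracted and only the positive residual kept, and the pooled vector is
layer-normalized (no learnable affine).  Lesion activations are spatially
sparse; without these steps the sample-to-sample differences after global
averaging are two orders of magnitude below the shared background
response, and from-scratch training cannot leave the uniform prediction in
any reasonable number of steps (a linear probe separates the raw features
perfectly — the problem is conditioning, not information).

A lightweight reconstruction head (1x1 convolution at the bottleneck,
nearest-upsampled) provides the consistency target; it can be disabled
(`use_recon=False`).

**Ablation variants** share the architecture: `baseline_unet` (plain
skips, no pixel attention), `no_lpca` (plain skips, pixel attention kept),
`lpca_spatial_only` (gate-only re-weighting, Phi = F + g*F), and `full`.
With gates clamped to zero the full variant reduces exactly to `no_lpca`,
which the test suite verifies with shared weights.

The network and its training run on a minimal numpy reverse-mode autograd
engine (`drwnet.nn`): im2col convolutions (row-chunked to ~256 MB buffers),
transposed convolutions as the adjoint, ceil-mode pooling, batched matmul
attention, and Adam.  Float32 throughout; He-normal initialization; a
`no_grad` context disables graph construction for inference.

## Objective

    L = 1.0 * L_seg + 1.0 * L_cls + 0.5 * L_align + 0.5 * L_cons

* `L_seg`: per-lesion-class hybrid Dice + beta-scaled BCE with smoothing
  eps (beta = 1.0, eps = 1e-6, per-class weights w_k = 1 by default; none
  of the three values is prescribed, all are config-exposed).
* `L_cls`: weighted cross-entropy with inverse-frequency weights
  omega_c = N / N_c.
* `L_align`: KL(prior || attention) between each gate map and the lesion
  prior saliency (max over MA/HEM/EX channels), both normalized to spatial
  probability distributions (uniform fallback for an all-zero map),
  averaged over scales.  This direction penalizes attention that misses
  prior mass.
* `L_cons`: mean squared error between the reconstruction head and the
  input.

## Training protocol

Adam (lr 0.001, weight decay 1e-5), batch size 16 (8 in the reduced
profiles), up to 50 epochs with early stopping on validation macro-F1
(patience 15); 5-fold stratified cross-validation with an 80/20 inner
train/validation split; checkpoint selection by best validation macro-F1.
Batches are processed sample-by-sample with gradient accumulation so the
alignment term sees each sample's own priors; the optimizer steps once per
batch on the averaged gradient.  A recorded momentum value (0.5) is kept
for provenance only — Adam uses its standard betas.

The **tiny-overfit protocol** (the learning-signal check) trains the
reduced-width model (channels 8/16/32 + 64 context) on 25 synthetic scenes
at 128 pixels with dropout and weight decay disabled — an overfit sanity
check verifies that the optimization path can memorize, which is exactly
what those regularizers exist to prevent.  It reaches 100% training
accuracy in roughly 40 epochs on one CPU core.  Problem sizes throughout
the test suite (64-128 pixel scenes, reduced channel widths, 1-2 epoch
cross-validation smoke runs) were chosen so the whole pipeline exercises
end-to-end on a single CPU; the full-width 644 configuration is exercised
in a forward-only architecture contract.

## Evaluation

Binary metrics follow the confusion-count formulas (precision,
sensitivity, accuracy, specificity, F1, Dice; F1 and Dice coincide
algebraically on identical counts).  Multiclass grading is scored
one-vs-rest per class and aggregated macro (unweighted) and weighted
(support-weighted); the confusion matrix is row-normalized.  ROC AUC uses
trapezoidal integration and AP step-wise interpolation (via
scikit-learn; the test suite checks both against brute-force threshold
enumeration).  Bootstrap confidence intervals are seeded percentile
intervals (default 1000 iterations, 95%); paired comparisons use the
paired t statistic across cross-validation folds, with t = 0 / p = 1 for
identical vectors and an error for zero-variance nonzero differences.
Zero denominators define the affected metric as 0 with a logged warning.

## Synthetic data

The generator renders fundus-like scenes: a dark circular field of view, a
bright Gaussian optic disc, a recursive branching vessel tree rooted at
the disc, and grade-dependent lesions — MA as 2-5 px dark dots, HEM as
irregular unions of dark disks, EX as bright yellow blob clusters.  Default
counts per grade: grade 0 none; grade 1 MA only (2-5); grade 2 MA 5-9,
HEM 1-3, EX 1-3; grade 3 MA 9-14, HEM 4-7, EX 3-6; grade 4 MA 12-18,
HEM 8-12, EX 6-10 — non-decreasing in grade, with illumination gradient
jitter (0.08) and Gaussian pixel noise (sd 0.01).  Lesions are placed off
the optic disc, off the vessel tree and mutually separated (MAs arise in
capillaries below imaging resolution; separation keeps each lesion an
isolated, countable object), and lesion sizes are absolute pixels so the
detectors behave consistently across working resolutions.  Generation is
bit-reproducible given (seed, grade, size).

What the generator does **not** emulate: camera noise ns color profiles,
illumination artifacts, media opacity, neovascularization and venous
beading (grades 3-4 are rendered as heavier burden of the same three
lesion types), DME features, and real anatomical variability.  Passing
tests therefore demonstrate that the pipeline is internally consistent and
that each stage does what it claims on data matching its assumptions —
not clinical performance.  Benchmark-scale results require the real
datasets and GPU-scale training, which are outside this package's scope.

## Numerical choices and degenerate inputs

Min-max normalization of a constant image returns zeros (logged).  A
degenerate single-valued top-hat response yields an empty exudate map
(Otsu undefined).  Probabilities are clamped at 1e-12 inside logs.  The
segmentation threshold for hard masks is 0.5.  Bicubic resize values are
clamped back to [0, 1].  Fold assignment requires at least n_folds samples
per grade.  Non-finite training losses abort with a diagnostic.

## Known limitations

* Spatial attention is computed on a pooled grid (<= 48 cells per side);
  very small lesions interact with attention only through the full-
  resolution gate.
* The numpy engine is single-threaded BLAS-bound; full-width training at
  644 is impractical on CPU (a full-resolution forward pass takes ~40 s),
  so training-dependent properties are established at reduced widths.
* Detected lesion *counts* can fragment or merge at low resolutions;
  count-based features are stable at 256 px and above.
* The classification branch's conditioning (contrast pooling + layer
  normalization) is a package-specific choice made for trainability from
  scratch; with pretrained backbones or batch-level normalization it may
  be unnecessary.
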