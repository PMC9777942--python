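# Methods

## Problem and pipeline

Gliomas are graded and delineated on multimodal MRI: four co-registered
pulse sequences per patient (FLAIR, T1, contrast-enhanced T1, T2), with
voxel labels for four tumor tissue classes — necrosis (1), edema (2),
non-enhancing tumor (3), enhancing tumor (4) — against background (0).
Evaluation uses three nested regions derived from those labels:
*complete* tumor (labels 1–4), *core* (1, 3, 4; edema excluded) and
*enhancing* (4 alone).

The package implements a two-stage cascade:

1. a lightweight **3-D U-Net** segments the whole tumor from a
   down-scaled four-channel volume;
2. a **five-layer DCNN** classifies the segmented region of interest
   (by default into high- vs low-grade glioma).

Both networks are written as a small NumPy layer framework with manual
backpropagation (`gliocascade._nn`): N-D convolution computed as one
BLAS matrix product per kernel offset, 2× max-pooling, nearest-neighbor
upsampling, stride-2 transposed convolution, batch normalization, dense
layers, and Adam.  Every backward pass is verified against central
finite differences in the test suite.

## Preprocessing

Volumes are resampled from acquisition resolution (e.g. 240×240×155) to
the network grid, 32³ by default, with pixel-center-aligned trilinear
interpolation for intensities and nearest-neighbor for labels (so the
output label set is a subset of the input's, and region masking
commutes with resampling on integer scale factors).  Each channel is
z-scored per volume — the four sequences have unrelated intensity
scales, so normalization is per-channel, and per-volume rather than
per-dataset because it requires no training-set statistics at inference
time.  A constant channel z-scores to all zeros by convention.  An
optional median filter is available but off by default: the network is
the denoiser of record, and an unstated filter would confound the
segmentation results.

## U-Net segmenter

Encoder: `depth` blocks (2–4 supported, default 4) of two 3×3×3
same-padded stride-1 convolutions with ELU followed by 2×2×2
max-pooling.  The filter ladder defaults to 8–16–32–64, doubling per
block so the feature mappings grow from the 4 input channels to 64 at
the deepest level; only the endpoints are architecturally meaningful
and the ladder is configurable.  At depth 4 a 32-voxel extent shrinks
to 2.  Decoder blocks mirror the encoder: 2× nearest-neighbor
upsampling then a 3×3×3 convolution (default), or a learned 2×2×2
stride-2 transposed convolution (`upsample_mode="transposed"`);
concatenation with the matching encoder output (doubling the channel
count at every merge); then two more convolutions.  A 1×1×1 convolution
with sigmoid produces the voxel probability map, thresholded at 0.5 by
default.

The head is binary: the training target is the *complete*-region mask
of the ground truth, resampled to the input grid ("tumor versus rest of
brain").  Core/enhancing metrics are obtained by training per-region
models (the `region` config field); a multi-class softmax head is
deliberately out of scope.  The loss is binary cross-entropy by
default; a soft-Dice loss is available.  Neither choice changes the
architecture.

Training uses Adam with the reference recipe: initial learning rate
10⁻³, batch size 16, L2 coefficient 4×10⁻⁴ on convolution and dense
weights (added to the gradient as 2λw), and a 200-epoch budget in the
`profiles/reference.yaml` profile.  The desk profile
(`profiles/desk.yaml`) uses 30 epochs, which suffices on phantoms.
`parameter_count` counts trainable arrays (convolution and dense
weights and biases, batch-norm scale/shift); batch-norm running
statistics are state, not parameters.

## DCNN classifier

Five blocks of [3×3×3 same-padded stride-1 convolution → batch
normalization → ReLU → 2×2×2 max-pool stride 2] take a 32-extent ROI to
extent 1 (32, 16, 8, 4, 2, 1); that divisibility constraint is the
reason the convolutions are stride 1 and the stride 2 sits on the
pooling stage.  The filter ladder defaults to 8–16–32–64–128
(configurable; only the layer count and block structure are fixed).  A
64-unit dense ReLU layer and a softmax output head complete the model.
ROIs are 3-D volumes by default (all spatial operators are the 3-D
variants); a 2-D slice mode exists behind `spatial_dims=2`.

ROI extraction zeroes intensities outside the predicted (or truth)
mask, crops the mask's tight bounding box, and resamples each channel
back to the classifier grid; an empty mask produces an all-zero tensor
flagged `empty`, which the cascade reports rather than classifies
silently.

The default task is grade (HGG vs LGG, 2 classes).  A K-class tissue
mode (e.g. the four tumor tissues, with ROIs taken per ground-truth
subregion) is supported by the same estimator since `classes_` is
inferred from the labels.

## Metrics and protocols

With TP/FP/TN/FN counted element-wise:
Dice = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN),
accuracy = (TP+TN)/total.  Conventions needed for tumor-free cases:
Dice of two empty masks is 1.0; sensitivity with an empty reference is
returned as NaN (flagged missing, excluded from aggregates); accuracy
of an empty comparison raises.

Two protocols are provided and not reconciled, since both are standard:
a fixed random 70/15/15 train/validation/test split, with
floor/floor/remainder arithmetic (880 images → 616/132/132), and k-fold
cross-validation (default k = 10) where each case appears in exactly
one test fold.  Fold aggregates are column means expressed in percent
and rounded **half-up** to one decimal, matching how such tables are
printed (mean fold Dice of exactly 88.75 prints as 88.8; banker's
rounding would print 88.7).

## Phantom generator

Each synthetic case is a spherical brain of uniform parenchyma with a
tumor of nested ellipsoids — edema outermost, then non-enhancing, an
enhancing shell, and a necrotic core — clipped to the brain.  Labels
are a pure function of geometry; the four channels are rendered from a
per-sequence × per-tissue contrast table (every tissue distinct on
every channel; edema bright on FLAIR/T2, the enhancing shell bright on
T1c) plus additive Gaussian noise (default SD 8 against tissue
contrasts of 10–90 units).  Defaults: 64³ volumes, brain radius 0.9 of
the half-extent, HGG tumor semi-axes ≈ (0.19, 0.16, 0.17) of the
extent with all four tissue classes, LGG ≈ (0.11, 0.095, 0.10) with no
enhancing shell — so grade is learnable from geometry and contrast.
Datasets default to 80 % HGG, echoing the HGG-heavy composition of real
glioma cohorts.  Tumor centers are drawn uniformly in the central
brain; all randomness flows through one master seed with per-case
seeds derived via `SeedSequence(master, spawn_key=(index,))`.

What the phantoms do *not* emulate: anatomy, bias fields,
partial-volume effects, scanner/site variation, irregular tumor shape.
Passing the recovery tests therefore demonstrates that the
implementation can learn and generalize on data of the intended
structure, not that it reaches any particular performance on clinical
scans.

## Evaluation problem sizes

The shipped desk-scale experiments (used by the tests and by
`scripts/acceptance.py`) are: U-Net trained on 40 phantoms (64³,
default noise, 80 % HGG) for 30 epochs with 10 held-out cases, where
it reaches pooled held-out whole-tumor Dice well above 0.9; and the
grade classifier trained on 20 balanced ROIs for 30 epochs with 20
held-out, where it is at or near 100 % accuracy.  A permutation-null
control (labels shuffled) stays near chance, confirming the signal is
real rather than an artifact of capacity.

## Numerical choices and edge cases

- float32 parameters and activations; losses and softmax/sigmoid in
  float64 for stability.
- He-scaled Gaussian initialization (suits ReLU/ELU).
- Max-pool gradient splits evenly across tied maxima (ties are
  measure-zero for real inputs).
- Thresholds are open-interval (0, 1); a threshold of exactly 0 or 1
  is rejected.
- Mask binarization uses `probability >= threshold`.
- Empty training sets, single-class label sets, non-binary targets,
  indivisible input extents and out-of-domain labels all raise typed
  errors (`gliocascade.errors`).

## Known limitations

- CPU-only NumPy training: fine at 32³ desk scale, not intended for
  full-resolution clinical volumes.
- The segmentation head is binary per region; simultaneous multi-class
  segmentation is out of scope.
- No bias-field correction or inter-site histogram matching.
- The published low-grade classification-accuracy fold column is not
  asserted anywhere: its printed average is not the mean of its printed
  fold values, so only the five self-consistent columns are used as
  worked examples.
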