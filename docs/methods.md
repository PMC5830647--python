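# Methods

## Problem and model

`fiberseg` segments myelinated nerve fibers in 8-bit grayscale electron-
microscopy images into three classes — background (0), myelin (1), axon
(2) — and derives morphometric maps from the resulting masks. The
segmentation model is a depth-4 fully convolutional encoder–decoder of the
U-Net family, in two variants tied to the imaging modality:

* **SEM** — 3 convolutions per block, working pixel size 0.1 µm;
* **TEM** — 2 convolutions per block, working pixel size 0.01 µm.

Per encoder block: `convs_per_block` bias-free convolutions (5×5 kernels in
the first block, 3×3 elsewhere), each followed by batch normalization and
ReLU, then a channel-preserving 5×5 stride-2 convolution. Widths double per
block from 16 (16/32/64/128). The decoder mirrors the encoder: bilinear ×2
upsampling, a 2×2 convolution down to the skip width, concatenation with
the block's pre-stride features, then `convs_per_block` convolutions whose
first halves the concatenated width (5×5 kernels at the finest level).
A biased 1×1 convolution maps to 3 channels; a softmax yields per-pixel
class probabilities.

The two variants have exactly 1,953,219 (SEM) and 1,552,387 (TEM)
trainable parameters. Several architectural conventions are not forced by
the prose description alone — whether block convolutions carry biases, the
kernel size of the strided and post-upsampling convolutions, the kernel
size of the finest expansion level, and whether the classifier is biased.
We fixed them by treating the two printed totals as simultaneous
constraints; the resulting ledger is

| term                   | SEM       | TEM     |
|------------------------|-----------|---------|
| contracting block convs| 497,040   | 297,104 |
| strided (down) convs   | 544,000   | 544,000 |
| 2×2 up-convs           | 108,544   | 108,544 |
| expanding block convs  | 799,744   | 599,808 |
| batch-norm scale/shift | 3,840     | 2,880   |
| classifier (1×1 + bias)| 51        | 51      |

and both totals are reproduced exactly, as is their difference (400,832 =
one extra bias-free convolution plus batch norm per block on both paths).
Any deviation from the conventions above breaks at least one total; the
test suite asserts all three numbers.

## Computational substrate

No GPU framework is used: the layers live in `fiberseg.engine` with
hand-written backpropagation, and convolutions are direct numba-compiled
kernels (`fiberseg._kernels`). At the small channel counts of this
architecture an im2col/GEMM formulation is memory-bound; the direct kernel
keeps the innermost loop on the contiguous output row and reaches an order
of magnitude higher throughput on one CPU core. Production arithmetic is
float32; the finite-difference gradient test builds a float64 model and
checks every layer's analytic gradient to 1e-4 relative error.

Numerical conventions:

* Convolution padding is `(k-1)//2` before and `k//2` after, so stride 1
  preserves shape for any kernel (including the even 2×2 up-conv kernel)
  and stride 2 maps H to ceil(H/2). Input sides must be divisible by
  `2**depth`.
* Bilinear ×2 upsampling uses the separable half-pixel kernel
  (out[2i] = 0.25·x[i−1] + 0.75·x[i], out[2i+1] = 0.75·x[i] + 0.25·x[i+1])
  with edge clamping; its backward pass is the exact adjoint.
* Batch-norm order is conv → BN → ReLU throughout, including the strided
  and up-convolutions; running statistics use the scheduled momentum below.
* Softmax ties at argmax resolve to the lowest class index.
* Probabilities are floored at 1e-12 inside the loss; normalization floors
  the patch variance at 1e-8 (a constant patch maps to all zeros).
* Weights are He-initialized (fan-in scaled normal), seeded.

## Data preparation

Images are resampled bilinearly to the variant's working pixel size
(masks with nearest-neighbor so labels stay in {0,1,2} — bilinear
interpolation of labels would create values outside the alphabet), tiled
into non-overlapping 512×512 patches over a mirror-padded canvas (the next
multiple of 512; mirror padding avoids intensity discontinuities at patch
borders), normalized patch-wise by global 256-bin histogram equalization
followed by standardization to zero mean and unit variance (equalization
first, so the network always sees zero-mean input), and split 70/30 into
train/validation by seeded permutation.

## Training procedure

Spatially-weighted 3-class cross-entropy, weights (1.1, 1.0, 1.3) for
(background, myelin, axon); Adam (β₁ 0.9, β₂ 0.999, ε 1e-8); starting
learning rate 0.001 under polynomial decay `lr₀(1 − t/T)^0.9` applied per
optimizer step (per-epoch decay is config-selectable and differs
negligibly) over a decay length of 200 epochs, after which training stops.
Samples are shuffled each epoch and consumed in batches of 8 (the last
partial batch is kept — desk-scale datasets are small); dropout 0.25 sits
after each block-convolution activation on both paths but not on the
strided/up/classifier convolutions, so the parameter checksum is
unaffected. Batch-norm momentum is scheduled from 0.7 toward 0.9 as
`m(e) = 0.9 − 0.2·exp(−5e/T)`: a literal "decay" from 0.7 to 0.9 is
contradictory (the value increases), so we implement the stated intent —
fast-adapting statistics early, stable statistics late — as an exponential
approach whose rate constant brings m within 0.0014 of 0.9 at e = T. The
checkpoint with the lowest validation loss is kept (validation patches are
not augmented).

Augmentation applies shift (≤10% of the patch side, random sign), rotation
(5–89°, random sign), rescale (1/1.2–1.2; factor > 1 crops the central
`round(512/f)` region and upscales, factor < 1 downscales and mirror-pads),
flip (horizontal or vertical), Gaussian blur (SD 0–4 px, image only) and
elastic deformation (per-pixel uniform [−1,1] fields smoothed with σ = 4
and scaled by α ∈ [1,8]) — in that order, each independently with
probability 0.5 (a standard default; the application probability is
configurable). All geometric warps use mirror fill, bilinear for the image
and nearest-neighbor for the label.

## Inference

Overlap-tile segmentation: the image is resampled to the working pixel
size, mirror-padded by the overlap d (default 25 px) on all sides plus a
remainder to a multiple of the emitted core (512 − 2d = 462), and each
512×512 window is normalized per window (matching training) and passed
through the network; only the central core of the probabilities is kept.
Cores tile the image exactly once. Stitched probabilities — not labels —
are resampled bilinearly back to the native resolution before the argmax,
which honors bilinear resampling without producing invalid label values.

## Evaluation metrics

Dice `2|A∩B|/(|A|+|B|)` per class (defined as 1 when both masks are
empty), pixel-wise accuracy over the three classes, and object-level
detection: 8-connected components of the axon class, each predicted
object's centroid (rounded to the nearest pixel) assigned to the
ground-truth object containing it. TP = truth objects containing ≥1
predicted centroid, FN = truth objects containing none, FP = predicted
objects whose centroid lies in no truth object plus surplus centroids
beyond the first in one object (so both misses and over-segmentation are
penalized). Sensitivity TP/(TP+FN) and precision TP/(TP+FP) are reported
as 0 with an explicit flag when their denominator is zero. Centroid
containment can fail for pathologically non-convex objects whose centroid
falls outside themselves; for the compact axon cross-sections this rule
targets, that case does not arise.

## Morphometry

Per-axon records come from 8-connected axon components: area in µm²
(pixel count × pixel_size²), centroid, equivalent diameter √(4·Area/π).
Aggregate maps use square bins of 50×50 µm² by default: axon diameter mean
and SD (unweighted over the axons whose centroid falls in the bin, so each
axon counts exactly once), axon density (centroid count per mm²), axon and
myelin volume fractions (AVF, MVF; pixel fractions), and the aggregate
g-ratio √(1/(1 + MVF/AVF)). Bins that are partial (image side not a bin
multiple), axon-free, or below 50% coverage of an optional region mask are
flagged invalid rather than rescaled.

## Synthetic data generator

The generator emulates osmium-stained EM at desk scale: fibers are
annuli — an axon disk of diameter d inside a myelin ring out to d/(2g) —
with log-normal diameters (median 3 µm, log-SD 0.3, optionally truncated
below) and truncated-normal g-ratios (mean 0.7, SD 0.05, bounds 0.4–0.95),
matching the 0.5–0.75 range typical of healthy white matter. Centers are
dart-thrown with rejection so outer circles never overlap (a 2-pixel
margin keeps rasterized fibers 8-disconnected, making the fiber count an
exact ground truth); rasterization samples pixel centers (no
anti-aliasing, so masks stay 3-valued); rendering assigns class-wise mean
intensities (myelin-bright for SEM-like, myelin-dark for TEM-like), then
Gaussian blur (0.7 px), Gaussian noise (SD 8) and clipping to [0,255].
The default canvas is 102.4 µm at 0.1 µm/px (1024² px) so patching is
exercised. The generator does not model subcellular texture, unmyelinated
axons, staining gradients or pathology; tests passing on this data show
the pipeline's mechanics and trainability, not performance on real tissue.

## Desk-scale problem sizes

The test suite trains a width-reduced TEM variant (base width 4 —
explicitly a config override; the full-width architecture is still built
and checksummed) for 30 epochs on 32 synthetic 512×512 patches (22
train / 10 validation) from eight 1024² scenes. All other training
hyperparameters keep their defaults; augmentation is off for this
noiseless, perfectly-labelled data. The trained model is evaluated on a
held-out synthetic scene (axon/myelin Dice) and reused for the
stitching-robustness check (overlap 25 vs 50). Gradient checks run on a
depth-2, width-2 float64 model at 8×8 resolution.

## Known limitations

* Single-channel 8-bit input only; anisotropic pixel sizes are out of scope.
* The engine is single-threaded CPU code: full-width training at realistic
  dataset sizes is not its purpose; it exists to make the architecture,
  training procedure and inference pipeline exact, testable and
  dependency-light.
* The centroid-matching detection rule has no distance tolerance; merged
  axons in a prediction count as one TP plus FNs for the missed objects.
* The g-ratio map is an aggregate estimate from volume fractions, not a
  per-fiber pairing of axons with their own myelin sheaths.
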