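# Methods

This note documents the models, numerical choices and limitations behind
`pfseg`, in the order the pipeline runs.

## Radiometric calibration and windowing

A radiometric frame is a 16-bit integer count field.  Two black-body
references at known set points (defaults 28 °C and 36 °C) define the unique
affine count→temperature map through the (mean count, set point) pairs of
the two reference regions; the map is fitted per frame and applied
pixelwise.  Affine is the minimal model two references can determine; no
emissivity, lens-distortion or non-uniformity corrections are attempted.
The region statistic is the mean by default (`statistic="median"` is
available for patches with outlier pixels).  Identical region means raise a
degenerate-calibration error rather than producing an unbounded slope.

Temperatures become gray values through a fixed temperature window of width
10 °C: `v = (T − (center − width/2)) / width`, clipped to [0, 1].  The
default center is 32 °C, the midpoint of the two reference set points; both
center and width are configurable.  With this default the 22 °C ambient
background windows to exactly 0, so early frames are almost entirely black —
the regime the adaptive enhancement has to cope with (see below).
Calibration targets are removed by taking the largest axis-aligned sub-image
that intersects no reference region (exact exhaustive search over candidate
region-edge rectangles; obstacle counts are tiny).  All pixel regions use
0-based, half-open row/column intervals.

## Two-stage adaptive gamma transform

Per image, the empirical CDF over 256 uniform intensity bins (configurable)
yields x₀ (CDF = 0.5) and x₁ (CDF = 0.75) under a step rule: the smallest
bin upper edge whose CDF reaches the quantile.  The step rule recovers data
values exactly when they sit on a bin edge (a constant-0.5 image gives
x₀ = 0.5, hence γ = 1 and an unchanged image) and is within one bin width of
any interpolated variant.  The contrast ratio β = (x₁ − x₀)/max(x₀, ε) uses
ε = 1e-6 so an all-black frame (x₀ = 0) is well defined: its enormous β
routes to the β > 1 branch, where γ = 1/(0.5 + 0) = 2 merely darkens an
already-black frame.

The exponent is chosen per regime:

* β ≤ 1 (flat histograms; early dark frames): γ = 0.5 + x₀ for x₀ ≤ 0.5,
  γ = 1/(1.5 − x₀) for x₀ > 0.5 — brightens dark-keyed images;
* β > 1 (strong upper-quartile spread; late frames): the pointwise
  reciprocal — compresses bright-keyed images.

"Two-stage" refers to these two β regimes selected per image, not to two
sequential transforms.  The two branches are exact reciprocals at every x₀,
are each continuous on [0, 1], meet at γ = 1 when x₀ = 0.5, and stay
strictly positive.  The transform is applied after cropping, so calibration
patches never bias the image statistics.

Baselines for comparison harnesses: fixed-exponent gamma, histogram
equalization (scikit-image), and a one-regime "adaptive" variant that always
applies the β ≤ 1 formula.  The comparison table computes MSE/PSNR between
each enhanced image and its original (the untransformed row has no reference
pair and reports empty cells), and MSE/PSNR are expressed on the 8-bit
(0–255) intensity scale.

## Network

The segmentation network is a U-shaped encoder–decoder built from residual
U-blocks with nested dense skips, attention gating and multi-side-output
fusion.

**Input stem.**  7×7 stride-2 convolution → batch norm → ReLU → 3×3
stride-2 max pool; each spatial side shrinks by 4 before the block ladder.

**RSU-L blocks.**  An RSU applies a local 3×3 transform F₁ and adds the
output of an internal L-level U-shaped sub-network fed with F₁:
out = F₁(x) + U(F₁(x)).  The plain variant pools L−1 times internally
(requiring ≥ 2^(L−1) pixels per side; violating this raises a configuration
error); the dilated variant replaces pooling with dilations 1, 2, 4, …, so
every internal map keeps the input resolution and the block is legal at any
size.  Up-sampling inside blocks and across the grid is bilinear with
`align_corners=False` semantics.

**Grid.**  Encoder rows 0–4 use depths L = 7, 6, 5, 4 and the dilated
variant on row 4, with channel geometry taken from the published full-size
residual-U design (mid channels 32/32/64/128/256, outputs
64/128/256/512/512) scaled by a width multiplier.  Decoder nodes X(i, j)
(j ≥ 1, i + j ≤ 4) concatenate all same-row predecessors with the 2×
up-sampled node below-left, pass the stack through a CBAM gate and a
row-geometry RSU.  `NetworkConfig.scaled(input_size, width_mult)` clamps
each row's L to what the row resolution admits, so 64×64 desk-scale inputs
use L = 5, 4, 3, 2 (+ dilated row 4) while 512×512 inputs get the full
ladder; the forward pass validates the configured input size.

**CBAM.**  Channel attention: a shared two-layer MLP (reduction ratio 16,
clamped to ≥ 1 hidden unit) scores global average- and max-pooled channel
descriptors; sigmoid of the sum scales channels.  Spatial attention: a 7×7
convolution over the channel-wise mean and max maps yields a per-pixel
sigmoid gate.  Both gates lie in (0, 1), so attention only attenuates.

**Side outputs and fusion.**  Nine grid nodes — the encoder column (i, 0),
i = 0..4, and the top decoder row (0, j), j = 1..4 — each get a 3×3
single-channel head resized to input resolution.  1×1 fusion convolutions
combine (concatenation followed by projection, a superset able to learn
plain addition): the top row into Y^(0,5), the encoder column into Y^(5,0),
and those two into the final Y^(5,5).  Eleven sigmoid maps are returned;
the ten non-final maps carry supervision weights (default 1) besides the
fused map.

**Normalization.**  Batch norm uses batch statistics in training and running
statistics (momentum 0.1) in eval mode.  Its eps is 1e-3 rather than the
customary 1e-5: thermal frames are dominated by a near-constant background,
so early feature channels can have almost zero batch variance, and the
larger eps caps the amplification that otherwise destabilizes SGD at
practical step sizes.

**Autodiff engine.**  The network runs on a package-internal reverse-mode
engine (`pfseg.autograd`) offering exactly the required operator set
(im2col convolution, max pooling, matrix-form bilinear resampling, fused
batch norm, attention reductions, logit-space BCE).  All operations are
deterministic; forward passes, training curves and checkpoints are
bit-for-bit reproducible under fixed seeds.  Gradients of every operator are
verified against central finite differences in the test suite.

## Loss

Training minimizes the weighted sum of per-map binary cross-entropies over
the ten supervised side maps plus the fused map.  The optimization loss is
computed in logit space (softplus form) for stability and averaged per
pixel, which keeps gradient magnitudes independent of image size; the
metric-level `bce` is the pixel-summed probability form with probabilities
clipped at ε = 1e-7.  The two differ only by the fixed factor N_pixels.

## Metrics

DSC and IoU use the standard count ratios with the both-empty case defined
as 1.  The Hausdorff distance is computed between mask boundaries (a mask
minus its 3×3 erosion) with Euclidean pixel distances via a k-d tree; tests
cross-check an exhaustive all-pairs oracle.  Because overlap scores and raw
HD live on different scales, a normalized convenience score
1 − HD/diagonal (clipped to [0, 1], higher better) is also exposed; it is a
package convention, clearly labeled, not a standard definition.
Predictions are binarized at 0.5 on the fused map.

## Phantom generator

The generator emulates the acquisition the pipeline targets: 22 °C constant
background; two mirror-symmetric feet (ellipse sole + five toe disks,
~28 % of the frame) rewarming from 18 °C toward 36 °C as
T(t) = T_end − (T_end − T_start)·exp(−t/τ) with τ = 180 s, so a 600-frame
1 Hz sequence spans the full dark-to-bright contrast evolution; additive
Gaussian noise with σ = 0.04 °C (the camera's NETD); black-body strips held
at 28/36 °C at the frame margins; optionally one to three Gaussian
temperature offsets inside the feet (±1.5 °C) emulating patchy cooling.
The foot-background crossing time τ·ln((T_end−T_start)/(T_end−T_bg)) ≈ 45 s
is the minimum-contrast instant and is checked in closed form.

What the phantom does *not* model: anatomy (silhouettes are stylized),
perfusion or thermoregulation physiology, subject motion, focus blur, or
camera non-uniformity.  Passing tests therefore demonstrate correctness of
the pipeline mechanics and the directional behavior of the enhancement, not
clinical segmentation accuracy.

Dataset assembly windows each sampled frame (one in ten by default —
consecutive frames differ only slightly), crops the calibration strips,
optionally doubles the set by horizontal flipping, and splits 85/5/10 **by
sequence** (floors for train/val, remainder to test, each bucket at least
one sequence): splitting by frame would leak near-duplicates between
buckets.

## Training recipe and desk-scale demonstration

The optimizer is SGD with momentum 0.9 and weight decay 1e-4.  Batch size
is a required setting with no default because the protocol this package
follows reports two conflicting values (5 and 8); the demonstration runs
use 5.  The learning rate is not reported upstream; the library default is
1e-3 and the desk-scale demonstrations use 5e-3 (stable under the eps-1e-3
batch norm).  `patch_size` is recorded in the config for provenance but has
no role in a purely convolutional network.  Best checkpoints are selected
on validation Dice; checkpoints embed an architecture hash and loading
refuses a mismatched configuration.

`demo_run` is the end-to-end seeded demonstration at the scale this package
uses for its own verification: one phantom sequence, two-stage enhancement,
a 1/8-width network at 64×64, 10 training frames, 300 SGD steps.  Two frame
selections are exposed: `stage="mixed"` spreads the training frames over
the whole recovery (the easiest learning problem; reaches training Dice
≈ 0.96) and `stage="early"` (default) trains on the first visible
low-contrast segment — the regime the adaptive enhancement targets, and the
setting in which enhancement-consistent inference (enhance at train time ⇒
enhance at test time) measurably outperforms feeding the same model raw
frames.  On dark frames the β > 1 branch compresses the near-empty dark
histogram, so enhancement strictly lowers mean 256-bin entropy there; on
late bright frames it can raise entropy while increasing foot/background
separation.

## Known limitations

* The phantom's simplicity makes segmentation easy at convergence; model
  ranking experiments (against other architectures) are out of scope.
* The numpy engine is single-threaded BLAS-bound; full-scale (512×512,
  width 1.0) training is possible but slow, and the package's own runs use
  the scaled configurations described above.
* The normalized Hausdorff score is a documented stand-in for mixed-scale
  reporting, not a community-standard metric.
* Automated quality control (blur/posture rejection) is not implemented;
  phantom sequences contain no such artifacts.
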