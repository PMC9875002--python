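# Methods

## The model

The package implements a dual-encoding, multiscale-feature-fusion
encoder–decoder for binary segmentation of low-contrast grayscale slices
(the motivating application is lesion segmentation in abdominal CT). One
preprocessed image enters the network twice: the full-resolution view
feeds a path of *single dense aggregation blocks* (SDAB) through a
stride-2 stem, and a half-resolution area-averaged view feeds a path of
bottleneck *residual blocks* (RB) through a stride-1 stem. The two stems
place both paths on the same spatial grid, so all later fusion is pure
channel concatenation.

**Residual block.** `ReLU(x + BN(conv1x1(conv3x3(conv1x1(x)))))` with the
inner width reduced by `rb_bottleneck_ratio` (default 4). The identity
skip requires the block input to already have the level's nominal width;
a 1×1 transition after each pooling step guarantees this.

**Single dense aggregation block.** A chain of `L` 3×3 convolutions of
constant width `sdab_growth`; each layer consumes only its immediate
predecessor, and all `L` outputs are concatenated once at the block's
end (the block input is excluded from the aggregation). A 1×1 projection
returns the `L·growth` concatenation to the level width. Compared to a
dense block this keeps the shallow features available to the aggregation
while avoiding the quadratic growth of intra-block connections.

**Multiscale fusion block.** At level *i* with path outputs `I1, I2` and
previous fused outputs `O1_prev, O2_prev`:

    O1 = proj(concat[I1, I2, down(O1_prev)])
    O2 = proj(concat[I2, I1, down(O2_prev)])

where `down` is a 2×2 max-pool followed by a 1×1 projection to a fixed
`carry_width`. Level 1 has no carry terms; the last level's fused outputs
feed only the bottleneck and decoder, not a further encoder level.

**Decoder.** From a 1×1-projected concatenation of the deepest fused
pair, each step is: bilinear 2× upsample → 3×3 conv to the level width →
concatenate a 1×1-projected `concat[O1, O2]` skip → coordinate attention
on the concatenation → two 3×3 conv+BN+ReLU. A 1×1 head, sigmoid, and a
final 2× upsample produce probabilities on the full-resolution grid.

**Coordinate attention.** Per-channel row means (C×H×1) and permuted
column means (C×W×1) are concatenated along the spatial axis, encoded by
a shared 1×1 conv + BN + non-linearity at `channels/ca_reduction` width,
split back, and expanded by two 1×1 convs with sigmoid into row and
column gates that multiply the input. The non-linearity is hard-swish by
default (the convention of the attention design this follows), with ReLU
as a config option. The BN over the concatenated H+W axis is shared
rather than split, since the encoder is a single 1×1 convolution.

## Width calibration

The architecture's text-level description leaves four widths free:
`base_width`, `sdab_growth`, `carry_width` and `bottleneck_width`. They
were calibrated once, analytically, against the published trainable-
parameter totals for dense-chain depths L = 4/6/8/10 (13.24 / 14.97 /
16.69 / 18.42 M). The count is exactly affine in L,
`count(L) = A + B·L`, where `B` sums `9g² + 2g + g·w` over the four
levels (3×3 conv + BN of one extra chain layer, plus its slice of the
1×1 projection). With widths doubling from `base_width = 64` and a
constant growth, `g = 142` gives `2B = 1,726,720`, matching the equal
~1.73 M printed increments; `carry_width = 304` and
`bottleneck_width = 1024` then place the absolute level `A` so that all
four totals round to the printed values, with every conv that precedes a
BatchNorm biasless and BN contributing two affine scalars per channel.
These are the package defaults; `count_parameters` reproduces the table
from a freshly built network, and equality of the three increments is
asserted exactly.

## Training

SGD with momentum 0.9, weight decay 1e-4 (applied to convolution weights
only by default — normalization affine parameters and biases are
excluded, with a flag to include them), batch size 8, and the polynomial
schedule `lr = initial_lr · (1 − iter/max_iter)^0.9` from
`initial_lr = 0.001` over 6,500 iterations. The loop is iteration-based
with an infinite reshuffling sampler; "one iteration" is one optimizer
step. The loss is the smoothed soft-Dice form
`1 − (2Σxy + 1)/(Σx² + Σy² + 1)`, computed per sample and averaged over
the batch; the +1 smoothing makes the empty–empty case a perfect score
and keeps the loss differentiable everywhere. Validation mean DSC is
evaluated every `eval_every` (default 50) iterations and the best
checkpoint is restored at the end; predictions are thresholded at 0.5.

Data management follows an 80/20 train/test split and 5-fold
cross-validation with a 4:1 train:val ratio inside the 80% pool; the
five validation sets partition the pool and the test set is identical
across folds.

### Numerical backend

The network, its gradients, and the optimizer are implemented directly
over NumPy: convolutions via im2col and BLAS matmul, hand-derived
backward passes for every primitive (convolution, batch normalization in
both training and eval mode, 2×2 max-pooling, bilinear 2× upsampling
with half-pixel centers, axis means, concatenation/slicing, the
pointwise non-linearities), assembled by a small reverse-mode autodiff
graph. Every primitive's backward pass is verified against central
finite differences in the test suite at tolerance 1e-6. All arithmetic
is float64; on a single device, runs with fixed seeds are bit-identical.

## Preprocessing

**Cropping** centers the window on the mask centroid (image center for
empty masks), clamped to the image; image and mask are cropped
identically, so a full-size target is the identity and cropping is
idempotent.

**Masked-histogram CLAHE.** Standard contrast-limited adaptive histogram
equalization with one addition: per-tile histogram statistics exclude
pixels below `background_threshold` (the near-black scanner background)
and the `tail_clip` extreme fraction at each end, so the contrast budget
is spent on tissue intensities. Each tile histogram is clipped at
`clip_limit` times the uniform bin height with the excess redistributed
uniformly (single pass), mapped through its CDF, and pixel values are
bilinearly blended between the four nearest tile-center mappings. Tiles
whose pixels are entirely filtered out fall back to the identity
mapping; an image with no surviving pixels anywhere is returned
unchanged with a warning. Defaults: clip 2.0, 8×8 tiles, 256 bins,
background threshold 0.05, tail clip 0.005 per side — conventional CLAHE
settings plus the masking thresholds, which the source description
names but does not quantify. In the degenerate limit (one tile, no
clipping, no masking) the operation reduces exactly to global histogram
equalization, which the tests exploit as an oracle.

**Dual input.** The low-resolution view is 2×2 area averaging (not
strided subsampling), avoiding aliasing that would differ between image
libraries.

**Augmentation.** With probability `augment_probability` (default 0.5):
rotation drawn uniformly from ±25°, bilinear for the image and
nearest-neighbor + re-binarization for the mask, plus additive Gaussian
intensity noise (default σ = 0.02) on the image only, clipped to [0, 1].
Mixup forms convex combinations of image pairs *and* their masks with
λ ~ Beta(0.2, 0.2); the resulting soft mask feeds the Dice loss
directly, which is well-defined on real-valued targets. None of these
settings are pinned by the source description; the defaults are the
common practice values.

## The phantom generator

`phantoms` emulates what matters about the clinical images for
exercising this pipeline: a near-zero border (so masked-histogram CLAHE
has a background to ignore), a mid-gray tissue region
(`tissue_level = 0.45`) with smooth Gaussian-filtered texture
(σ = 0.02, correlation length 8 px), and 1–3 lesions per slice whose
intensity sits only `lesion_contrast = 0.12` above tissue, under
additive pixel noise σ = 0.03 — visibly low-contrast, but learnable by a
small network on CPU. Lesions are ellipses with low-order sinusoidal
boundary perturbation (modes 2–4, amplitude ≤ 5% each), producing
irregular outlines without any CT physics. Masks are exact: the mask is
1 precisely where the lesion indicator was rasterized. Same spec + same
seed gives bit-identical output; datasets derive per-image seeds from a
splittable seed sequence.

What the phantoms do *not* emulate: 3D anatomy and partial-volume
effects, CT noise correlation and artifacts, HU calibration, organ
context, or inter-observer label noise. Tests passing on phantoms
demonstrate that the pipeline's machinery (preprocessing, optimization,
metrics, ablation switches) is correct and trainable — not that the
architecture reaches any particular accuracy on clinical data.

## Test-scale choices

The overfit fixture trains a reduced configuration (base width 8, L = 4,
growth 8, carry 16, bottleneck 128) on 32 phantoms of 64×64 for 300
iterations at batch 8 with fixed seeds, and requires training mean
DSC ≥ 0.90. The learning rate for this fixture is 0.05: the tiny
network's full-recipe rate of 0.001 is tuned for a 18M-parameter model
over 6,500 iterations, and scaling it up is the normal choice for a
short overfit run. Ablation variants (fusion off, attention off, either
encoder path replaced by plain convolutions) are trained briefly on the
same fixture to verify they build and optimize.

## Known limitations

- CPU-only and float64: full-recipe training (6,500 iterations at
  512-channel widths) is far slower than a GPU framework; the package is
  sized for method verification and small studies, not clinical-scale
  training.
- The dense-chain non-linearity order is implemented conv→BN→ReLU by
  default for numerical sanity; the literal conv→ReLU→BN reading is
  available via `theta_order="act_first"`.
- Aggregates report mean ± population std over test images (matching the
  per-image framing of the DSC distribution summaries); std over CV
  folds is not implemented.
- Undefined metrics (e.g. sensitivity on an empty ground truth) are
  excluded from aggregates and counted, not imputed.
- No 3D volumes, DICOM, boundary metrics, transposed convolutions,
  pretrained weights, or multi-GPU support.
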