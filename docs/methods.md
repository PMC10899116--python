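# Methods

## Model

The segmentation network reads one H&E patch at x20 (~0.45 µm/px) and
produces a 7-class probability map (non-tumor + the six LUAD growth
patterns).  Three encoder streams see the patch at x10, x5 and x2.5,
obtained by area-average (block-mean) downsampling with factors 2/4/8 —
area averaging is alias-free and exactly testable against a brute-force
block mean.

Each stream is a reduced-width residual encoder: a 3x3 stem (stride 1),
then three stages of bottleneck blocks (1x1 reduce → 3x3 → 1x1 expand, with
batch normalization and projection shortcuts), two blocks per stage, stride
2 at each stage transition, stage widths (48, 96, 192) x `width_multiplier`.
The streams do **not** share weights; with three resolutions the streams
see genuinely different statistics, and independent weights keep the
ablation arithmetic (which toggle owns which parameters) exact.

Cross-stream coupling:

- **First-order attention** (stage 1): the coarse stream's stage-1 features
  are globally average-pooled and passed through a two-layer bottleneck
  (width C → C/4 → C) with a sigmoid output; the resulting per-channel gate
  in (0,1) rescales the fine and intermediate streams' stage-1 features.
  A zero pre-activation therefore halves the gated features
  (sigmoid(0) = 0.5), which the tests exploit as a closed-form anchor.
- **Depth alignment**: after stage 3 the coarse and intermediate outputs
  pass through a 1x1 convolution and are bilinearly resampled to the fine
  stream's grid (1/16 of the patch edge).
- **Pyramid pooling** on the fine stream: for bins (1, 2, 3, 6), adaptive
  average pooling, 1x1 reduction to C/4 channels, ReLU, bilinear upsampling
  back to the grid; branches are concatenated with the input and fused by a
  3x3 convolution.
- **Second-order attention**: each stream is projected by a 1x1
  convolution; for every ordered pair of distinct streams the CxC Gram
  matrix of flattened features, scaled by 1/sqrt(HW) and row-softmaxed,
  reweights the channels of the second stream; the fused map is the sum
  over pairs.  For identical constant inputs the softmax rows are uniform
  and the output reduces to channel means — another closed-form anchor.

The decoder applies two 3x3 conv + BN + ReLU + bilinear x2 stages, a 1x1
head to 7 logits, and a final bilinear x4 to the input resolution.  Labels
are the per-pixel argmax, ties broken toward the lowest class index
(numpy's argmax convention, documented rather than accidental).

Ablation variants are configuration values: `n_streams=1` (single-stream),
`fusion="add"` (plain summation), `"fo"`, `"so"`, `"fo+so"` (the reference
model).  Instrumentation counters record whether the attention operators
ran, so "add never invokes attention" is a testable contract.

The **width multiplier of the reference configuration is 1.67**, calibrated
once so the trainable parameter count is 4.10 million to two decimals
(4,098,725), and frozen.  The parameter count is the only quantity the
reference width is asked to reproduce; all training in the test-suite uses
reduced widths.

## Training

Pixel-wise cross-entropy minimized by Adam with the step-wise schedule
1e-3 / 1e-4 / 1e-5 over epochs 1-10 / 11-50 / 51-60 (batch 8).  Shortened
runs keep the 1:4:1 phase proportions via `TrainSchedule.scaled`.
Augmentation jointly applies one sampled geometric transform (rotation
within ±90°, shifts up to 20%, zoom in (0.8, 1.2)) to image and mask —
reflect fill for the image, class 0 for the mask — and saturation (0.8-2.0)
/ hue (±0.1) jitter to the image only.  An identity policy is bit-exact,
which pins the augmentation path in tests.

The network, its layers and Adam run on a minimal numpy reverse-mode
autograd core (`anorak.nn`): conv2d via im2col/matmul, bilinear resampling
as two separable interpolation matrices (hence an exact adjoint), batch
normalization with the standard analytic backward.  Gradients are verified
against central finite differences in float64.

## Whole-slide inference

Slides at x20 are divided into 2000-px tiles, non-overlapping except that
bottom/right edge tiles anchor to the slide edge.  Each tile is normalized
(below), chopped into network patches with the same edge rule, predicted,
and stitched; the stitched x20 label raster is downsampled 16x to the
~7.2 µm/px analysis mask by per-block majority vote (ties to the lowest
class index — majority preserves minority islands far better than
nearest-neighbour at 16x).  Postprocessing removes connected components
(8-connectivity) strictly below 0.05 mm² for lepidic and 0.015 mm² for
papillary, cribriform and solid; acinar and micropapillary are never
filtered.  The filter is idempotent and never increases any class's count.

`infer_slide(..., context_px=c)` optionally predicts each patch from a
reflect-padded halo of c pixels and keeps only the center: patch-seam
artifacts (single-pixel spurious fragments exactly on patch borders)
disappear with c = 32.  The default is c = 0 (plain chopping).

Color normalization is Reinhard-style statistics matching in CIELAB: the
tile's per-channel mean/std are affinely mapped onto a target.  The default
target (L*, a*, b* mean (78, 12, −9), std (10, 8, 7)) was chosen near the
center of the synthetic tile family and deliberately *gamut-safe*: the
matching is exactly idempotent only while the affine map stays inside the
sRGB gamut, so a moderate target spread matters more than fidelity to any
particular reference image.  Tiles with near-zero variance (blank glass)
are returned unchanged.  Note that normalizing tiles that are mostly glass
stretches background noise into tissue-like colors; the synthetic
end-to-end runs therefore disable normalization (the caricature palette is
already uniform), which is what the `normalize` flag is for.

## Grading

Tumor-level proportions pool pixel counts over slides
(`g_j = Σ_i S_ij / Σ_i Σ_j S_ij`); the package never averages per-slide
proportions, and the synthetic tumor generator builds deliberately uneven
slide mixes so the two disagree in tests.  Non-tumor pixels are excluded
from the denominator.  Predominance ties break toward the more aggressive
pattern (solid > micropapillary > cribriform > acinar > papillary >
lepidic) — clinically conservative.  The 20% high-grade boundary is
evaluated with exact rational arithmetic on pixel counts (`Fraction`), so
"exactly 20%" is grade 3 without float flips.  Shannon diversity uses the
natural logarithm; kappa statistics are computed with exact fractions and
cross-checked against scikit-learn (Cohen) and statsmodels (Fleiss).

## Spatial statistics

Islands are 8-connected components at analysis resolution.  Centroids are
unweighted means of member pixel centers; solidity divides the pixel count
by the number of pixels whose centers lie in the convex hull of the member
pixel centers (Delaunay point-inclusion; degenerate collinear islands fall
back to the integer points on the extreme segment).  The acinar scattering
score is the standard distance of island centroids normalized by
`sqrt(n·N)`; N defaults to the non-background pixel count of the mask and
can be overridden with an external tissue mask.  d is dimensionless,
translation-invariant and invariant to scaling coordinates by s with N by
s²; d = 0 for a single island, and an empty island set raises rather than
returning 0 (no acini is not the same as clustered acini).  Tumor level:
mean island area/solidity pooled over slides (reported only when the
tumor's acinar share is ≥ 5%), median of per-slide d over slides with ≥ 1
island (empty slides excluded, not imputed), dichotomized at the fixed
cutoff 0.36 with strict `>` for "high".  The cutoff is a configurable
constant; selecting it from data is out of scope.

## Synthetic data

The generators are pure functions of (spec, seed).  Pattern tiles render
H&E *caricatures*: solid = dense dark nuclear sheet; cribriform = dark mass
punched by small lumina; acinar = nuclear rings around secretion-tinted
lumina in pink stroma; papillary = thick pink cores rimmed by nuclei in
airspace; micropapillary = small detached tufts in cooler, cleft-like
airspace; lepidic = thin curvilinear septa in airspace.  Intratumoral
airspace is faintly tinted relative to background glass — real airspace
within tumor carries septal walls and debris, and a locally learnable
tissue/glass distinction is what makes the white-dominant patterns
segmentable at all.  Each pattern has a distinct white-lumen fraction, the
documented one-statistic separation the tests assert.  These textures
support overfit and round-trip testing; they are **not** histologically
realistic and must not be used as a benchmark.

Island layouts place exact-geometry shapes (squares and L-shapes hit the
target pixel count exactly; discs/ellipses within 2% via a fine scan over
radius and sub-pixel center) and emit the realized pixel counts, centroids,
hull counts and solidities, which the analysis layer must recover exactly.
Multi-slide tumors apportion pooled pattern counts by largest remainder
(pooled proportions within one pixel of target) and split each pattern
unevenly across slides with a Dirichlet draw.

## Scales used by the test-suite

All sizes are package choices documented here: unit and property tests use
tiny networks (width 0.25) and 128-px tiles (the smallest edge compatible
with the /64 stride chain and pyramid bin 6).  The overfit check trains the
full three-stream fo+so network at width 0.75 on twenty 128-px
single-pattern tiles for 30 epochs (scaled schedule, fixed seeds) and
reaches macro Dice ≈ 0.91 over the six patterns (threshold 0.70).  The
end-to-end check trains a width-0.5 network on 44 tiles (20 single-pattern,
20 Voronoi-mosaic, 4 glass) for 180 epochs with batch 4 — mosaic and glass
tiles are what force local texture learning rather than tile-level
memorization — then renders a 4000x4000 slide (five acinar discs, one
solid and one lepidic region), segments it with a 32-px context halo, and
recovers the constructed predominant pattern (acinar), grade (3), island
count (5) and scattering class (high) exactly; per-class Dice on that slide
is ≥ 0.95 for lepidic/solid and ≈ 0.95 for acinar.

## Limitations

The autograd core is single-threaded numpy: full-scale 768-px, width-1.67
training is far outside its intended envelope — it exists to make the
architecture, loss and schedule executable and verifiable at desk scale.
Synthetic textures do not model stain variability, tissue artifacts,
mucinous or preinvasive morphologies, or inter-pattern transitions; passing
the synthetic end-to-end check demonstrates that the pipeline's plumbing
and analytics are correct, not that the model generalizes to real H&E.
Tiles are predicted independently (no overlap blending); the optional
context halo mitigates, but does not eliminate, boundary effects.
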