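# Methods

## The screening model

`fundus_vcdr` implements a structural-biomarker pipeline for glaucoma
screening from color fundus photographs.  The biomarker is the **vertical
cup-to-disc ratio** (vCDR): the vertical diameter of the optic cup divided
by the vertical diameter of the optic disc.  Glaucomatous damage enlarges
the cup relative to the disc, and the pipeline classifies an eye as
glaucoma-suspect when vCDR > 0.5 (strictly; a ratio of exactly 0.5 is
classified normal).  The pipeline has four stages:

1. **Detection** — locate the optic disc on the full frame and keep one
   box per image (confidence threshold 0.5, then greedy non-maximum
   suppression at IoU 0.3; the low NMS threshold deliberately removes
   duplicates even under small overlap, since each image contains exactly
   one disc).
2. **Square ROI crop** — expand the box by a 70-pixel margin on all four
   sides, take the larger of the expanded width/height as the side of a
   square window centered on the expanded box, and shift (never shrink)
   the window back inside the frame if necessary.  Squareness is a
   functional requirement, not cosmetics: the segmentation stage resizes
   its input, and only an isotropic resize leaves the cup/disc diameter
   ratio unchanged.
3. **Segmentation** — a U-shaped encoder–decoder assigns each ROI pixel
   one of three classes (0 background, 1 disc rim, 2 cup), trained with
   soft multi-class Dice loss under Adam.
4. **vCDR and classification** — the predicted mask's disc and cup
   regions are replaced by their least-squares ellipses (smoothing ragged
   network output), vertical diameters are measured as raster row extents,
   and the 0.5 rule is applied.

Throughout, the *disc region* means the union of labels 1 and 2: the cup
lies inside the disc anatomically, so label 1 alone is only the
neuroretinal rim.

## Vertical diameter convention

The vertical diameter of a region is the number of raster rows it touches
(inclusive row extent).  This is integer-exact, orientation-locked to the
image y-axis, and coincides with the vertical axis of an axis-aligned
ellipse to within one pixel.  It also makes the crop-invariance contract
exact: any crop that contains the whole disc leaves both row counts, and
hence the vCDR, unchanged.  A mask with no cup yields vCDR 0 with a
degeneracy flag; a mask with no disc raises an explicit error — 0/0 is
never silently reported.

## Ellipse refitting

For each of the disc region and the cup, the largest 8-connected
component is taken (size ties broken by the component whose first pixel
comes earliest in row-major order), its sub-pixel boundary is extracted,
and a least-squares ellipse is fit to the boundary points.  The output
mask rasterizes the cup ellipse interior as 2 and the disc-ellipse
interior minus the cup as 1, with the cup always clipped to the disc
interior.  An ellipse has five degrees of freedom, so a component with
fewer than five boundary pixels is declared degenerate and its raw region
is passed through unchanged; a mask with no disc pixels at all produces
an all-background mask with the degeneracy flag set.  On masks that are
already two nested ellipses the refit is idempotent to within 1% of
pixels (the residual disagreement is boundary rasterization).

## The segmentation network

No deep-learning runtime is used: the network's forward and backward
passes are written directly in numpy (im2col convolutions), which keeps
training deterministic on CPU under a single seed.  The architecture is
the standard U shape: per level, two 3×3 same-padded convolutions with
ReLU; 2×2 max-pooling between encoder levels; nearest-neighbor ×2
upsampling with a skip concatenation from the matching encoder level in
the decoder; a 1×1 convolution and per-pixel 3-way softmax head.  He
initialization.  Three presets set the base width and depth —
small (8, 2), medium (16, 2), large (24, 3) — giving strictly increasing
parameter counts; they play the role that backbone choices play in the
transfer-learning literature, but are trained from random initialization.

The loss is 1 − mean over the three classes of the soft Dice coefficient
(2·Σpt + ε)/(Σp + Σt + ε) with ε = 1e-6.  The background class is
included in the mean, not ignored.  The analytic gradient is verified
against central finite differences in the test suite.  Masks are always
resampled nearest-neighbor (labels are categorical); images bilinearly.

Defaults follow the training protocol the pipeline emulates: Adam,
batch size 2, 100 epochs, learning rate 5e-5, input 224×224.  The
package's own smoke-scale demonstrations use input 112×112 and learning
rate 5e-4: a from-scratch randomly initialized network (no pretrained
encoder) needs a larger step than a fine-tuned one to overfit a small
set within 200 epochs, and 112 px keeps a full training run in minutes
on one CPU core.  At those settings the small preset overfits 8 synthetic
ROI crops to hard Dice ≈ 0.96–0.98 for disc and cup, with the loss trace
non-increasing over every 20-epoch window up to fluctuations < 0.02.

## Detection and evaluation

The built-in detector is an explicitly non-learned stand-in that exploits
the optic disc's defining photometric property — it is the brightest
large structure in the frame: grayscale → Gaussian smoothing (σ = 5) →
threshold at the 95th intensity percentile → 8-connected components →
one box per component with pseudo-confidence equal to the component's
mean smoothed brightness normalized to [0, 1].  Genuine discs score far
above the 0.5 confidence cut; dim speckle falls below it.  Externally
produced detections can be substituted via YOLO-txt files.

Boxes are half-open pixel intervals ([x_min, x_max) × [y_min, y_max),
0-based, origin top-left), which makes areas and IoU integer-exact and
the conversion to center/size-normalized YOLO encoding lossless to float
rounding.  Average precision uses 101-point interpolation (precision
envelope made monotone from the right, averaged at recall 0, 0.01, …, 1);
mAP@0.5–0.95 averages AP over the IoU ladder 0.50:0.05:0.95.  Matching is
greedy in descending confidence with strict IoU > threshold, one
ground-truth box per prediction.  Crop arithmetic is snapped to a 1e-3
pixel grid before integer rounding so that boxes which round-tripped
through 6-decimal normalized annotation files crop identically.

Segmentation metrics are computed from per-class pixel confusion counts,
IoU = TP/(TP+FP+FN) and DSC = 2TP/(2TP+FP+FN), macro-averaged: the metric
is computed per image and then averaged over images.  (Global pixel
pooling is the other defensible convention; macro is declared and fixed
here so numbers are reproducible.)  A class absent from both masks of an
image is excluded from that class's average rather than scored 0 or 1.
Mean IoU includes the background class.  Mean vCDR error is the mean
absolute difference between predicted and true ratios; predictions with
no disc are excluded from it, counted as degenerate, and classified as
predicted-normal.

## The synthetic generator

The generator emulates exactly the features the pipeline depends on: a
bright yellow-orange elliptical disc (semi-axes ≈ 9–13% of the frame,
slightly taller than wide) containing a brighter concentric cup, on a
dark reddish background with mild texture, a ±5% vertical brightness
gradient, dark quadratic-Bézier vessel curves, and additive Gaussian
image noise (default σ = 8 of 255).  The mask is rendered by exact
ellipse-interior tests and never receives noise; the recorded true vCDR
is measured from the rendered mask itself, so downstream recovery is
compared like with like.  Normal eyes draw the vertical cup ratio
uniformly from [0.30, 0.45] and glaucomatous eyes from [0.55, 0.80] —
both clear of the 0.5 boundary so rasterization cannot flip a label; the
ranges are a modeling choice motivated by the clinical rule, not a claim
about any specific dataset's distribution.  Cup-center jitter is capped
at 10% of the free axis difference, which keeps cup-inside-disc
containment provable.  Per-sample seeds are derived from one master seed
by fixed affine increments.

What the generator does *not* emulate — camera vignetting and specular
artifacts, the macula and fovea, peripapillary atrophy, inter-device
color shifts, discs whose brightness ordering is violated — bounds what
passing tests show: they validate the geometry, arithmetic and training
contracts of the pipeline, not clinical performance on real fundus data.

## Augmentation and class balancing

Eight paired image/mask operators: horizontal, vertical and combined
flip; rotation uniform in ±10°; horizontal flip + rotation; translation
uniform in ±1% of each dimension; center zoom uniform in ±10% (output
kept at the original frame size); and a photometric brightness ±20% /
contrast ±10% adjustment applied to the image only, with the fixed affine
form out = clip((in − 127.5)·(1+c) + 127.5 + 255·b).  Geometric ranges
are small on purpose: large rotations or shifts change the apparent disc
and cup extents and thereby the vCDR the labels are based on.  Areas
transformed in from outside the frame are filled with background — the
alternative (reflection or edge replication) would fabricate anatomy.
Each augmented sample's vCDR ground truth is re-measured from its
transformed mask so the label invariant (glaucoma ⇔ vCDR > 0.5) holds
after augmentation.

Minority balancing applies each of the eight techniques exactly once per
minority sample, growing the minority from m to 9m with the majority
untouched; under the 1:9 clinical imbalance this lands exactly at parity.

## Problem sizes and reproducibility

The package's standard demonstration sizes, chosen to keep every run in
minutes on a single CPU core: 640×640 synthetic frames for detection and
cropping; 100-sample corpora for vCDR-recovery and crop-contract checks;
8-image training sets at 112×112 for overfit demonstrations; 2-epoch
64×64 runs for end-to-end reproducibility checks.  Every random choice —
generator, shuffling, augmentation parameters, weight initialization —
flows from explicit integer seeds, and the full pipeline writes
byte-identical CSV outputs when rerun with the same configuration.

## Known limitations

- The detector is brightness-based and will fail on images where the
  disc is not the brightest large structure (severe peripapillary
  atrophy, overexposed borders); it is a stand-in for a learned detector
  behind the same box/NMS/crop interface.
- The vCDR rule is a fixed-threshold screen; no probabilistic output or
  ROC analysis is meaningful for it.
- Horizontal CDR, rim width (ISNT), and vessel-based features are out of
  scope.
- The numpy network trains at desk scale only; it makes no claim to the
  accuracy of GPU-trained pretrained-backbone segmenters on real data.
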