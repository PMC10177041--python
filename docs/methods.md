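# Methods

## The segmentation problem

Post-chemotherapy Wilms tumor specimens mix vital tumor components
(blastema, stroma, epithelium), chemotherapy-induced changes (necrosis,
bleeding, regression) and a spectrum of normal renal and extrarenal
tissues.  The pipeline treats slide analysis as sparse-supervision
semantic segmentation: pathologists outline polygonal regions and tag
them with one of 15 tissue classes; a model learns a per-pixel
classifier from patches inside those polygons; whole images are then
segmented by tiled inference and scored on held-out annotated pixels.

Four further annotation classes — background, anaplasia, adrenal cortex
and adrenal medulla — are parsed but never modeled.  Anaplasia in
particular is a nuclear-morphology call that needs point-level rather
than region-level analysis, and the remaining three are too rare to
learn; readers of annotation files get them dropped with a logged count.

Two coarse "tumor"/"non-tumor" meta-labels partition the 15 classes and
are exposed for optional auxiliary supervision.  They do not enter the
default training objective: nothing in the published recipe pins down
their role, so the partition is data (`ClassTaxonomy.overarching`,
overridable in the serialized taxonomy), not architecture.

## Coordinate and rasterization conventions

Polygon vertices live in 0-based pixel coordinates at the case's base
spacing, x = column, y = row.  A pixel belongs to a polygon iff its
center (col + 0.5, row + 0.5) does, so an axis-aligned square with
corners (10,10)–(20,20) covers exactly the 10×10 pixel block — the
convention is testable against an O(H·W·V) point-in-polygon loop, and
the suite does exactly that.  Where annotations overlap, the highest
annotation id wins ("last drawn"); any fixed rule would do, this one is
auditable.  Rasterizing at a different spacing scales vertices by
base_spacing / target_spacing first.

## Case-exclusive splitting

Annotations from one case must never straddle partitions, so the
70/15/15 split assigns whole cases.  Cases are shuffled by a seeded
permutation of the sorted case-id list (the split therefore depends
only on case ids and the seed, never on annotation order) and cut where
the cumulative annotation count crosses the target fractions, a case on
a boundary going to the side holding its midpoint.  Exact fractions are
unattainable at case granularity; the realized fractions are logged and
are guaranteed within one case-worth of the targets.  Every partition
gets at least one case, which with 3 cases forces one case each.

## Synthetic cohort

The generator emulates the *statistical* structure the analysis
assumes, not histology itself:

* **Layout** — each case is a seeded Voronoi tessellation of uniform
  random sites (default 30 regions on a 256×256 canvas), clipped to the
  image.  Cells are simple polygons, exported verbatim to the ASAP-style
  XML dialect, so the ground truth and the annotation format share one
  geometry.  Edges stay straight; smoothing would buy realism but break
  the exact polygon↔mask correspondence the oracles rely on.
* **Appearance** — every class has a texture model: an H&E-plausible
  mean RGB with per-region jitter, per-pixel Gaussian noise, and nuclei
  drawn as filled ellipses with Poisson counts (dense small dark nuclei
  for blastema and lymph nodes, sparse elongated ones for stroma and
  mesenchyme, none for necrosis and bleeding).  Nuclei share one
  hematoxylin-dark color, so classes are separated by color *and*
  nuclear density/shape — enough signal for texture cues to matter, not
  enough to need real histology.
* **Difficulty** — a dial in [0, 1].  At 0 all 15 color means are at
  least 30 RGB-distance apart; at 1 the pairs that genuinely confuse
  pathologists and the published model (epithelium→blastema,
  mesenchyme→stroma, regression→stroma) share a color mean and noise
  doubles.  A fixed nearest-color-mean classifier degrades monotonically
  in this dial, which the suite asserts.
* **Sparsity and quotas** — a random subset of regions (default 70 %)
  is exported as annotations; the full dense mask is kept as evaluation
  ground truth.  Each case force-includes every class once (a seeded
  override of 15 random regions), so per-class metrics are always
  defined.  Region-class frequencies follow configurable weights and
  pass a chi-square goodness-of-fit check at 1000 regions.
* **Determinism** — everything derives from `(seed, case_index)`;
  regeneration is bit-identical.

What it does **not** emulate: stain variation between laboratories,
out-of-focus regions, tissue folds, pen marks, the pyramid structure of
real WSIs, and spatial correlation of classes (real necrosis abuts
regression; Voronoi neighbors are independent).  Passing the recovery
suite therefore demonstrates that the pipeline's machinery — sampling,
optimization, stitching, ensembling, scoring — recovers known structure
under the stated noise model; it says nothing about clinical accuracy.

## Patch sampling and augmentation

Images are resampled from base spacing (default 0.24 μm/pixel) to the
working 0.5 μm/pixel — bilinear for pixels, nearest for labels — and
patches are cropped around annotated centers with mirror padding.
Class-balanced mode (default on) first draws a class present in the
image uniformly, then a pixel of that class: with sparse annotations
the pixel-level class distribution is heavily skewed, and uniform pixel
sampling would starve minority classes; the flag restores the uniform
alternative.

The augmentation stack: right-angle rotations (so labels never need
interpolation) and flips applied to pixels and labels together; and, to
pixels only, Gaussian blur (σ ∈ [0.5, 1.5], p = 0.25), additive
Gaussian noise (sd ∈ [0.01, 0.05] on [0,1] pixels, p = 0.25) — the
recipe's prose and its summary table disagree on blur vs. noise, so
both are implemented with separate probabilities — and HSV jitter
(±0.02 hue, ±0.1 saturation/value, p = 0.5), the minimal interpretable
reading of "color augmentation".

## Networks and training

Both families map an RGB patch to per-pixel class probabilities through
a final softmax, so their outputs ensemble by plain averaging.

* **U-Net**: same-padding encoder–decoder with skip connections.
  Same-padding (output size = input size) rather than the original
  valid-padding, because stitched whole-image output needs full-patch
  predictions.
* **DenseNet**: densely connected 3×3 blocks with 1×1 transition +
  average-pool downsampling, a 1×1 classifier head, and
  nearest-neighbor upsampling back to input resolution.  The reference
  DenseNet is a classification network; per-pixel ensembling forces a
  dense-prediction adaptation.  Nearest-neighbor (not bilinear)
  upsampling keeps the backward pass an exact 2×2 sum-pool; at these
  scales the two are indistinguishable after the following convolutions.

The original publication gives no widths or depths, so capacity is a
preset:

* `paper` — reference scale: U-Net 4 down/4 up at 64 base filters;
  DenseNet 4 blocks of 4 layers, growth 16, stem 48.  Buildable and
  contract-tested, not trained in the suite.
* `tiny` — desk scale: U-Net 1 pooling level at 20 base filters
  (64×64 patches); DenseNet 2 blocks of 3 layers, growth 8, stem 16
  (32×32 patches).  Sized empirically so that both families converge
  under the fixed published recipe (Adam, lr 5·10⁻⁴, batch 4/16) within
  a 500-iteration budget: narrower or deeper normalization-free
  variants train too slowly at that fixed learning rate to be useful
  for CPU-scale experiments.

Inputs in [0, 1] are standardized as (x − 0.5)·4 inside the model; the
stacks carry no batch normalization, and without this the early
gradient signal is too weak at the pinned learning rate.

Training follows the published recipe: masked categorical cross-entropy
(unannotated pixels contribute nothing; an all-unannotated batch is an
error, not a zero), Adam at 5·10⁻⁴, halved after 5 consecutive epochs
without strict validation-loss improvement ("plateau" monitored on
validation loss, min-delta 0, counter reset after each decay — the
scheduler is a pure function of the loss history and the suite recomputes
the recorded rate sequence from it).  The best-validation-loss epoch's
weights are returned.  Divergence (non-finite loss) aborts.

## Inference and ensembling

Tiles of the family's native patch size slide with stride
`tile − 2·overlap`; each pixel's probability vector comes from the one
tile whose interior contains it (interior-crop stitching), making the
map independent of traversal order and, for models with receptive field
≤ 2·overlap, of the overlap itself.  Default overlap is a quarter of
the tile.  Overlap-averaging exists behind a flag.  The ensemble is the
per-pixel arithmetic mean of the two softmax fields; decoding is
arg-max with ties to the lowest class id.

## Evaluation

Confusion is tallied over pixels whose true label is annotated.
Per-class precision/recall/Dice come from the matrix margins; group and
overall scores are micro-pooled (TP/FP/FN summed over member classes
first) — the published overall row has P = R = Dice, which only
micro-pooling produces.  0/0 ratios are reported as undefined (NaN),
never as 0, so absent classes cannot silently deflate averages.
Display rounding is decimal half-up to 2 places; machine-readable
output keeps full precision.

The published per-class table for the original clinical cohort ships in
`wtseg.reference` as comparison data; each of its 18 rows satisfies
Dice = round(2PR/(P+R)) exactly, which the suite and the acceptance
script verify.

## Problem sizes in the test suite

The recovery experiment runs the study conditions at desk scale: a
difficulty-0 cohort of 20 cases at 256×256 generated directly at the
0.5 μm/pixel working spacing (the synthetic textures carry no
sub-0.5 μm structure, so generating at 0.24 and resampling would only
exercise a resampling path that has its own dedicated tests), tiny
presets, 10 epochs × 50 iterations, three seeds, evaluated on the
rasterized test-partition annotations.  Each network reaches held-out
macro Dice ≥ 0.8 and the ensemble is never more than 0.02 below the
weaker network.  Oracle-equivalence checks run on ≥ 100 random small
instances per primitive; split guarantees on 200 random cohorts;
determinism checks assert bit-identical regeneration.

## Known limitations

* The numpy training backend is single-threaded and desk-scale; the
  `paper` preset is provided for structural fidelity, not for
  replicating the 200 × 600-iteration budget.
* No test-time augmentation, no sliding-window importance weighting,
  no stain-deconvolution augmentation, no elastic deformation.
* Pixel-level evaluation only — no case-level aggregation, no
  confidence intervals.
* The synthetic cohort's independence of neighboring region classes
  understates the spatial-context difficulty of real tissue.
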