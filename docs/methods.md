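# Methods

## The problem and the model

A whole-slide image (WSI) is a gigapixel scan of a stained tissue section.
Expert pixel-level annotation is prohibitively expensive, so training uses
only the slide-level diagnosis — here a three-way endometrial label:
*malignant*, *benign/other*, *insufficient* (too little tissue to diagnose).
This is multiple-instance learning (MIL): a slide is a *bag* of patch feature
vectors, the label attaches to the bag, and no patch is individually
labelled.

The classifier is a clustering-constrained attention MIL model.  For a bag of
N patch features `x_n` (D-dimensional) and C classes:

- a gated two-layer attention network scores each patch per class branch,
  `s_{n,c} = w_c^T ( tanh(V x_n) ⊙ σ(U x_n) )`, and the scores are
  softmaxed over the bag so each branch's weights `a_{n,c}` lie on the
  simplex;
- attention pooling forms one slide representation per class,
  `m_c = Σ_n a_{n,c} x_n`, and per-class linear heads give the slide logits;
- an auxiliary *instance-clustering* head per class is trained with binary
  cross-entropy on the top-k attention-ranked patches (positives) and
  bottom-k (negatives) of the true-class branch, sharpening what counts as a
  class-representative patch.  Because the encoder is fixed and pooling acts
  on raw features, this head is an auxiliary probe rather than a shared
  feature-space regularizer; its loss enters the objective with weight c2.

The training objective is `c1 · CE(bag) + c2 · L_instance` with c1 = 0.7,
c2 = 0.3, optimized by Adam (lr 2e-4, weight decay 1e-5 on weight matrices)
with bags visited singly in inverse-class-frequency weighted order and early
stopping on validation loss (patience 20, ≥20 epochs, ≤200).  All linear
algebra and gradients are plain numpy with analytically derived backward
passes, which makes runs bit-reproducible on one CPU thread given a seed.
The baseline is the multiclass max-pooling MIL model: per-patch class logits
aggregated by a rigid max over the bag.

## Pipeline stages

**Tissue segmentation** runs on a downsampled thumbnail: RGB→HSV, median
blur of the saturation channel (kernel 7), binarization (Otsu by default —
robust to stain-intensity variation across labs; a fixed 0–255 threshold is
accepted), morphological closing (kernel 5) that never removes pre-closing
foreground, filling of holes below `min_hole_area` (16 px²; border-touching
background is never treated as a hole), and removal of components below
`min_contour_area` (16 px²).  A blank-glass image (saturation range < 8)
yields a valid empty mask.  **Patching** lays non-overlapping level-0
patches over each retained contour's bounding box, keeping a patch when its
tissue coverage is at least `min_tissue_fraction`; grids from overlapping
contour boxes are deduplicated so patches never overlap.  Slides whose
tissue is too sparse to clear the bar keep one fallback patch centred on the
tissue so every slide yields a non-empty bag.

**Encoding** is a pluggable contract mapping fixed-size RGB patches to
fixed-length vectors.  Two encoders ship: a truncated convolutional network
with adaptive mean-spatial pooling to 1024 dimensions (seeded random weights
by default, loadable weights otherwise), and a seeded random linear
projection of the block-mean-downsampled patch — exact, fast, and linear,
which gives closed-form input gradients.  No color normalization is applied
anywhere.  Encoding is deterministic and batch-size invariant.

**Cohort splitting** holds out entire staining labs for the test set, plus a
10% stratified draw from the remaining labs; validation is then a 25%
stratified draw of what remains.  Stratified allocations use
largest-remainder rounding; remainder ties are broken by a seeded shuffle of
the strata (a lexicographic tie-break would systematically drain
alphabetically-early labels at small cohort sizes), and within-stratum draws
shuffle the lexicographically sorted slide ids with the same generator, so
splits are deterministic and auditable.

**Feature standardization** (pipeline-level, on by default) centres features
on the training mean and scales by the single global standard deviation.
Per-dimension z-scoring is available but not the default: it amplifies
low-variance directions, which are exactly the directions most sensitive to
staining shifts from labs unseen in training.

## Saliency segmentation

Hierarchical Perturbation (HiPe) attributes the prediction to pixels without
gradients.  The input is split into `initial_cells²` cells (default 4²);
each cell is perturbed and the per-class logit decrease
(unperturbed − perturbed) is recorded as a saliency *density* (divided by
the cell area so scales are commensurate); cells passing a threshold test
are split 2×2 and recursed until `min_cell` or `max_depth`.  Two threshold
rules:

- *standard*: refine where the masked saliency maximum reaches the global
  map midpoint `min s + (max s − min s)/2` (refine high-saliency regions);
- *class-variance*: refine where the masked maximum of the across-class
  saliency variance is at most the across-class variance of the per-class
  global midpoints — i.e. where the class maps still agree and the model is
  least certain which class predominates.  `V(X) = (1/n) Σ (x_i − x̄)²` with
  divisor n; the comparison carries a 1e-9 relative tolerance so exact
  mathematical ties still refine.  Whether midpoints use global or
  masked-region extrema is configurable (`midpoint_scope`); global is the
  default, mirroring the standard rule.

By default each pixel keeps the density of the *finest* cell probed there
(`accumulation="finest"`); the count-normalized multi-scale mean is
available as `accumulation="mean"`.  The finest-scale estimate is the
default because it preserves pixel ranking: against exhaustive single-pixel
occlusion on a linear model it reaches Spearman ≈ 0.85, while the
multi-scale mean dilutes fine estimates with coarse-cell averages and drops
to ≈ 0.7.  Perturbation operators: `mean_fill` (default; replace a cell with
its mean color), `blur`, and `fade` toward a configurable baseline.  For
brightfield histology the pipeline uses fade-to-white (`fade_to=1.0`):
fading to the glass background is the "remove this tissue" ablation, whereas
mean-fill preserves a cell's mean color — precisely the statistic carrying
most class evidence under a linear encoder.

Per-patch stacks are stitched onto the slide canvas (collisions are errors),
and the saliency segmentation takes the per-pixel argmax over min-max
normalized planes, with background (uncovered or non-tissue) labelled 0 and
rendered white; malignant is red, benign blue, insufficient yellow.  For
quantitative comparison against reference masks, the malignant plane is
first smoothed with a Gaussian of σ = patch_size / initial_cells — the map
carries no structure below the depth-0 cell scale, and smoothing merges the
piecewise-constant cells — then min-max binarized at 0.5 (configurable).
Segmentation metrics are the pixel confusion counts
tp = Στρ, tn = Σ(1−τ)(1−ρ), fp = Σ(1−τ)ρ, fn = Στ(1−ρ) and
P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R), A = (tp+tn)/total, averaged
macro over slides (micro behind a flag); undefined 0/0 ratios are NaN and
skipped with a reported count.  Classification reporting uses accuracy,
macro one-vs-rest ROC AUC (midrank ties), per-class sensitivity, and the
C×C confusion matrix.

## Feature visualization

Activation maximization: from a zero image, plain gradient ascent on one
pre-softmax class logit, `x ← x + lr · ∂logit/∂x`, with defaults size 256,
lr 0.001, 1000 epochs.  No jitter, decay or frequency regularization in the
default path, and no value clamping unless requested.  With the linear
patch encoder the gradient is exact (back-projection through the fixed
projection and mean-pooling operators, with the standardization chain rule),
and for a purely linear logit the trajectory has the closed form
x_k = k · lr · w, which the tests verify.

## The synthetic cohort generator

Real endometrial cohorts are private, so the generator emulates the
statistical structure the pipeline relies on — not histology.  Slides are
white-background images with irregular tissue fragments (random-radius
polygons, low-frequency intensity modulation, dark nuclear speckle on 12% of
tissue pixels), tinted H&E-like and then passed through a per-lab staining
transform (absorbance scaled by a lab intensity and a per-channel tint).
Malignant slides carry a sub-region of their largest fragment with a
gland-like ring texture and (in the easy preset) a strong dark-violet color
shift, recorded in a ground-truth mask channel.  Insufficient slides have a
tiny tissue fragment (0.2–0.8% of slide area, strictly below the benign
range) surrounded by pale mucus smears; the mucus is faintly saturated so
segmentation keeps it in the foreground, which matters because attention
pooling is count-invariant — a bag's *composition* (mucus-dominated), not
its size, is what makes "insufficient" learnable.  Everything derives from a
SeedSequence, so cohorts are reproducible to the pixel.

Two presets fix difficulty: **easy** (slide 1024², lesion fills 85% of its
host fragment, color shift 0.7, lab jitter 4%) is designed to be cleanly
separable — slide mean color alone separates malignant from benign; **hard**
(lesion 30% of one fragment, no color shift, jitter 10%) defeats slide mean
color (held-out accuracy ≤ 0.7) while patch-level attention still exceeds
it.  The `CohortSpec` default slide size is 2048² — a desk-scale stand-in
for gigapixel inputs; the presets use 1024² with 128-px patches and the
256-d linear test encoder so a 120-slide study (generation, encoding, six
training runs, saliency evaluation) completes in minutes on one CPU.

What passing the synthetic study does and does not show: it demonstrates
that the pipeline wiring is correct end to end — weak labels suffice to
recover slide classes across held-out staining styles, attention pooling
matches or beats rigid max pooling, and perturbation saliency localizes the
generator's lesion (F1 ≈ 0.55–0.65 against generator masks, with the
recall-heavy profile the σ-smoothed 0.5 threshold implies).  It does not
show that these accuracies transfer to real tissue: the generator has no
scanner noise or compression artifacts, its class cues are far cleaner than
real morphology, and its color statistics are cartoon-like.

## Numerical and degenerate-input choices

Population variance uses divisor n.  Softmax is max-shifted; sigmoid is the
numerically stable two-branch form.  Instance-loss k is clamped to
⌊N/2⌋ and skipped (loss 0) for single-patch bags.  Empty bags raise; empty
masks yield empty grids, not errors.  Coordinates are level-0 based, origin
top-left, half-open patch extents.  Model checkpoints are npz parameter
archives.  A single run seed fans out to per-stage seeds by hashing the
stage name (CRC32), isolating stochasticity per stage.

## Known limitations

- The bundled encoders are untrained (seeded random weights); with
  pretrained backbone weights unavailable, absolute feature quality is far
  below an ImageNet-pretrained ResNet50, which the encoder contract is
  shaped to accept.
- Input-gradient feature visualization requires the linear encoder; the
  convolutional encoder supports forward encoding only.
- The instance-clustering head cannot reshape a frozen feature space; with a
  trainable encoder it would act as the feature-space constraint it is in
  the full method.
- Proprietary slide formats are out of scope; readers plug in through the
  `read_region` contract.
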