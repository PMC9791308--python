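# histoweak

Weakly supervised whole-slide-image (WSI) diagnosis with an interpretability
suite, for computational-pathology researchers who have slide-level labels
but no pixel-level annotations.

Gigapixel histology slides are far too large to classify directly, and
expert region annotation is too costly to scale.  `histoweak` implements the
standard weakly supervised recipe end to end: segment tissue from the glass
background on a thumbnail, tile the tissue into non-overlapping 256×256
(configurable) patches at full resolution, encode each patch into a feature
vector, and treat each slide as a *bag* of patch features with a single
label — here the three-way endometrial call *malignant / benign-other /
insufficient*.  A clustering-constrained attention MIL classifier

&nbsp;&nbsp;&nbsp;&nbsp;
a·(n,c) = softmax_n [ wᶜᵀ( tanh(V xₙ) ⊙ σ(U xₙ) ) ],&nbsp;&nbsp;
m꜀ = Σₙ a(n,c) xₙ,&nbsp;&nbsp; logit꜀ = θ꜀ᵀ m꜀

pools patches by learned attention and classifies the slide, with an
auxiliary instance head trained on the top-/bottom-attention patches; a
multiclass max-pooling MIL model is the baseline.  On top of the classifier
sit three interpretability tools:

- **attention heatmaps** — per-patch contribution to the slide decision,
  red = high, blue = low;
- **saliency segmentation** — Hierarchical Perturbation (HiPe) adapted to
  run over all classes at once, refining regions whose *between-class
  saliency variance* is low (`t = 1 iff max V(sᵢ∘m) ≤ V(min sᵢ + (max sᵢ −
  min sᵢ)/2)`), yielding pixel-level class maps scored by
  P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R), A = (tp+tn)/d²;
- **feature visualization** — gradient ascent on a class logit from a zero
  input (lr 0.001, 1000 epochs by default).

Real cohorts of this kind are private, so the package ships a synthetic
slide generator (white background, irregular H&E-tinted fragments, per-lab
hue/intensity jitter, textured malignant lesions with ground-truth masks,
tiny-tissue insufficient slides) that makes every stage testable offline.
All neural components are seeded numpy with hand-derived gradients — runs
are exactly reproducible on one CPU.

## Worked example

`examples/03_train_and_evaluate.py` generates a 36-slide synthetic cohort,
holds out two staining labs entirely, trains both MIL models on patch-feature
bags, and evaluates on the held-out slides:

```text
attention  held-out accuracy 100.00%  AUC 100.00%  (200 epochs)
milmax     held-out accuracy  85.71%  AUC  97.50%  (200 epochs)
attention - maxpool: 14.29 percentage points
```

Held-out accuracy is measured on slides from labs never seen in training —
the generalization the lab hold-out is designed to probe.  The attention
model beats the rigid max-pooling aggregation, here by 14 points on a small
cohort.  `examples/04_saliency_and_heatmaps.py` continues with the
interpretability suite on a malignant slide:

```text
attention heatmap for malignant_004: overlay shape (128, 128, 3), max weight 0.502 over 17 patches
saliency segmentation: 12.5% of pixels labelled malignant (873 model calls across 17 patches)
```

The other examples cover cohort generation (`01`), segmentation and patching
(`02`), and feature visualization (`05`).  A thin CLI wraps the same calls:
`histoweak fixtures|segment|extract|train|pipeline|featviz`.

## Layout

```
src/histoweak/
  slide_io.py            manifests, lab-held-out splits, readers, HDF5 feature bags
  tissue_seg.py          HSV-saturation tissue segmentation, patch grids
  patch_encoder.py       pluggable patch encoders (truncated CNN, linear projection)
  attention_mil.py       gated-attention MIL + instance clustering, max-pool baseline
  interpret_saliency.py  HiPe saliency, class-variance threshold, segmentation
  visualization.py       attention heatmaps, activation maximization
  seg_metrics.py         pixel P/R/F1/A, classification reports
  synthetic_fixtures.py  synthetic slide cohorts with ground truth
  pipeline.py            end-to-end orchestration
  cli.py                 thin command-line interface
docs/methods.md          model, parameters, design choices, limitations
examples/                one narrative script per capability
```
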