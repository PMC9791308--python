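"""Interpretability: attention heatmaps and HiPe saliency segmentation.

The attention heatmap shows how much each *patch* contributed to the slide
decision.  Hierarchical Perturbation works at the *pixel* level instead: it
fades regions to the white background, records per-class logit drops, and
refines regions where the between-class saliency variance is low (where the
model is least certain which class predominates).  The argmax over class
planes yields a saliency segmentation.
"""

import numpy as np

from histoweak import ModelConfig
from histoweak.attention_mil import train
from histoweak.interpret_saliency import hipe_saliency, saliency_segmentation, stitch_slide_saliency
from histoweak.patch_encoder import make_test_encoder
from histoweak.pipeline import (
    EncodedPatchModel,
    FeatureStandardizer,
    RunConfig,
    build_bags,
    cohort_labels,
    derive_seed,
)
from histoweak.slide_io import split_cohort
from histoweak.synthetic_fixtures import easy_cohort_spec, generate_cohort
from histoweak.visualization import HeatmapConfig, attention_heatmap

cohort = generate_cohort(easy_cohort_spec(n_per_class=8, seed=0))
config = RunConfig(patch_size=128, encoder_dim=256, model=ModelConfig(feat_dim=256), seed=1)
labels = cohort_labels(cohort.manifest)
train_m, val_m, test_m = split_cohort(cohort.manifest, set(config.held_out_labs),
                                      seed=derive_seed(1, "split"))
encoder = make_test_encoder(dim=256, seed=derive_seed(1, "encoder"), input_size=128)
bags, grids, _ = build_bags(cohort, config, encoder)
std = FeatureStandardizer.fit([bags[s] for s in train_m.slide_ids])
bags = {k: std.apply(v) for k, v in bags.items()}
model, _ = train([bags[s] for s in train_m.slide_ids], [bags[s] for s in val_m.slide_ids],
                 labels, config.model, seed=3)

sid = next(s for s in test_m.slide_ids if labels[s] == 0)  # a malignant slide
_, attn = model.attention_pool(bags[sid])
thumb = cohort.images[sid][::8, ::8]
overlay = attention_heatmap(attn, grids[sid], thumb, class_index=0,
                            config=HeatmapConfig(alpha=0.6), downsample=8)
print(f"attention heatmap for {sid}: overlay shape {overlay.shape}, "
      f"max weight {attn.weights[:, 0].max():.3f} over {len(grids[sid])} patches")

patch_model = EncodedPatchModel(encoder, model, std)
maps = [hipe_saliency(patch_model,
                      cohort.images[sid][y:y + 128, x:x + 128].astype(float) / 255,
                      config.hipe, threshold="class_variance")
        for x, y in grids[sid].coords]
slide_map = stitch_slide_saliency(maps, grids[sid])
seg_labels, rgb = saliency_segmentation(slide_map)
frac_mal = float(np.mean(seg_labels == 1))
calls = sum(m.meta["model_calls"] for m in maps)
print(f"saliency segmentation: {frac_mal:.1%} of pixels labelled malignant "
      f"({calls} model calls across {len(maps)} patches)")
# Red pixels mark where removing tissue most reduces the malignant logit -
# on this cohort they concentrate on the generator's textured lesion.
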