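"""End-to-end orchestration: segment -> patch -> encode -> train -> evaluate -> interpret.

The pipeline is deterministic per (config, seed): one global seed fans out to
per-stage seeds by stable hashing of the stage name, so stochasticity is
isolated per stage and every artifact can be regenerated from the resolved
config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import seg_metrics
from .attention_mil import (
    CLASS_NAMES,
    LABEL_TO_INDEX,
    AttentionMILModel,
    MaxPoolMILModel,
    ModelConfig,
    accuracy,
    predict_proba,
    train,
)
from .interpret_saliency import HiPeConfig, hipe_saliency, stitch_slide_saliency
from .patch_encoder import LinearPatchEncoder, make_test_encoder
from .seg_metrics import BinaryMaskPair, MetricsReport, binarize_saliency, evaluate_segmentation_set
from .slide_io import ArraySlideReader, FeatureBag, Manifest, split_cohort
from .synthetic_fixtures import Cohort
from .tissue_seg import PatchGrid, SegParams, TissueMask, extract_patch_grid, segment_tissue
from .visualization import FeatVizConfig, HeatmapConfig

log = logging.getLogger("histoweak")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash the stage name into the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    seg: SegParams = field(default_factory=lambda: SegParams(downsample=8))
    model: ModelConfig = field(default_factory=ModelConfig)
    #: Saliency defaults for brightfield slides: fading a cell to the white
    #: glass background is the "remove this tissue" ablation.
    hipe: HiPeConfig = field(
        default_factory=lambda: HiPeConfig(min_cell=16, perturbation="fade", fade_to=1.0)
    )
    featviz: FeatVizConfig = field(default_factory=FeatVizConfig)
    heatmap: HeatmapConfig = field(default_factory=HeatmapConfig)
    patch_size: int = 256
    min_tissue_fraction: float = 0.1
    encoder_dim: int = 1024
    encoder_pool: int = 16
    standardize_features: bool = True  # center/scale on train statistics
    held_out_labs: tuple[str, ...] = ("lab5", "lab6")
    val_fraction: float = 0.25
    test_fraction_other: float = 0.10
    n_saliency_slides: int = 8
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def slide_to_bag(
    image: np.ndarray,
    slide_id: str,
    seg_params: SegParams,
    encoder,
    patch_size: int = 256,
    min_tissue_fraction: float = 0.1,
) -> tuple[FeatureBag, PatchGrid, TissueMask]:
    """Segment one slide, extract its patch grid and encode the patches.

    If no patch clears ``min_tissue_fraction`` (tiny-tissue slides), the single
    best-covered candidate patch is kept so every slide yields a non-empty bag.
    """
    reader = ArraySlideReader(image)
    level = int(np.log2(seg_params.downsample))
    thumb = reader.level_image(min(level, reader.level_count - 1))
    eff_params = dataclasses.replace(
        seg_params, downsample=reader.level_downsamples[min(level, reader.level_count - 1)]
    )
    tissue = segment_tissue(thumb, eff_params)
    grid = extract_patch_grid(
        tissue, slide_id, patch_size=patch_size, min_tissue_fraction=min_tissue_fraction
    )
    if len(grid) == 0 and not tissue.is_empty:
        grid = _fallback_grid(tissue, slide_id, patch_size, image.shape[:2])
    patches = [
        reader.read_region(int(x), int(y), 0, patch_size, patch_size)
        for x, y in grid.coords
    ]
    if patches:
        feats = encoder.encode_batch(np.stack(patches))
    else:
        feats = np.zeros((0, encoder.spec.output_dim))
    bag = FeatureBag(slide_id, feats.astype(np.float32), grid.coords, patch_size)
    return bag, grid, tissue


def _fallback_grid(
    tissue: TissueMask, slide_id: str, patch_size: int, slide_shape: tuple[int, int]
) -> PatchGrid:
    ds = tissue.downsample_factor
    ys, xs = np.nonzero(tissue.mask)
    cy, cx = float(ys.mean() * ds), float(xs.mean() * ds)
    H, W = slide_shape
    x0 = int(np.clip(cx - patch_size / 2, 0, max(W - patch_size, 0)))
    y0 = int(np.clip(cy - patch_size / 2, 0, max(H - patch_size, 0)))
    return PatchGrid(slide_id, 0, patch_size, np.array([[x0, y0]], dtype=np.int64))


def build_bags(
    cohort: Cohort, config: RunConfig, encoder
) -> tuple[dict[str, FeatureBag], dict[str, PatchGrid], dict[str, TissueMask]]:
    bags, grids, tissues = {}, {}, {}
    for rec in cohort.manifest:
        t0 = time.perf_counter()
        bag, grid, tissue = slide_to_bag(
            cohort.images[rec.slide_id],
            rec.slide_id,
            config.seg,
            encoder,
            config.patch_size,
            config.min_tissue_fraction,
        )
        bags[rec.slide_id] = bag
        grids[rec.slide_id] = grid
        tissues[rec.slide_id] = tissue
        log.debug(
            json.dumps(
                {
                    "stage": "encode",
                    "slide_id": rec.slide_id,
                    "n_patches": bag.n_patches,
                    "seconds": round(time.perf_counter() - t0, 4),
                }
            )
        )
    return bags, grids, tissues


def cohort_labels(manifest: Manifest) -> dict[str, int]:
    return {r.slide_id: LABEL_TO_INDEX[r.label.value] for r in manifest}


@dataclass
class FeatureStandardizer:
    """Feature centering/scaling fitted on training-bag statistics.

    Raw projection features share a large common (brightness) component;
    centering on the training mean puts the class-informative directions on a
    common footing before MIL training.  The default scales by the single
    global standard deviation: per-dimension scaling would amplify
    low-variance directions, which are exactly the ones most sensitive to
    staining (lab) shifts unseen during training.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, bags: list[FeatureBag], per_dimension: bool = False) -> "FeatureStandardizer":
        allf = np.concatenate([b.features for b in bags if b.n_patches > 0])
        if per_dimension:
            std = allf.std(axis=0) + 1e-8
        else:
            std = np.full(allf.shape[1], float(allf.std()) + 1e-8)
        return cls(mean=allf.mean(axis=0), std=std)

    def apply(self, bag: FeatureBag) -> FeatureBag:
        feats = ((bag.features - self.mean) / self.std).astype(np.float32)
        return FeatureBag(bag.slide_id, feats, bag.coords, bag.patch_size)

    def apply_features(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.mean) / self.std


class EncodedPatchModel:
    """Patch-level classifier: linear encoder + trained MIL head, with exact
    input gradients (single-patch bags make the attention weight identically 1,
    so the logit is linear in the encoded feature)."""

    def __init__(self, encoder: LinearPatchEncoder, mil_model, standardizer: FeatureStandardizer | None = None):
        self.encoder = encoder
        self.model = mil_model
        self.standardizer = standardizer

    def logits(self, image: np.ndarray) -> np.ndarray:
        feats = self.encoder.encode_batch(np.asarray(image)[None])
        if self.standardizer is not None:
            feats = self.standardizer.apply_features(feats)
        return self.model.logits_from_features(feats)

    __call__ = logits

    def _feature_gradient(self, class_index: int) -> np.ndarray:
        if isinstance(self.model, AttentionMILModel):
            return self.model.params["Wc"][class_index]
        if isinstance(self.model, MaxPoolMILModel):
            return self.model.params["W"][:, class_index]
        raise TypeError("unsupported MIL model for gradient computation")

    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray:
        g = self._feature_gradient(class_index)
        if self.standardizer is not None:
            g = g / self.standardizer.std  # z-scoring is affine: exact chain rule
        return self.encoder.input_gradient(g)


def evaluate_saliency_segmentation(
    cohort: Cohort,
    model,
    encoder,
    bags: Mapping[str, FeatureBag],
    grids: Mapping[str, PatchGrid],
    slide_ids: list[str],
    hipe_config: HiPeConfig,
    threshold: str = "class_variance",
    binarize_at: float = 0.5,
    standardizer: FeatureStandardizer | None = None,
) -> tuple[MetricsReport, dict[str, int], list[str]]:
    """Score malignant-class saliency segmentations against generator masks.

    For each slide the per-patch saliency stacks are stitched onto the slide
    canvas; the malignant plane is smoothed at the coarsest perturbation-cell
    scale (sigma = patch_size / initial_cells — the map carries no structure
    below that scale at depth 0, and smoothing merges the piecewise-constant
    cells), min-max binarized at ``binarize_at``, and pixel P/R/F1/A are
    computed against the ground-truth malignant-region mask over the area
    covered by evaluated patches.  Macro-averaged over slides.
    """
    from scipy import ndimage as ndi

    patch_model = EncodedPatchModel(encoder, model, standardizer)
    pairs, used = [], []
    for sid in slide_ids:
        grid = grids[sid]
        if len(grid) == 0:
            continue
        maps = [
            hipe_saliency(patch_model, _read_patch(cohort, sid, x, y, grid.patch_size),
                          hipe_config, threshold=threshold)
            for x, y in grid.coords
        ]
        slide_map = stitch_slide_saliency(maps, grid)
        covered = slide_map.meta["covered"]
        mal_index = CLASS_NAMES.index("malignant")
        sigma = grid.patch_size / hipe_config.initial_cells
        plane = ndi.gaussian_filter(slide_map.stack[mal_index], sigma)
        rho = binarize_saliency(plane, binarize_at)
        gt = cohort.masks[sid][: plane.shape[0], : plane.shape[1], 1]
        pairs.append(BinaryMaskPair(tau=(gt > 0)[covered].astype(int), rho=rho[covered]))
        used.append(sid)
    if not pairs:
        raise ValueError("no slides could be evaluated")
    report, skipped = evaluate_segmentation_set(pairs)
    return report, skipped, used


def _read_patch(cohort: Cohort, sid: str, x: int, y: int, size: int) -> np.ndarray:
    return cohort.images[sid][y : y + size, x : x + size].astype(np.float64) / 255.0


def run_pipeline(config: RunConfig, cohort: Cohort) -> dict:
    """Execute the full weakly supervised pipeline on a cohort.

    Returns a results dictionary (splits, per-model classification reports,
    saliency segmentation metrics); if ``config.out_dir`` is set, the resolved
    config and a metrics JSON are written next to the artifacts.
    """
    t_start = time.perf_counter()
    encoder = make_test_encoder(
        dim=config.encoder_dim,
        seed=derive_seed(config.seed, "encoder"),
        input_size=config.patch_size,
        pool=config.encoder_pool,
    )
    train_m, val_m, test_m = split_cohort(
        cohort.manifest,
        held_out_labs=set(config.held_out_labs),
        val_fraction=config.val_fraction,
        test_fraction_other=config.test_fraction_other,
        seed=derive_seed(config.seed, "split"),
    )
    log.info(json.dumps({"stage": "split", "train": len(train_m), "val": len(val_m),
                         "test": len(test_m), "train_labs": sorted(train_m.labs)}))
    bags, grids, _tissues = build_bags(cohort, config, encoder)
    labels = cohort_labels(cohort.manifest)
    standardizer = None
    if config.standardize_features:
        standardizer = FeatureStandardizer.fit([bags[s] for s in train_m.slide_ids])
        bags = {sid: standardizer.apply(bag) for sid, bag in bags.items()}

    results: dict = {
        "splits": {
            "train": train_m.slide_ids, "val": val_m.slide_ids, "test": test_m.slide_ids,
        },
        "models": {},
    }
    trained = {}
    for model_type in ("attention", "milmax"):
        model, history = train(
            [bags[s] for s in train_m.slide_ids],
            [bags[s] for s in val_m.slide_ids],
            labels,
            config.model,
            seed=derive_seed(config.seed, f"train-{model_type}"),
            model_type=model_type,
        )
        trained[model_type] = model
        test_bags = [bags[s] for s in test_m.slide_ids]
        probs = predict_proba(model, test_bags)
        y_test = np.array([labels[s] for s in test_m.slide_ids])
        report = seg_metrics.classification_report(probs, y_test)
        results["models"][model_type] = {
            "test_accuracy": report.accuracy,
            "test_auc": report.auc,
            "val_accuracy": 100.0 * accuracy(model, [bags[s] for s in val_m.slide_ids], labels),
            "per_class_sensitivity": report.per_class_sensitivity.tolist(),
            "confusion_matrix": report.confusion_matrix.tolist(),
            "epochs": len(history["train_loss"]),
        }
        log.info(json.dumps({"stage": f"train-{model_type}",
                             "test_acc": report.accuracy, "test_auc": report.auc}))

    results["accuracy_improvement_pp"] = seg_metrics.accuracy_improvement(
        results["models"]["attention"]["test_accuracy"],
        results["models"]["milmax"]["test_accuracy"],
    )

    # Saliency segmentation on correctly classified malignant test slides.
    attn_model = trained["attention"]
    mal_ids = [
        s for s in test_m.slide_ids
        if labels[s] == LABEL_TO_INDEX["malignant"]
        and bags[s].n_patches > 0
        and attn_model.forward(bags[s]).label == LABEL_TO_INDEX["malignant"]
    ][: config.n_saliency_slides]
    if mal_ids:
        seg_report, skipped, used = evaluate_saliency_segmentation(
            cohort, attn_model, encoder, bags, grids, mal_ids, config.hipe,
            standardizer=standardizer,
        )
        results["saliency_segmentation"] = {
            "accuracy": seg_report.accuracy, "f1": seg_report.f1,
            "precision": seg_report.precision, "recall": seg_report.recall,
            "n_slides": len(used), "skipped": skipped,
        }
    results["seconds"] = round(time.perf_counter() - t_start, 2)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "resolved_config.json", "w") as f:
            json.dump(config.to_dict(), f, indent=2, default=str)
        with open(out / "metrics.json", "w") as f:
            json.dump(results, f, indent=2)
    return results
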