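"""Hierarchical Perturbation (HiPe) saliency and saliency-based segmentation.

HiPe estimates pixel-level class saliency without gradients: the input is
partitioned into coarse cells, each cell is perturbed (mean-fill by default)
and the per-class logit decrease is accumulated as additive saliency over the
cell; cells passing a threshold test are split 2x2 and recursed, so model
evaluations concentrate where they matter.  Two threshold rules are provided:

* ``standard`` — refine cells whose masked saliency maximum reaches the
  global midpoint of the map (refine where saliency is high);
* ``class_variance`` — refine cells whose masked between-class saliency
  variance stays at or below the variance of the per-class map midpoints
  (refine where the model is least certain which class predominates).  This
  rule operates over all C class maps simultaneously and is what turns the
  saliency stack into a usable multi-class segmentation.

Per-patch stacks can be stitched onto a slide canvas and argmax-labelled into
a saliency segmentation (malignant red, benign blue, insufficient yellow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .attention_mil import CLASS_NAMES
from .tissue_seg import PatchGrid


@dataclass
class SaliencyMap:
    """Stack of C per-class saliency planes for one input."""

    stack: np.ndarray  # C x H x W
    class_names: Sequence[str] = CLASS_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 3:
            raise ValueError("saliency stack must be C x H x W")
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("saliency stack contains non-finite values")

    @property
    def n_classes(self) -> int:
        return self.stack.shape[0]


@dataclass
class HiPeConfig:
    initial_cells: int = 4
    min_cell: int = 8
    perturbation: Literal["mean_fill", "blur", "fade"] = "mean_fill"
    #: Baseline the ``fade`` operator fades to.  0 is a black baseline (natural
    #: images); 1.0 is the white glass background, i.e. "remove the tissue",
    #: which is the meaningful ablation for brightfield histology.
    fade_to: float = 0.0
    max_depth: int | None = None
    #: "finest" keeps, at every pixel, the logit-change density of the smallest
    #: cell probed there (best pixel-ranking fidelity); "mean" averages the
    #: densities over all scales that covered the pixel.
    accumulation: Literal["finest", "mean"] = "finest"

    def __post_init__(self) -> None:
        if self.initial_cells < 2:
            raise ValueError("initial_cells must be >= 2")
        if self.min_cell < 1:
            raise ValueError("min_cell must be >= 1")


def variance(values) -> float:
    """Population variance (divisor n) of a list of reals."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("variance of an empty list is undefined")
    return float(np.mean((arr - arr.mean()) ** 2))


def _check_mask(plane_shape: tuple[int, int], m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=bool)
    if m.shape != plane_shape:
        raise ValueError(f"mask shape {m.shape} does not match plane shape {plane_shape}")
    if not m.any():
        raise ValueError("perturbation mask is empty")
    return m


def threshold_standard(s: np.ndarray, m: np.ndarray) -> int:
    """Original HiPe test: 1 iff ``max(s o m) >= min s + (max s - min s)/2``."""
    s = np.asarray(s, dtype=np.float64)
    m = _check_mask(s.shape, m)
    midpoint = s.min() + (s.max() - s.min()) / 2.0
    return int(s[m].max() >= midpoint)


def threshold_class_variance(
    stack: np.ndarray | SaliencyMap,
    m: np.ndarray,
    midpoint_scope: Literal["global", "masked"] = "global",
) -> int:
    """Between-class variance test: 1 iff the masked maximum of the
    across-class saliency variance is at most the across-class variance of the
    per-class map midpoints ``min s_i + (max s_i - min s_i)/2``.

    Low between-class variance means the class maps agree locally — i.e. the
    model is uncertain which class predominates — so the cell is refined.
    ``midpoint_scope`` selects whether midpoints use each plane's global or
    masked-region extrema (the global reading mirrors the standard threshold).
    """
    s = stack.stack if isinstance(stack, SaliencyMap) else np.asarray(stack, dtype=np.float64)
    if s.ndim != 3 or s.shape[0] < 2:
        raise ValueError("between-class variance needs a stack of >= 2 class planes")
    m = _check_mask(s.shape[1:], m)
    left = float(s[:, m].var(axis=0).max())
    if midpoint_scope == "masked":
        lo, hi = s[:, m].min(axis=1), s[:, m].max(axis=1)
    else:
        lo = s.reshape(s.shape[0], -1).min(axis=1)
        hi = s.reshape(s.shape[0], -1).max(axis=1)
    midpoints = lo + (hi - lo) / 2.0
    right = variance(midpoints)
    # tolerate float noise so exact mathematical ties still refine
    return int(left <= right * (1.0 + 1e-9) + 1e-12)


# ---------------------------------------------------------------------------
# Hierarchical perturbation
# ---------------------------------------------------------------------------


def _perturb(image: np.ndarray, y0, y1, x0, x1, mode: str, fade_to: float = 0.0) -> np.ndarray:
    out = image.copy()
    region = out[y0:y1, x0:x1]
    if mode == "mean_fill":
        out[y0:y1, x0:x1] = region.mean(axis=(0, 1), keepdims=True)
    elif mode == "blur":
        sigma = max(y1 - y0, x1 - x0) / 2.0
        if image.ndim == 3:
            out[y0:y1, x0:x1] = ndi.gaussian_filter(image, (sigma, sigma, 0))[y0:y1, x0:x1]
        else:
            out[y0:y1, x0:x1] = ndi.gaussian_filter(image, sigma)[y0:y1, x0:x1]
    elif mode == "fade":
        out[y0:y1, x0:x1] = fade_to
    else:
        raise ValueError(f"unknown perturbation {mode!r}")
    return out


ThresholdLike = Literal["standard", "class_variance", "exhaustive"] | Callable


def hipe_saliency(
    model_fn: Callable[[np.ndarray], np.ndarray],
    image: np.ndarray,
    config: HiPeConfig | None = None,
    threshold: ThresholdLike = "standard",
    class_names: Sequence[str] | None = None,
) -> SaliencyMap:
    """Compute a C-plane saliency stack for one input image.

    ``model_fn`` maps an image to the C pre-softmax class logits.  Saliency is
    the signed logit decrease (unperturbed minus perturbed) expressed as a
    per-pixel density (divided by the perturbed cell's area so coarse and fine
    scales are commensurate), accumulated additively over each perturbed cell
    and normalized by the accumulation count.  The number of model evaluations
    is recorded in ``result.meta["model_calls"]``.

    ``threshold`` selects the refinement rule; ``"exhaustive"`` refines every
    cell down to ``min_cell`` (the brute-force ceiling the adaptive rules are
    measured against), and a callable ``f(stack, mask) -> bool`` may be given.
    """
    config = config or HiPeConfig()
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape[:2]
    base = np.asarray(model_fn(image), dtype=np.float64).ravel()
    C = base.size
    if threshold == "class_variance" and C < 2:
        raise ValueError("class_variance threshold requires >= 2 classes")
    calls = 1
    sal = np.zeros((C, H, W))
    cnt = np.zeros((H, W))
    fin = np.zeros((C, H, W))  # finest-scale density estimate per pixel

    def current_stack() -> np.ndarray:
        if config.accumulation == "finest":
            return fin
        return sal / np.maximum(cnt, 1.0)

    def decide(mask: np.ndarray) -> bool:
        stack = current_stack()
        if callable(threshold):
            return bool(threshold(stack, mask))
        if threshold == "exhaustive":
            return True
        if threshold == "standard":
            return any(threshold_standard(stack[c], mask) for c in range(C))
        if threshold == "class_variance":
            return bool(threshold_class_variance(stack, mask))
        raise ValueError(f"unknown threshold {threshold!r}")

    ys = np.linspace(0, H, config.initial_cells + 1).astype(int)
    xs = np.linspace(0, W, config.initial_cells + 1).astype(int)
    cells = [
        (ys[i], ys[i + 1], xs[j], xs[j + 1])
        for i in range(config.initial_cells)
        for j in range(config.initial_cells)
        if ys[i + 1] > ys[i] and xs[j + 1] > xs[j]
    ]
    depth = 0
    while cells:
        for y0, y1, x0, x1 in cells:
            pert = _perturb(image, y0, y1, x0, x1, config.perturbation, config.fade_to)
            delta = base - np.asarray(model_fn(pert), dtype=np.float64).ravel()
            calls += 1
            area = (y1 - y0) * (x1 - x0)
            sal[:, y0:y1, x0:x1] += delta[:, None, None] / area
            cnt[y0:y1, x0:x1] += 1.0
            fin[:, y0:y1, x0:x1] = delta[:, None, None] / area
        depth += 1
        if config.max_depth is not None and depth >= config.max_depth:
            break
        nxt = []
        for y0, y1, x0, x1 in cells:
            h, w = y1 - y0, x1 - x0
            if h // 2 < config.min_cell or w // 2 < config.min_cell:
                continue
            mask = np.zeros((H, W), dtype=bool)
            mask[y0:y1, x0:x1] = True
            if not decide(mask):
                continue
            ym, xm = y0 + h // 2, x0 + w // 2
            nxt.extend(
                (a, b, c, d)
                for a, b, c, d in [
                    (y0, ym, x0, xm), (y0, ym, xm, x1),
                    (ym, y1, x0, xm), (ym, y1, xm, x1),
                ]
                if b > a and d > c
            )
        cells = nxt

    names = list(class_names) if class_names is not None else list(CLASS_NAMES)[:C]
    if len(names) != C:
        names = [f"class_{i}" for i in range(C)]
    return SaliencyMap(current_stack(), names, meta={"model_calls": calls})


# ---------------------------------------------------------------------------
# Slide-level stitching and segmentation
# ---------------------------------------------------------------------------


def stitch_slide_saliency(
    patch_maps: Sequence[SaliencyMap],
    grid: PatchGrid,
    canvas_shape: tuple[int, int] | None = None,
) -> SaliencyMap:
    """Place per-patch saliency stacks onto a level-0 slide canvas.

    Patches must be non-overlapping (overlap 0); a coordinate collision is an
    error.  Uncovered canvas is zero.
    """
    if len(patch_maps) != len(grid):
        raise ValueError("number of patch maps does not match grid size")
    if not patch_maps:
        shape = canvas_shape or (0, 0)
        return SaliencyMap(np.zeros((len(CLASS_NAMES),) + shape))
    C = patch_maps[0].n_classes
    ph, pw = patch_maps[0].stack.shape[1:]
    if canvas_shape is None:
        H = int(grid.coords[:, 1].max()) + ph
        W = int(grid.coords[:, 0].max()) + pw
    else:
        H, W = canvas_shape
    canvas = np.zeros((C, H, W))
    covered = np.zeros((H, W), dtype=bool)
    for smap, (x, y) in zip(patch_maps, grid.coords):
        if smap.stack.shape != (C, ph, pw):
            raise ValueError("all patch maps must share the same shape")
        if covered[y : y + ph, x : x + pw].any():
            raise ValueError(f"patch at ({x}, {y}) collides with an earlier patch")
        canvas[:, y : y + ph, x : x + pw] = smap.stack
        covered[y : y + ph, x : x + pw] = True
    return SaliencyMap(canvas, patch_maps[0].class_names, meta={"covered": covered})


SEGMENTATION_COLORS = {
    "malignant": (255, 0, 0),
    "benign_other": (0, 0, 255),
    "insufficient": (255, 255, 0),
}
BACKGROUND_COLOR = (255, 255, 255)


def _minmax(plane: np.ndarray) -> np.ndarray:
    lo, hi = plane.min(), plane.max()
    if hi - lo <= 0:
        return np.zeros_like(plane)
    return (plane - lo) / (hi - lo)


def saliency_segmentation(
    slide_stack: SaliencyMap,
    tissue_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax-label a saliency stack into a segmentation and an RGB rendering.

    Each plane is min-max normalized first (saliency scales are not comparable
    across classes), then every non-background pixel takes the class of the
    largest normalized plane.  Background (label 0) is anywhere outside
    ``tissue_mask`` when given, plus pixels never covered by saliency.
    Returned labels are ``1 + class index``; the rendering uses malignant red,
    benign blue, insufficient yellow on a white background.
    """
    s = slide_stack.stack
    C, H, W = s.shape
    norm = np.stack([_minmax(s[c]) for c in range(C)])
    background = ~np.any(s != 0, axis=0)
    if tissue_mask is not None:
        background |= ~np.asarray(tissue_mask, dtype=bool)
    labels = np.argmax(norm, axis=0).astype(np.int32) + 1
    labels[background] = 0
    rgb = np.full((H, W, 3), BACKGROUND_COLOR, dtype=np.uint8)
    for c, name in enumerate(slide_stack.class_names):
        color = SEGMENTATION_COLORS.get(name, (128, 128, 128))
        rgb[labels == c + 1] = color
    return labels, rgb
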