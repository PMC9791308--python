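"""Foreground tissue segmentation and patch-grid extraction.

Slides are segmented at a downsampled level: the RGB thumbnail is converted to
HSV, the saturation channel is median-blurred and thresholded (stained tissue
is saturated, glass background is not), small gaps are closed morphologically,
small holes are filled, and contours below an area threshold are dropped.
Patch coordinates are then laid over the bounding boxes of the retained
contours at full resolution (level 0), keeping patches whose tissue coverage
exceeds a minimum fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.color import rgb2hsv


@dataclass
class SegParams:
    """Segmentation parameters at the working (downsampled) level.

    ``sat_threshold`` may be an integer in 0-255 or ``"otsu"``; Otsu adapts to
    the large stain-intensity variance across labs.  Areas are in pixels^2 at
    the working level.
    """

    downsample: int = 64
    median_kernel: int = 7
    sat_threshold: int | Literal["otsu"] = "otsu"
    close_kernel: int = 5
    min_contour_area: float = 16.0
    min_hole_area: float = 16.0

    def __post_init__(self) -> None:
        for name in ("median_kernel", "close_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 1, got {k}")
        if self.min_contour_area < 0 or self.min_hole_area < 0:
            raise ValueError("area thresholds must be non-negative")


@dataclass
class TissueMask:
    """Binary foreground mask plus retained contour polygons.

    ``downsample_factor`` converts mask pixels to level-0 pixels.  Contours and
    holes are closed polygons in mask (x, y) coordinates.
    """

    mask: np.ndarray
    downsample_factor: float
    contours: list[np.ndarray] = field(default_factory=list)
    holes: list[np.ndarray] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class PatchGrid:
    """Non-overlapping level-0 patch origins over segmented tissue."""

    slide_id: str
    level: int
    patch_size: int
    coords: np.ndarray  # N x 2 int64 (x, y), row-major sorted

    def __len__(self) -> int:
        return len(self.coords)


def _saturation_u8(rgb: np.ndarray) -> np.ndarray:
    hsv = rgb2hsv(rgb)
    return np.clip(np.rint(hsv[:, :, 1] * 255), 0, 255).astype(np.uint8)


def binarize_saturation(
    sat: np.ndarray, threshold: int | Literal["otsu"] = "otsu"
) -> tuple[np.ndarray, float]:
    """Threshold a (blurred) saturation channel; tissue = saturation > t."""
    if threshold == "otsu":
        if int(sat.max()) - int(sat.min()) < 8:
            # Degenerate (blank glass) image: no meaningful bimodality.
            return np.zeros(sat.shape, dtype=bool), float("inf")
        from skimage.filters import threshold_otsu

        t = float(threshold_otsu(sat))
    else:
        t = float(threshold)
    return sat > t, t


def _small_components(
    mask: np.ndarray, min_area: float, exclude_border: bool = False
) -> np.ndarray:
    """Connected components of ``mask`` with area strictly below ``min_area``.

    With ``exclude_border`` (used when scanning for holes), components touching
    the image border are kept out — the glass background is not a hole."""
    if min_area <= 0 or not mask.any():
        return np.zeros_like(mask)
    labeled, n = ndi.label(mask)
    areas = np.bincount(labeled.ravel())
    small = np.zeros(n + 1, dtype=bool)
    small[1:] = areas[1:] < min_area
    if exclude_border:
        border = np.unique(
            np.concatenate([labeled[0], labeled[-1], labeled[:, 0], labeled[:, -1]])
        )
        small[border] = False
    small[0] = False
    return small[labeled]


def segment_tissue(rgb: np.ndarray, params: SegParams | None = None) -> TissueMask:
    """Segment stained tissue from background on a downsampled slide image.

    Pipeline order is fixed: RGB -> HSV; median blur of saturation; binarize
    (> threshold); morphological closing; fill holes below ``min_hole_area``;
    drop connected components below ``min_contour_area``.  An all-background
    image yields a valid empty mask.
    """
    params = params or SegParams()
    rgb = np.asarray(rgb)
    if rgb.size == 0 or rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected a non-empty H x W x 3 RGB image")
    sat = _saturation_u8(rgb)
    sat = ndi.median_filter(sat, size=params.median_kernel)
    binary, _ = binarize_saturation(sat, params.sat_threshold)
    closed = ndi.binary_closing(
        binary, structure=np.ones((params.close_kernel, params.close_kernel), dtype=bool)
    )
    # Closing may clip foreground at the image border; never lose pre-closing tissue.
    closed |= binary
    filled = closed | _small_components(~closed, params.min_hole_area, exclude_border=True)
    kept = filled & ~_small_components(filled, params.min_contour_area)

    contours = [c[:, ::-1] for c in measure.find_contours(kept.astype(float), 0.5)]
    hole_mask = filled & ~closed  # regions that were filled
    holes = [c[:, ::-1] for c in measure.find_contours(hole_mask.astype(float), 0.5)]
    return TissueMask(
        mask=kept,
        downsample_factor=float(params.downsample),
        contours=contours,
        holes=holes,
    )


def extract_patch_grid(
    tissue: TissueMask,
    slide_id: str = "",
    patch_size: int = 256,
    level: int = 0,
    overlap: int = 0,
    min_tissue_fraction: float = 0.5,
) -> PatchGrid:
    """Lay a patch grid over the tissue mask and keep sufficiently covered patches.

    The grid is anchored at the top-left of the mask's foreground bounding box
    and steps by ``patch_size - overlap`` in level-0 pixels.  A patch is kept
    iff the mask fraction under its footprint is at least
    ``min_tissue_fraction``.  Partial patches at the slide edge are discarded.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    if not 0 <= overlap < patch_size:
        raise ValueError("overlap must satisfy 0 <= overlap < patch_size")
    ds = tissue.downsample_factor
    step = (patch_size - overlap) * 2**level
    extent = patch_size * 2**level  # level-0 pixels covered by one patch
    mask = tissue.mask
    H0 = int(mask.shape[0] * ds)
    W0 = int(mask.shape[1] * ds)
    if tissue.is_empty:
        return PatchGrid(slide_id, level, patch_size, np.zeros((0, 2), dtype=np.int64))

    labeled, n = ndi.label(mask)
    boxes = sorted(
        ndi.find_objects(labeled), key=lambda o: (o[0].start, o[1].start)
    )
    coords: list[tuple[int, int]] = []
    occupied: list[tuple[int, int]] = []  # kept origins, for cross-contour overlap
    for obj in boxes:
        y0 = int(obj[0].start * ds)
        x0 = int(obj[1].start * ds)
        y1 = int(obj[0].stop * ds)
        x1 = int(obj[1].stop * ds)
        for y in range(y0, y1, step):
            if y + extent > H0:
                continue
            for x in range(x0, x1, step):
                if x + extent > W0:
                    continue
                if overlap == 0 and any(
                    abs(x - ox) < extent and abs(y - oy) < extent for ox, oy in occupied
                ):
                    continue  # grids of distinct contours must not overlap
                frac = _mask_fraction(mask, ds, x, y, extent)
                if frac >= min_tissue_fraction:
                    coords.append((x, y))
                    occupied.append((x, y))
    arr = np.array(sorted(set(coords), key=lambda c: (c[1], c[0])), dtype=np.int64)
    if arr.size == 0:
        arr = np.zeros((0, 2), dtype=np.int64)
    return PatchGrid(slide_id, level, patch_size, arr)


def _mask_fraction(mask: np.ndarray, ds: float, x: int, y: int, extent: int) -> float:
    my0 = int(np.floor(y / ds))
    mx0 = int(np.floor(x / ds))
    my1 = max(my0 + 1, int(np.ceil((y + extent) / ds)))
    mx1 = max(mx0 + 1, int(np.ceil((x + extent) / ds)))
    window = mask[my0:my1, mx0:mx1]
    if window.size == 0:
        return 0.0
    return float(window.mean())


def patch_tissue_fraction(tissue: TissueMask, x: int, y: int, patch_size: int, level: int = 0) -> float:
    """Tissue coverage of one patch footprint (for auditing grid decisions)."""
    return _mask_fraction(tissue.mask, tissue.downsample_factor, x, y, patch_size * 2**level)


def render_mask_overlay(
    rgb: np.ndarray, tissue: TissueMask, color: tuple[int, int, int] = (0, 200, 0)
) -> np.ndarray:
    """Draw contour outlines on a copy of the downsampled slide for QC."""
    rgb = np.asarray(rgb)
    if rgb.shape[:2] != tissue.mask.shape:
        raise ValueError(
            f"image shape {rgb.shape[:2]} does not match mask shape {tissue.mask.shape}"
        )
    out = rgb.copy()
    if tissue.is_empty:
        return out
    boundary = tissue.mask ^ ndi.binary_erosion(
        tissue.mask, structure=np.ones((3, 3), dtype=bool)
    )
    out[boundary] = np.array(color, dtype=out.dtype)
    return out
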