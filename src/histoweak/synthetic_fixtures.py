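"""Synthetic slide cohorts with known labels, masks and lab-style variation.

The generator emulates the statistical structure a weakly supervised slide
pipeline relies on, without claiming histological realism: a white glass
background; irregular H&E-tinted tissue fragments (random-radius polygons
with low-frequency intensity modulation and nuclear speckle); per-lab hue and
intensity jitter; a distinct high-frequency ring ("gland-like") texture inside
a sub-region of malignant slides, recorded in a ground-truth mask; and a tiny
tissue fraction plus pale mucus smears for insufficient slides.  Every slide
ships with a two-channel mask (tissue, malignant region) so segmentation and
saliency outputs can be scored exactly.

Two presets control class separability: ``easy`` adds a strong color contrast
to the malignant region (slide mean color alone separates classes), ``hard``
shrinks the lesion and removes the color shift so only localized texture in a
few patches carries the label — the regime where attention-based MIL should
beat whole-slide color summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw

from .slide_io import Label, Manifest, SlideRecord

SUBCATEGORIES = {
    Label.MALIGNANT: ("adenocarcinoma", "hyperplasia_atypia", "carcinosarcoma"),
    Label.BENIGN_OTHER: ("proliferative", "secretory", "atrophic", "hormonal"),
    Label.INSUFFICIENT: ("insufficient",),
}

SITES = ("site_A", "site_B", "site_C", "site_D")


@dataclass(frozen=True)
class LabStyle:
    """Per-lab staining character: overall intensity and RGB tint tilt."""

    name: str
    intensity: float = 1.0
    tint: tuple[float, float, float] = (1.0, 1.0, 1.0)


def default_labs(n: int = 6, jitter: float = 0.06, seed: int = 7) -> list[LabStyle]:
    """Deterministic set of lab styles with bounded hue/intensity variation."""
    rng = np.random.default_rng(seed)
    labs = []
    for i in range(n):
        intensity = 1.0 + float(rng.uniform(-jitter, jitter))
        tint = tuple(1.0 + rng.uniform(-jitter, jitter, size=3))
        labs.append(LabStyle(name=f"lab{i + 1}", intensity=intensity, tint=tint))
    return labs


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_per_class: int = 40
    labs: list[LabStyle] = field(default_factory=default_labs)
    slide_size: int = 2048
    tissue_fraction_range: dict[Label, tuple[float, float]] = field(
        default_factory=lambda: {
            Label.MALIGNANT: (0.15, 0.35),
            Label.BENIGN_OTHER: (0.15, 0.35),
            Label.INSUFFICIENT: (0.002, 0.008),
        }
    )
    malignant_region_fraction: float = 0.45  # of the host fragment's area
    malignant_color_shift: float = 0.25      # 0 = texture only
    texture_period: float = 28.0             # ring wavelength, pixels
    texture_strength: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        ins_hi = self.tissue_fraction_range[Label.INSUFFICIENT][1]
        ben_lo = self.tissue_fraction_range[Label.BENIGN_OTHER][0]
        if ins_hi >= ben_lo:
            raise ValueError(
                "insufficient-class tissue fraction must lie strictly below the benign range"
            )


def easy_cohort_spec(n_per_class: int = 40, seed: int = 0) -> CohortSpec:
    """Desk-scale preset with a clear malignant color + texture cue."""
    return CohortSpec(
        n_per_class=n_per_class,
        labs=default_labs(6, jitter=0.04),
        slide_size=1024,
        malignant_region_fraction=0.85,
        malignant_color_shift=0.70,
        texture_strength=0.80,
        seed=seed,
    )


def hard_cohort_spec(n_per_class: int = 40, seed: int = 0) -> CohortSpec:
    """Preset where only localized texture carries the malignant label."""
    return CohortSpec(
        n_per_class=n_per_class,
        labs=default_labs(6, jitter=0.10),
        slide_size=1024,
        malignant_region_fraction=0.30,
        malignant_color_shift=0.0,
        texture_strength=0.75,
        seed=seed,
    )


# Base tissue tints (float RGB in [0, 1]); H&E-like pink/purple.
_STROMA = np.array([0.80, 0.55, 0.75])
_MALIGNANT = np.array([0.45, 0.22, 0.58])
# Mucus is pale but still faintly stained: saturated enough that tissue
# segmentation keeps it in the foreground, as on real insufficient slides.
_MUCUS = np.array([0.95, 0.80, 0.89])
_SPECKLE_DARKEN = 0.82


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    r0: float,
    rng: np.random.Generator,
    amp: float = 0.35,
    n_angles: int = 96,
) -> np.ndarray:
    """Irregular closed polygon: radius = r0 * (1 + amp * smooth noise)."""
    noise = rng.standard_normal(n_angles)
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np.tile(noise, 3), kernel, mode="same")[n_angles : 2 * n_angles]
    smooth /= max(np.abs(smooth).max(), 1e-9)
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.maximum(r0 * (1 + amp * smooth), 2.0)
    ys = center[0] + radii * np.sin(theta)
    xs = center[1] + radii * np.cos(theta)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.polygon(ys, xs, shape)
    mask[rr, cc] = True
    return mask


def _lowfreq_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    return f / max(np.abs(f).max(), 1e-9)


def generate_slide(
    label: Label,
    lab_style: LabStyle,
    spec: CohortSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one slide image and its two-channel ground-truth mask.

    Returns ``(rgb uint8 S x S x 3, mask uint8 S x S x 2)`` with mask channel 0
    = tissue and channel 1 = malignant region (empty unless malignant).
    Deterministic given (label, lab_style, spec, seed).
    """
    rng = np.random.default_rng(seed)
    S = spec.slide_size
    img = np.ones((S, S, 3), dtype=np.float64)
    tissue = np.zeros((S, S), dtype=bool)
    malignant = np.zeros((S, S), dtype=bool)

    lo, hi = spec.tissue_fraction_range[label]
    frac = float(rng.uniform(lo, hi))
    n_blobs = 1 if label is Label.INSUFFICIENT else int(rng.integers(2, 4))
    blobs = []
    for _ in range(n_blobs):
        area = frac * S * S / n_blobs
        r0 = np.sqrt(area / np.pi)
        margin = min(r0 * 1.6, S / 2 - 1)
        cy = float(rng.uniform(margin, S - margin))
        cx = float(rng.uniform(margin, S - margin))
        b = _blob_mask((S, S), (cy, cx), r0, rng)
        blobs.append(b)
        tissue |= b

    # Mucus smears surrounding the tissue: pale but stained, excluded from the
    # tissue mask (they are what makes an insufficient slide non-diagnostic).
    if label is Label.INSUFFICIENT:
        cy0, cx0 = S / 2, S / 2
        if tissue.any():
            ys0, xs0 = np.nonzero(tissue)
            cy0, cx0 = float(ys0.mean()), float(xs0.mean())
        for _ in range(int(rng.integers(3, 5))):
            r0 = float(rng.uniform(0.10, 0.18)) * S
            cy = float(np.clip(cy0 + rng.uniform(-0.2, 0.2) * S, r0, S - r0))
            cx = float(np.clip(cx0 + rng.uniform(-0.2, 0.2) * S, r0, S - r0))
            smear = _blob_mask((S, S), (cy, cx), r0, rng, amp=0.5) & ~tissue
            img[smear] = _MUCUS * (1.0 + 0.05 * rng.standard_normal(3))

    # Stroma coloring with low-frequency intensity modulation + nuclear speckle.
    mod = _lowfreq_field((S, S), sigma=S / 40, rng=rng) * 0.10
    base = _STROMA[None, None, :] * (1.0 + mod[:, :, None])
    img = np.where(tissue[:, :, None], base, img)
    fine = ndi.gaussian_filter(rng.standard_normal((S, S)), 1.2)
    speckle = tissue & (fine > np.quantile(fine[tissue] if tissue.any() else fine, 0.88))
    img[speckle] *= _SPECKLE_DARKEN

    if label is Label.MALIGNANT:
        host = max(blobs, key=lambda b: b.sum())
        ys, xs = np.nonzero(host)
        j = int(rng.integers(len(ys)))
        host_area = host.sum()
        r_reg = np.sqrt(spec.malignant_region_fraction * host_area / np.pi)
        region = _blob_mask((S, S), (float(ys[j]), float(xs[j])), r_reg, rng, amp=0.2)
        region &= host
        malignant = region
        if region.any():
            # Gland-like ring motif: thresholded band-pass noise arranged in rings.
            yy, xx = np.mgrid[0:S, 0:S]
            phase = _lowfreq_field((S, S), sigma=S / 24, rng=rng) * spec.texture_period
            dist = np.sqrt((yy - float(ys[j])) ** 2 + (xx - float(xs[j])) ** 2)
            rings = np.abs(np.sin(2 * np.pi * (dist + phase) / spec.texture_period)) < 0.35
            texture = region & rings
            shift = spec.malignant_color_shift
            if shift > 0:
                img[region] += shift * (_MALIGNANT[None, :] - img[region])
            img[texture] = (
                img[texture] * (1 - spec.texture_strength)
                + _MALIGNANT[None, :] * spec.texture_strength
            )

    # Lab staining character: intensity scales stain darkness, tint tilts hue.
    stained = img < 0.999
    absorb = (1.0 - img) * lab_style.intensity * np.asarray(lab_style.tint)[None, None, :]
    img = np.where(stained, 1.0 - absorb, img)

    img = np.clip(img, 0.0, 1.0)
    rgb = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    mask = np.stack([tissue, malignant], axis=-1).astype(np.uint8)
    return rgb, mask


@dataclass
class Cohort:
    """In-memory synthetic cohort: manifest plus per-slide images and masks."""

    spec: CohortSpec
    manifest: Manifest
    images: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]

    def save(self, out_dir: str | Path) -> Path:
        """Write PNG slides, PNG masks and the manifest CSV."""
        import imageio.v3 as iio

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        records = []
        for rec in self.manifest:
            img_path = out / "images" / f"{rec.slide_id}.png"
            iio.imwrite(img_path, self.images[rec.slide_id])
            mask = self.masks[rec.slide_id]
            mask_rgb = np.zeros(mask.shape[:2] + (3,), dtype=np.uint8)
            mask_rgb[:, :, 0] = mask[:, :, 0] * 255
            mask_rgb[:, :, 1] = mask[:, :, 1] * 255
            iio.imwrite(out / "masks" / f"{rec.slide_id}.png", mask_rgb)
            records.append(replace(rec, image_uri=str(img_path)))
        Manifest(records).to_csv(out / "manifest.csv")
        return out / "manifest.csv"


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate ``n_per_class`` slides per class across the spec's labs.

    Labs, sites and subcategories are assigned cyclically so that every lab
    holds all classes (required for lab-held-out splits).  Slide seeds derive
    from ``spec.seed`` through a SeedSequence, so the cohort is reproducible
    and slides are mutually independent.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_slides = spec.n_per_class * 3
    children = ss.spawn(n_slides)
    records, images, masks = [], {}, {}
    idx = 0
    for ci, label in enumerate((Label.MALIGNANT, Label.BENIGN_OTHER, Label.INSUFFICIENT)):
        subs = SUBCATEGORIES[label]
        for i in range(spec.n_per_class):
            lab = spec.labs[(i + ci) % len(spec.labs)]
            slide_id = f"{label.value}_{i:03d}"
            seed = int(children[idx].generate_state(1)[0] % (2**31))
            img, mask = generate_slide(label, lab, spec, seed)
            records.append(
                SlideRecord(
                    slide_id=slide_id,
                    image_uri=f"synthetic://{slide_id}",
                    label=label,
                    subcategory=subs[i % len(subs)],
                    site=SITES[i % len(SITES)],
                    lab=lab.name,
                )
            )
            images[slide_id] = img
            masks[slide_id] = mask
            idx += 1
    cohort = Cohort(spec=spec, manifest=Manifest(records), images=images, masks=masks)
    if out_dir is not None:
        cohort.save(out_dir)
    return cohort


def tissue_fraction(mask: np.ndarray) -> float:
    """Fraction of slide area covered by tissue, from a ground-truth mask."""
    return float(mask[:, :, 0].mean())


def mean_color_features(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """(mean non-white RGB per slide, integer labels) — the naive baseline
    representation used to audit cohort difficulty."""
    from .attention_mil import LABEL_TO_INDEX

    feats, labels = [], []
    for rec in cohort.manifest:
        img = cohort.images[rec.slide_id].astype(np.float64) / 255.0
        nonwhite = img.min(axis=2) < 0.97
        if nonwhite.any():
            feats.append(img[nonwhite].mean(axis=0))
        else:
            feats.append(np.ones(3))
        labels.append(LABEL_TO_INDEX[rec.label.value])
    return np.asarray(feats), np.asarray(labels)
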