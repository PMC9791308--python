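"""Slide manifests, cohort splitting, tiled image readers, and feature-bag persistence.

A *manifest* is the bookkeeping unit of a weakly supervised study: one row per
slide (one slide per patient), carrying only the slide-level diagnosis and the
staining provenance (site, lab) needed for generalization-aware splits.  The
reader contract abstracts pyramid access so that proprietary scanner formats
can be plugged in without touching the pipeline; plain raster images and
in-memory arrays are supported out of the box.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd


class Label(str, enum.Enum):
    """Slide-level diagnostic category."""

    MALIGNANT = "malignant"
    BENIGN_OTHER = "benign_other"
    INSUFFICIENT = "insufficient"


#: Case-folded synonyms accepted in manifest CSVs.  Clinical exports spell the
#: benign category several ways; everything maps onto the three canonical labels.
LABEL_SYNONYMS: Mapping[str, Label] = {
    "malignant": Label.MALIGNANT,
    "benign_other": Label.BENIGN_OTHER,
    "benign": Label.BENIGN_OTHER,
    "other/benign": Label.BENIGN_OTHER,
    "normal/benign": Label.BENIGN_OTHER,
    "other_benign": Label.BENIGN_OTHER,
    "other": Label.BENIGN_OTHER,
    "insufficient": Label.INSUFFICIENT,
}

MANIFEST_COLUMNS = ("slide_id", "image_uri", "label", "subcategory", "site", "lab")


class ManifestError(ValueError):
    """Schema or invariant violation in a slide manifest."""


def parse_label(raw: str) -> Label:
    key = str(raw).strip().casefold()
    if key not in LABEL_SYNONYMS:
        raise ManifestError(f"unknown slide label {raw!r}")
    return LABEL_SYNONYMS[key]


@dataclass(frozen=True)
class SlideRecord:
    slide_id: str
    image_uri: str
    label: Label
    subcategory: str = ""
    site: str = ""
    lab: str = ""


@dataclass
class Manifest:
    """Ordered collection of slide records with unique ids."""

    records: list[SlideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.slide_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestError(f"duplicate slide_id(s): {dupes}")
        for r in self.records:
            if not str(r.lab):
                raise ManifestError(f"slide {r.slide_id}: empty lab")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SlideRecord]:
        return iter(self.records)

    @property
    def slide_ids(self) -> list[str]:
        return [r.slide_id for r in self.records]

    @property
    def labs(self) -> set[str]:
        return {r.lab for r in self.records}

    def subset(self, slide_ids: Iterable[str]) -> "Manifest":
        wanted = set(slide_ids)
        return Manifest([r for r in self.records if r.slide_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slide_id": r.slide_id,
                    "image_uri": r.image_uri,
                    "label": r.label.value,
                    "subcategory": r.subcategory,
                    "site": r.site,
                    "lab": r.lab,
                }
                for r in self.records
            ],
            columns=list(MANIFEST_COLUMNS),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_manifest(path: str | Path) -> Manifest:
    """Read and validate a CSV slide manifest.

    The header must define the six canonical columns; labels are case-folded
    through the synonym table.  Rows with unknown labels raise a
    :class:`ManifestError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            label = parse_label(row["label"])
        except ManifestError as exc:
            raise ManifestError(f"manifest {path} row {i}: {exc}") from None
        records.append(
            SlideRecord(
                slide_id=row["slide_id"],
                image_uri=row["image_uri"],
                label=label,
                subcategory=row["subcategory"],
                site=row["site"],
                lab=row["lab"],
            )
        )
    return Manifest(records)


# ---------------------------------------------------------------------------
# Cohort splitting
# ---------------------------------------------------------------------------


def _stratum_key(record: SlideRecord, keys: Sequence[str]) -> tuple:
    return tuple(getattr(record, k) if k != "label" else record.label.value for k in keys)


def _stratified_draw(
    records: list[SlideRecord],
    fraction: float,
    stratify_keys: Sequence[str],
    rng: np.random.Generator,
) -> list[SlideRecord]:
    """Draw ``fraction`` of ``records``, balanced over the stratification keys.

    Per-stratum allocations use largest-remainder rounding against a global
    target of ``round(fraction * n)``; ties are broken by stratum key order and,
    within a stratum, slides are drawn from a seeded shuffle of the
    lexicographically sorted ids so the draw is deterministic and auditable.
    """
    n_total = len(records)
    target = int(round(fraction * n_total))
    strata: dict[tuple, list[SlideRecord]] = {}
    for r in records:
        strata.setdefault(_stratum_key(r, stratify_keys), []).append(r)
    keys = sorted(strata)
    quotas = {k: fraction * len(strata[k]) for k in keys}
    alloc = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = target - sum(alloc.values())
    # Remainder ties are broken by a seeded shuffle: deterministic, but without
    # the systematic bias a lexicographic order would give to early labels.
    tie_rank = {k: int(r) for k, r in zip(keys, rng.permutation(len(keys)))}
    if leftover > 0:
        by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - alloc[k]), tie_rank[k]))
        for k in by_remainder[:leftover]:
            alloc[k] += 1
    elif leftover < 0:
        by_remainder = sorted(keys, key=lambda k: (quotas[k] - alloc[k], tie_rank[k]))
        for k in by_remainder[: -leftover]:
            alloc[k] = max(0, alloc[k] - 1)
    chosen: list[SlideRecord] = []
    for k in keys:
        members = sorted(strata[k], key=lambda r: r.slide_id)
        take = alloc[k]
        if take > len(members):
            warnings.warn(
                f"stratum {k}: requested {take} slides but only {len(members)} available; "
                "taking all (best effort)",
                stacklevel=3,
            )
            take = len(members)
        order = rng.permutation(len(members))
        chosen.extend(members[i] for i in order[:take])
    return chosen


def split_cohort(
    manifest: Manifest,
    held_out_labs: Iterable[str] = (),
    val_fraction: float = 0.25,
    test_fraction_other: float = 0.10,
    stratify_keys: Sequence[str] = ("label", "subcategory", "lab"),
    seed: int = 0,
) -> tuple[Manifest, Manifest, Manifest]:
    """Split a cohort into (train, val, test) with lab-level hold-out.

    The test set contains every slide from ``held_out_labs`` plus a stratified
    ``test_fraction_other`` draw from the remaining labs (the lab hold-out
    probes generalization to unseen staining protocols).  The validation set is
    then a stratified ``val_fraction`` draw of what remains.  The three parts
    partition the manifest and are deterministic given ``seed``.
    """
    held = set(held_out_labs)
    unknown = held - manifest.labs
    if unknown:
        raise ManifestError(f"held_out_labs not present in manifest: {sorted(unknown)}")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    held_records = [r for r in manifest if r.lab in held]
    other = [r for r in manifest if r.lab not in held]
    test_draw = _stratified_draw(other, test_fraction_other, stratify_keys, rng)
    test_ids = {r.slide_id for r in held_records} | {r.slide_id for r in test_draw}

    remaining = [r for r in other if r.slide_id not in test_ids]
    val_draw = _stratified_draw(remaining, val_fraction, stratify_keys, rng)
    val_ids = {r.slide_id for r in val_draw}

    train = Manifest([r for r in manifest if r.slide_id not in test_ids | val_ids])
    val = Manifest([r for r in manifest if r.slide_id in val_ids])
    test = Manifest([r for r in manifest if r.slide_id in test_ids])
    return train, val, test


# ---------------------------------------------------------------------------
# Tiled image readers
# ---------------------------------------------------------------------------


class ReaderError(RuntimeError):
    pass


class BoundsError(ReaderError):
    pass


class ArraySlideReader:
    """In-memory pyramid reader over a level-0 RGB array.

    Lower-resolution levels are emulated by 2x block-mean downsampling, which
    is what scanner pyramids approximate.  All region coordinates are level-0
    based, origin top-left, x rightward, y downward, half-open extents.
    """

    def __init__(self, image: np.ndarray, max_levels: int = 8, min_side: int = 32):
        image = np.asarray(image)
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ReaderError("expected an H x W x 3 image")
        self._levels = [np.ascontiguousarray(image)]
        while (
            len(self._levels) < max_levels
            and min(self._levels[-1].shape[:2]) // 2 >= min_side
        ):
            self._levels.append(_block_mean_2x(self._levels[-1]))

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""
        h, w = self._levels[0].shape[:2]
        return (w, h)

    @property
    def level_count(self) -> int:
        return len(self._levels)

    @property
    def level_downsamples(self) -> list[int]:
        return [2**i for i in range(len(self._levels))]

    def read_region(self, x: int, y: int, level: int, w: int, h: int) -> np.ndarray:
        """Return a ``h x w x 3`` tile.  (x, y) are level-0 coordinates; (w, h)
        are in pixels of the requested level."""
        if not 0 <= level < len(self._levels):
            raise ReaderError(f"unsupported pyramid level {level}")
        ds = 2**level
        img = self._levels[level]
        lx, ly = x // ds, y // ds
        if x < 0 or y < 0 or lx + w > img.shape[1] or ly + h > img.shape[0]:
            raise BoundsError(
                f"region ({x},{y},{w}x{h}) at level {level} exceeds slide bounds"
            )
        return img[ly : ly + h, lx : lx + w].copy()

    def get_thumbnail(self, downsample: int) -> np.ndarray:
        """Closest pyramid level at or above the requested downsample."""
        level = min(
            range(len(self._levels)),
            key=lambda i: abs(self.level_downsamples[i] - downsample),
        )
        return self._levels[level].copy()

    def level_image(self, level: int) -> np.ndarray:
        return self._levels[level].copy()


class RasterSlideReader(ArraySlideReader):
    """Reader for plain raster slides (PNG/TIFF) loaded fully into memory."""

    def __init__(self, path: str | Path, **kwargs):
        import imageio.v3 as iio

        image = iio.imread(path)
        if image.ndim == 3 and image.shape[2] == 4:
            image = image[:, :, :3]
        super().__init__(image, **kwargs)
        self.path = Path(path)


def open_slide(uri: str | Path) -> ArraySlideReader:
    return RasterSlideReader(uri)


def _block_mean_2x(img: np.ndarray) -> np.ndarray:
    h, w = img.shape[:2]
    h2, w2 = h // 2 * 2, w // 2 * 2
    x = img[:h2, :w2].astype(np.float64)
    x = x.reshape(h2 // 2, 2, w2 // 2, 2, -1).mean(axis=(1, 3))
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(x), 0, 255).astype(img.dtype)
    return x.astype(img.dtype)


# ---------------------------------------------------------------------------
# Feature-bag persistence
# ---------------------------------------------------------------------------


@dataclass
class FeatureBag:
    """Per-slide bag of patch features aligned to grid coordinates.

    ``features`` is N x D (D = 1024 for the reference encoder); ``coords`` is
    N x 2 level-0 (x, y) patch origins in the same row order.
    """

    slide_id: str
    features: np.ndarray
    coords: np.ndarray
    patch_size: int = 256

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32).reshape(
            -1, self.features.shape[-1] if np.ndim(self.features) > 1 else 0
        )
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"bag {self.slide_id}: {self.features.shape[0]} feature rows vs "
                f"{self.coords.shape[0]} coordinates"
            )

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


class BagIOError(IOError):
    pass


def _write_bag(group: h5py.Group, bag: FeatureBag) -> None:
    group.create_dataset("features", data=bag.features.astype(np.float32))
    group.create_dataset("coords", data=bag.coords.astype(np.int64))
    group.attrs["slide_id"] = bag.slide_id
    group.attrs["patch_size"] = bag.patch_size


def _read_bag(group: h5py.Group) -> FeatureBag:
    feats = np.asarray(group["features"], dtype=np.float32)
    coords = np.asarray(group["coords"], dtype=np.int64)
    if feats.ndim != 2 or coords.ndim != 2 or coords.shape[1] != 2:
        raise BagIOError("corrupt feature container: bad dataset shapes")
    if feats.shape[0] != coords.shape[0]:
        raise BagIOError(
            f"corrupt feature container: {feats.shape[0]} features vs "
            f"{coords.shape[0]} coords"
        )
    return FeatureBag(
        slide_id=str(group.attrs.get("slide_id", "")),
        features=feats,
        coords=coords,
        patch_size=int(group.attrs.get("patch_size", 256)),
    )


def save_feature_bag(bag: FeatureBag, path: str | Path) -> None:
    """Persist a bag in an HDF5 container (datasets ``features`` and ``coords``)."""
    with h5py.File(path, "w") as f:
        _write_bag(f, bag)


def load_feature_bag(path: str | Path) -> FeatureBag:
    with h5py.File(path, "r") as f:
        return _read_bag(f)


def save_feature_bags(bags: Iterable[FeatureBag], path: str | Path) -> None:
    """Persist several bags in one container, one group per slide_id."""
    with h5py.File(path, "w") as f:
        for bag in bags:
            _write_bag(f.create_group(bag.slide_id), bag)


def load_feature_bags(path: str | Path) -> dict[str, FeatureBag]:
    out: dict[str, FeatureBag] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            out[name] = _read_bag(f[name])
    return out
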