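"""Patch feature extraction behind a pluggable encoder contract.

An encoder maps a batch of fixed-size RGB patches to fixed-length feature
vectors (1024-d by default, matching a ResNet50 truncated after its third
residual stage with adaptive mean pooling — the standard backbone for
weakly supervised slide classification).  Two encoders ship with the package:

* :class:`ConvFeatureEncoder` — a small truncated convolutional network with
  adaptive mean-spatial pooling, seeded random weights by default and
  loadable weights otherwise.  The architecture alone fixes the output
  dimension at 1024.
* :class:`LinearPatchEncoder` (via :func:`make_test_encoder`) — a fixed
  seeded random linear projection of the block-mean-downsampled patch.  It is
  cheap, deterministic and exactly linear in the input, which makes it the
  workhorse for desk-scale experiments and for input-gradient computations.

No color normalization is applied at any point; patches enter at native 8-bit
scale divided by 255.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .slide_io import FeatureBag


@dataclass
class EncoderSpec:
    """Descriptor for an encoder: name, output dimension and input size."""

    name: str
    output_dim: int = 1024
    input_size: int = 256
    weights: object | None = None

    def __post_init__(self) -> None:
        if self.output_dim <= 0:
            raise ValueError("output_dim must be positive")


class PatchEncoder(Protocol):
    spec: EncoderSpec

    def encode_batch(self, patches: np.ndarray) -> np.ndarray: ...


def _as_float01(patches: np.ndarray) -> np.ndarray:
    patches = np.asarray(patches)
    if np.issubdtype(patches.dtype, np.integer):
        return patches.astype(np.float64) / 255.0
    return patches.astype(np.float64)


def _check_patches(patches: Sequence[np.ndarray] | np.ndarray, size: int) -> np.ndarray:
    if isinstance(patches, np.ndarray) and patches.ndim == 4:
        items = list(patches)
    else:
        items = [np.asarray(p) for p in patches]
    for i, p in enumerate(items):
        if p.shape != (size, size, 3):
            raise ValueError(f"patch {i}: expected {size}x{size}x3, got {p.shape}")
    if not items:
        return np.zeros((0, size, size, 3))
    return np.stack(items)


class LinearPatchEncoder:
    """Fixed random linear projection of the block-mean-downsampled patch.

    ``feature = P.T @ vec(blockmean(x))`` with P drawn once from a seeded
    standard normal scaled by 1/sqrt(d_in).  Linearity makes input gradients
    exact: ``d(w . f)/dx`` distributes ``P @ w`` uniformly over each block.
    """

    def __init__(self, dim: int = 1024, seed: int = 0, input_size: int = 256, pool: int = 16):
        if dim <= 0:
            raise ValueError("dim must be positive")
        if input_size % pool != 0:
            raise ValueError("input_size must be divisible by pool")
        rng = np.random.default_rng(seed)
        d_in = pool * pool * 3
        self.pool = pool
        self.block = input_size // pool
        self.projection = rng.standard_normal((d_in, dim)) / np.sqrt(d_in)
        self.spec = EncoderSpec(
            name=f"linear-proj-{dim}d-seed{seed}",
            output_dim=dim,
            input_size=input_size,
            weights=None,
        )

    def _downsample(self, batch: np.ndarray) -> np.ndarray:
        b, h, w, c = batch.shape
        p, k = self.pool, self.block
        return batch.reshape(b, p, k, p, k, c).mean(axis=(2, 4))

    def encode_batch(self, patches: np.ndarray) -> np.ndarray:
        batch = _as_float01(_check_patches(patches, self.spec.input_size))
        pooled = self._downsample(batch).reshape(batch.shape[0], -1)
        return pooled @ self.projection

    def input_gradient(self, feature_grad: np.ndarray) -> np.ndarray:
        """Gradient of ``feature_grad . feature`` w.r.t. the input patch.

        Exact for this (linear) encoder: back-project through P, then spread
        each pooled-pixel gradient uniformly over its block (mean pooling).
        """
        g = (self.projection @ np.asarray(feature_grad)).reshape(self.pool, self.pool, 3)
        g = g / (self.block * self.block)
        return np.kron(g.transpose(2, 0, 1), np.ones((self.block, self.block))).transpose(1, 2, 0)


def make_test_encoder(dim: int = 1024, seed: int = 0, input_size: int = 256, pool: int = 16) -> LinearPatchEncoder:
    """Cheap deterministic encoder for desk-scale tests and experiments."""
    return LinearPatchEncoder(dim=dim, seed=seed, input_size=input_size, pool=pool)


class ConvFeatureEncoder:
    """Truncated convolutional encoder with adaptive mean-spatial pooling.

    Three conv stages (3 -> 64 -> 256 -> 1024 channels, each preceded by mean
    pooling) followed by global adaptive mean pooling yield a 1024-d vector,
    mirroring the channel width at the third residual stage of a ResNet50.
    Weights are seeded He-initialized random filters unless a weight blob is
    supplied; random projections of this form preserve patch similarity
    structure well enough for desk-scale work, and the architecture alone
    fixes the output dimension.
    """

    STAGES = ((3, 64, 4), (64, 256, 2), (256, 1024, 2))  # (c_in, c_out, pre-pool)

    def __init__(self, seed: int = 0, input_size: int = 256, weights: list[np.ndarray] | None = None):
        rng = np.random.default_rng(seed)
        self.filters: list[np.ndarray] = []
        for c_in, c_out, _ in self.STAGES:
            fan_in = c_in * 9
            if weights is not None:
                self.filters.append(np.asarray(weights[len(self.filters)], dtype=np.float64))
            else:
                self.filters.append(
                    rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)
                )
        self.spec = EncoderSpec(
            name="conv-trunc-1024",
            output_dim=1024,
            input_size=input_size,
            weights="seeded-random" if weights is None else "loaded",
        )

    @staticmethod
    def _mean_pool(x: np.ndarray, k: int) -> np.ndarray:
        c, h, w = x.shape
        return x[:, : h // k * k, : w // k * k].reshape(c, h // k, k, w // k, k).mean(axis=(2, 4))

    @staticmethod
    def _conv3x3(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
        c_in, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        cols = np.empty((c_in * 9, h * w))
        idx = 0
        for dy in range(3):
            for dx in range(3):
                cols[idx * c_in : (idx + 1) * c_in] = xp[:, dy : dy + h, dx : dx + w].reshape(c_in, -1)
                idx += 1
        w_mat = filt.transpose(2, 3, 1, 0).reshape(c_in * 9, -1)  # match cols layout
        out = w_mat.T @ cols
        return out.reshape(-1, h, w)

    def encode_batch(self, patches: np.ndarray) -> np.ndarray:
        batch = _as_float01(_check_patches(patches, self.spec.input_size))
        feats = np.empty((batch.shape[0], 1024))
        for i in range(batch.shape[0]):
            x = batch[i].transpose(2, 0, 1)
            for filt, (_, _, k) in zip(self.filters, self.STAGES):
                x = self._mean_pool(x, k)
                x = np.maximum(self._conv3x3(x, filt), 0.0)
            feats[i] = x.mean(axis=(1, 2))  # adaptive mean-spatial pooling
        return feats


def encode_patches(
    patches: Sequence[np.ndarray] | np.ndarray,
    encoder: PatchEncoder,
    batch_size: int = 64,
    slide_id: str = "",
    coords: np.ndarray | None = None,
    patch_size: int | None = None,
) -> FeatureBag:
    """Encode patches into a :class:`FeatureBag`, preserving patch order.

    Encoding is performed in evaluation mode — no augmentation, identical
    output for identical input — and is invariant to ``batch_size``.
    """
    arr = _check_patches(patches, encoder.spec.input_size)
    n = arr.shape[0]
    chunks = [
        encoder.encode_batch(arr[i : i + batch_size]) for i in range(0, n, batch_size)
    ]
    feats = np.concatenate(chunks, axis=0) if chunks else np.zeros((0, encoder.spec.output_dim))
    if coords is None:
        coords = np.zeros((n, 2), dtype=np.int64)
    return FeatureBag(
        slide_id=slide_id,
        features=feats.astype(np.float32),
        coords=coords,
        patch_size=patch_size or encoder.spec.input_size,
    )
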