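"""Attention heatmaps and input-optimization feature visualization.

The heatmap renders per-patch attention weights for one class branch over a
slide thumbnail through a diverging colormap (red = high attention, blue =
low).  Feature visualization asks what input the trained classifier "wants to
see" for each class: starting from a zero image, plain gradient ascent on the
class logit (before the softmax) at a fixed learning rate for a fixed number
of epochs.  The defaults — 256x256 input, learning rate 0.001, 1000 epochs —
match standard practice for this kind of activation maximization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Protocol

import numpy as np
from matplotlib import colormaps

from .attention_mil import AttentionScores
from .tissue_seg import PatchGrid


@dataclass
class HeatmapConfig:
    colormap: str = "coolwarm"  # diverging, red = high, blue = low
    alpha: float = 0.5
    normalize: Literal["percentile", "minmax"] = "percentile"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class FeatVizConfig:
    size: int = 256
    lr: float = 0.001
    epochs: int = 1000
    init: Literal["zeros"] = "zeros"
    clamp: tuple[float, float] | None = None  # optional value clamp, off by default

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def _normalize_weights(w: np.ndarray, mode: str) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if mode == "percentile":
        lo, hi = np.percentile(w, [1, 99]) if w.size > 1 else (w.min(), w.max())
        w = np.clip(w, lo, hi)
    elif mode != "minmax":
        raise ValueError(f"unknown normalization {mode!r}")
    span = w.max() - w.min()
    if span <= 0:
        return np.full_like(w, 0.5)
    return (w - w.min()) / span


def attention_heatmap(
    attn: AttentionScores,
    grid: PatchGrid,
    thumb: np.ndarray,
    class_index: int,
    config: HeatmapConfig | None = None,
    downsample: float = 1.0,
) -> np.ndarray:
    """Alpha-blend per-patch attention for one class branch onto a thumbnail.

    ``downsample`` is the ratio of level-0 pixels per thumbnail pixel, used to
    scale the level-0 patch footprints.  A pure function of its arguments.
    """
    config = config or HeatmapConfig()
    if not 0 <= class_index < attn.weights.shape[1]:
        raise IndexError(f"class_index {class_index} out of range")
    if attn.weights.shape[0] != len(grid):
        raise ValueError("attention rows do not align with the patch grid")
    weights = _normalize_weights(attn.weights[:, class_index], config.normalize)
    cmap = colormaps[config.colormap]
    colors = (np.asarray(cmap(weights))[:, :3] * 255.0)
    out = np.asarray(thumb, dtype=np.float64).copy()
    H, W = out.shape[:2]
    extent = grid.patch_size * 2**grid.level
    for color, (x, y) in zip(colors, grid.coords):
        x0, y0 = int(x / downsample), int(y / downsample)
        x1 = min(W, int(np.ceil((x + extent) / downsample)))
        y1 = min(H, int(np.ceil((y + extent) / downsample)))
        if x1 <= x0 or y1 <= y0:
            continue
        out[y0:y1, x0:x1] = (1 - config.alpha) * out[y0:y1, x0:x1] + config.alpha * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


class DifferentiableModel(Protocol):
    """An image classifier exposing logits and their input gradient."""

    def logits(self, image: np.ndarray) -> np.ndarray: ...

    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray: ...


class LinearLogitModel:
    """``logits[c] = sum(W[c] * x) + b[c]`` — the closed-form reference model."""

    def __init__(self, W: np.ndarray, b: np.ndarray | None = None):
        self.W = np.asarray(W, dtype=np.float64)
        self.b = np.zeros(self.W.shape[0]) if b is None else np.asarray(b, dtype=np.float64)

    def logits(self, image: np.ndarray) -> np.ndarray:
        flat = np.asarray(image, dtype=np.float64).reshape(-1)
        return self.W.reshape(self.W.shape[0], -1) @ flat + self.b

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.logits(image)

    def input_gradient(self, image: np.ndarray, class_index: int) -> np.ndarray:
        return self.W[class_index].reshape(np.asarray(image).shape).astype(np.float64)


def feature_visualization(
    model: DifferentiableModel,
    class_index: int,
    config: FeatVizConfig | None = None,
    shape: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimize an input image to maximize one class logit.

    Starts from a zero image of ``shape`` (default ``size x size x 3``) and
    performs plain gradient ascent — ``x <- x + lr * d logit / dx`` — for
    ``epochs`` steps.  No jitter, decay or frequency regularization is applied
    in this default path, and pixel values are not clamped unless
    ``config.clamp`` is set.  Returns the optimized image and the per-epoch
    logit trace (length ``epochs + 1``, including the starting logit).
    """
    config = config or FeatVizConfig()
    if shape is None:
        shape = (config.size, config.size, 3)
    x = np.zeros(shape, dtype=np.float64)
    trace = [float(np.asarray(model.logits(x)).ravel()[class_index])]
    for step in range(config.epochs):
        g = np.asarray(model.input_gradient(x, class_index), dtype=np.float64)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient at step {step} (|g|max="
                f"{np.abs(g[np.isfinite(g)]).max() if np.isfinite(g).any() else 'nan'})"
            )
        x = x + config.lr * g
        if config.clamp is not None:
            x = np.clip(x, *config.clamp)
        trace.append(float(np.asarray(model.logits(x)).ravel()[class_index]))
    return x, np.asarray(trace)
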