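"""Online image preprocessing and augmentation.

Inference-time preprocessing is letterboxing alone: the frame is resized to
fit a 640 x 640 canvas with its aspect ratio preserved and the remainder
padded with mid-gray.  Training-time augmentation composes four stochastic
ops in order — horizontal flip (p = 0.50), random resize (shorter-side scale
0.90-1.10 with +/-10% aspect-ratio jitter), random crop (side ratio
0.80-1.00, sub-0.80 proposals rejected and redrawn) and HSV jitter (hue
+/-0.015 additive with wrap, saturation and value multiplicative gains of
1 +/- 0.70 and 1 +/- 0.40).  Everything is generated per image per
iteration from a seeded generator, so an epoch's augmented stream is
reproducible without storing augmented images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import color as _skcolor

__all__ = [
    "LetterboxResult",
    "AugmentConfig",
    "letterbox",
    "random_flip",
    "random_resize",
    "random_crop",
    "hsv_jitter",
    "augment",
]

#: Conventional letterbox pad fill, per 8-bit channel.
PAD_FILL = 114


def _round_half_away(x: float) -> int:
    """Round half away from zero (fixed so resized dims are bit-stable)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class LetterboxResult:
    """A letterboxed image plus the geometry needed to invert it."""

    image: np.ndarray          # target x target x C
    scale: float               # target / max(H, W)
    pad: tuple[int, int, int, int]  # top, bottom, left, right (pixels)

    @property
    def content_shape(self) -> tuple[int, int]:
        t, b, l, r = self.pad
        return (self.image.shape[0] - t - b, self.image.shape[1] - l - r)


@dataclass
class AugmentConfig:
    """Augmentation parameters; defaults are the training-pipeline values."""

    flip_p: float = 0.50
    resize_scale: tuple[float, float] = (0.90, 1.10)
    aspect_jitter: float = 0.10
    crop_ratio: tuple[float, float] = (0.80, 1.00)
    hsv_h: float = 0.015
    hsv_s: float = 0.70
    hsv_v: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.resize_scale, self.crop_ratio):
            if not (0.0 < lo <= hi < 2.0):
                raise ValueError("augmentation intervals must lie within (0, 2)")
        if not 0.0 <= self.flip_p <= 1.0:
            raise ValueError("flip_p must be a probability")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _resize(image: np.ndarray, h: int, w: int) -> np.ndarray:
    """Bilinear resize via Pillow (deterministic, matches uint8 pipelines)."""
    out = Image.fromarray(image).resize((w, h), Image.BILINEAR)
    return np.asarray(out)


def letterbox(image: np.ndarray, target: int = 640) -> LetterboxResult:
    """Fit an image onto a square canvas without distortion.

    ``scale = target / max(H, W)``; the content is resized to
    ``round(H*scale) x round(W*scale)`` (round half away from zero) and
    centered, pads filled with mid-gray; an odd leftover pixel goes to the
    bottom/right edge.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None].repeat(3, axis=2)
    h, w = arr.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("empty image")
    scale = target / max(h, w)
    nh = min(target, max(1, _round_half_away(h * scale)))
    nw = min(target, max(1, _round_half_away(w * scale)))
    content = _resize(arr, nh, nw) if (nh, nw) != (h, w) else arr
    top = (target - nh) // 2
    bottom = target - nh - top
    left = (target - nw) // 2
    right = target - nw - left
    canvas = np.full((target, target, arr.shape[2]), PAD_FILL, dtype=arr.dtype)
    canvas[top:target - bottom, left:target - right] = content
    return LetterboxResult(image=canvas, scale=scale, pad=(top, bottom, left, right))


def random_flip(image: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Horizontal mirror with probability ``p``; identity otherwise."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if rng.random() < p:
        return np.asarray(image)[:, ::-1].copy()
    return np.asarray(image)


def random_resize(
    image: np.ndarray,
    scale_interval: tuple[float, float] = (0.90, 1.10),
    aspect_jitter: float = 0.10,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rescale with the shorter side drawn from ``scale_interval``.

    The shorter side is multiplied by u ~ Uniform[lo, hi]; the aspect ratio
    (long/short) by an independent v ~ Uniform[1-j, 1+j].  Output dimensions
    are at least 1 px.
    """
    rng = np.random.default_rng() if rng is None else rng
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    u = rng.uniform(*scale_interval)
    v = rng.uniform(1.0 - aspect_jitter, 1.0 + aspect_jitter)
    if h <= w:  # h is the shorter side
        nh = max(1, _round_half_away(h * u))
        nw = max(1, _round_half_away(w * u * v))
    else:
        nw = max(1, _round_half_away(w * u))
        nh = max(1, _round_half_away(h * u * v))
    if (nh, nw) == (h, w):
        return arr
    return _resize(arr, nh, nw)


def random_crop(
    image: np.ndarray,
    ratio_interval: tuple[float, float] = (0.80, 1.00),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Crop a uniformly placed window whose side ratio is in the interval.

    Proposals whose realized ratio falls below the interval's lower bound
    (possible through integer rounding) are rejected and redrawn.
    """
    rng = np.random.default_rng() if rng is None else rng
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image too small to crop (need at least 2 x 2)")
    lo, hi = ratio_interval
    if lo >= 1.0 and hi >= 1.0:
        return arr
    for _ in range(100):
        r = rng.uniform(lo, hi)
        ch, cw = _round_half_away(h * r), _round_half_away(w * r)
        ch, cw = min(ch, h), min(cw, w)
        if ch / h < lo - 1e-12 or cw / w < lo - 1e-12 or ch < 1 or cw < 1:
            continue  # realized ratio under the floor: reject, redraw
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        return arr[top:top + ch, left:left + cw]
    raise RuntimeError("random_crop: no admissible window in 100 proposals")


def hsv_jitter(
    image: np.ndarray,
    h: float = 0.015,
    s: float = 0.70,
    v: float = 0.40,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Color jitter in HSV space.

    Hue shifts additively by Uniform[-h, +h] (wrapping at 1); saturation and
    value are scaled by 1 + Uniform[-s, +s] and 1 + Uniform[-v, +v] with the
    result clipped to [0, 1] before conversion back to RGB.
    """
    rng = np.random.default_rng() if rng is None else rng
    arr = np.asarray(image)
    dh = rng.uniform(-h, h)
    gs = 1.0 + rng.uniform(-s, s)
    gv = 1.0 + rng.uniform(-v, v)
    hsv = _skcolor.rgb2hsv(arr.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * gs, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * gv, 0.0, 1.0)
    out = _skcolor.hsv2rgb(hsv)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """One training-time augmentation pass: flip -> resize -> crop -> HSV.

    Pass an external generator to draw successive epochs from one seeded
    stream; with ``rng=None`` a fresh generator is created from
    ``config.seed`` (so repeated calls are then identical).
    """
    rng = config.rng() if rng is None else rng
    out = random_flip(image, config.flip_p, rng)
    out = random_resize(out, config.resize_scale, config.aspect_jitter, rng)
    out = random_crop(out, config.crop_ratio, rng)
    out = hsv_jitter(out, config.hsv_h, config.hsv_s, config.hsv_v, rng)
    return out
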