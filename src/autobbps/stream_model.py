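"""Frame vocabulary, per-frame observations and the pluggable classifier seam.

The scoring engine consumes a stream of per-frame classifier outputs drawn
from a fixed six-class vocabulary: the four Boston Bowel Preparation Scale
cleanliness grades (BBPS 0-3), the ileocecal landmark and instrument
operation.  Any classifier that can map an image to a
:class:`FrameObservation` can drive the engine; a synthetic *oracle*
classifier that reads the category encoded into generator-produced frames
is provided so the whole pipeline is testable without a trained network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameCategory",
    "VOCABULARY",
    "CATEGORY_WEIGHTS",
    "CLEANLINESS",
    "ILEOCECAL",
    "INSTRUMENT",
    "canonical_category",
    "FrameObservation",
    "ClassifierContract",
    "SyntheticFrameError",
    "oracle_classify",
    "top_k",
    "encode_frame",
    "read_labels_csv",
    "write_labels_csv",
]


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameCategory:
    """One member of the six-class frame vocabulary.

    ``weight`` is the contribution of one counted frame of this category to
    the cumulative score numerator: 3/6/9 for BBPS 1/2/3, zero for BBPS 0,
    the ileocecal landmark and instrument frames.
    """

    name: str
    weight: int
    index: int  # fixed vocabulary position, used for deterministic tie-breaks

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


BBPS0 = FrameCategory("BBPS 0", 0, 0)
BBPS1 = FrameCategory("BBPS 1", 3, 1)
BBPS2 = FrameCategory("BBPS 2", 6, 2)
BBPS3 = FrameCategory("BBPS 3", 9, 3)
ILEOCECAL = FrameCategory("ileocecal part", 0, 4)
INSTRUMENT = FrameCategory("instrument", 0, 5)

#: Fixed vocabulary order; also the tie-break order for equal confidences.
VOCABULARY: tuple[FrameCategory, ...] = (
    BBPS0, BBPS1, BBPS2, BBPS3, ILEOCECAL, INSTRUMENT,
)

#: The four cleanliness grades, in score order.
CLEANLINESS: tuple[FrameCategory, ...] = (BBPS0, BBPS1, BBPS2, BBPS3)

CATEGORY_WEIGHTS: dict[str, int] = {c.name: c.weight for c in VOCABULARY}

_BY_LOWER = {c.name.lower(): c for c in VOCABULARY}


def canonical_category(label: str | FrameCategory) -> FrameCategory:
    """Resolve a label to its vocabulary member, case-insensitively.

    Accepts e.g. ``"Instrument"`` or ``"bbps 3"``; the canonical spelling is
    the lowercase ``"instrument"`` / title-case ``"BBPS 3"`` form.
    """
    if isinstance(label, FrameCategory):
        return label
    key = str(label).strip().lower()
    try:
        return _BY_LOWER[key]
    except KeyError:
        raise ValueError(
            f"unknown frame category {label!r}; expected one of "
            f"{[c.name for c in VOCABULARY]}"
        ) from None


# --------------------------------------------------------------------------
# Observations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameObservation:
    """One frame's classifier output: the atomic input to scoring.

    ``confidence_vector``, when present, maps every category name to its
    score; ``confidence`` must then equal the vector's maximum (within 1e-6).
    """

    frame_index: int
    category: FrameCategory
    confidence: float
    timestamp: float | None = None
    confidence_vector: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.confidence_vector is not None:
            vec = {canonical_category(k).name: float(v)
                   for k, v in self.confidence_vector.items()}
            object.__setattr__(self, "confidence_vector", vec)
            if sum(vec.values()) > 1.0 + 1e-6:
                raise ValueError("confidence_vector sums to more than 1")
            if abs(max(vec.values()) - self.confidence) > 1e-6:
                raise ValueError(
                    "confidence must equal max(confidence_vector) within 1e-6"
                )


def top_k(
    confidence_vector: Mapping[str, float], k: int,
) -> list[tuple[FrameCategory, float]]:
    """Ranked top-k (category, confidence) pairs from a confidence vector.

    Descending by confidence; ties broken by fixed vocabulary order. This is
    the deployment-style report: the system surfaces the top five predicted
    categories with their confidences for each image.
    """
    if not 1 <= k <= len(VOCABULARY):
        raise ValueError(f"k must be in [1, {len(VOCABULARY)}], got {k}")
    scored = {canonical_category(name): float(v)
              for name, v in confidence_vector.items()}
    full = [(c, scored.get(c, 0.0)) for c in VOCABULARY]
    full.sort(key=lambda cv: (-cv[1], cv[0].index))
    return full[:min(k, len(full))]


# --------------------------------------------------------------------------
# Classifier contract
# --------------------------------------------------------------------------

@dataclass
class ClassifierContract:
    """Adapter seam for any per-frame classifier.

    ``classify`` maps an H x W x 3 uint8 image to a :class:`FrameObservation`
    and must be deterministic for a fixed image.  Exported neural models
    (e.g. ONNX) plug in here: the adapter is expected to letterbox to
    ``input_size`` and emit a six-float confidence vector; no model file
    ships with this package.
    """

    classify: Callable[[np.ndarray, int], FrameObservation]
    model_id: str = "unspecified"
    input_size: int = 640

    def __call__(self, image: np.ndarray, frame_index: int = 0) -> FrameObservation:
        return self.classify(image, frame_index)


# --------------------------------------------------------------------------
# Synthetic frame encoding + oracle classifier
# --------------------------------------------------------------------------

class SyntheticFrameError(ValueError):
    """Raised when an image does not carry the synthetic category encoding."""


# Reserved border hues (degrees), 60 degrees apart so the +/-0.015-turn hue
# jitter (~5.4 degrees) can never move one category's hue into another's cell.
_CATEGORY_HUES = {c.name: 60.0 * c.index for c in VOCABULARY}

_BORDER_FRAC = 0.08   # border width as a fraction of the short side
_CONF_RING = 2        # width in px of the grayscale confidence ring


def _border_width(h: int, w: int) -> int:
    return max(4, int(round(_BORDER_FRAC * min(h, w))))


def _hue_to_rgb(hue_deg: float) -> np.ndarray:
    """Fully saturated, full-value RGB for a hue in degrees (uint8)."""
    import colorsys

    r, g, b = colorsys.hsv_to_rgb((hue_deg % 360.0) / 360.0, 1.0, 1.0)
    return np.array([round(r * 255), round(g * 255), round(b * 255)], dtype=np.uint8)


def encode_frame(
    category: str | FrameCategory,
    confidence: float = 1.0,
    size: tuple[int, int] = (96, 96),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a synthetic frame that unambiguously encodes its category.

    The outer border is a solid reserved hue (one per category, 60 degrees
    apart); just inside it a 2-px grayscale ring encodes the confidence as
    ``round(confidence * 255)``.  The interior is filled with seeded noise
    standing in for mucosa texture.  :func:`oracle_classify` inverts this
    encoding exactly on unaugmented frames.
    """
    cat = canonical_category(category)
    if not (0.0 <= confidence <= 1.0):
        raise ValueError("confidence outside [0, 1]")
    h, w = size
    if h < 16 or w < 16:
        raise ValueError("synthetic frames must be at least 16 x 16")
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = _hue_to_rgb(_CATEGORY_HUES[cat.name])
    b = _border_width(h, w)
    level = int(round(confidence * 255))
    img[b:-b, b:-b] = level
    inner = b + _CONF_RING
    if rng is None:
        rng = np.random.default_rng(cat.index)
    img[inner:-inner, inner:-inner] = rng.integers(
        40, 200, size=(h - 2 * inner, w - 2 * inner, 3), dtype=np.uint8
    )
    return img


def _decode_hue(rgb: np.ndarray) -> float:
    """Hue in degrees of a mean RGB triple; NaN for achromatic pixels."""
    import colorsys

    r, g, b = (float(x) / 255.0 for x in rgb)
    hue, sat, val = colorsys.rgb_to_hsv(r, g, b)
    if sat < 0.2 or val < 0.05:
        return math.nan
    return hue * 360.0


def oracle_classify(image: np.ndarray, frame_index: int = 0) -> FrameObservation:
    """Read the category (and confidence) encoded into a synthetic frame.

    Acts as the test stand-in for a trained per-frame network: deterministic,
    never wrong on generator output.  Raises :class:`SyntheticFrameError` on
    images that do not carry the encoding (e.g. natural photographs).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3 or min(arr.shape[:2]) < 16:
        raise SyntheticFrameError("not a synthetic frame: bad shape")
    h, w = arr.shape[:2]
    b = _border_width(h, w)
    ring = np.concatenate([
        arr[:b].reshape(-1, 3), arr[-b:].reshape(-1, 3),
        arr[b:-b, :b].reshape(-1, 3), arr[b:-b, -b:].reshape(-1, 3),
    ])
    if ring.std(axis=0).max() > 8.0:
        raise SyntheticFrameError("not a synthetic frame: border is not solid")
    hue = _decode_hue(ring.mean(axis=0))
    if math.isnan(hue):
        raise SyntheticFrameError("not a synthetic frame: achromatic border")
    best, dist = None, math.inf
    for name, ref in _CATEGORY_HUES.items():
        d = abs((hue - ref + 180.0) % 360.0 - 180.0)
        if d < dist:
            best, dist = name, d
    if dist > 20.0:
        raise SyntheticFrameError(
            f"not a synthetic frame: border hue {hue:.1f} matches no category"
        )
    conf_ring = arr[b:b + _CONF_RING, b:w - b]
    confidence = float(conf_ring.mean()) / 255.0
    cat = canonical_category(best)
    return FrameObservation(
        frame_index=frame_index,
        category=cat,
        confidence=min(1.0, max(0.0, confidence)),
    )


#: Ready-to-use oracle wrapped in the classifier contract.
ORACLE = ClassifierContract(
    classify=lambda img, idx=0: oracle_classify(img, idx),
    model_id="synthetic-oracle",
)


# --------------------------------------------------------------------------
# Frame-label CSV I/O
# --------------------------------------------------------------------------

def read_labels_csv(path: str | Path) -> list[FrameObservation]:
    """Read a frame-label table (columns frame_index, category, confidence)."""
    df = pd.read_csv(path)
    required = {"frame_index", "category", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label CSV missing columns: {sorted(missing)}")
    obs = [
        FrameObservation(
            frame_index=int(row.frame_index),
            category=canonical_category(row.category),
            confidence=float(row.confidence),
        )
        for row in df.itertuples(index=False)
    ]
    obs.sort(key=lambda o: o.frame_index)
    return obs


def write_labels_csv(path: str | Path, observations: Iterable[FrameObservation]) -> None:
    df = pd.DataFrame(
        [
            {
                "frame_index": o.frame_index,
                "category": o.category.name,
                "confidence": o.confidence,
            }
            for o in observations
        ]
    )
    df.to_csv(path, index=False)
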