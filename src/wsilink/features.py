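"""Feature extraction and similarity measures for slide thumbnails.

A linkage attacker works on fixed-length embeddings of whole-slide image
(WSI) thumbnails.  This module owns the image container, the preprocessing
contract (networks and hand-crafted extractors alike consume square inputs,
224 px by default), a pluggable extractor registry with a deterministic
built-in descriptor, and the two similarity measures used to rank candidate
patients: cosine similarity (range [-1, 1]) and an inverse-squared-distance
Euclidean similarity (range (0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
from PIL import Image

__all__ = [
    "ImageThumb",
    "ExtractorSpec",
    "FeatureVector",
    "register_extractor",
    "registered_extractors",
    "get_extractor_spec",
    "preprocess_image",
    "extract_features",
    "cosine_similarity",
    "euclidean_similarity",
    "similarity_matrix",
    "MEASURES",
    "DEFAULT_EXTRACTOR",
]

DEFAULT_EXTRACTOR = "grid-stats-512"


@dataclass
class ImageThumb:
    """An RGB thumbnail with float pixels in [0, 1].

    ``provenance`` records whether the frame is the whole downscaled slide or
    a crop of its interior ("full-downscaled" | "cropped").
    """

    pixels: np.ndarray
    slide_id: str = ""
    provenance: str = "full-downscaled"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image too small: {px.shape[0]}x{px.shape[1]} (need >= 8)")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixel values")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ExtractorSpec:
    """Declared contract of a feature extractor.

    ``k`` is the output dimension (2048 for a ResNet-style plugin, 512 for the
    built-in descriptor); ``input_side`` the square input size in pixels.
    """

    name: str = DEFAULT_EXTRACTOR
    k: int = 512
    input_side: int = 224
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.input_side <= 0:
            raise ValueError("input_side must be positive")
        if self.k <= 0:
            raise ValueError("output dimension k must be positive")


@dataclass
class FeatureVector:
    values: np.ndarray
    extractor: str = DEFAULT_EXTRACTOR

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite entries")
        self.values = v

    @property
    def k(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_image(image: ImageThumb, mode: str = "downscale", side: int = 224) -> ImageThumb:
    """Fit a thumbnail to a square ``side`` x ``side`` frame.

    ``downscale`` resamples the whole frame with area (box) interpolation, so
    the overall tissue shape survives; ``center_crop`` takes the centred
    window and errors if the image is smaller than the window.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    px = image.pixels
    if mode == "downscale":
        if px.shape[0] == side and px.shape[1] == side:
            out = px
        else:
            channels = [
                np.asarray(
                    Image.fromarray(px[:, :, c].astype(np.float32), mode="F").resize(
                        (side, side), resample=Image.Resampling.BOX
                    ),
                    dtype=np.float64,
                )
                for c in range(3)
            ]
            out = np.clip(np.stack(channels, axis=2), 0.0, 1.0)
        provenance = image.provenance
    elif mode == "center_crop":
        h, w = px.shape[:2]
        if h < side or w < side:
            raise ValueError(f"cannot center-crop {h}x{w} image to {side}x{side}")
        top = (h - side) // 2
        left = (w - side) // 2
        out = px[top : top + side, left : left + side, :]
        provenance = "cropped"
    else:
        raise ValueError(f"unknown preprocess mode {mode!r} (use 'downscale' or 'center_crop')")
    return ImageThumb(pixels=out, slide_id=image.slide_id, provenance=provenance)


# ---------------------------------------------------------------------------
# Extractor registry
# ---------------------------------------------------------------------------

_REGISTRY: Dict[str, Tuple[ExtractorSpec, Callable[[np.ndarray], np.ndarray]]] = {}


def register_extractor(spec: ExtractorSpec, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register ``fn`` (pixels -> length-k vector) under ``spec.name``.

    This is the plugin point for CNN backbones (ResNet, VGG16, Inception,
    SimCLRv2 ...): wrap the network forward pass in a function and declare its
    output dimension.  Violating the declared dimension or returning
    non-finite values is rejected at call time.
    """
    _REGISTRY[spec.name] = (spec, fn)


def registered_extractors() -> Sequence[str]:
    return sorted(_REGISTRY)


def get_extractor_spec(name: str) -> ExtractorSpec:
    try:
        return _REGISTRY[name][0]
    except KeyError:
        raise KeyError(
            f"unknown extractor {name!r}; registered: {', '.join(registered_extractors())}"
        ) from None


def extract_features(image: ImageThumb, spec: ExtractorSpec | str = DEFAULT_EXTRACTOR) -> FeatureVector:
    """Run the named extractor on an already-preprocessed square image."""
    name = spec if isinstance(spec, str) else spec.name
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown extractor {name!r}; registered: {', '.join(registered_extractors())}"
        )
    reg_spec, fn = _REGISTRY[name]
    side = reg_spec.input_side
    if image.pixels.shape[0] != side or image.pixels.shape[1] != side:
        raise ValueError(
            f"extractor {name!r} expects {side}x{side} input, got "
            f"{image.height}x{image.width}; run preprocess_image first"
        )
    values = np.asarray(fn(image.pixels), dtype=np.float64).ravel()
    if values.size != reg_spec.k:
        raise ValueError(
            f"extractor {name!r} declared k={reg_spec.k} but returned {values.size} values"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"extractor {name!r} returned non-finite values")
    return FeatureVector(values=values, extractor=name)


# Gradient-magnitude split point for the 2-bin cell histogram, on [0,1] pixels.
_GRAD_SPLIT = 0.05


def _grid_stats_512(pixels: np.ndarray) -> np.ndarray:
    """Deterministic 512-d descriptor: 8x8 grid of local colour and edge stats.

    Per cell: per-channel mean and standard deviation (6 values) plus a 2-bin
    histogram of gradient magnitude (fractions of cell pixels below/above a
    fixed split), giving 8*8*8 = 512 values, L2-normalised.
    """
    side = pixels.shape[0]
    g = 8
    if side % g != 0:
        raise ValueError(f"grid-stats-512 needs a side divisible by {g}, got {side}")
    cell = side // g
    cells = pixels.reshape(g, cell, g, cell, 3)
    means = cells.mean(axis=(1, 3))
    stds = cells.std(axis=(1, 3))

    gray = pixels @ np.array([0.299, 0.587, 0.114])
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy).reshape(g, cell, g, cell)
    low = (mag < _GRAD_SPLIT).mean(axis=(1, 3))
    high = 1.0 - low

    feat = np.concatenate(
        [means, stds, low[..., None], high[..., None]], axis=2
    ).ravel()
    norm = np.linalg.norm(feat)
    if norm > 0:
        feat = feat / norm
    return feat


register_extractor(ExtractorSpec(name=DEFAULT_EXTRACTOR, k=512, input_side=224), _grid_stats_512)


# ---------------------------------------------------------------------------
# Similarity measures
# ---------------------------------------------------------------------------

def _as_vector(v) -> np.ndarray:
    return np.asarray(getattr(v, "values", v), dtype=np.float64).ravel()


def cosine_similarity(v, w) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1]."""
    a, b = _as_vector(v), _as_vector(w)
    if a.size != b.size:
        raise ValueError(f"dimension mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def euclidean_similarity(v, w) -> float:
    """Inverse squared-distance similarity 1 / (1 + ||v - w||^2), in (0, 1]."""
    a, b = _as_vector(v), _as_vector(w)
    if a.size != b.size:
        raise ValueError(f"dimension mismatch: {a.size} vs {b.size}")
    d = a - b
    return float(1.0 / (1.0 + np.dot(d, d)))


MEASURES: Dict[str, Callable] = {
    "cosine": cosine_similarity,
    "euclidean": euclidean_similarity,
}


def similarity_matrix(probe_vecs: Sequence, background_vecs: Sequence, measure: str = "cosine") -> np.ndarray:
    """All-pairs similarity: entry (i, j) = M(probe_i, background_j)."""
    if len(probe_vecs) == 0 or len(background_vecs) == 0:
        raise ValueError("similarity_matrix requires non-empty probe and background sets")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; use one of {sorted(MEASURES)}")
    P = np.stack([_as_vector(v) for v in probe_vecs])
    B = np.stack([_as_vector(v) for v in background_vecs])
    if P.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {P.shape[1]} vs {B.shape[1]}")
    if measure == "cosine":
        pn = np.linalg.norm(P, axis=1)
        bn = np.linalg.norm(B, axis=1)
        if np.any(pn == 0.0) or np.any(bn == 0.0):
            raise ValueError("cosine similarity undefined for a zero vector")
        return np.clip((P @ B.T) / np.outer(pn, bn), -1.0, 1.0)
    d2 = (
        np.sum(P * P, axis=1)[:, None]
        - 2.0 * (P @ B.T)
        + np.sum(B * B, axis=1)[None, :]
    )
    return 1.0 / (1.0 + np.maximum(d2, 0.0))
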