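"""Deep-feature extractor contract and a deterministic surrogate.

A pretrained convolutional network used in feature-extraction mode is,
from the pipeline's point of view, just a deterministic mapping from an
ROI to a fixed-length real vector.  This module pins down that contract
(:class:`FeatureExtractor`), keeps a registry of the standard ImageNet
backbones with their penultimate-layer dimensions, and provides a
self-contained surrogate extractor -- a bank of seeded random
convolution filters with rectification and global average pooling -- so
the whole pipeline is exercisable without downloading any weights.

The real backbones are optional plugins: requesting one without the
corresponding deep-learning backend installed raises an error naming
the missing backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage import transform as sktransform

from .preprocess import ROIPatch

__all__ = [
    "FeatureExtractor",
    "DeepFeatureVector",
    "EXTRACTOR_REGISTRY",
    "surrogate_extractor",
    "get_extractor",
    "extract_deep",
    "concat_features",
]

#: Penultimate-layer feature dimension of each supported backbone.
EXTRACTOR_REGISTRY: dict[str, dict] = {
    "VGG19": {"backend": "keras", "dim": 4096, "input_size": (224, 224)},
    "VGG16": {"backend": "keras", "dim": 4096, "input_size": (224, 224)},
    "ResNET-50": {"backend": "keras", "dim": 2048, "input_size": (224, 224)},
    "Inception v3": {"backend": "keras", "dim": 2048, "input_size": (299, 299)},
    "Mobilenet v1": {"backend": "keras", "dim": 1024, "input_size": (224, 224)},
    "Mobilenet v2": {"backend": "keras", "dim": 1280, "input_size": (224, 224)},
    "DenseNET-201": {"backend": "keras", "dim": 1920, "input_size": (224, 224)},
    "Xception": {"backend": "keras", "dim": 2048, "input_size": (299, 299)},
}


@dataclass(frozen=True)
class FeatureExtractor:
    """Deterministic mapping from an ROI to a length-``dim`` vector."""

    name: str
    dim: int
    transform: Callable[[ROIPatch], np.ndarray]


@dataclass(frozen=True)
class DeepFeatureVector:
    values: np.ndarray
    extractor_name: str


def surrogate_extractor(
    seed: int, dim: int, input_size: int = 32, patch: int = 7, stride: int = 2
) -> FeatureExtractor:
    """Seeded random-filter extractor standing in for a pretrained CNN.

    The ROI is resized (bilinear) to ``input_size`` square, ``dim``
    random ``patch x patch x 3`` filters are applied with the given
    stride, responses are rectified at zero and globally averaged.  The
    weights are a pure function of ``seed``, so the extractor is
    deterministic, and the output is nonnegative and sensitive to both
    color and texture of the lesion.
    """
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")
    rng = np.random.default_rng(seed)
    n_in = patch * patch * 3
    weights = rng.standard_normal((n_in, dim)) / np.sqrt(n_in)

    def _transform(roi: ROIPatch) -> np.ndarray:
        img = sktransform.resize(
            np.asarray(roi.rgb, dtype=np.float64) / 255.0,
            (input_size, input_size, 3),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
        # im2col: all patch x patch x 3 windows at the given stride
        windows = np.lib.stride_tricks.sliding_window_view(img, (patch, patch, 3))
        windows = windows[::stride, ::stride, 0]
        cols = windows.reshape(-1, n_in)
        responses = np.maximum(0.0, cols @ weights)  # rectifying pooling
        return responses.mean(axis=0)

    return FeatureExtractor(name=f"surrogate-{seed}-{dim}", dim=dim, transform=_transform)


def get_extractor(name: str, seed: int = 0, dim: int = 64) -> FeatureExtractor:
    """Look up an extractor by name.

    ``"surrogate"`` builds the seeded random-filter extractor; any
    registry backbone name attempts to load its deep-learning backend
    and raises a clear error when that backend is unavailable.
    """
    if name == "surrogate":
        return surrogate_extractor(seed=seed, dim=dim)
    if name in EXTRACTOR_REGISTRY:
        entry = EXTRACTOR_REGISTRY[name]
        raise RuntimeError(
            f"extractor {name!r} requires the {entry['backend']!r} backend with "
            f"pretrained weights, which is not installed; use the 'surrogate' "
            f"extractor or install the backend"
        )
    known = ["surrogate", *EXTRACTOR_REGISTRY]
    raise KeyError(f"unknown extractor {name!r}; known: {known}")


def extract_deep(roi: ROIPatch, ex: FeatureExtractor) -> DeepFeatureVector:
    """Apply an extractor to an ROI, validating the declared contract."""
    values = np.asarray(ex.transform(roi), dtype=np.float64)
    if values.shape != (ex.dim,):
        raise ValueError(
            f"extractor {ex.name!r} declared dim {ex.dim} but produced "
            f"shape {values.shape}"
        )
    if not np.isfinite(values).all():
        raise ValueError(f"extractor {ex.name!r} produced non-finite values")
    return DeepFeatureVector(values=values, extractor_name=ex.name)


def concat_features(deep: DeepFeatureVector, hand: np.ndarray) -> np.ndarray:
    """Fuse by concatenation: deep block first, then the 43 handcraft slots."""
    hand = np.asarray(hand, dtype=np.float64)
    if not np.isfinite(hand).all():
        raise ValueError("handcraft vector contains non-finite values")
    return np.concatenate([deep.values, hand])
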