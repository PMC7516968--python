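"""Lesion segmentation and ROI extraction for dermoscopy images.

The preprocessing chain turns a raw RGB dermoscopy image into a cropped
region of interest (ROI) together with a binary lesion mask:

1. Gaussian blur to suppress hair and other curvilinear artifacts.
2. Conversion to the CIE L*a*b* color space (sRGB, D65 white point),
   whose channels decorrelate lightness from chroma and separate the
   darker pigmented lesion from the surrounding skin.
3. Mean thresholding of each of the L, a*, b* channels: a pixel is
   marked 1 when its value is greater than or equal to the channel mean.
4. Pixelwise AND of the three thresholded channels.
5. 5x5 median filtering of the combined mask to remove residual specks.
6. Polarity/component resolution: the lesion is taken to be the largest
   8-connected component (of either mask polarity) that does not touch
   the image border -- lesions are darker than skin and interior to the
   frame, while the bright skin background reaches the border.
7. Tight bounding box around the lesion and cropping of the RGB image,
   its Lab representation, and the mask.

Coordinates are 0-based, half-open, row-major throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import measure

__all__ = [
    "BoundingBox",
    "ROIPatch",
    "gaussian_blur",
    "rgb_to_lab",
    "mean_threshold_channel",
    "combine_masks",
    "median_filter_mask",
    "lesion_mask",
    "bounding_box",
    "preprocess",
]

#: Lesions smaller than this (in pixels) trigger a warning: the mask is
#: probably noise rather than a pigmented lesion.
MIN_LESION_AREA = 25


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based and half-open: rows [row_min, row_max)."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_min, self.row_max), slice(self.col_min, self.col_max))


@dataclass(frozen=True)
class ROIPatch:
    """Cropped lesion region: RGB crop, Lab crop, lesion mask, source box."""

    rgb: np.ndarray  # (H, W, 3) in [0, 255]
    lab: np.ndarray  # (H, W, 3): L in [0, 100], a*, b* chroma
    mask: np.ndarray  # (H, W) uint8 in {0, 1}, lesion = 1
    box: BoundingBox

    def __post_init__(self) -> None:
        if self.rgb.shape[:2] != self.mask.shape or self.lab.shape[:2] != self.mask.shape:
            raise ValueError("rgb, lab and mask must share spatial dimensions")
        if self.mask.sum() < 1:
            raise ValueError("ROI mask must contain at least one lesion pixel")


def _check_rgb(img: np.ndarray, min_size: int = 1) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < min_size or img.shape[1] < min_size:
        raise ValueError(
            f"image too small: {img.shape[:2]}, need at least {min_size}x{min_size}"
        )
    return img.astype(np.float64, copy=False)


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Blur each channel with an isotropic 2-D Gaussian kernel.

    Parameters
    ----------
    img : (H, W, 3) array, values in [0, 255].
    sigma : standard deviation of the kernel in pixels; must be > 0.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    img = _check_rgb(img)
    out = ndi.gaussian_filter(img, sigma=(sigma, sigma, 0), mode="reflect")
    return np.clip(out, 0.0, 255.0)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Standard sRGB -> CIE L*a*b* conversion (D65 white point).

    Input values are in [0, 255]; output L is in [0, 100] and a*, b* in
    their usual chroma ranges (roughly [-128, 127]).
    """
    img = _check_rgb(img)
    return skcolor.rgb2lab(img / 255.0)


def mean_threshold_channel(channel: np.ndarray) -> np.ndarray:
    """Binarize a channel against its own mean: 1 where value >= mean."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise ValueError("cannot threshold an empty channel")
    return (channel >= channel.mean()).astype(np.uint8)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("binary mask must contain only 0 and 1")
    return mask.astype(np.uint8, copy=False)


def combine_masks(m_l: np.ndarray, m_a: np.ndarray, m_b: np.ndarray) -> np.ndarray:
    """Pixelwise AND of the three per-channel threshold masks."""
    m_l, m_a, m_b = (_check_mask(m) for m in (m_l, m_a, m_b))
    if not (m_l.shape == m_a.shape == m_b.shape):
        raise ValueError("mask dimensions differ")
    return (m_l & m_a & m_b).astype(np.uint8)


def median_filter_mask(mask: np.ndarray, size: int = 5) -> np.ndarray:
    """Majority vote in each size x size window (zero-padded at borders)."""
    if size % 2 == 0 or size < 3:
        raise ValueError(f"median filter size must be odd and >= 3, got {size}")
    mask = _check_mask(mask)
    return ndi.median_filter(mask, size=size, mode="constant", cval=0).astype(np.uint8)


def _components(mask: np.ndarray) -> list[tuple[int, bool, np.ndarray]]:
    """8-connected components of a {0,1} mask: (area, touches_border, pixels)."""
    labels = measure.label(mask, connectivity=2)
    out = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        touches = bool(
            comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any()
        )
        out.append((int(comp.sum()), touches, comp))
    return out


def lesion_mask(binmask: np.ndarray) -> np.ndarray:
    """Resolve which component of the thresholded mask is the lesion.

    Candidates are the 8-connected components of the mask's foreground
    and of its background (the thresholding marks bright skin as 1, so
    the darker lesion usually appears as an interior background
    component).  The largest candidate that does not touch the image
    border wins; if every candidate touches the border, the largest
    component overall is returned with a warning.
    """
    binmask = _check_mask(binmask)
    candidates = _components(binmask) + _components(1 - binmask)
    if not candidates:
        raise ValueError("mask has no components")
    interior = [c for c in candidates if not c[1]]
    if interior:
        area, _, comp = max(interior, key=lambda c: c[0])
    else:
        warnings.warn(
            "no off-border component found; falling back to the largest "
            "component overall -- segmentation is likely unreliable",
            stacklevel=2,
        )
        area, _, comp = max(candidates, key=lambda c: c[0])
    return comp.astype(np.uint8)


def bounding_box(mask: np.ndarray) -> BoundingBox:
    """Tightest half-open box enclosing all 1-pixels of the mask."""
    mask = _check_mask(mask)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("cannot bound an empty mask")
    (rmin, cmin), (rmax, cmax) = coords.min(axis=0), coords.max(axis=0)
    return BoundingBox(int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1)


def preprocess(img: np.ndarray, sigma: float = 3.0) -> ROIPatch:
    """Full segmentation chain: raw RGB image -> cropped ROI + lesion mask.

    The blur/threshold/median stages run on the blurred image; the
    returned RGB and Lab crops are taken from the *original* image so
    that downstream color and texture statistics see unsmoothed data.
    """
    img = _check_rgb(img, min_size=16)
    blurred = gaussian_blur(img, sigma)
    lab = rgb_to_lab(blurred)
    th = combine_masks(
        mean_threshold_channel(lab[..., 0]),
        mean_threshold_channel(lab[..., 1]),
        mean_threshold_channel(lab[..., 2]),
    )
    th = median_filter_mask(th, size=5)
    lesion = lesion_mask(th)
    box = bounding_box(lesion)
    if lesion.sum() < MIN_LESION_AREA:
        warnings.warn(
            f"segmented lesion is only {int(lesion.sum())} px "
            f"(< {MIN_LESION_AREA}); result may be noise",
            stacklevel=2,
        )
    sl = box.slices()
    rgb_crop = img[sl[0], sl[1], :]
    return ROIPatch(
        rgb=rgb_crop,
        lab=rgb_to_lab(rgb_crop),
        mask=lesion[sl].astype(np.uint8),
        box=box,
    )
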