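"""ABCD-derived handcraft features: symmetry, shape, color, texture.

The handcraft vector encodes the clinical ABCD reading of a pigmented
skin lesion with image-processing surrogates:

* **Asymmetry** -- one score in [0, 1]: the lesion mask is reflected
  about each of its two principal axes (through the centroid, oriented
  by the second central moments); each axis scores ``1 - FS/A`` where
  ``A`` is the union area of mask and reflection and ``FS`` the area of
  their non-overlapping (symmetric-difference) region; the two axis
  scores are averaged.
* **Shape** -- area (pixel count), perimeter (contour length),
  circularity ``4*pi*area/perimeter**2``, diameter (major-axis length of
  the image-moment ellipse) and eccentricity of that ellipse.
* **Color** -- min, max, population variance and mean of each of the
  R, G, B and L, a*, b* channels over the lesion pixels (24 values).
* **Texture** -- 13 Haralick statistics of the gray-level co-occurrence
  matrix (GLCM) of the quantized luminance, averaged over four
  orientations at distance 1.

The fixed slot order of the 43-element vector is given by
:data:`HANDCRAFT_FEATURE_NAMES`.

A small scoring utility, :func:`tds_score`, implements the clinical
Total Dermatoscopic Score ``TDS = 1.3*A + 0.1*B + 0.5*C + 0.5*D`` with
the standard benign (< 4.75) / suspicious / malignant (> 5.45) cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from skimage import color as skcolor
from skimage import measure

from .preprocess import ROIPatch, _check_mask

__all__ = [
    "ShapeFeatures",
    "ColorFeatures",
    "GLCM",
    "TextureFeatures",
    "HANDCRAFT_FEATURE_NAMES",
    "symmetry",
    "shape_features",
    "color_features",
    "glcm",
    "haralick_features",
    "handcraft_vector",
    "tds_score",
]

#: Default GLCM configuration: luminance quantized to 32 gray levels,
#: distance-1 pairs at 0/45/90/135 degrees, accumulated symmetrically.
DEFAULT_GLCM_LEVELS = 32
DEFAULT_GLCM_DISTANCE = 1
DEFAULT_GLCM_ANGLES = (0.0, 45.0, 90.0, 135.0)

_COLOR_CHANNELS = ("R", "G", "B", "L", "a", "b")
_COLOR_STATS = ("min", "max", "var", "mean")

_TEXTURE_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imcorr1",
    "imcorr2",
)

#: Fixed, documented order of the 43 handcraft slots.
HANDCRAFT_FEATURE_NAMES: tuple[str, ...] = (
    ("symmetry", "area", "perimeter", "circularity", "diameter", "eccentricity")
    + tuple(f"{stat}_{ch}" for ch in _COLOR_CHANNELS for stat in _COLOR_STATS)
    + _TEXTURE_NAMES
)
assert len(HANDCRAFT_FEATURE_NAMES) == 43


@dataclass(frozen=True)
class ShapeFeatures:
    area: float
    perimeter: float
    circularity: float
    diameter: float
    eccentricity: float
    symmetry: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.symmetry,
                self.area,
                self.perimeter,
                self.circularity,
                self.diameter,
                self.eccentricity,
            ]
        )


@dataclass(frozen=True)
class ColorFeatures:
    """24 statistics: {min, max, var, mean} x {R, G, B, L, a*, b*}."""

    values: np.ndarray  # length 24, ordered per HANDCRAFT_FEATURE_NAMES
    names: tuple[str, ...]


@dataclass(frozen=True)
class GLCM:
    """Normalized gray-level co-occurrence matrices, one per offset.

    ``p`` has shape (Ng, Ng, n_offsets); each slice is symmetric and
    sums to 1.
    """

    p: np.ndarray
    levels: int
    offsets: tuple[tuple[int, float], ...]  # (distance, angle in degrees)


@dataclass(frozen=True)
class TextureFeatures:
    asm: float
    contrast: float
    correlation: float
    variance: float
    idm: float
    entropy: float
    sum_average: float
    sum_variance: float
    sum_entropy: float
    difference_variance: float
    difference_entropy: float
    imcorr1: float
    imcorr2: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


# ---------------------------------------------------------------------------
# asymmetry


def _principal_angle(mask: np.ndarray) -> float:
    """Orientation (radians) of the major principal axis from central moments."""
    coords = np.argwhere(mask)
    c = coords.mean(axis=0)
    d = coords - c
    mu20 = np.mean(d[:, 0] ** 2)
    mu02 = np.mean(d[:, 1] ** 2)
    mu11 = np.mean(d[:, 0] * d[:, 1])
    return 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)


def symmetry(mask: np.ndarray) -> float:
    """Average bilateral symmetry about the two principal axes, in [0, 1].

    For each axis the mask is reflected about the axis line through the
    centroid; with ``A`` the union area and ``FS`` the symmetric
    difference, the axis score is ``1 - FS/A``.  1 means perfectly
    bilaterally symmetric, 0 means reflection and original are disjoint.
    """
    mask = _check_mask(mask)
    if mask.sum() < 1:
        raise ValueError("symmetry of an empty mask is undefined")
    theta = _principal_angle(mask)
    coords = np.argwhere(mask).astype(np.float64)
    d = coords - coords.mean(axis=0)
    span = int(np.ceil(np.abs(d).max())) + 2
    width = 2 * span + 1

    def _cells(points: np.ndarray) -> np.ndarray:
        # encode rounded centroid-centered coordinates as unique scalars
        rc = np.rint(points).astype(np.int64) + span
        return np.unique(rc[:, 0] * width + rc[:, 1])

    original = _cells(d)
    scores = []
    for ax_angle in (theta, theta + np.pi / 2.0):
        u = np.array([np.cos(ax_angle), np.sin(ax_angle)])
        householder = 2.0 * np.outer(u, u) - np.eye(2)
        mirrored = _cells(d @ householder.T)  # nearest-neighbor resampling
        n_common = len(np.intersect1d(original, mirrored, assume_unique=True))
        n_union = len(original) + len(mirrored) - n_common
        fs = n_union - n_common  # symmetric difference = false-symmetry area
        scores.append(1.0 - fs / n_union if n_union else 1.0)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# shape


def shape_features(mask: np.ndarray) -> ShapeFeatures:
    """Area, perimeter, circularity and moment-ellipse descriptors of a mask."""
    mask = _check_mask(mask)
    if mask.sum() < 4:
        raise ValueError("shape features need at least 4 lesion pixels")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    # Crofton-formula contour length: unbiased for smooth digital shapes
    # (the line-segment chain count overestimates a disc's perimeter ~5%)
    perimeter = float(measure.perimeter_crofton(mask, directions=4))
    if perimeter <= 0:
        raise ValueError("mask has no measurable contour")
    circularity = 4.0 * np.pi * area / perimeter**2
    diameter = float(props.axis_major_length)
    if props.axis_minor_length == 0:
        warnings.warn(
            "degenerate (1-pixel-wide) mask: eccentricity clamped to 1",
            stacklevel=2,
        )
        eccentricity = 1.0
    else:
        eccentricity = float(props.eccentricity)
    return ShapeFeatures(
        area=area,
        perimeter=perimeter,
        circularity=float(circularity),
        diameter=diameter,
        eccentricity=eccentricity,
        symmetry=symmetry(mask),
    )


# ---------------------------------------------------------------------------
# color


def color_features(roi: ROIPatch, lesion_only: bool = True) -> ColorFeatures:
    """Min/max/variance/mean of R, G, B, L, a*, b* over the lesion pixels.

    With ``lesion_only=False`` the statistics are computed over the whole
    rectangular crop instead.  Variance is the population variance.
    """
    channels = {
        "R": roi.rgb[..., 0],
        "G": roi.rgb[..., 1],
        "B": roi.rgb[..., 2],
        "L": roi.lab[..., 0],
        "a": roi.lab[..., 1],
        "b": roi.lab[..., 2],
    }
    sel = roi.mask.astype(bool) if lesion_only else np.ones(roi.mask.shape, bool)
    values, names = [], []
    for ch, grid in channels.items():
        px = np.asarray(grid, dtype=np.float64)[sel]
        stats = {
            "min": float(px.min()),
            "max": float(px.max()),
            "var": float(px.var()),
            "mean": float(px.mean()),
        }
        for stat in _COLOR_STATS:
            values.append(stats[stat])
            names.append(f"{stat}_{ch}")
    return ColorFeatures(values=np.array(values), names=tuple(names))


# ---------------------------------------------------------------------------
# texture


def glcm(
    gray: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    distance: int = DEFAULT_GLCM_DISTANCE,
    angles: tuple[float, ...] = DEFAULT_GLCM_ANGLES,
    mask: np.ndarray | None = None,
) -> GLCM:
    """Symmetric, normalized co-occurrence matrices of a quantized image.

    Parameters
    ----------
    gray : (H, W) integer grid with values in [0, levels).
    levels : number of gray levels Ng.
    distance : pixel offset distance d.
    angles : offset directions in degrees; 0 is "east" (along rows' +col
        direction), 90 is "north".
    mask : optional boolean grid; when given, only pixel pairs with both
        endpoints inside the mask are counted.

    Each (i, j) co-occurrence is accumulated together with (j, i), and
    every per-offset matrix is normalized to sum 1.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("gray image must be 2-D")
    if not np.issubdtype(gray.dtype, np.integer):
        raise ValueError("gray image must be integer-valued (quantized)")
    if gray.min() < 0 or gray.max() >= levels:
        raise ValueError(f"gray values must lie in [0, {levels})")
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != gray.shape:
            raise ValueError("mask shape must match the gray image")

    mats = []
    offsets = []
    for ang in angles:
        rad = np.radians(ang)
        dr = -int(np.rint(distance * np.sin(rad)))
        dc = int(np.rint(distance * np.cos(rad)))
        h, w = gray.shape
        r0 = slice(max(0, -dr), min(h, h - dr))
        c0 = slice(max(0, -dc), min(w, w - dc))
        r1 = slice(max(0, dr), min(h, h + dr))
        c1 = slice(max(0, dc), min(w, w + dc))
        a = gray[r0, c0].ravel()
        b = gray[r1, c1].ravel()
        valid = (mask[r0, c0] & mask[r1, c1]).ravel()
        a, b = a[valid], b[valid]
        counts = np.zeros((levels, levels), dtype=np.float64)
        np.add.at(counts, (a, b), 1.0)
        counts = counts + counts.T  # symmetric accumulation
        total = counts.sum()
        if total == 0:
            raise ValueError("no valid pixel pairs for GLCM accumulation")
        mats.append(counts / total)
        offsets.append((distance, float(ang)))
    return GLCM(p=np.stack(mats, axis=-1), levels=levels, offsets=tuple(offsets))


def _entropy(p: np.ndarray) -> float:
    """-sum p ln p with 0*ln(0) := 0."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _haralick_single(p: np.ndarray) -> np.ndarray:
    """The 13 texture statistics of one normalized GLCM (natural log)."""
    ng = p.shape[0]
    i = np.arange(ng, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float((((ii - mu_x) * (jj - mu_y) * p).sum()) / (sd_x * sd_y))
    else:
        correlation = 0.0  # single-level image: no linear structure to measure
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    entropy = _entropy(p.ravel())

    # sum and difference distributions over i+j and |i-j|
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=np.float64)
    k_diff = np.arange(ng, dtype=np.float64)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    mu_diff = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - mu_diff) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    # informational measures of correlation
    hx, hy = _entropy(px), _entropy(py)
    hxy = entropy
    outer = np.outer(px, py)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log(outer[pos])).sum())
    pos2 = outer > 0
    hxy2 = float(-(outer[pos2] * np.log(outer[pos2])).sum())
    denom = max(hx, hy)
    imcorr1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imcorr2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            entropy,
            sum_average,
            sum_variance,
            sum_entropy,
            difference_variance,
            difference_entropy,
            imcorr1,
            imcorr2,
        ]
    )


def haralick_features(g: GLCM | np.ndarray) -> TextureFeatures:
    """13 Haralick statistics, averaged over the GLCM's offsets.

    Accepts either a :class:`GLCM` or a single normalized Ng x Ng matrix.
    """
    if isinstance(g, GLCM):
        mats = [g.p[..., k] for k in range(g.p.shape[-1])]
    else:
        g = np.asarray(g, dtype=np.float64)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("expected a square co-occurrence matrix")
        mats = [g]
    vals = []
    for m in mats:
        total = m.sum()
        if total <= 0:
            raise ValueError("co-occurrence matrix is all zero")
        vals.append(_haralick_single(m / total))
    avg = np.mean(vals, axis=0)
    return TextureFeatures(*(float(v) for v in avg))


def _quantize_luminance(roi: ROIPatch, levels: int) -> np.ndarray:
    """Luminance of the RGB crop quantized to [0, levels)."""
    gray = skcolor.rgb2gray(np.asarray(roi.rgb, dtype=np.float64) / 255.0)
    q = np.floor(gray * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def texture_features(
    roi: ROIPatch,
    levels: int = DEFAULT_GLCM_LEVELS,
    distance: int = DEFAULT_GLCM_DISTANCE,
    angles: tuple[float, ...] = DEFAULT_GLCM_ANGLES,
    lesion_only: bool = True,
) -> TextureFeatures:
    """Haralick features of the ROI's quantized luminance."""
    gray = _quantize_luminance(roi, levels)
    mask = roi.mask.astype(bool) if lesion_only else None
    try:
        g = glcm(gray, levels=levels, distance=distance, angles=angles, mask=mask)
    except ValueError:
        # lesion thinner than the offset distance: fall back to the whole crop
        warnings.warn(
            "lesion too small for masked GLCM accumulation; using whole crop",
            stacklevel=2,
        )
        g = glcm(gray, levels=levels, distance=distance, angles=angles)
    return haralick_features(g)


# ---------------------------------------------------------------------------
# assembly


def handcraft_vector(
    roi: ROIPatch,
    glcm_levels: int = DEFAULT_GLCM_LEVELS,
    glcm_distance: int = DEFAULT_GLCM_DISTANCE,
    lesion_only: bool = True,
) -> np.ndarray:
    """The ordered 43-element handcraft feature vector of an ROI.

    Slot order is :data:`HANDCRAFT_FEATURE_NAMES`: symmetry, 5 shape
    features, 24 color statistics, 13 texture statistics.
    """
    shape = shape_features(roi.mask)
    col = color_features(roi, lesion_only=lesion_only)
    tex = texture_features(
        roi, levels=glcm_levels, distance=glcm_distance, lesion_only=lesion_only
    )
    vec = np.concatenate([shape.as_vector(), col.values, tex.as_vector()])
    assert vec.shape == (43,)
    if not np.isfinite(vec).all():
        raise ValueError("non-finite handcraft feature encountered")
    return vec


# ---------------------------------------------------------------------------
# clinical TDS utility

_TDS_BENIGN_MAX = 4.75
_TDS_MALIGNANT_MIN = 5.45


def tds_score(asym: int, borders: int, colors: int, structures: int) -> tuple[float, str]:
    """Total Dermatoscopic Score and its clinical category.

    Parameters follow the clinical ABCD ranges: asymmetry 0-2, abrupt
    border segments 0-8, colors 1-6, dermatoscopic structures 1-4.
    Returns ``(score, category)`` with category one of ``benign`` /
    ``suspicious`` / ``malignant`` (cutoffs 4.75 and 5.45).
    """
    ranges = {
        "asym": (asym, 0, 2),
        "borders": (borders, 0, 8),
        "colors": (colors, 1, 6),
        "structures": (structures, 1, 4),
    }
    for name, (val, lo, hi) in ranges.items():
        if not (isinstance(val, (int, np.integer)) and lo <= val <= hi):
            raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {val!r}")
    score = 1.3 * asym + 0.1 * borders + 0.5 * colors + 0.5 * structures
    if score < _TDS_BENIGN_MAX:
        category = "benign"
    elif score > _TDS_MALIGNANT_MIN:
        category = "malignant"
    else:
        category = "suspicious"
    return float(score), category
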