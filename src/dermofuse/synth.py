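"""Synthetic dermoscopy-like images and feature tables with ground truth.

The image generator emulates the gross structure of a dermoscopy frame:
a lighter skin-colored background carrying a darker, roughly elliptical
pigmented lesion with a controllable number of interior colors, interior
texture, controllable bilateral asymmetry, hair-like curvilinear
artifacts (dark quadratic Bezier arcs, 1-3 px wide), and additive pixel
noise.  Every generated image comes with its exact ground-truth lesion
mask and generating attributes, so segmentation and feature code can be
validated without any external dataset.

Asymmetry is produced by a one-sided radial perturbation of the ellipse
boundary: for polar angle theta in (0, pi) the boundary radius is
inflated by ``asymmetry_level * sin(theta)**2``, which breaks symmetry
about the major axis monotonically in the level while leaving the minor
axis untouched.

The table generator emulates a fused feature matrix: a handful of
informative columns whose class-conditional means are shifted by a
standardized effect size, the rest independent standard normal noise,
with a fixed-count class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .fusion import FeatureMatrix

__all__ = [
    "SyntheticLesionSpec",
    "SyntheticTableSpec",
    "DEFAULT_LESION_PALETTE",
    "SKIN_COLOR",
    "make_lesion_image",
    "make_feature_table",
    "class_lesion_spec",
    "make_two_class_corpus",
]

#: Default light skin tone (warm, above-mean in L, a* and b*).
SKIN_COLOR = (224, 172, 144)

#: Melanin-like lesion colors, darkest first: black, dark brown, brown,
#: light brown, blue-gray, reddish -- the clinically counted palette.
DEFAULT_LESION_PALETTE = (
    (40, 26, 20),
    (74, 44, 28),
    (108, 66, 40),
    (140, 92, 58),
    (88, 92, 104),
    (130, 60, 48),
)


@dataclass
class SyntheticLesionSpec:
    image_size: tuple[int, int] = (450, 600)
    center: tuple[float, float] | None = None  # defaults to image center
    semi_axes: tuple[float, float] = (140.0, 95.0)
    rotation_deg: float = 0.0
    asymmetry_level: float = 0.0  # boundary perturbation amplitude in [0, 1]
    n_colors: int = 2  # 1..6 lesion colors from the palette
    skin_color: tuple[int, int, int] = SKIN_COLOR
    hair_count: int = 0
    noise_sd: float = 2.0  # additive Gaussian noise, intensity units
    texture_amplitude: float = 10.0  # smooth interior intensity modulation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymmetry_level <= 1.0:
            raise ValueError("asymmetry_level must be in [0, 1]")
        if not 1 <= self.n_colors <= 6:
            raise ValueError("n_colors must be in 1..6")
        h, w = self.image_size
        if self.center is None:
            self.center = (h / 2.0, w / 2.0)
        a, b = self.semi_axes
        # maximal boundary radius including the asymmetry bump
        theta = np.linspace(-np.pi, np.pi, 721)
        r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        bump = np.where(theta > 0, np.sin(theta) ** 2, 0.0)
        reach = float((r_ell * (1.0 + self.asymmetry_level * bump)).max())
        cy, cx = self.center
        if (
            cy - reach < 5
            or cx - reach < 5
            or cy + reach > h - 5
            or cx + reach > w - 5
        ):
            raise ValueError("ellipse (with perturbation) must fit with >=5 px margin")


@dataclass(frozen=True)
class SyntheticTableSpec:
    n: int = 2000
    p: int = 1000
    n_informative: int = 10
    class_balance: float = 0.5  # minority fraction
    effect_size: float = 3.0  # standardized mean shift of informative columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.p:
            raise ValueError("n_informative cannot exceed p")
        if not 0.0 < self.class_balance <= 0.5:
            raise ValueError("class_balance must be in (0, 0.5]")


def _lesion_mask_from_spec(spec: SyntheticLesionSpec) -> np.ndarray:
    h, w = spec.image_size
    cy, cx = spec.center
    a, b = spec.semi_axes
    rot = np.radians(spec.rotation_deg)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame
    u = np.cos(rot) * dx + np.sin(rot) * dy
    v = -np.sin(rot) * dx + np.cos(rot) * dy
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    # polar radius of the unperturbed ellipse boundary
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    bump = np.where(theta > 0, np.sin(theta) ** 2, 0.0)
    r_bound = r_ell * (1.0 + spec.asymmetry_level * bump)
    return (rho <= r_bound).astype(np.uint8)


def _paint_lesion(
    canvas: np.ndarray, mask: np.ndarray, spec: SyntheticLesionSpec, rng: np.random.Generator
) -> None:
    """Fill the lesion with a Voronoi mosaic of palette colors + texture."""
    coords = np.argwhere(mask)
    palette = np.array(DEFAULT_LESION_PALETTE[: spec.n_colors], dtype=np.float64)
    if spec.n_colors == 1:
        assign = np.zeros(len(coords), dtype=int)
    else:
        # color regions: nearest of a few random seed points per color
        sites = coords[rng.integers(0, len(coords), size=3 * spec.n_colors)]
        site_color = np.repeat(np.arange(spec.n_colors), 3)
        d2 = ((coords[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
        assign = site_color[np.argmin(d2, axis=1)]
    canvas[coords[:, 0], coords[:, 1]] = palette[assign]
    if spec.texture_amplitude > 0:
        field_ = rng.standard_normal(canvas.shape[:2])
        field_ = ndi.gaussian_filter(field_, sigma=4.0)
        field_ /= max(np.abs(field_).max(), 1e-12)
        mod = spec.texture_amplitude * field_[coords[:, 0], coords[:, 1]]
        canvas[coords[:, 0], coords[:, 1]] += mod[:, None]


def _draw_hairs(canvas: np.ndarray, spec: SyntheticLesionSpec, rng: np.random.Generator) -> None:
    """Dark quadratic Bezier arcs, 1-3 px wide, alpha-blended."""
    h, w = spec.image_size
    # dark terminal hair: the skin's melanin hue at much lower lightness,
    # so strands read as shadows rather than as chromatic foreign objects
    hair_color = np.array([128.0, 84.0, 59.0])
    for _ in range(spec.hair_count):
        pts = rng.uniform([0, 0], [h - 1, w - 1], size=(3, 2))
        thick = bool(rng.uniform() < 0.3)  # a minority of coarse 3 px hairs
        alpha = float(rng.uniform(0.25, 0.45)) if thick else float(rng.uniform(0.35, 0.6))
        t = np.linspace(0.0, 1.0, 600)[:, None]
        curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + (t**2) * pts[2]
        stamp = np.zeros((h, w), dtype=bool)
        rr = np.clip(np.rint(curve[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(curve[:, 1]).astype(int), 0, w - 1)
        stamp[rr, cc] = True
        if thick:
            stamp = ndi.binary_dilation(stamp)
        canvas[stamp] = (1 - alpha) * canvas[stamp] + alpha * hair_color


def make_lesion_image(
    spec: SyntheticLesionSpec,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render a synthetic dermoscopy image.

    Returns ``(rgb, mask, attributes)``: a (H, W, 3) uint8 image, the
    exact uint8 ground-truth lesion mask, and the generating attributes
    (true area, axis lengths, asymmetry level, seed).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    mask = _lesion_mask_from_spec(spec)
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:] = np.array(spec.skin_color, dtype=np.float64)
    _paint_lesion(canvas, mask, spec, rng)
    _draw_hairs(canvas, spec, rng)
    if spec.noise_sd > 0:
        canvas += rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    rgb = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    attributes = {
        "true_area": int(mask.sum()),
        "semi_axes": tuple(spec.semi_axes),
        "asymmetry_level": spec.asymmetry_level,
        "n_colors": spec.n_colors,
        "hair_count": spec.hair_count,
        "seed": spec.seed,
    }
    return rgb, mask, attributes


def class_lesion_spec(
    label: int, seed: int, image_size: tuple[int, int] = (450, 600), hair_count: int = 3
) -> SyntheticLesionSpec:
    """Well-separated nevus-like (0) vs melanoma-like (1) lesion spec.

    The nevus class is a compact, nearly symmetric, single-color lesion;
    the melanoma class is elongated, strongly asymmetric, multi-colored
    and more textured -- the axes on which the ABCD rule separates them.
    """
    h, w = image_size
    scale = min(h / 450.0, w / 600.0)
    if label == 0:
        return SyntheticLesionSpec(
            image_size=image_size,
            seed=seed,
            n_colors=1,
            asymmetry_level=0.05,
            semi_axes=(110.0 * scale, 90.0 * scale),
            hair_count=hair_count,
            texture_amplitude=5.0,
        )
    return SyntheticLesionSpec(
        image_size=image_size,
        seed=seed,
        n_colors=4,
        asymmetry_level=0.5,
        semi_axes=(150.0 * scale, 80.0 * scale),
        hair_count=hair_count,
        texture_amplitude=15.0,
    )


def make_two_class_corpus(
    n_images: int, seed: int = 0, image_size: tuple[int, int] = (450, 600)
) -> tuple[list[np.ndarray], np.ndarray]:
    """Alternating nevus-like / melanoma-like labeled image corpus."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n_images):
        label = i % 2
        spec = class_lesion_spec(label, seed=int(rng.integers(2**31)), image_size=image_size)
        rgb, _, _ = make_lesion_image(spec)
        images.append(rgb)
        labels.append(label)
    return images, np.array(labels, dtype=np.int64)


def make_feature_table(spec: SyntheticTableSpec) -> FeatureMatrix:
    """Synthetic feature matrix with known information structure.

    The minority class has exactly ``round(class_balance * n)`` rows
    (label 1).  Informative columns are N(0, 1) for class 0 and
    N(effect_size, 1) for class 1; noise columns are N(0, 1) regardless
    of the label.
    """
    rng = np.random.default_rng(spec.seed)
    n_min = int(round(spec.class_balance * spec.n))
    y = np.zeros(spec.n, dtype=np.int64)
    y[rng.permutation(spec.n)[:n_min]] = 1
    X = rng.standard_normal((spec.n, spec.p))
    X[:, : spec.n_informative] += spec.effect_size * y[:, None]
    names = tuple(
        f"informative_{j}" if j < spec.n_informative else f"noise_{j}"
        for j in range(spec.p)
    )
    return FeatureMatrix(X=X, feature_names=names, y=y)
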