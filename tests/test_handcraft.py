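"""Handcraft features: symmetry, shape, color, GLCM/Haralick, TDS."""

import numpy as np
import pytest

from dermofuse import (
    HANDCRAFT_FEATURE_NAMES,
    color_features,
    glcm,
    handcraft_vector,
    haralick_features,
    shape_features,
    symmetry,
    tds_score,
)
from dermofuse.handcraft import texture_features
from dermofuse.preprocess import ROIPatch, BoundingBox, rgb_to_lab


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius**2).astype(np.uint8)


def reflection_symmetry_oracle(mask):
    """Brute-force pixel oracle: reflect lesion coordinates about each
    principal axis through the centroid, rasterize, count union and
    symmetric difference."""
    coords = np.argwhere(mask).astype(float)
    c = coords.mean(axis=0)
    d = coords - c
    mu20, mu02 = (d[:, 0] ** 2).mean(), (d[:, 1] ** 2).mean()
    mu11 = (d[:, 0] * d[:, 1]).mean()
    theta = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    scores = []
    for ax_angle in (theta, theta + np.pi / 2):
        u = np.array([np.cos(ax_angle), np.sin(ax_angle)])
        refl = 2 * np.outer(u, u) - np.eye(2)
        reflected = d @ refl.T
        orig = {tuple(p) for p in np.rint(d).astype(int)}
        mirr = {tuple(p) for p in np.rint(reflected).astype(int)}
        union = len(orig | mirr)
        fs = len(orig ^ mirr)
        scores.append(1.0 - fs / union)
    return float(np.mean(scores))


class TestSymmetry:
    def test_disc_is_fully_symmetric(self):
        m = disc_mask((101, 101), (50, 50), 35)
        assert symmetry(m) == pytest.approx(1.0, abs=0.02)

    def test_half_disc_matches_pixel_oracle(self):
        m = disc_mask((101, 101), (50, 50), 35)
        m[51:, :] = 0  # half-disc: symmetric about one axis only
        assert symmetry(m) == pytest.approx(reflection_symmetry_oracle(m), abs=0.05)

    def test_asymmetric_blob_matches_pixel_oracle(self, rng):
        m = disc_mask((121, 121), (55, 50), 28)
        m |= disc_mask((121, 121), (75, 75), 18)
        assert symmetry(m) == pytest.approx(reflection_symmetry_oracle(m), abs=0.05)

    def test_translation_invariance(self):
        m1 = disc_mask((101, 101), (40, 40), 20)
        m1[55:61, 30:60] = 1
        m2 = np.roll(np.roll(m1, 5, axis=0), -7, axis=1)
        assert symmetry(m1) == pytest.approx(symmetry(m2), abs=0.01)

    def test_rotation_90_invariance(self):
        m = disc_mask((101, 101), (50, 50), 25)
        m[40:45, 50:90] = 1
        assert symmetry(m) == pytest.approx(symmetry(np.rot90(m).copy()), abs=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            symmetry(np.zeros((10, 10), np.uint8))


class TestShapeFeatures:
    def test_square_area(self):
        m = np.zeros((20, 20), np.uint8)
        m[5:15, 5:15] = 1
        assert shape_features(m).area == 100

    def test_large_disc_circularity_near_one(self):
        m = disc_mask((160, 160), (80, 80), 64)
        assert 0.95 <= shape_features(m).circularity <= 1.1

    def test_rectangle_eccentricity_closed_form(self):
        m = np.zeros((60, 60), np.uint8)
        m[10:20, 10:50] = 1  # 40 x 10 rectangle
        f = shape_features(m)
        expected = np.sqrt(1.0 - (10.0 / 40.0) ** 2)
        assert f.eccentricity == pytest.approx(expected, rel=0.05)
        assert f.diameter > 40.0 * 0.9  # major axis tracks the long side

    def test_disc_beats_ellipses_in_circularity(self):
        """Among equal-area moment ellipses the disc maximizes circularity."""
        area = np.pi * 30 * 30
        circ = []
        for ratio in (1.0, 1.5, 2.5, 4.0):
            b = np.sqrt(area / (np.pi * ratio))
            a = ratio * b
            yy, xx = np.mgrid[0:201, 0:201]
            m = ((((yy - 100) / b) ** 2 + ((xx - 100) / a) ** 2) <= 1).astype(np.uint8)
            circ.append(shape_features(m).circularity)
        assert np.argmax(circ) == 0

    def test_too_few_pixels_raises(self):
        m = np.zeros((10, 10), np.uint8)
        m[3, 3] = 1
        with pytest.raises(ValueError):
            shape_features(m)


def make_roi(rgb, mask):
    rgb = np.asarray(rgb, dtype=float)
    return ROIPatch(
        rgb=rgb,
        lab=rgb_to_lab(rgb),
        mask=mask.astype(np.uint8),
        box=BoundingBox(0, 0, rgb.shape[0], rgb.shape[1]),
    )


class TestColorFeatures:
    def test_constant_lesion_collapses_stats(self):
        rgb = np.full((10, 10, 3), 120.0)
        roi = make_roi(rgb, np.ones((10, 10)))
        f = color_features(roi)
        vals = dict(zip(f.names, f.values))
        for ch in "RGB":
            assert vals[f"min_{ch}"] == vals[f"max_{ch}"] == vals[f"mean_{ch}"] == 120.0
            assert vals[f"var_{ch}"] == 0.0

    def test_two_value_population_variance(self):
        rgb = np.zeros((2, 2, 3))
        rgb[:, 0] = 50.0
        rgb[:, 1] = 150.0
        f = color_features(make_roi(rgb, np.ones((2, 2))))
        vals = dict(zip(f.names, f.values))
        assert vals["mean_R"] == 100.0
        assert vals["var_R"] == 2500.0  # population variance of {50, 150}

    def test_masked_stats_match_brute_force(self, rng):
        rgb = rng.uniform(0, 255, (20, 20, 3))
        mask = (rng.uniform(size=(20, 20)) > 0.5).astype(np.uint8)
        mask[10, 10] = 1
        roi = make_roi(rgb, mask)
        f = color_features(roi, lesion_only=True)
        vals = dict(zip(f.names, f.values))
        sel = mask.astype(bool)
        for i, ch in enumerate("RGB"):
            px = rgb[..., i][sel]
            assert vals[f"min_{ch}"] == px.min()
            assert vals[f"max_{ch}"] == px.max()
            assert vals[f"mean_{ch}"] == pytest.approx(px.mean())
            assert vals[f"var_{ch}"] == pytest.approx(px.var())


def glcm_pair_counting_oracle(gray, levels, dr, dc, mask=None):
    """Exhaustive double loop over all pixel pairs at one offset."""
    h, w = gray.shape
    if mask is None:
        mask = np.ones((h, w), bool)
    counts = np.zeros((levels, levels))
    for i in range(h):
        for j in range(w):
            i2, j2 = i + dr, j + dc
            if 0 <= i2 < h and 0 <= j2 < w and mask[i, j] and mask[i2, j2]:
                counts[gray[i, j], gray[i2, j2]] += 1
                counts[gray[i2, j2], gray[i, j]] += 1
    return counts / counts.sum()


class TestGLCM:
    def test_constant_image_single_diagonal_cell(self):
        g = glcm(np.full((8, 8), 3, dtype=int), levels=8, angles=(0.0,))
        p = g.p[..., 0]
        assert p[3, 3] == 1.0
        assert p.sum() == pytest.approx(1.0)

    def test_checkerboard_off_diagonal_mass(self):
        gray = np.indices((8, 8)).sum(axis=0) % 2
        g = glcm(gray, levels=2, angles=(0.0,))
        p = g.p[..., 0]
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        assert p[0, 0] == p[1, 1] == 0.0

    @pytest.mark.parametrize("angle,dr,dc", [(0.0, 0, 1), (45.0, -1, 1), (90.0, -1, 0), (135.0, -1, -1)])
    def test_matches_pair_counting_oracle(self, rng, angle, dr, dc):
        gray = rng.integers(0, 4, (8, 8))
        g = glcm(gray, levels=4, angles=(angle,))
        oracle = glcm_pair_counting_oracle(gray, 4, dr, dc)
        np.testing.assert_allclose(g.p[..., 0], oracle, atol=1e-12)

    def test_masked_accumulation_matches_oracle(self, rng):
        gray = rng.integers(0, 4, (10, 10))
        mask = rng.uniform(size=(10, 10)) > 0.4
        g = glcm(gray, levels=4, angles=(0.0,), mask=mask)
        oracle = glcm_pair_counting_oracle(gray, 4, 0, 1, mask)
        np.testing.assert_allclose(g.p[..., 0], oracle, atol=1e-12)

    def test_agrees_with_skimage_reference(self, rng):
        from skimage.feature import graycomatrix

        gray = rng.integers(0, 8, (16, 16)).astype(np.uint8)
        g = glcm(gray, levels=8, angles=(0.0,))
        ref = graycomatrix(gray, [1], [0.0], levels=8, symmetric=True, normed=True)
        np.testing.assert_allclose(g.p[..., 0], ref[..., 0, 0], atol=1e-12)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match="values"):
            glcm(np.full((4, 4), 9, dtype=int), levels=8)


def haralick_oracle(p):
    """Independent double-loop evaluation of all 13 texture statistics."""
    ng = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = np.zeros(2 * ng - 1)
    p_diff = np.zeros(ng)
    asm = contrast = corr = var = idm = ent = 0.0
    hxy1 = hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            p_sum[i + j] += v
            p_diff[abs(i - j)] += v
            asm += v * v
            contrast += (i - j) ** 2 * v
            if sd_x > 0 and sd_y > 0:
                corr += (i - mu_x) * (j - mu_y) * v / (sd_x * sd_y)
            var += (i - mu_x) ** 2 * v
            idm += v / (1 + (i - j) ** 2)
            if v > 0:
                ent -= v * np.log(v)
            if px[i] * py[j] > 0:
                if v > 0:
                    hxy1 -= v * np.log(px[i] * py[j])
                hxy2 -= px[i] * py[j] * np.log(px[i] * py[j])
    sum_avg = sum(k * p_sum[k] for k in range(2 * ng - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * ng - 1))
    sum_ent = -sum(v * np.log(v) for v in p_sum if v > 0)
    mu_d = sum(k * p_diff[k] for k in range(ng))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(ng))
    diff_ent = -sum(v * np.log(v) for v in p_diff if v > 0)
    hx = -sum(v * np.log(v) for v in px if v > 0)
    hy = -sum(v * np.log(v) for v in py if v > 0)
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent))))
    return np.array([asm, contrast, corr, var, idm, ent, sum_avg, sum_var,
                     sum_ent, diff_var, diff_ent, imc1, imc2])


class TestHaralick:
    def test_constant_image_limits(self):
        p = np.zeros((8, 8))
        p[3, 3] = 1.0
        f = haralick_features(p)
        assert f.asm == 1.0
        assert f.entropy == 0.0
        assert f.contrast == 0.0
        assert f.idm == 1.0

    def test_checkerboard_closed_form(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        f = haralick_features(p)
        assert f.contrast == pytest.approx(1.0)
        assert f.asm == pytest.approx(0.5)
        assert f.entropy == pytest.approx(np.log(2))

    @pytest.mark.parametrize("ng", [2, 5, 8, 16])
    def test_matches_double_loop_oracle(self, rng, ng):
        p = rng.uniform(size=(ng, ng))
        p = p + p.T  # symmetric, as produced by accumulation
        p /= p.sum()
        f = haralick_features(p).as_vector()
        np.testing.assert_allclose(f, haralick_oracle(p), atol=1e-10)

    def test_invariant_bounds_on_random_glcms(self, rng):
        for _ in range(20):
            p = rng.uniform(size=(6, 6))
            p /= p.sum()
            f = haralick_features(p)
            assert 0 < f.asm <= 1
            assert f.entropy >= 0
            assert 0 < f.idm <= 1
            assert 0 <= f.imcorr2 <= 1

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            haralick_features(np.zeros((4, 4)))


class TestHandcraftVector:
    def test_length_is_43_and_finite(self, lesion_roi):
        vec = handcraft_vector(lesion_roi)
        assert vec.shape == (43,)
        assert np.isfinite(vec).all()
        assert len(HANDCRAFT_FEATURE_NAMES) == 43

    def test_deterministic(self, lesion_roi):
        np.testing.assert_array_equal(
            handcraft_vector(lesion_roi), handcraft_vector(lesion_roi)
        )

    def test_slots_match_standalone_operations(self, lesion_roi):
        vec = handcraft_vector(lesion_roi)
        shape = shape_features(lesion_roi.mask)
        np.testing.assert_allclose(vec[:6], shape.as_vector())
        col = color_features(lesion_roi)
        np.testing.assert_allclose(vec[6:30], col.values)
        tex = texture_features(lesion_roi)
        np.testing.assert_allclose(vec[30:], tex.as_vector())


class TestTDS:
    @pytest.mark.parametrize(
        "abcd,score,category",
        [
            ((0, 0, 1, 1), 1.0, "benign"),
            ((2, 8, 6, 4), 8.4, "malignant"),
            ((1, 8, 4, 3), 5.6, "malignant"),
            ((1, 5, 3, 2), 4.3, "benign"),
            ((1, 8, 3, 3), 5.1, "suspicious"),
        ],
    )
    def test_weighted_sum_and_category(self, abcd, score, category):
        got_score, got_cat = tds_score(*abcd)
        assert got_score == pytest.approx(score)
        assert got_cat == category

    @pytest.mark.parametrize("abcd", [(3, 0, 1, 1), (0, 9, 1, 1), (0, 0, 0, 1), (0, 0, 1, 5)])
    def test_out_of_range_rejected(self, abcd):
        with pytest.raises(ValueError):
            tds_score(*abcd)
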