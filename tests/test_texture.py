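"""The 49-feature texture panel against brute-force oracles."""

import numpy as np
import pytest

from pctpath import (
    FEATURE_NAMES,
    extract_all,
    gds_features,
    ggcm_features,
    gh_features,
    glcm_features,
    quantize,
    wavelet_features,
)
from pctpath.texture import GDS_DISPLACEMENTS, GLCM_ANGLES, _OFFSETS

LEVELS = 16


def naive_quantize(image, levels):
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if lo == hi:
        return np.zeros(img.shape, dtype=int)
    out = np.empty(img.shape, dtype=int)
    for idx in np.ndindex(img.shape):
        out[idx] = min(int((img[idx] - lo) / (hi - lo) * levels), levels - 1)
    return out


def naive_glcm(image, angle, distance=1, levels=LEVELS):
    """Pairwise double-loop co-occurrence oracle."""
    q = naive_quantize(image, levels)
    dr, dc = (distance * o for o in _OFFSETS[angle])
    counts = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1  # symmetric
    p = counts / counts.sum()
    energy = (p**2).sum()
    homogeneity = contrast = 0.0
    for i in range(levels):
        for j in range(levels):
            homogeneity += p[i, j] / (1 + (i - j) ** 2)
            contrast += (i - j) ** 2 * p[i, j]
    pi_, pj = p.sum(axis=1), p.sum(axis=0)
    mi = sum(i * pi_[i] for i in range(levels))
    mj = sum(j * pj[j] for j in range(levels))
    vi = sum((i - mi) ** 2 * pi_[i] for i in range(levels))
    vj = sum((j - mj) ** 2 * pj[j] for j in range(levels))
    if vi <= 0 or vj <= 0:
        corr = 0.0
    else:
        corr = sum(
            (i - mi) * (j - mj) * p[i, j]
            for i in range(levels) for j in range(levels)
        ) / np.sqrt(vi * vj)
    return energy, homogeneity, contrast, corr


def naive_ggcm(image, levels=LEVELS):
    from scipy import ndimage

    img = np.asarray(image, dtype=float)
    grad = np.hypot(ndimage.sobel(img, axis=0, mode="reflect"),
                    ndimage.sobel(img, axis=1, mode="reflect"))
    qi, qj = naive_quantize(img, levels), naive_quantize(grad, levels)
    H = np.zeros((levels, levels))
    for idx in np.ndindex(img.shape):
        H[qi[idx], qj[idx]] += 1
    T = H.sum()
    p = H / T
    feats = np.zeros(15)
    for i in range(levels):
        for j in range(levels):
            feats[0] += H[i, j] / (j + 1) ** 2 / T
            feats[1] += H[i, j] * j**2 / T
            feats[4] += p[i, j] ** 2
            feats[13] += (i - j) ** 2 * p[i, j]
            feats[14] += p[i, j] / (1 + (i - j) ** 2)
    feats[2] = sum(H[i, :].sum() ** 2 for i in range(levels)) / T
    feats[3] = sum(H[:, j].sum() ** 2 for j in range(levels)) / T
    pi_, pj = p.sum(axis=1), p.sum(axis=0)
    mi = sum(i * pi_[i] for i in range(levels))
    mj = sum(j * pj[j] for j in range(levels))
    vi = sum((i - mi) ** 2 * pi_[i] for i in range(levels))
    vj = sum((j - mj) ** 2 * pj[j] for j in range(levels))
    feats[5], feats[6] = mi, mj
    feats[7], feats[8] = np.sqrt(vi), np.sqrt(vj)
    if vi > 0 and vj > 0:
        feats[9] = sum((i - mi) * (j - mj) * p[i, j]
                       for i in range(levels) for j in range(levels)) / np.sqrt(vi * vj)
    feats[10] = -sum(x * np.log(x) for x in pi_ if x > 0)
    feats[11] = -sum(x * np.log(x) for x in pj if x > 0)
    feats[12] = -sum(x * np.log(x) for x in p.ravel() if x > 0)
    return feats


def naive_gds(image, levels=LEVELS):
    q = naive_quantize(image, levels)
    h, w = q.shape
    feats = np.zeros(4)
    for dr, dc in GDS_DISPLACEMENTS:
        hist = np.zeros(levels)
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    hist[abs(q[r, c] - q[r2, c2])] += 1
        p = hist / hist.sum()
        contrast = sum(k**2 * p[k] for k in range(levels))
        asm = (p**2).sum()
        entropy = -sum(x * np.log(x) for x in p if x > 0)
        mean = sum(k * p[k] for k in range(levels))
        feats += np.array([contrast, asm, entropy, mean])
    return feats / 4


class TestQuantize:
    def test_constant_image_all_zero(self):
        assert np.all(quantize(np.full((5, 5), 9.0)) == 0)

    def test_two_valued_image_hits_extremes(self):
        img = np.array([[0.0, 255.0], [255.0, 0.0]])
        q = quantize(img, 16)
        assert set(q.ravel()) == {0, 15}

    def test_monotone_transform_preserves_level_order(self, rng):
        img = rng.random((8, 8)) * 100
        q1 = quantize(img, 16)
        q2 = quantize(np.exp(img / 50.0), 16)
        # equal ranks of quantized levels under a monotone gray transform
        order1 = np.argsort(img.ravel(), kind="stable")
        assert np.all(np.diff(q1.ravel()[order1]) >= 0)
        assert np.all(np.diff(q2.ravel()[order1]) >= 0)


class TestGlcm:
    def test_constant_image_degenerate_values(self):
        energy, homogeneity, contrast, corr = glcm_features(np.full((8, 8), 3.0))
        assert (energy, homogeneity, contrast, corr) == (1.0, 1.0, 0.0, 0.0)

    def test_checkerboard_contrast(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        _, _, contrast, _ = glcm_features(board, angle=0)
        assert contrast == pytest.approx((LEVELS - 1) ** 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    @pytest.mark.parametrize("angle", GLCM_ANGLES)
    def test_matches_double_loop_oracle(self, seed, angle):
        img = np.random.default_rng(seed).integers(0, 256, (8, 8)).astype(float)
        got = glcm_features(img, angle=angle)
        want = naive_glcm(img, angle)
        assert np.allclose(got, want, atol=1e-12)

    def test_agrees_with_skimage_cooccurrence(self, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 256, (16, 16))
        q = quantize(img.astype(float), LEVELS).astype(np.uint8)
        ref = graycomatrix(q, [1], [0], levels=LEVELS, symmetric=True, normed=True)
        energy, *_ = glcm_features(img.astype(float), angle=0)
        assert energy == pytest.approx(float((ref[:, :, 0, 0] ** 2).sum()), abs=1e-12)

    def test_offset_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((3, 3)) + np.eye(3), angle=0, distance=5)


class TestGgcm:
    def test_constant_image_small_gradient_dominates(self):
        feats = ggcm_features(np.full((8, 8), 5.0))
        assert feats[0] == pytest.approx(1.0)   # E1
        assert feats[1] == pytest.approx(0.0)   # E2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_double_loop_oracle(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (8, 8)).astype(float)
        assert np.allclose(ggcm_features(img), naive_ggcm(img), atol=1e-12)

    def test_energy_bounds(self, rng):
        feats = ggcm_features(rng.integers(0, 256, (12, 12)).astype(float))
        assert 0.0 < feats[4] <= 1.0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ggcm_features(np.zeros((2, 2)))


class TestGh:
    def test_constant_image(self):
        mean, var, skew, kurt, energy = gh_features(np.full((6, 6), 42.0))
        assert (mean, var, skew, kurt, energy) == (42.0, 0.0, 0.0, 0.0, 1.0)

    def test_two_point_distribution(self):
        img = np.concatenate([np.zeros(32), np.full(32, 255.0)]).reshape(8, 8)
        mean, var, skew, kurt, energy = gh_features(img)
        assert mean == pytest.approx(127.5)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert energy == pytest.approx(0.5)

    def test_moments_match_direct_pixel_computation(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(float)
        mean, var, skew, kurt, _ = gh_features(img)
        assert mean == pytest.approx(img.mean(), abs=1e-9)
        assert var == pytest.approx(img.var(), abs=1e-9)
        assert skew == pytest.approx(
            np.mean((img - img.mean()) ** 3) / img.var() ** 1.5, abs=1e-9
        )
        assert kurt == pytest.approx(
            np.mean((img - img.mean()) ** 4) / img.var() ** 2, abs=1e-9
        )


class TestGds:
    def test_constant_image(self):
        assert np.allclose(gds_features(np.full((8, 8), 9.0)), [0.0, 1.0, 0.0, 0.0])

    def test_checkerboard_hand_enumeration(self):
        board = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        contrast, asm, entropy, mean = gds_features(board)
        # horizontal/vertical differences all 15, diagonals all 0
        assert contrast == pytest.approx((15**2 + 15**2 + 0 + 0) / 4)
        assert asm == pytest.approx(1.0)
        assert entropy == pytest.approx(0.0)
        assert mean == pytest.approx((15 + 15 + 0 + 0) / 4)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_double_loop_oracle(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (8, 8)).astype(float)
        assert np.allclose(gds_features(img), naive_gds(img), atol=1e-12)


class TestWavelet:
    def test_constant_image_no_detail_energy(self):
        assert np.allclose(wavelet_features(np.full((16, 16), 5.0)), 0.0)

    def test_period2_stripes_concentrate_in_one_subband(self):
        stripes = np.tile(np.array([0.0, 1.0]), (16, 8))  # vertical stripes, period 2
        feats = wavelet_features(stripes)
        level1 = feats[:3]
        assert level1.max() / feats.sum() > 0.9

    def test_parseval_with_approximation_band(self, rng):
        import pywt

        img = rng.random((32, 32))
        feats = wavelet_features(img)
        coeffs = pywt.wavedec2(img, "haar", level=3, mode="periodization")
        approx_energy = np.sum(coeffs[0] ** 2) / np.sum(img**2)
        assert feats.sum() + approx_energy == pytest.approx(1.0, abs=1e-9)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            wavelet_features(np.zeros((4, 4)))


class TestExtractAll:
    def test_length_and_fixed_name_order(self, rng):
        fv = extract_all(rng.integers(0, 256, (32, 32)).astype(float))
        assert len(fv.values) == 49
        assert fv.names == FEATURE_NAMES
        assert fv.names[:4] == ("A1", "A2", "A3", "A4")
        assert fv.names[16] == "E1" and fv.names[31] == "H1"
        assert fv.names[36] == "I1" and fv.names[40] == "M1"

    def test_constant_image_degenerate_vector(self):
        fv = extract_all(np.full((32, 32), 100.0))
        d = fv.as_dict()
        for angle_prefix in "ABCD":
            assert d[f"{angle_prefix}1"] == 1.0   # energy
            assert d[f"{angle_prefix}3"] == 0.0   # contrast
        assert d["E1"] == 1.0 and d["E2"] == 0.0
        assert d["H1"] == 100.0 and d["H2"] == 0.0 and d["H5"] == 1.0
        assert d["I2"] == 1.0 and d["I1"] == 0.0
        assert all(d[f"M{i}"] == 0.0 for i in range(1, 10))

    def test_gray_shift_invariance_of_quantized_families(self, rng):
        img = rng.integers(0, 200, (16, 16)).astype(float)
        a = extract_all(img).values
        b = extract_all(img + 55.0).values
        # co-occurrence and difference families see the same quantized image
        assert np.allclose(a[:31], b[:31], atol=1e-12)   # A..E
        assert np.allclose(a[36:40], b[36:40], atol=1e-12)  # I

    def test_no_nan_on_texture_dataset(self):
        from pctpath import make_texture_dataset

        images, _ = make_texture_dataset(3, 2, image_size=32, seed=5)
        for img in images:
            assert np.all(np.isfinite(extract_all(img).values))
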