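"""The 49-feature texture panel for tumor micro-structural quantification.

Five classical texture families, concatenated in a fixed order:

* GLCM (A1-D4): gray-level co-occurrence statistics — energy, homogeneity,
  contrast, correlation — at the four unit-distance directions 0deg, 45deg,
  90deg, 135deg (16 symmetric, normalized gray levels);
* GGCM (E1-E15): gray-gradient co-occurrence features — joint statistics of
  the 16-level quantized gray value and the 16-level quantized Sobel
  gradient magnitude at each pixel;
* GH (H1-H5): moments and energy of the 256-bin gray-level histogram;
* GDS (I1-I4): gray-level difference statistics, averaged over the four
  unit displacements (0,1), (1,0), (1,1), (1,-1) on the 16-level image;
* Wavelet (M1-M9): relative energies of the nine detail subbands of a
  3-level 2D Haar decomposition.

Entropies use the natural logarithm with 0*log(0) = 0; correlations are
defined as 0 when a marginal variance vanishes.  Gray quantization is a
linear min-max rescale (a constant image maps entirely to level 0), so the
co-occurrence families are invariant to affine gray rescaling of a
non-constant image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "quantize",
    "glcm_features",
    "ggcm_features",
    "gh_features",
    "gds_features",
    "wavelet_features",
    "extract_all",
]

GLCM_ANGLES = (0, 45, 90, 135)
#: (row, col) offset per direction; 0deg = +column, 90deg = +row
_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{prefix}{i}" for prefix, n in zip("ABCD", [4] * 4) for i in range(1, n + 1)]
    + [f"E{i}" for i in range(1, 16)]
    + [f"H{i}" for i in range(1, 6)]
    + [f"I{i}" for i in range(1, 5)]
    + [f"M{i}" for i in range(1, 10)]
)
assert len(FEATURE_NAMES) == 49


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 49-entry texture descriptor with its fixed label list."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} features, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains non-finite entries")
        object.__setattr__(self, "values", values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def quantize(image: np.ndarray, levels: int = 16) -> np.ndarray:
    """Linear min-max quantization to integer levels 0 .. levels-1.

    A constant image maps entirely to level 0.  Monotone gray transforms
    preserve the rank order of the quantized levels.
    """
    if levels < 2:
        raise ValueError("need at least 2 quantization levels")
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if lo == hi:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy, natural log, 0*log0 = 0."""
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def glcm_features(
    image: np.ndarray,
    angle: int = 0,
    distance: int = 1,
    levels: int = 16,
) -> tuple[float, float, float, float]:
    """(energy, homogeneity, contrast, correlation) of the symmetric GLCM.

    The co-occurrence matrix p(i, j) counts quantized gray-level pairs at
    the given direction/distance offset, symmetrized and normalized to sum
    to 1.  Correlation is 0 when either marginal variance is 0.
    """
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("image must be at least 2x2")
    dr, dc = (distance * o for o in _OFFSETS[angle])
    if abs(dr) >= img.shape[0] or abs(dc) >= img.shape[1]:
        raise ValueError("offset larger than the image")
    q = quantize(img, levels)

    h, w = q.shape
    a = q[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)].ravel()
    b = q[max(0, dr):h - max(0, -dr), max(0, dc):w - max(0, -dc)].ravel()
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T                       # symmetric
    p = counts / counts.sum()

    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    pi_, pj = p.sum(axis=1), p.sum(axis=0)
    mu_i, mu_j = float(i @ pi_), float(i @ pj)
    var_i = float(((i - mu_i) ** 2) @ pi_)
    var_j = float(((i - mu_j) ** 2) @ pj)
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((ii - mu_i) * (jj - mu_j) * p) / np.sqrt(var_i * var_j)
        )
    return energy, homogeneity, contrast, correlation


def ggcm_features(
    image: np.ndarray,
    gray_levels: int = 16,
    gradient_levels: int = 16,
) -> np.ndarray:
    """The 15 gray-gradient co-occurrence features E1 .. E15.

    Gradient magnitude is computed with the Sobel operator; gray value and
    gradient are each min-max quantized (a uniform gradient field maps to
    level 0).  With joint counts H(i, j), total T and p = H/T:

    E1  small gradient dominance   [sum H(i,j)/(j+1)^2] / T
    E2  large gradient dominance   [sum H(i,j)*j^2] / T
    E3  gray-level nonuniformity   [sum_i (sum_j H)^2] / T
    E4  gradient nonuniformity     [sum_j (sum_i H)^2] / T
    E5  energy                     sum p^2
    E6/E7   marginal means of gray (i) and gradient (j)
    E8/E9   marginal standard deviations
    E10 correlation (0 on zero marginal variance)
    E11/E12 gray / gradient marginal entropies
    E13 mixed (joint) entropy
    E14 inertia                    sum (i-j)^2 p
    E15 inverse difference moment  sum p / (1+(i-j)^2)
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be at least 3x3 for the Sobel stencil")
    gz = ndimage.sobel(img, axis=0, mode="reflect")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    grad = np.hypot(gz, gx)
    qi = quantize(img, gray_levels)
    qj = quantize(grad, gradient_levels)

    counts = np.zeros((gray_levels, gradient_levels), dtype=float)
    np.add.at(counts, (qi.ravel(), qj.ravel()), 1.0)
    total = counts.sum()
    p = counts / total
    i = np.arange(gray_levels, dtype=float)
    j = np.arange(gradient_levels, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")

    e1 = float(np.sum(counts / (jj + 1.0) ** 2) / total)
    e2 = float(np.sum(counts * jj**2) / total)
    e3 = float(np.sum(counts.sum(axis=1) ** 2) / total)
    e4 = float(np.sum(counts.sum(axis=0) ** 2) / total)
    e5 = float(np.sum(p**2))
    pi_, pj = p.sum(axis=1), p.sum(axis=0)
    e6, e7 = float(i @ pi_), float(j @ pj)
    var_i = float(((i - e6) ** 2) @ pi_)
    var_j = float(((j - e7) ** 2) @ pj)
    e8, e9 = float(np.sqrt(var_i)), float(np.sqrt(var_j))
    if var_i <= 0 or var_j <= 0:
        e10 = 0.0
    else:
        e10 = float(np.sum((ii - e6) * (jj - e7) * p) / np.sqrt(var_i * var_j))
    e11, e12 = _entropy(pi_), _entropy(pj)
    e13 = _entropy(p.ravel())
    e14 = float(np.sum((ii - jj) ** 2 * p))
    e15 = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    return np.array([e1, e2, e3, e4, e5, e6, e7, e8, e9, e10, e11, e12, e13, e14, e15])


def gh_features(image: np.ndarray) -> np.ndarray:
    """Gray-histogram moments (H1-H5) over integer gray values 0..255.

    Pixel values are floored and clipped to the 8-bit range; with the
    normalized histogram h(k): mean, variance, skewness, kurtosis
    (standardized 3rd/4th moments, 0 on zero variance) and energy sum h^2.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    k = np.clip(np.floor(img).astype(int), 0, 255)
    h = np.bincount(k.ravel(), minlength=256).astype(float)
    h /= h.sum()
    levels = np.arange(256, dtype=float)
    mean = float(levels @ h)
    var = float(((levels - mean) ** 2) @ h)
    if var > 0:
        skew = float(((levels - mean) ** 3) @ h) / var**1.5
        kurt = float(((levels - mean) ** 4) @ h) / var**2
    else:
        skew = kurt = 0.0
    energy = float(np.sum(h**2))
    return np.array([mean, var, skew, kurt, energy])


GDS_DISPLACEMENTS = ((0, 1), (1, 0), (1, 1), (1, -1))


def gds_features(image: np.ndarray, levels: int = 16) -> np.ndarray:
    """Gray-level difference statistics I1-I4, averaged over 4 displacements.

    For each unit displacement, the normalized histogram p(k) of absolute
    quantized-gray differences gives contrast sum k^2 p, angular second
    moment sum p^2, entropy -sum p ln p and mean sum k p; the reported
    features are the averages over (0,1), (1,0), (1,1), (1,-1).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError("image must be at least 2x2")
    q = quantize(img, levels)
    feats = np.zeros(4)
    k = np.arange(levels, dtype=float)
    for dr, dc in GDS_DISPLACEMENTS:
        a = q[max(0, dr):q.shape[0] - max(0, -dr),
              max(0, dc):q.shape[1] - max(0, -dc)]
        b = q[max(0, -dr):q.shape[0] - max(0, dr),
              max(0, -dc):q.shape[1] - max(0, dc)]
        diff = np.abs(a - b).ravel()
        p = np.bincount(diff, minlength=levels).astype(float)
        p /= p.sum()
        contrast = float(k**2 @ p)
        asm = float(np.sum(p**2))
        entropy = _entropy(p)
        mean = float(k @ p)
        feats += np.array([contrast, asm, entropy, mean])
    return feats / len(GDS_DISPLACEMENTS)


def wavelet_features(
    image: np.ndarray,
    wavelet: str = "haar",
    levels: int = 3,
) -> np.ndarray:
    """Relative detail-subband energies of a multilevel 2D wavelet transform.

    M_(3(l-1)+s) is the energy of detail subband s in {horizontal,
    vertical, diagonal} at decomposition level l (level 1 = finest),
    normalized by the total image energy.  Periodized boundary handling
    keeps the transform orthogonal, so the nine detail energies plus the
    approximation energy sum to the image energy.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2**levels:
        raise ValueError(f"image must be at least {2**levels} pixels per side")
    total = float(np.sum(img**2))
    if total == 0:
        return np.zeros(3 * levels)
    coeffs = pywt.wavedec2(img, wavelet, level=levels, mode="periodization")
    # coeffs = [cA_L, (cH_L, cV_L, cD_L), ..., (cH_1, cV_1, cD_1)]
    out = np.zeros(3 * levels)
    for lvl in range(1, levels + 1):            # finest first
        ch, cv, cd = coeffs[-lvl]
        base = 3 * (lvl - 1)
        out[base + 0] = np.sum(ch**2) / total
        out[base + 1] = np.sum(cv**2) / total
        out[base + 2] = np.sum(cd**2) / total
    return out


def extract_all(
    image: np.ndarray,
    levels: int = 16,
    wavelet: str = "haar",
) -> FeatureVector:
    """Full ordered 49-feature panel for one grayscale image.

    Concatenates GLCM at the four directions (A1-D4), the 15 GGCM features
    (E1-E15), the histogram moments (H1-H5), the difference statistics
    (I1-I4) and the nine wavelet subband energies (M1-M9).
    """
    parts = []
    for angle in GLCM_ANGLES:
        parts.extend(glcm_features(image, angle=angle, distance=1, levels=levels))
    parts.extend(ggcm_features(image, gray_levels=levels, gradient_levels=levels))
    parts.extend(gh_features(image))
    parts.extend(gds_features(image, levels=levels))
    parts.extend(wavelet_features(image, wavelet=wavelet))
    return FeatureVector(values=np.asarray(parts, dtype=float))


def extract_table(images, labels=None, levels: int = 16, wavelet: str = "haar"):
    """Feature table (one row per image) as a pandas DataFrame."""
    import pandas as pd

    rows = [extract_all(im, levels=levels, wavelet=wavelet).values for im in images]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        df.insert(0, "label", np.asarray(labels))
    return df
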