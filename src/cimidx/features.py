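"""Fixed-layout 1037-dimensional texture feature vector for an ROI.

Four families, concatenated in a stable named layout:

* A (113, slots 0-112): the nine 3x3 orthogonal-polynomial coefficient
  planes, 12 statistics each, plus 5 first-order ROI statistics.
* B (448, slots 113-560): a two-level 2x2 orthonormal sub-band decomposition
  (basis (1,1)/ sqrt(2), (-1,1)/sqrt(2), decimated by 2; each level-1 band
  decomposed again) giving 16 level-2 sub-bands, with 14 statistical and 14
  spectral measures per sub-band.
* C (336, slots 561-896): the 5x5 bivariate discrete orthogonal-polynomial
  transform (Gram basis, degrees 0..4), DC plane dropped, 14 statistics per
  remaining plane.
* D (140, slots 897-1036): gray-level co-occurrence matrices of the
  8-level-quantized gradient magnitude, 4 directions x 5 distances, 7
  Haralick-style measures each.

All families crop to the mask bounding box and replace pixels outside the
mask with the in-mask mean, so the features are invariant to anything outside
the mask.  The layout is identical on the training and test paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .segment import op_transform

FAMILY_SIZES = {"A": 113, "B": 448, "C": 336, "D": 140}
TOTAL_FEATURES = 1037

_STATS12 = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy",
            "min", "max", "range", "median", "mad", "rms")
_STATS14 = _STATS12 + ("p10", "p90")
_SPECTRAL = ("spec_energy", "spec_entropy") \
    + tuple(f"radial{k}" for k in range(8)) + tuple(f"angular{k}" for k in range(4))
_GLCM_MEASURES = ("contrast", "correlation", "energy", "homogeneity",
                  "entropy", "dissimilarity", "max_prob")
_BANDS = ("LL", "LH", "HL", "HH")
GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))   # 0, 45, 90, 135 degrees
GLCM_DISTANCES = (1, 2, 3, 4, 5)
GLCM_LEVELS = 8


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        assert len(self.values) == len(self.names) == TOTAL_FEATURES
        assert np.all(np.isfinite(self.values)), "non-finite feature values"

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def _build_names() -> tuple[str, ...]:
    names: list[str] = []
    for i in range(3):
        for j in range(3):
            names += [f"A.b{i}{j}.{s}" for s in _STATS12]
    names += [f"A.roi.{s}" for s in ("mean", "variance", "skewness", "kurtosis", "entropy")]
    for b1 in _BANDS:
        for b2 in _BANDS:
            names += [f"B.{b1}{b2}.{s}" for s in _STATS14 + _SPECTRAL]
    for i in range(5):
        for j in range(5):
            if i == j == 0:
                continue
            names += [f"C.b{i}{j}.{s}" for s in _STATS14]
    for d, (dr, dc) in zip((0, 45, 90, 135), GLCM_DIRECTIONS):
        for dist in GLCM_DISTANCES:
            names += [f"D.d{d}r{dist}.{m}" for m in _GLCM_MEASURES]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _build_names()
assert len(FEATURE_NAMES) == TOTAL_FEATURES
assert len(set(FEATURE_NAMES)) == TOTAL_FEATURES


# ---------------------------------------------------------------------------
# shared statistics
# ---------------------------------------------------------------------------

def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, variance (ddof=0), skewness and excess kurtosis; the shape
    statistics are 0 by convention when the variance vanishes."""
    mu = float(x.mean())
    var = float(x.var())
    if var <= 0:
        return mu, 0.0, 0.0, 0.0
    z = (x - mu) / np.sqrt(var)
    return mu, var, float(np.mean(z ** 3)), float(np.mean(z ** 4) - 3.0)


def _entropy16(x: np.ndarray) -> float:
    """Shannon entropy (bits) of a 16-equal-width-bin histogram over the
    observed range; 0 for a constant sample."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=16, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def stats12(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    mu, var, skew, kurt = _moments(x)
    return np.array([
        mu, var, skew, kurt,
        float(np.mean(x ** 2)),            # energy
        _entropy16(x),
        float(x.min()), float(x.max()), float(np.ptp(x)),
        float(np.median(x)),
        float(np.mean(np.abs(x - mu))),    # mean absolute deviation
        float(np.sqrt(np.mean(x ** 2))),   # RMS
    ])


def stats14(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return np.concatenate([stats12(x), np.percentile(x, [10, 90])])


# ---------------------------------------------------------------------------
# ROI preparation
# ---------------------------------------------------------------------------

def _crop_to_mask(roi_image: np.ndarray, roi_mask: np.ndarray,
                  min_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Crop to the mask bounding box; pixels outside the mask are replaced by
    the in-mask mean so content beyond the mask cannot leak into features."""
    img = np.asarray(roi_image, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty ROI mask")
    rr, cc = np.nonzero(mask)
    sl = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
    crop, mcrop = img[sl], mask[sl]
    if crop.shape[0] < min_size or crop.shape[1] < min_size:
        raise ValueError(f"ROI must be at least {min_size}x{min_size} pixels "
                         f"(got {crop.shape[0]}x{crop.shape[1]})")
    fill = crop[mcrop].mean()
    out = np.where(mcrop, crop, fill)
    return out, mcrop


# ---------------------------------------------------------------------------
# family A: orthogonal-polynomial texture (113)
# ---------------------------------------------------------------------------

def extract_family_a(roi_image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    crop, mask = _crop_to_mask(roi_image, roi_mask, min_size=9)
    planes = op_transform(crop).planes
    vals = [stats12(planes[i, j][mask]) for i in range(3) for j in range(3)]
    pix = crop[mask]
    mu, var, skew, kurt = _moments(pix)
    vals.append(np.array([mu, var, skew, kurt, _entropy16(pix)]))
    out = np.concatenate(vals)
    assert out.size == FAMILY_SIZES["A"]
    return out


# ---------------------------------------------------------------------------
# family B: sub-band statistical + spectral (448)
# ---------------------------------------------------------------------------

def subband_split(x: np.ndarray) -> dict[str, np.ndarray]:
    """One orthonormal 2x2 sub-band split (decimation by 2).

    Basis (1,1)/sqrt(2) and (-1,1)/sqrt(2) applied separably to disjoint 2x2
    blocks: sum of the four band energies equals the input energy (Parseval).
    Odd trailing rows/columns are cropped.
    """
    x = np.asarray(x, dtype=float)
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    a, b = x[0::2, 0::2], x[0::2, 1::2]
    c, d = x[1::2, 0::2], x[1::2, 1::2]
    return {
        "LL": (a + b + c + d) / 2.0,
        "LH": (-a + b - c + d) / 2.0,   # horizontal detail
        "HL": (-a - b + c + d) / 2.0,   # vertical detail
        "HH": (a - b - c + d) / 2.0,
    }


def _spectral14(band: np.ndarray) -> np.ndarray:
    power = np.abs(np.fft.fft2(band)) ** 2
    total = float(power.sum())
    if total <= 0:
        return np.zeros(14)
    p = power.ravel() / total
    p = p[p > 0]
    spec_entropy = float(-(p * np.log2(p)).sum())

    fr = np.fft.fftfreq(band.shape[0])[:, None]
    fc = np.fft.fftfreq(band.shape[1])[None, :]
    radius = np.hypot(fr, fc)
    rbin = np.minimum((radius / (radius.max() + 1e-12) * 8).astype(int), 7)
    radial = np.array([power[rbin == k].sum() for k in range(8)])

    angle = np.mod(np.arctan2(fr, fc), np.pi)          # orientation, mod pi
    abin = np.minimum((angle / np.pi * 4).astype(int), 3)
    angular = np.array([power[abin == k].sum() for k in range(4)])
    return np.concatenate([[total, spec_entropy], radial, angular])


def extract_family_b(roi_image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    crop, _ = _crop_to_mask(roi_image, roi_mask, min_size=16)
    level1 = subband_split(crop)
    vals = []
    for b1 in _BANDS:
        level2 = subband_split(level1[b1])
        for b2 in _BANDS:
            band = level2[b2]
            vals.append(np.concatenate([stats14(band), _spectral14(band)]))
    out = np.concatenate(vals)
    assert out.size == FAMILY_SIZES["B"]
    return out


# ---------------------------------------------------------------------------
# family C: bivariate discrete orthogonal polynomials (336)
# ---------------------------------------------------------------------------

#: 1-D Gram (discrete Chebyshev) basis on 5 points, degrees 0..4
GRAM5 = np.array([
    [1.0, 1.0, 1.0, 1.0, 1.0],
    [-2.0, -1.0, 0.0, 1.0, 2.0],
    [2.0, -1.0, -2.0, -1.0, 2.0],
    [-1.0, 2.0, 0.0, -2.0, 1.0],
    [1.0, -4.0, 6.0, -4.0, 1.0],
])


def bivariate_transform(image: np.ndarray) -> np.ndarray:
    """25 sliding-window coefficient planes of the 5x5 bivariate Gram basis:
    beta_ij = <window, outer(g_i, g_j)> / <O_ij, O_ij>, borders replicated."""
    img = np.asarray(image, dtype=float)
    planes = np.empty((5, 5) + img.shape)
    for i in range(5):
        for j in range(5):
            kernel = np.outer(GRAM5[i], GRAM5[j])
            planes[i, j] = ndi.correlate(img, kernel, mode="nearest") / (kernel ** 2).sum()
    return planes


def extract_family_c(roi_image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    crop, mask = _crop_to_mask(roi_image, roi_mask, min_size=10)
    planes = bivariate_transform(crop)
    vals = [stats14(planes[i, j][mask])
            for i in range(5) for j in range(5) if not (i == 0 and j == 0)]
    out = np.concatenate(vals)
    assert out.size == FAMILY_SIZES["C"]
    return out


# ---------------------------------------------------------------------------
# family D: gradient GLCM (140)
# ---------------------------------------------------------------------------

def gradient_quantized(roi_image: np.ndarray, roi_mask: np.ndarray,
                       levels: int = GLCM_LEVELS) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient magnitude quantized to equal-width levels
    over the masked range; returns (level image, cropped mask)."""
    crop, mask = _crop_to_mask(roi_image, roi_mask, min_size=8)
    gy, gx = np.gradient(crop)
    mag = np.hypot(gx, gy)
    lo, hi = float(mag[mask].min()), float(mag[mask].max())
    if hi <= lo:
        q = np.zeros(crop.shape, dtype=int)
    else:
        q = np.minimum(((mag - lo) / (hi - lo) * levels).astype(int), levels - 1)
        q = np.clip(q, 0, levels - 1)
    return q, mask


def glcm(levels_img: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
         n_levels: int = GLCM_LEVELS) -> np.ndarray | None:
    """Symmetric, normalized co-occurrence matrix over pairs (p, p+offset)
    with both endpoints inside the mask; None when fewer than 2 pairs exist
    (the caller zeroes that matrix's measures)."""
    dr, dc = offset
    h, w = levels_img.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    src = levels_img[r0:r1, c0:c1]
    dst = levels_img[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if valid.sum() < 2:
        return None
    i, j = src[valid], dst[valid]
    m = np.zeros((n_levels, n_levels))
    np.add.at(m, (i, j), 1.0)
    m = m + m.T                                   # symmetric
    return m / m.sum()


def glcm_measures(p: np.ndarray) -> np.ndarray:
    """contrast, correlation, energy, homogeneity, entropy, dissimilarity,
    maximum probability.  Correlation is 1 for a degenerate (point-mass)
    matrix."""
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    dissim = float((p * np.abs(i - j)).sum())
    energy = float((p ** 2).sum())
    homog = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    max_prob = float(p.max())
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    si = np.sqrt(float((p * (i - mu_i) ** 2).sum()))
    sj = np.sqrt(float((p * (j - mu_j) ** 2).sum()))
    if si <= 0 or sj <= 0:
        corr = 1.0
    else:
        corr = float((p * (i - mu_i) * (j - mu_j)).sum() / (si * sj))
    return np.array([contrast, corr, energy, homog, entropy, dissim, max_prob])


def extract_family_d(roi_image: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    q, mask = gradient_quantized(roi_image, roi_mask)
    vals = []
    for dr, dc in GLCM_DIRECTIONS:
        for dist in GLCM_DISTANCES:
            m = glcm(q, mask, (dr * dist, dc * dist))
            if m is None:
                warnings.warn(f"GLCM offset ({dr * dist},{dc * dist}) has <2 pairs; "
                              "zeroing its measures", stacklevel=2)
                vals.append(np.zeros(7))
            else:
                vals.append(glcm_measures(m))
    out = np.concatenate(vals)
    assert out.size == FAMILY_SIZES["D"]
    return out


def extract_all(roi_image: np.ndarray, roi_mask: np.ndarray) -> FeatureVector:
    """Concatenate families A||B||C||D in the fixed layout (1037 slots)."""
    values = np.concatenate([
        extract_family_a(roi_image, roi_mask),
        extract_family_b(roi_image, roi_mask),
        extract_family_c(roi_image, roi_mask),
        extract_family_d(roi_image, roi_mask),
    ])
    return FeatureVector(values=values, names=FEATURE_NAMES)
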