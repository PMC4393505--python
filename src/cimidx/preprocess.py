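"""Breast-contour identification and pectoral-muscle removal.

Two-phase pre-processing of an MLO mammogram:

1. A region-based two-phase level-set evolution (piecewise-constant energy,
   run on a Gaussian-bias-corrected image, initialized from a coarse Otsu
   threshold) isolates the breast profile; the image is mirrored to a
   canonical left orientation (chest wall at column 0) when needed.
2. Six landmarks x1, x2, y1, y2, x3, y3 on the breast boundary locate the
   pectoral muscle; seeded region growing from x1, clipped to the half-plane
   above the straight line through x3 and y3 and smoothed by a morphological
   opening, yields the pectoral mask.  The area of interest (AOI) is the
   breast minus the pectoral muscle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import deque

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk
from skimage.segmentation import morphological_chan_vese


class NoBreastRegionError(ValueError):
    """The level-set evolution produced no foreground component."""


class NoPectoralBoundaryError(ValueError):
    """No intensity drop found along either landmark walk; the caller should
    treat the whole breast mask as the AOI."""


@dataclass
class BreastContourResult:
    breast_mask: np.ndarray          # canonical (left) orientation
    orientation_flipped: bool
    image: np.ndarray                # the input in canonical orientation

    def check_invariants(self) -> None:
        assert self.breast_mask.any(), "breast mask is empty"
        n = label(self.breast_mask, connectivity=1).max()
        assert n == 1, f"breast mask has {n} 4-connected components"


@dataclass(frozen=True)
class ControlPoints:
    """Pectoral-muscle landmarks, each a (row, col) coordinate.

    x1: top-left corner of the breast contour (the seed); x2: top-right
    breast pixel on the same boundary row; y1/y2: lowest breast pixels on the
    left/right edges of the boundary (y2 is retained for completeness but
    unused downstream); x3/y3: first abrupt intensity change walking x1->x2
    and x1->y1.
    """
    x1: tuple[int, int]
    x2: tuple[int, int]
    y1: tuple[int, int]
    y2: tuple[int, int]
    x3: tuple[int, int]
    y3: tuple[int, int]


@dataclass
class AOIResult:
    aoi_mask: np.ndarray
    pectoral_mask: np.ndarray
    cut_line: tuple[float, float]    # (m, c) of row = m * col + c through x3, y3

    def check_invariants(self) -> None:
        assert not np.any(self.aoi_mask & self.pectoral_mask), "AOI overlaps pectoral"


def extract_breast_contour(image: np.ndarray, max_iter: int = 200) -> BreastContourResult:
    """Segment the breast profile and mirror to canonical left orientation.

    The image is first divided through a heavy Gaussian-blur bias estimate so
    smooth intensity inhomogeneity does not tilt the two-phase energy, then a
    morphological Chan-Vese evolution (coarse-threshold initialization,
    capped at ``max_iter`` sweeps) separates breast from background.  The
    largest 4-connected component, hole-filled, is returned.
    """
    img = _as_gray(image)
    f = img.astype(float)

    # local bias estimate: divide by a heavy blur, re-center on the global mean
    blur = ndi.gaussian_filter(f, sigma=max(img.shape) / 4.0)
    corrected = f / np.maximum(blur, 1e-6) * blur.mean()

    if np.ptp(corrected) < 1e-9:
        raise NoBreastRegionError("no breast region: image is constant")
    init = corrected > threshold_otsu(corrected)
    if not init.any() or init.all():
        raise NoBreastRegionError("no breast region: threshold produced no foreground")

    mask = morphological_chan_vese(corrected, num_iter=max_iter, init_level_set=init)
    mask = np.asarray(mask, dtype=bool)
    # the phase with the higher mean intensity is the breast
    if mask.any() and not mask.all():
        if f[mask].mean() < f[~mask].mean():
            mask = ~mask
    if not mask.any() or mask.all():
        raise NoBreastRegionError("no breast region: evolution converged to empty mask")

    lbl = label(mask, connectivity=1)
    counts = np.bincount(lbl.ravel())
    counts[0] = 0
    mask = ndi.binary_fill_holes(lbl == counts.argmax())

    flipped = False
    centroid_col = (mask * np.arange(mask.shape[1])[None, :]).sum() / mask.sum()
    if centroid_col > (mask.shape[1] - 1) / 2.0:
        mask = mask[:, ::-1]
        img = img[:, ::-1]
        flipped = True

    res = BreastContourResult(breast_mask=mask, orientation_flipped=flipped, image=img)
    res.check_invariants()
    return res


def locate_control_points(image: np.ndarray, contour: BreastContourResult) -> ControlPoints:
    """Locate the six pectoral landmarks on the canonical-orientation image.

    x3 (resp. y3) is the first pixel on the straight raster walk x1->x2
    (x1->y1) whose forward intensity difference exceeds
    max(10, 2 * median |forward difference|) along that walk.
    """
    img = contour.image.astype(float)
    mask = contour.breast_mask

    rows_any = np.nonzero(mask.any(axis=1))[0]
    top = int(rows_any[0])
    top_cols = np.nonzero(mask[top])[0]
    x1 = (top, int(top_cols[0]))
    x2 = (top, int(top_cols[-1]))

    cols_any = np.nonzero(mask.any(axis=0))[0]
    left_col, right_col = int(cols_any[0]), int(cols_any[-1])
    y1 = (int(np.nonzero(mask[:, left_col])[0][-1]), left_col)
    y2 = (int(np.nonzero(mask[:, right_col])[0][-1]), right_col)

    x3 = _first_intensity_jump(img[top, x1[1]:x2[1] + 1])
    y3 = _first_intensity_jump(img[x1[0]:y1[0] + 1, x1[1]])
    if x3 is None or y3 is None:
        raise NoPectoralBoundaryError("no pectoral boundary: no abrupt intensity change "
                                      "along either landmark walk")
    return ControlPoints(x1=x1, x2=x2, y1=y1, y2=y2,
                         x3=(top, x1[1] + x3), y3=(x1[0] + y3, x1[1]))


def _first_intensity_jump(profile: np.ndarray) -> int | None:
    """Index of the first pixel whose forward difference exceeds the gradient
    threshold max(10, 2 * median absolute forward difference); None if none."""
    d = np.abs(np.diff(profile))
    if d.size == 0:
        return None
    thr = max(10.0, 2.0 * float(np.median(d)))
    hits = np.nonzero(d > thr)[0]
    return int(hits[0]) if hits.size else None


def remove_pectoral_muscle(image: np.ndarray, contour: BreastContourResult,
                           cp: ControlPoints | None, srg_tol: float = 16.0,
                           opening_radius: int = 3) -> AOIResult:
    """Segment the pectoral muscle and return the AOI.

    Seeded region growing (4-connected, homogeneity |I(p) - running region
    mean| <= srg_tol) from x1, intersected with the half-plane on x1's side
    of the straight line through x3 and y3, then morphologically opened to
    remove the rough edges near the landmarks.  With ``cp=None`` (no pectoral
    boundary found upstream) the AOI is the whole breast mask.
    """
    mask = contour.breast_mask
    img = contour.image.astype(float)

    if cp is None:
        return AOIResult(aoi_mask=mask.copy(),
                         pectoral_mask=np.zeros_like(mask),
                         cut_line=(0.0, 0.0))

    region = _seeded_region_grow(img, mask, seed=cp.x1, tol=srg_tol)

    if cp.x3 == cp.y3:
        warnings.warn("degenerate cut line (x3 == y3); using the SRG region alone",
                      stacklevel=2)
        pect = region
        m, c = 0.0, float(cp.x3[0])
    else:
        rr, cc = np.mgrid[0:mask.shape[0], 0:mask.shape[1]].astype(float)
        (r3, c3), (r3b, c3b) = cp.x3, cp.y3
        # signed side of the line through x3 -> y3; keep x1's side (and the line itself)
        side = (c3b - c3) * (rr - r3) - (r3b - r3) * (cc - c3)
        s1 = (c3b - c3) * (cp.x1[0] - r3) - (r3b - r3) * (cp.x1[1] - c3)
        half = side * np.sign(s1 if s1 != 0 else 1.0) >= 0
        pect = region & half
        if c3b != c3:
            m = (r3b - r3) / (c3b - c3)
            c = r3 - m * c3
        else:
            m, c = float("inf"), float(c3)

    if opening_radius > 0 and pect.any():
        pect = ndi.binary_opening(pect, structure=disk(opening_radius))
    pect &= mask

    res = AOIResult(aoi_mask=mask & ~pect, pectoral_mask=pect, cut_line=(m, c))
    res.check_invariants()
    return res


def _seeded_region_grow(img: np.ndarray, domain: np.ndarray,
                        seed: tuple[int, int], tol: float) -> np.ndarray:
    """4-connected SRG: accrete pixels whose intensity stays within ``tol``
    of the running region mean."""
    h, w = img.shape
    region = np.zeros((h, w), dtype=bool)
    if not domain[seed]:
        return region
    region[seed] = True
    total = float(img[seed])
    count = 1
    q: deque[tuple[int, int]] = deque([seed])
    while q:
        r, c = q.popleft()
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < h and 0 <= nc < w and domain[nr, nc] and not region[nr, nc]:
                if abs(img[nr, nc] - total / count) <= tol:
                    region[nr, nc] = True
                    total += float(img[nr, nc])
                    count += 1
                    q.append((nr, nc))
    return region


def preprocess_image(image: np.ndarray, srg_tol: float = 16.0
                     ) -> tuple[BreastContourResult, ControlPoints | None, AOIResult]:
    """Full pre-processing: contour, landmarks (None when no pectoral edge), AOI."""
    contour = extract_breast_contour(image)
    try:
        cp = locate_control_points(image, contour)
    except NoPectoralBoundaryError:
        cp = None
    aoi = remove_pectoral_muscle(image, contour, cp, srg_tol=srg_tol)
    return contour, cp, aoi


def _as_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.shape[0] < 64 or img.shape[1] < 64:
        raise ValueError("image must be at least 64x64")
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        img = img.astype(np.uint8)
    return img
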