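"""Orthogonal-polynomial transform, statistical edge detection, DRLSE refinement."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from cimidx.phantom import generate_phantom
from cimidx.preprocess import preprocess_image
from cimidx.segment import (LevelSetParams, detect_edges, op_transform,
                            refine_contour)
from conftest import dice


def naive_op_transform(img: np.ndarray) -> np.ndarray:
    """Independent double-loop oracle with replicated borders."""
    u = (np.array([1.0, 1.0, 1.0]), np.array([-1.0, 0.0, 1.0]),
         np.array([1.0, -2.0, 1.0]))
    pad = np.pad(img.astype(float), 1, mode="edge")
    out = np.empty((3, 3) + img.shape)
    for i in range(3):
        for j in range(3):
            kern = np.outer(u[i], u[j])
            norm = (kern ** 2).sum()
            for r in range(img.shape[0]):
                for c in range(img.shape[1]):
                    out[i, j, r, c] = (pad[r:r + 3, c:c + 3] * kern).sum() / norm
    return out


class TestOpTransform:
    def test_constant_image_identity(self):
        img = np.full((20, 20), 37.0)
        planes = op_transform(img)
        assert np.allclose(planes[0, 0], 37.0)
        for i in range(3):
            for j in range(3):
                if (i, j) != (0, 0):
                    assert np.allclose(planes[i, j], 0.0)

    def test_vertical_step_response(self):
        img = np.zeros((11, 11))
        img[:, 6:] = 1.0          # unit step between columns 5 and 6
        planes = op_transform(img)
        interior = planes[0, 1][3:-3, :]
        step_cols = np.argmax(np.abs(interior), axis=1)
        assert np.all(np.isin(step_cols, (5, 6)))
        # direct 3x3 inner-product oracle at a step-adjacent pixel
        window = img[4:7, 4:7]
        expected = (window * np.outer((1, 1, 1), (-1, 0, 1))).sum() / 6.0
        assert planes[0, 1][5, 5] == pytest.approx(expected)
        assert planes[1, 0][5, 5] == pytest.approx(0.0)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        i1, i2 = rng.normal(size=(2, 12, 12))
        lhs = op_transform(a * i1 + b * i2).planes
        rhs = a * op_transform(i1).planes + b * op_transform(i2).planes
        assert np.allclose(lhs, rhs, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_double_loop(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(float)
        assert np.allclose(op_transform(img).planes, naive_op_transform(img))


class TestDetectEdges:
    def test_constant_image_empty(self):
        planes = op_transform(np.full((32, 32), 50.0))
        assert not detect_edges(planes).edges.any()

    def test_lesion_boundary_recall(self, clean_spec):
        """>= 90% of true disc-boundary pixels within 1 px of a detected edge."""
        spec = replace(clean_spec, noise_sigma=4.0)
        img, truth = generate_phantom(spec)
        _, _, aoi = preprocess_image(img)
        planes = op_transform(img.astype(float), aoi.aoi_mask)
        edges = detect_edges(planes)
        from scipy import ndimage as ndi
        lesion = truth.lesion_masks[0]
        boundary = lesion ^ ndi.binary_erosion(lesion)
        near_edge = ndi.binary_dilation(edges.edges, iterations=1)
        recall = (boundary & near_edge).sum() / boundary.sum()
        assert recall >= 0.90

    def test_null_calibration_of_f_test(self):
        """On pure iid noise (a pixel-shuffled image is exactly that), the
        F-stage candidate count stays within binomial 99% bounds of
        significance x number of windows."""
        rng = np.random.default_rng(0)
        img = rng.normal(128, 8, size=(100, 100))
        planes = op_transform(img)
        em = detect_edges(planes, significance=0.05)
        n = img.size
        lo, hi = binom.ppf([0.005, 0.995], n, 0.05)
        # overlapping windows correlate neighbouring statistics, so allow the
        # binomial band plus a 50% margin on its half-width
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        count = int(em.f_candidates.sum())
        assert mid - 1.5 * half <= count <= mid + 1.5 * half

    def test_threshold_maximizes_snr(self, noisy_spec):
        img, _ = generate_phantom(noisy_spec)
        _, _, aoi = preprocess_image(img)
        planes = op_transform(img.astype(float), aoi.aoi_mask)
        em = detect_edges(planes)
        e = em.magnitude[planes.domain]

        def snr(t):
            up, lo_ = e[e >= t], e[e < t]
            if up.size == 0:
                return -np.inf
            return up.mean() / ((lo_.std() if lo_.size else 0.0) + 1e-6)

        grid = np.unique(np.percentile(e, np.arange(50, 100)))
        best = max(grid, key=snr)
        assert snr(em.threshold) == pytest.approx(snr(best))


class TestRefineContour:
    def test_single_lesion_single_roi(self, clean_spec):
        img, truth = generate_phantom(clean_spec)
        _, _, aoi = preprocess_image(img)
        planes = op_transform(img.astype(float), aoi.aoi_mask)
        edges = detect_edges(planes)
        edges.edges &= aoi.aoi_mask
        rois = refine_contour(img.astype(float), edges, aoi=aoi.aoi_mask)
        big = [r for r in rois if r.area >= 100]
        assert len(big) == 1
        assert dice(big[0].mask, truth.lesion_masks[0]) >= 0.90

    def test_empty_edges_empty_rois(self):
        planes = op_transform(np.full((64, 64), 9.0))
        em = detect_edges(planes)
        assert len(refine_contour(np.full((64, 64), 9.0), em)) == 0

    def test_signed_distance_band(self, clean_spec):
        """Distance regularization keeps |grad phi| in [0.8, 1.2] on >= 90%
        of the band around the zero level set where the front is active
        (|phi| <= epsilon, the Dirac support; outside it phi flattens to
        +-c0 by design, so the signed-distance profile applies only here)."""
        params = LevelSetParams(max_iter=300)
        img, _ = generate_phantom(clean_spec)
        _, _, aoi = preprocess_image(img)
        planes = op_transform(img.astype(float), aoi.aoi_mask)
        edges = detect_edges(planes)
        edges.edges &= aoi.aoi_mask
        rois = refine_contour(img.astype(float), edges, params=params,
                              aoi=aoi.aoi_mask)
        roi = max(rois, key=lambda r: r.area)
        gy, gx = np.gradient(roi.phi)
        mag = np.hypot(gx, gy)
        band = np.abs(roi.phi) <= params.epsilon
        assert band.sum() > 50
        frac = np.mean((mag[band] >= 0.8) & (mag[band] <= 1.2))
        assert frac >= 0.90

    def test_rois_inside_aoi_and_deterministic(self, noisy_spec):
        img, _ = generate_phantom(noisy_spec)
        _, _, aoi = preprocess_image(img)
        planes = op_transform(img.astype(float), aoi.aoi_mask)
        edges = detect_edges(planes)
        edges.edges &= aoi.aoi_mask
        r1 = refine_contour(img.astype(float), edges, aoi=aoi.aoi_mask)
        r2 = refine_contour(img.astype(float), edges, aoi=aoi.aoi_mask)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.mask, b.mask)
            assert not np.any(a.mask & ~aoi.aoi_mask)
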