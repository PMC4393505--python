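"""1037-slot texture feature extractor: layout contract, constant-input
identities, and independent brute-force oracles."""

import numpy as np
import pytest

from cimidx import features as ft
from cimidx.features import (FAMILY_SIZES, FEATURE_NAMES, TOTAL_FEATURES,
                             extract_all, extract_family_a, extract_family_b,
                             extract_family_c, extract_family_d, glcm,
                             subband_split)


@pytest.fixture
def roi():
    rng = np.random.default_rng(11)
    img = rng.integers(60, 200, (24, 24)).astype(float)
    mask = np.zeros((24, 24), dtype=bool)
    mask[2:22, 2:22] = True
    return img, mask


class TestLayoutContract:
    def test_family_lengths(self, roi):
        img, mask = roi
        assert len(extract_family_a(img, mask)) == FAMILY_SIZES["A"] == 113
        assert len(extract_family_b(img, mask)) == FAMILY_SIZES["B"] == 448
        assert len(extract_family_c(img, mask)) == FAMILY_SIZES["C"] == 336
        assert len(extract_family_d(img, mask)) == FAMILY_SIZES["D"] == 140

    def test_total_and_names(self, roi):
        img, mask = roi
        fv = extract_all(img, mask)
        assert len(fv) == sum(FAMILY_SIZES.values()) == TOTAL_FEATURES == 1037
        assert len(set(fv.names)) == 1037
        assert fv.names == FEATURE_NAMES
        prefixes = [n[0] for n in fv.names]
        assert prefixes == ["A"] * 113 + ["B"] * 448 + ["C"] * 336 + ["D"] * 140

    def test_deterministic(self, roi):
        img, mask = roi
        assert np.array_equal(extract_all(img, mask).values,
                              extract_all(img, mask).values)

    def test_too_small_roi_rejected(self):
        img = np.zeros((20, 20))
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:6, 0:6] = True
        with pytest.raises(ValueError, match="at least"):
            extract_family_a(img, mask)


class TestConstantRoi:
    def setup_method(self):
        self.img = np.full((20, 20), 120.0)
        self.mask = np.ones((20, 20), dtype=bool)

    def test_family_a(self):
        vals = dict(zip([n for n in FEATURE_NAMES if n.startswith("A.")],
                        extract_family_a(self.img, self.mask)))
        assert vals["A.b00.mean"] == pytest.approx(120.0)
        assert vals["A.roi.mean"] == pytest.approx(120.0)
        for name, v in vals.items():
            if name.endswith((".variance", ".entropy")):
                assert v == 0.0
            if ".b" in name and not name.endswith("b00.energy") \
                    and name.endswith(".energy"):
                assert v == 0.0

    def test_family_b_detail_energies_zero(self):
        names = [n for n in FEATURE_NAMES if n.startswith("B.")]
        vals = dict(zip(names, extract_family_b(self.img, self.mask)))
        for name, v in vals.items():
            band = name.split(".")[1]
            if band != "LLLL" and name.endswith(".energy"):
                assert v == pytest.approx(0.0)

    def test_family_c_all_zero(self):
        assert np.allclose(extract_family_c(self.img, self.mask), 0.0)

    def test_family_d_degenerate_glcm(self):
        names = [n for n in FEATURE_NAMES if n.startswith("D.")]
        vals = dict(zip(names, extract_family_d(self.img, self.mask)))
        for name, v in vals.items():
            if name.endswith((".energy", ".max_prob")):
                assert v == pytest.approx(1.0)
            if name.endswith((".contrast", ".dissimilarity", ".entropy")):
                assert v == pytest.approx(0.0)


class TestOracles:
    def test_family_a_stats_match_naive_recomputation(self, roi):
        """Statistics recomputed directly from naively transformed masked
        samples (double-loop transform from the segmentation tests)."""
        from test_segment import naive_op_transform
        img, mask = roi
        rr, cc = np.nonzero(mask)
        crop = img[rr.min():rr.max() + 1, cc.min():cc.max() + 1]
        vals = extract_family_a(img, mask)
        planes = naive_op_transform(crop)
        x = planes[0, 1][np.ones(crop.shape, dtype=bool)]
        block = dict(zip([n for n in FEATURE_NAMES if n.startswith("A.b01.")],
                         vals[12:24]))
        assert block["A.b01.mean"] == pytest.approx(x.mean())
        assert block["A.b01.variance"] == pytest.approx(x.var())
        assert block["A.b01.median"] == pytest.approx(np.median(x))
        assert block["A.b01.rms"] == pytest.approx(np.sqrt(np.mean(x ** 2)))
        z = (x - x.mean()) / x.std()
        assert block["A.b01.skewness"] == pytest.approx(np.mean(z ** 3))
        assert block["A.b01.kurtosis"] == pytest.approx(np.mean(z ** 4) - 3)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_family_b_parseval(self, seed):
        x = np.random.default_rng(seed).normal(size=(16, 16))
        bands = subband_split(x)
        assert sum((b ** 2).sum() for b in bands.values()) \
            == pytest.approx((x ** 2).sum())

    @pytest.mark.parametrize("seed", [1, 4])
    def test_family_c_matches_naive_windows(self, seed):
        """5x5 bivariate plane values vs naive per-window inner products."""
        img = np.random.default_rng(seed).integers(0, 256, (12, 12)).astype(float)
        planes = ft.bivariate_transform(img)
        pad = np.pad(img, 2, mode="edge")
        for i, j in [(0, 1), (2, 3), (4, 4), (1, 0)]:
            kern = np.outer(ft.GRAM5[i], ft.GRAM5[j])
            norm = (kern ** 2).sum()
            for r, c in [(0, 0), (5, 7), (11, 11)]:
                expected = (pad[r:r + 5, c:c + 5] * kern).sum() / norm
                assert planes[i, j, r, c] == pytest.approx(expected)

    def test_glcm_matches_brute_force_pair_counts(self):
        """4x4 toy raster: symmetric co-occurrence vs explicit enumeration."""
        levels = np.array([[0, 0, 1, 1],
                           [0, 2, 2, 1],
                           [3, 2, 0, 0],
                           [3, 3, 1, 0]])
        mask = np.ones((4, 4), dtype=bool)
        for offset in [(0, 1), (-1, 1), (-1, 0), (-1, -1)]:
            m = glcm(levels, mask, offset, n_levels=4)
            brute = np.zeros((4, 4))
            for r in range(4):
                for c in range(4):
                    r2, c2 = r + offset[0], c + offset[1]
                    if 0 <= r2 < 4 and 0 <= c2 < 4:
                        brute[levels[r, c], levels[r2, c2]] += 1
                        brute[levels[r2, c2], levels[r, c]] += 1
            assert np.allclose(m, brute / brute.sum())

    def test_glcm_matches_skimage_on_full_mask(self):
        """Independent cross-check against skimage.feature.graycomatrix."""
        from skimage.feature import graycomatrix
        rng = np.random.default_rng(2)
        levels = rng.integers(0, 8, (12, 12))
        mask = np.ones((12, 12), dtype=bool)
        ours = glcm(levels, mask, (0, 2), n_levels=8)
        ref = graycomatrix(levels.astype(np.uint8), [2], [0], levels=8,
                           symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(ours, ref)


class TestMaskInvariance:
    def test_constant_border_outside_mask(self, roi):
        img, mask = roi
        base = extract_all(img, mask).values
        altered = img.copy()
        altered[~mask] = 251.0       # arbitrary constant outside the mask
        assert np.array_equal(extract_all(altered, mask).values, base)

    def test_padding_the_canvas_changes_nothing(self, roi):
        img, mask = roi
        base = extract_all(img, mask).values
        big_img = np.pad(img, 6, constant_values=33.0)
        big_mask = np.pad(mask, 6)
        assert np.array_equal(extract_all(big_img, big_mask).values, base)
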