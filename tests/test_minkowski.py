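"""Minkowski functionals: cell counting, spectra and the feature vector.

The genus and perimeter formulas are checked against two fully independent
oracles: connected-component labelling (white components under
8-connectivity minus enclosed black components under 4-connectivity) and a
brute-force scan of boundary edges.
"""

import numpy as np
import pytest
from scipy import ndimage

import minkrad as mk
from minkrad.io import NormalizedROI, TumourImage
from minkrad.minkowski import FEATURE_NAMES


def _norm_from_grid(grid, mask=None):
    """Wrap an already-[0,1] grid as a NormalizedROI."""
    grid = np.asarray(grid, dtype=float)
    if mask is None:
        mask = np.ones_like(grid, dtype=bool)
    return NormalizedROI(values=[grid[mask]], masks=[mask],
                         shapes=[grid.shape], lo=0.0, hi=1.0)


# ---------------------------------------------------------------- oracles

def euler_by_labelling(white):
    """Components (8-connected white) minus holes (4-connected enclosed black)."""
    white = np.asarray(white).astype(bool)
    n_comp = ndimage.label(white, structure=np.ones((3, 3)))[0].max() if white.any() else 0
    black_lab, n_black = ndimage.label(~white)  # 4-connectivity default
    holes = 0
    border = np.zeros_like(white)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for lab in range(1, n_black + 1):
        if not (border & (black_lab == lab)).any():
            holes += 1
    return int(n_comp) - holes


def perimeter_by_edge_scan(white):
    """Count unit edges with a white pixel on exactly one side."""
    white = np.asarray(white).astype(bool)
    padded = np.pad(white, 1)
    u = 0
    u += int(np.sum(padded[1:, :] != padded[:-1, :]))
    u += int(np.sum(padded[:, 1:] != padded[:, :-1]))
    return u


# ---------------------------------------------------------------- thresholds

class TestThresholdSequence:
    def test_default_gives_eleven_starting_at_zero(self):
        t = mk.threshold_sequence()
        assert len(t) == 11
        assert t[0] == 0.0
        assert np.all(np.diff(t) > 0)

    def test_formula(self):
        np.testing.assert_allclose(mk.threshold_sequence(2), [0.0, 0.5])
        assert mk.threshold_sequence(11)[10] == pytest.approx(10 / 11)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            mk.threshold_sequence(1)


class TestBinarize:
    def test_threshold_zero_all_white(self):
        norm = _norm_from_grid([[0.0, 0.5, 1.0]])
        assert mk.binarize(norm, 0, 0.0).all()

    def test_mid_threshold(self):
        norm = _norm_from_grid([[0.0, 0.5, 1.0]])
        np.testing.assert_array_equal(
            mk.binarize(norm, 0, 0.6), [[False, False, True]]
        )

    def test_tie_goes_white(self):
        norm = _norm_from_grid([[0.5]])
        assert mk.binarize(norm, 0, 0.5).all()

    def test_top_value_white_at_every_threshold(self):
        norm = _norm_from_grid([[1.0]])
        for t in mk.threshold_sequence():
            assert mk.binarize(norm, 0, float(t)).all()

    def test_pixels_outside_roi_excluded(self):
        mask = np.array([[True, False]])
        grid = np.array([[1.0, 1.0]])
        norm = NormalizedROI(values=[grid[mask]], masks=[mask],
                             shapes=[grid.shape], lo=0.0, hi=1.0)
        white = mk.binarize(norm, 0, 0.0)
        assert white[0, 0] and not white[0, 1]


# ---------------------------------------------------------------- counting

SINGLE = np.array([[1]])
BLOCK22 = np.ones((2, 2), dtype=int)
DIAG = np.array([[1, 0], [0, 1]])
RING = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


class TestCountCells:
    @pytest.mark.parametrize(
        "white, expected",
        [
            (SINGLE, (1, 4, 4)),
            (BLOCK22, (4, 12, 9)),
            (DIAG, (2, 8, 7)),
            (RING, (8, 24, 16)),
            (np.zeros((3, 3), dtype=int), (0, 0, 0)),
        ],
        ids=["single-pixel", "2x2-block", "diagonal-pair", "ring", "empty"],
    )
    def test_worked_cells(self, white, expected):
        assert mk.count_cells(white) == expected

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((1, 4, 4), (1, 4, 1)),
            ((8, 24, 16), (8, 16, 0)),
            ((2, 8, 7), (2, 8, 1)),
        ],
        ids=["unit-square", "ring", "diagonal-pair"],
    )
    def test_worked_functionals(self, counts, expected):
        assert mk.minkowski_2d(*counts) == expected

    def test_count_bounds_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            w = rng.random((6, 7)) < rng.uniform(0.1, 0.9)
            p, e, v = mk.count_cells(w)
            if p == 0:
                assert (e, v) == (0, 0)
            else:
                assert 2 * p <= e <= 4 * p
                assert p <= v <= 4 * p

    def test_additivity_over_disjoint_union(self):
        rng = np.random.default_rng(6)
        a = rng.random((5, 5)) < 0.5
        b = rng.random((5, 5)) < 0.5
        stacked = np.zeros((12, 5), dtype=bool)  # gap row keeps them disjoint
        stacked[:5] = a
        stacked[7:] = b
        pa, ea, va = mk.count_cells(a)
        pb, eb, vb = mk.count_cells(b)
        assert mk.count_cells(stacked) == (pa + pb, ea + eb, va + vb)


class TestOracleEquivalence:
    """chi = p - e + v and U = -4p + 2e versus independent oracles."""

    def test_genus_and_perimeter_on_random_images(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            h, w = rng.integers(1, 13, size=2)
            white = rng.random((h, w)) < rng.uniform(0.05, 0.95)
            p, e, v = mk.count_cells(white)
            _, u, chi = mk.minkowski_2d(p, e, v)
            assert chi == euler_by_labelling(white)
            assert u == perimeter_by_edge_scan(white)


# ---------------------------------------------------------------- spectrum

class TestMFSpectrum:
    def test_implied_area_at_threshold_one_is_unity(self):
        rng = np.random.default_rng(1)
        norm = _norm_from_grid(rng.random((8, 8)))
        spec = mk.mf_spectrum(norm)
        p0 = spec.counts[0][0]
        assert p0 == norm.n_pixels_total  # normalized area would be exactly 1

    def test_single_pixel_spectrum(self):
        spec = mk.mf_spectrum(_norm_from_grid([[1.0]]))
        assert spec.nperi[0] == 4.0
        assert spec.ngenus[0] == 1.0

    def test_two_uniform_slices_pool_counts(self):
        grid = np.ones((2, 2))
        mask = np.ones((2, 2), dtype=bool)
        norm = NormalizedROI(values=[grid[mask]] * 2, masks=[mask] * 2,
                             shapes=[grid.shape] * 2, lo=0.0, hi=1.0)
        spec = mk.mf_spectrum(norm)
        assert spec.n_pixels_total == 8
        np.testing.assert_allclose(spec.nperi, 16 / 8)

    def test_exactly_32_values(self):
        rng = np.random.default_rng(2)
        spec = mk.mf_spectrum(_norm_from_grid(rng.random((6, 6))))
        assert len(spec.narea) == 10
        assert len(spec.nperi) == 11
        assert len(spec.ngenus) == 11
        assert len(spec.as_dict()) == 32

    def test_area_monotone_and_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            spec = mk.mf_spectrum(_norm_from_grid(rng.random((7, 9))))
            assert np.all(np.diff(spec.narea) <= 1e-12)
            assert np.all((spec.narea >= 0) & (spec.narea <= 1))

    def test_slice_duplication_leaves_normalized_mfs_unchanged(self):
        img = mk.make_phantom(mk.PhantomSpec(seed=4))
        doubled = TumourImage(
            slices=img.slices + img.slices,
            roi=img.roi + img.roi,
            reference=img.reference + img.reference,
            tumour_id="doubled",
        )
        s1 = mk.mf_spectrum(mk.normalize_roi(img))
        s2 = mk.mf_spectrum(mk.normalize_roi(doubled))
        np.testing.assert_allclose(s2.narea, s1.narea, atol=1e-12)
        np.testing.assert_allclose(s2.nperi, s1.nperi, atol=1e-12)
        np.testing.assert_allclose(s2.ngenus, s1.ngenus, atol=1e-12)
        ta1, tp1 = mk.size_features(img)
        ta2, tp2 = mk.size_features(doubled)
        assert (ta2, tp2) == (2 * ta1, 2 * tp1)

    def test_checkerboard_more_heterogeneous_than_uniform(self):
        """More heterogeneous ROI -> higher mid-threshold normalized perimeter."""
        yy, xx = np.mgrid[0:8, 0:8]
        checker = ((yy + xx) % 2).astype(float)
        uniform = np.full((8, 8), 1.0)
        s_het = mk.mf_spectrum(_norm_from_grid(checker))
        s_uni = mk.mf_spectrum(_norm_from_grid(uniform))
        mid = slice(3, 8)
        assert np.all(s_het.nperi[mid] > s_uni.nperi[mid])


# ---------------------------------------------------------------- features

class TestSizeAndSIFeatures:
    def test_single_pixel_size(self):
        img = TumourImage(slices=[np.array([[5.0]])], roi=[np.array([[1]])])
        assert mk.size_features(img) == (1.0, 4.0)

    def test_two_slice_blocks(self):
        sl = np.ones((4, 4))
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        img = TumourImage(slices=[sl, sl], roi=[m, m])
        assert mk.size_features(img) == (8.0, 16.0)

    def test_ring_mask(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        m[2, 2] = False
        img = TumourImage(slices=[np.ones((5, 5))], roi=[m])
        assert mk.size_features(img) == (8.0, 16.0)

    def test_si_ratios(self):
        img = TumourImage(slices=[np.array([[100.0, 120.0]])],
                          roi=[np.array([[1, 1]])])
        mu, sd, mx, mn = mk.si_features(img, ref_mean=110.0)
        assert mu == pytest.approx(1.0)
        assert mx == pytest.approx(120 / 110)
        assert mn == pytest.approx(100 / 110)
        assert sd == pytest.approx(10.0 / 110)

    def test_constant_roi_zero_sd(self):
        img = TumourImage(slices=[np.full((2, 2), 9.0)],
                          roi=[np.ones((2, 2), dtype=bool)])
        assert mk.si_features(img, ref_mean=9.0)[1] == 0.0

    def test_nonpositive_reference_rejected(self):
        img = TumourImage(slices=[np.ones((2, 2))],
                          roi=[np.ones((2, 2), dtype=bool)])
        with pytest.raises(ValueError):
            mk.si_features(img, ref_mean=0.0)


class TestExtractFeatures:
    def test_vector_has_38_named_features(self):
        fv = mk.extract_features(mk.make_phantom(mk.PhantomSpec(seed=9)))
        d = fv.as_dict()
        assert len(d) == 38
        assert list(d) == list(FEATURE_NAMES)
        assert np.isfinite(fv.as_array()).all()

    def test_deterministic(self):
        spec = mk.PhantomSpec(seed=10)
        a = mk.extract_features(mk.make_phantom(spec)).as_array()
        b = mk.extract_features(mk.make_phantom(spec)).as_array()
        np.testing.assert_array_equal(a, b)

    def test_mf_and_size_invariant_to_intensity_scaling(self):
        img = mk.make_phantom(mk.PhantomSpec(seed=11))
        scaled = TumourImage(
            slices=[3.0 * s for s in img.slices],
            roi=[m.copy() for m in img.roi],
            reference=[m.copy() for m in img.reference],
            tumour_id=img.tumour_id,
        )
        fa = mk.extract_features(img).as_dict()
        fb = mk.extract_features(scaled).as_dict()
        for name in FEATURE_NAMES:
            if name.startswith(("nArea", "nPeri", "nGenus", "Total", "SI")):
                assert fb[name] == pytest.approx(fa[name], abs=1e-9), name

    def test_si_bounds(self):
        fv = mk.extract_features(mk.make_phantom(mk.PhantomSpec(seed=12)))
        assert fv.si_min <= fv.si_mean <= fv.si_max
        assert fv.si_sd >= 0
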