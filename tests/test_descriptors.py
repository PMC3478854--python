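"""Color histogram, Unser texture, Graham scan, morphology measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from fruitvision import descriptors as d


class TestColorHistogram:
    def test_constant_color_lands_in_computed_bin(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[:] = (10, 70, 130)  # bins (0, 1, 2) -> index 0*16 + 1*4 + 2
        h = d.color_histogram(img)
        assert h.counts[6] == 16 and h.counts.sum() == 16

    def test_histogram_has_64_cells_and_unit_mass(self):
        img = np.random.default_rng(0).integers(0, 256, (16, 16, 3)).astype(np.uint8)
        h = d.color_histogram(img)
        assert len(h.counts) == 64
        assert h.normalized.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotation_and_mirror_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        base = d.color_histogram(img).counts
        assert np.array_equal(base, d.color_histogram(np.rot90(img)).counts)
        assert np.array_equal(base, d.color_histogram(img[:, ::-1]).counts)

    def test_masked_counts_match_mask_size(self):
        img = np.random.default_rng(2).integers(0, 256, (10, 10, 3)).astype(np.uint8)
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:9] = True
        assert d.color_histogram(img, mask).counts.sum() == mask.sum()

    def test_empty_mask_raises(self):
        img = np.zeros((4, 4, 3), np.uint8)
        with pytest.raises(d.DescriptorError):
            d.color_histogram(img, np.zeros((4, 4), bool))


class TestSumDiffHistograms:
    def test_constant_image_mass_at_2g_and_zero(self):
        g = np.full((8, 8), 17)
        h = d.sum_diff_histograms(g, (1, 1))
        assert h.h_s[34] == h.n_pairs
        assert h.h_d[63] == h.n_pairs  # j = 0 at offset G-1

    def test_single_pair(self):
        g = np.array([[5, 9]])
        h = d.sum_diff_histograms(g, (0, 1))
        assert h.n_pairs == 1
        assert h.h_s[14] == 1
        assert h.h_d[(5 - 9) + 63] == 1

    def test_checkerboard_splits_differences_evenly(self):
        yy, xx = np.mgrid[0:8, 0:8]
        board = np.where((xx + yy) % 2 == 0, 0, 63)
        h = d.sum_diff_histograms(board, (0, 1))
        assert h.h_d[63 - 63] == h.h_d[63 + 63] == h.n_pairs // 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_pair_count_conservation(self, s):
        rng = np.random.default_rng(s)
        g = rng.integers(0, 64, size=(9, 11))
        d1, d2 = rng.integers(-2, 3), rng.integers(-2, 3)
        if d1 == 0 and d2 == 0:
            d2 = 1
        h = d.sum_diff_histograms(g, (int(d1), int(d2)))
        expected = (9 - abs(d1)) * (11 - abs(d2))
        assert h.h_s.sum() == h.h_d.sum() == expected

    def test_out_of_range_displacement_raises(self):
        with pytest.raises(d.DescriptorError):
            d.sum_diff_histograms(np.zeros((3, 3), int), (5, 0))


class TestUnserIndexes:
    def test_constant_image_closed_form(self):
        g = np.full((10, 10), 21)
        u = d.unser_indexes(d.sum_diff_histograms(g, (1, 1)))
        assert u.mean == pytest.approx(21)
        assert u.contrast == 0
        assert u.homogeneity == pytest.approx(1)
        assert u.energy == pytest.approx(1)
        assert u.variance == 0
        assert u.correlation == 0
        assert u.entropy == pytest.approx(0, abs=1e-12)

    def test_two_pair_fixture(self):
        h = d.SumDiffHistograms(
            h_s=np.bincount([0, 126], minlength=127),
            h_d=np.bincount([63, 63], minlength=127),
            displacement=(1, 1),
            levels=64,
        )
        u = d.unser_indexes(h)
        assert u.mean == pytest.approx(31.5)
        assert u.contrast == 0
        assert u.energy == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_variance_identity_on_random_histograms(self, s):
        """sigma^2 = correlation + contrast, an algebraic identity."""
        rng = np.random.default_rng(s)
        g = rng.integers(0, 64, size=(8, 8))
        u = d.unser_indexes(d.sum_diff_histograms(g, (1, 1)))
        assert u.variance == pytest.approx(u.correlation + u.contrast, abs=1e-9)
        assert 0 < u.energy <= 1 + 1e-12
        assert 0 < u.homogeneity <= 1 + 1e-12
        assert u.entropy >= -1e-12
        assert u.contrast >= 0

    def test_texture_invariant_under_90_degree_rotation_with_swapped_delta(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 256, size=(12, 12))
        u1 = d.texture_features(g, displacement=(1, 2))
        # rot90 counterclockwise maps displacement (d1, d2) -> (-d2, d1)
        u2 = d.texture_features(np.rot90(g), displacement=(-2, 1))
        assert u1.as_array() == pytest.approx(u2.as_array(), abs=1e-9)


def hull_oracle(points):
    """A point is a hull vertex iff it is NOT a convex combination of the
    others — tested by LP feasibility, independently of any scan order."""
    pts = np.unique(np.asarray(points, float), axis=0)
    verts = []
    for i, p in enumerate(pts):
        others = np.delete(pts, i, axis=0)
        A_eq = np.vstack([others.T, np.ones(len(others))])
        b_eq = np.array([p[0], p[1], 1.0])
        res = linprog(np.zeros(len(others)), A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * len(others), method="highs")
        if not res.success:
            verts.append(tuple(p))
    return set(verts)


class TestGrahamScan:
    def test_square_with_interior_point(self):
        pts = [(0, 0), (4, 0), (4, 4), (0, 4), (2, 2)]
        hull = d.graham_scan(pts)
        assert {tuple(p) for p in hull} == {(0, 0), (4, 0), (4, 4), (0, 4)}

    def test_collinear_boundary_points_excluded(self):
        pts = [(0, 0), (2, 0), (4, 0), (4, 4), (0, 4)]
        hull = d.graham_scan(pts)
        assert (2, 0) not in {tuple(p) for p in hull}

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            d.graham_scan([(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            d.graham_scan([(0, 0), (1, 1), (2, 2), (3, 3)])

    def test_hull_of_hull_is_itself(self):
        rng = np.random.default_rng(7)
        hull = d.graham_scan(rng.normal(size=(40, 2)))
        again = d.graham_scan(hull)
        assert {tuple(p) for p in hull} == {tuple(p) for p in again}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_matches_convex_combination_oracle(self, s):
        rng = np.random.default_rng(s)
        pts = rng.integers(-30, 31, size=(rng.integers(8, 50), 2)).astype(float)
        try:
            hull = d.graham_scan(pts)
        except ValueError:
            return  # degenerate draw
        assert {tuple(p) for p in hull} == hull_oracle(pts)

    def test_counterclockwise_orientation(self):
        hull = d.graham_scan(np.random.default_rng(0).normal(size=(30, 2)))
        area2 = 0.0
        for k in range(len(hull)):
            x1, y1 = hull[k]
            x2, y2 = hull[(k + 1) % len(hull)]
            area2 += x1 * y2 - x2 * y1
        assert area2 > 0


class TestShapeFeatures:
    def test_solid_square(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        s = d.shape_features(m)
        assert s.area == 100
        assert s.perimeter == 40
        assert s.euler == 1
        assert s.convex_area == 100
        assert s.solidity == 1
        assert s.eccentricity == pytest.approx(0, abs=1e-9)

    def test_square_with_hole(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        m[5:7, 5:7] = False
        s = d.shape_features(m)
        assert s.area == 96
        assert s.euler == 0

    def test_disk_matches_analytic_moments(self):
        yy, xx = np.mgrid[0:50, 0:50]
        m = (xx - 25) ** 2 + (yy - 25) ** 2 <= 20**2
        s = d.shape_features(m)
        assert s.major_length == pytest.approx(40, rel=0.02)
        assert s.minor_length == pytest.approx(40, rel=0.02)
        assert s.eccentricity < 0.1
        assert s.solidity > 0.95

    def test_scaling_a_rectangle(self):
        m1 = np.zeros((20, 20), bool)
        m1[4:10, 2:14] = True  # 6 x 12
        m2 = np.zeros((40, 40), bool)
        m2[8:20, 4:28] = True  # 12 x 24
        s1, s2 = d.shape_features(m1), d.shape_features(m2)
        assert s2.area == 4 * s1.area
        assert s2.perimeter == 2 * s1.perimeter
        # doubled axes up to the constant +1/12 moment correction
        assert s2.major_length == pytest.approx(2 * s1.major_length, rel=0.01)
        assert s2.minor_length == pytest.approx(2 * s1.minor_length, rel=0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariants_on_random_blobs(self, s):
        rng = np.random.default_rng(s)
        m = rng.random((15, 15)) > 0.6
        if not m.any():
            return
        f = d.shape_features(m)
        assert f.area <= f.convex_area
        assert 0 < f.solidity <= 1
        assert f.minor_length <= f.major_length + 1e-9
        assert 0 <= f.eccentricity < 1

    def test_empty_mask_raises(self):
        with pytest.raises(d.DescriptorError):
            d.shape_features(np.zeros((5, 5), bool))


class TestAssembly:
    def test_layout_is_79_dimensional_and_ordered(self):
        img = np.random.default_rng(0).integers(0, 256, (32, 32, 3)).astype(np.uint8)
        mask = np.zeros((32, 32), bool)
        mask[8:24, 8:24] = True
        vec = d.extract_features(img, mask)
        assert vec.shape == (79,)
        assert len(d.FEATURE_NAMES) == 79
        # color part is a unit-mass histogram
        assert vec[:64].sum() == pytest.approx(1.0, abs=1e-9)
        # slot 64 is the Unser mean, slot 71 the area
        from fruitvision.segmentation import to_gray

        u = d.texture_features(to_gray(img), mask)
        assert vec[64] == pytest.approx(u.mean)
        assert vec[71] == mask.sum()
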