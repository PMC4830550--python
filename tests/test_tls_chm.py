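import numpy as np
import pytest

from cropsense.core_io import NODATA, PointCloud, RasterGrid, ValidationError
from cropsense.tls_chm import (ChmParams, chm_difference, csm_percentile,
                               dtm_moving_planes, filter_ground,
                               gaussian_seamless, max_filter, reference_chm,
                               row_spacing_filter)


def brute_force_max_filter(grid: RasterGrid, diameter: float) -> np.ndarray:
    """Independent double-loop oracle for the circular local-maximum filter."""
    r2 = (diameter / 2.0) ** 2 + 1e-12
    out = np.full_like(grid.values, grid.nodata)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            best = None
            for ii in range(grid.n_rows):
                for jj in range(grid.n_cols):
                    d2 = ((ii - i) * grid.cell) ** 2 + ((jj - j) * grid.cell) ** 2
                    if d2 <= r2 and grid.values[ii, jj] != grid.nodata:
                        v = grid.values[ii, jj]
                        best = v if best is None else max(best, v)
            if best is not None:
                out[i, j] = best
    return out


class TestFilterGround:
    def test_off_terrain_point_removed(self):
        pts = [[x, y, 0.0] for x in np.linspace(0, 2, 10) for y in np.linspace(0, 2, 10)]
        pts.append([1.0, 1.0, 1.0])
        kept = filter_ground(PointCloud(np.array(pts)), cell=1.0, slope_tol_cm=10)
        assert len(kept) == 100
        assert kept.z.max() == 0.0

    def test_coplanar_cloud_unchanged(self):
        pts = np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 1.0], [1, 1, 1.0]])
        kept = filter_ground(PointCloud(pts), cell=0.5, slope_tol_cm=5)
        assert len(kept) == 4

    def test_infinite_tolerance_keeps_all(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, (50, 3))
        kept = filter_ground(PointCloud(pts), cell=1.0, slope_tol_cm=np.inf)
        assert len(kept) == 50

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValidationError):
            filter_ground(PointCloud(np.empty((0, 3))), 1.0, 10)


class TestDtmMovingPlanes:
    def test_exact_plane_recovery(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 10, (400, 2))
        z = 2.0 + 0.1 * xy[:, 0]
        cloud = PointCloud(np.column_stack([xy, z]))
        params = ChmParams(cell=1.0)
        dtm = dtm_moving_planes(cloud, params)
        xs, ys = dtm.cell_centers()
        expected = 2.0 + 0.1 * xs[None, :] + 0.0 * ys[:, None]
        np.testing.assert_allclose(dtm.values, expected, atol=1e-9)

    def test_far_cell_is_nodata(self):
        cloud = PointCloud(np.array([[0, 0, 1.0], [0.1, 0, 1.0], [0, 0.1, 1.0],
                                     [0.1, 0.1, 1.1]]))
        grid = RasterGrid(0, 0, 1.0, np.full((1, 10), NODATA))
        params = ChmParams(cell=1.0, search_radius=2.0)
        dtm = dtm_moving_planes(cloud, params, grid)
        assert dtm.values[0, 0] != NODATA
        assert dtm.values[0, 9] == NODATA

    def test_noisy_plane_rmse_below_noise(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 20, (4000, 2))
        z = 5.0 + 0.02 * xy[:, 0] - 0.01 * xy[:, 1] + rng.normal(0, 0.01, 4000)
        dtm = dtm_moving_planes(PointCloud(np.column_stack([xy, z])),
                                ChmParams(cell=1.0))
        xs, ys = dtm.cell_centers()
        truth = 5.0 + 0.02 * xs[None, :] - 0.01 * ys[:, None]
        valid = dtm.valid
        rmse = np.sqrt(np.mean((dtm.values[valid] - truth[valid]) ** 2))
        assert rmse < 0.01

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            dtm_moving_planes(PointCloud(np.array([[0, 0, 1.0]])), ChmParams())


class TestCsmPercentile:
    def test_linear_interpolation_definition(self):
        z = np.arange(1.0, 101.0)
        cloud = PointCloud(np.column_stack([np.full(100, 0.2),
                                            np.full(100, 0.2), z]))
        grid = RasterGrid(0, 0, 1.0, np.full((1, 1), NODATA))
        csm = csm_percentile(cloud, ChmParams(cell=1.0), grid)
        assert csm.values[0, 0] == pytest.approx(99.01)

    def test_single_point_cell(self):
        cloud = PointCloud(np.array([[0.5, 0.5, 7.25]]))
        grid = RasterGrid(0, 0, 1.0, np.full((1, 1), NODATA))
        csm = csm_percentile(cloud, ChmParams(cell=1.0), grid)
        assert csm.values[0, 0] == 7.25

    def test_percentile_100_is_maximum(self):
        rng = np.random.default_rng(3)
        z = rng.uniform(0, 5, 37)
        cloud = PointCloud(np.column_stack([np.full(37, 0.5), np.full(37, 0.5), z]))
        grid = RasterGrid(0, 0, 1.0, np.full((1, 1), NODATA))
        csm = csm_percentile(cloud, ChmParams(cell=1.0, csm_percentile=100), grid)
        assert csm.values[0, 0] == z.max()


class TestChmDifference:
    def test_identical_grids_zero(self):
        g = RasterGrid(0, 0, 1.0, np.full((3, 3), 107.0))
        chm, n = chm_difference(g, g)
        np.testing.assert_array_equal(chm.values, 0.0)
        assert n == 0

    def test_constant_offset_in_cm(self):
        dtm = RasterGrid(0, 0, 1.0, np.full((2, 2), 107.0))
        csm = dtm.copy_with(dtm.values + 1.4)
        chm, _ = chm_difference(csm, dtm)
        np.testing.assert_allclose(chm.values, 140.0)

    def test_nodata_propagates_and_negative_clamped(self):
        dtm = RasterGrid(0, 0, 1.0, np.array([[107.0, NODATA], [107.0, 107.0]]))
        csm = RasterGrid(0, 0, 1.0, np.array([[106.9, 108.0], [108.0, 108.0]]))
        chm, n_clamped = chm_difference(csm, dtm)
        assert chm.values[0, 1] == NODATA
        assert chm.values[0, 0] == 0.0 and n_clamped == 1

    def test_geometry_mismatch(self):
        a = RasterGrid(0, 0, 1.0, np.zeros((2, 2)))
        b = RasterGrid(0, 0, 0.5, np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            chm_difference(a, b)


class TestMaxFilter:
    def test_four_neighborhood_example(self):
        vals = np.full((5, 5), 50.0)
        vals[2, 2] = 100.0
        out = max_filter(RasterGrid(0, 0, 1.0, vals), diameter=2.0)
        expected = np.full((5, 5), 50.0)
        for i, j in [(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)]:
            expected[i, j] = 100.0
        np.testing.assert_array_equal(out.values, expected)

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            shape = rng.integers(2, 9, 2)
            vals = rng.uniform(0, 100, shape)
            vals[rng.uniform(size=shape) < 0.2] = NODATA
            cell = float(rng.uniform(0.3, 1.5))
            diameter = float(rng.uniform(1.0, 4.0)) * cell
            g = RasterGrid(0, 0, cell, vals)
            out = max_filter(g, diameter)
            np.testing.assert_allclose(out.values,
                                       brute_force_max_filter(g, diameter))

    def test_constant_grid_unchanged_and_monotone(self):
        g = RasterGrid(0, 0, 1.0, np.full((4, 4), 3.0))
        out = max_filter(g, 3.0)
        np.testing.assert_array_equal(out.values, g.values)
        rng = np.random.default_rng(5)
        g2 = RasterGrid(0, 0, 1.0, rng.uniform(0, 10, (6, 6)))
        assert np.all(max_filter(g2, 3.0).values >= g2.values)


class TestRowSpacingFilter:
    def test_threshold_rule(self):
        small = RasterGrid(0, 0, 1.0, np.array([[100.0, 100.0, 100.0]]))
        large = RasterGrid(0, 0, 1.0, np.array([[105.0, 112.0, 100.0]]))
        out = row_spacing_filter(small, large, threshold_cm=10.0)
        assert out.values[0, 0] == 100.0   # diff 5 kept
        assert out.values[0, 1] == NODATA  # diff 12 dropped
        assert out.values[0, 2] == 100.0   # equal grids keep everything

    def test_large_kernel_dominates_small(self, small_scene, small_clouds):
        # kernel-inclusion monotonicity on a real CHM
        terr, can = small_clouds
        params = ChmParams(cell=0.5)
        chmref, _ = reference_chm(terr, can, params, grid=small_scene.empty_grid())
        chm15 = max_filter(chmref, 1.0)
        chm80 = max_filter(chm15, 2.0)
        both = chm15.valid & chm80.valid
        assert np.all(chm80.values[both] >= chm15.values[both])


class TestGaussianSeamless:
    def test_constant_preserved(self):
        g = RasterGrid(0, 0, 1.0, np.full((6, 6), 42.0))
        out = gaussian_seamless(g, sigma=1.5)
        np.testing.assert_allclose(out.values, 42.0, atol=1e-9)

    def test_hole_filled_with_constant(self):
        vals = np.full((5, 5), 17.0)
        vals[2, 2] = NODATA
        out = gaussian_seamless(RasterGrid(0, 0, 1.0, vals), sigma=1.0)
        assert out.values[2, 2] == pytest.approx(17.0)

    def test_output_within_input_range(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(10, 90, (8, 8))
        vals[rng.uniform(size=(8, 8)) < 0.3] = NODATA
        g = RasterGrid(0, 0, 1.0, vals)
        out = gaussian_seamless(g, sigma=1.0)
        valid_in = vals[vals != NODATA]
        assert out.values.min() >= valid_in.min() - 1e-9
        assert out.values.max() <= valid_in.max() + 1e-9

    def test_all_nodata_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_seamless(RasterGrid(0, 0, 1.0, np.full((2, 2), NODATA)), 1.0)


class TestReferenceChm:
    def test_accuracy_against_generator_truth(self, small_scene, small_clouds):
        terr, can = small_clouds
        chmref, report = reference_chm(terr, can, ChmParams(),
                                       grid=small_scene.empty_grid())
        interior = np.zeros(chmref.values.shape, bool)
        interior[1:-1, 1:-1] = True
        d = (chmref.values - small_scene.true_height.values)[interior]
        assert np.sqrt(np.mean(d ** 2)) < 5.0
        # seamlessness: no nodata anywhere in the field
        assert np.all(chmref.valid)
        assert report.n_ground_points <= report.n_terrain_points

    def test_deterministic_and_point_order_invariant(self, small_scene, small_clouds):
        terr, can = small_clouds
        a, _ = reference_chm(terr, can, ChmParams(), grid=small_scene.empty_grid())
        rng = np.random.default_rng(0)
        perm_t = PointCloud(terr.xyz[rng.permutation(len(terr))])
        perm_c = PointCloud(can.xyz[rng.permutation(len(can))])
        b, _ = reference_chm(perm_t, perm_c, ChmParams(),
                             grid=small_scene.empty_grid())
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)
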