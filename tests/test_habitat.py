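"""Kernel densities, high-use areas, hulls, buffers and SDM thresholds."""

import numpy as np
import pytest

from seaplan.geometry import polygon_area
from seaplan.grid import ACRE_M2, PlanningGrid
from seaplan.habitat import (
    Bathymetry,
    buffered_hull_habitat,
    buffered_residence_areas,
    density_raster_spec,
    kernel_density,
    sdm_threshold_layer,
    upper_quartile_hua,
    volume_contour,
)


def fine_spec(xy, radius_km, cells_per_radius=10):
    return density_raster_spec(np.atleast_2d(xy), radius_km,
                               cells_per_radius=cells_per_radius)


class TestKernelDensity:
    def test_single_point_unit_mass_and_compact_support(self):
        pt = np.array([[0.0, 0.0]])
        d = kernel_density(pt, 19.0, raster_spec=fine_spec(pt, 19.0))
        assert d.mass() == pytest.approx(1.0, rel=5e-3)
        gx, gy = d.grid.cell_centers()
        dist = np.hypot(gx, gy)
        assert np.all(d.values[dist > 19_000.0] == 0.0)

    @pytest.mark.parametrize("kernel", ["quartic", "gaussian"])
    def test_mass_conservation(self, kernel, rng):
        pts = rng.normal(0, 5000, size=(30, 2))
        d = kernel_density(pts, 10.0, raster_spec=fine_spec(pts, 10.0),
                           kernel=kernel)
        assert d.mass() == pytest.approx(30.0, rel=5e-3)

    def test_superposition_of_distant_points(self):
        """Two points farther apart than twice the radius produce the
        sum of the single-point surfaces, cellwise."""
        r = 5.0
        both = np.array([[0.0, 0.0], [60_000.0, 0.0]])
        spec = fine_spec(both, r)
        d_both = kernel_density(both, r, raster_spec=spec)
        d_a = kernel_density(both[:1], r, raster_spec=spec)
        d_b = kernel_density(both[1:], r, raster_spec=spec)
        np.testing.assert_allclose(d_both.values, d_a.values + d_b.values,
                                   atol=1e-15)

    def test_argmax_near_cluster_centroid(self, rng):
        pts = rng.multivariate_normal([50_000, 50_000],
                                      [[4e6, 0], [0, 4e6]], size=100)
        d = kernel_density(pts, 19.0)
        r, c = np.unravel_index(np.argmax(d.values), d.grid.shape)
        gx, gy = d.grid.cell_centers()
        centroid = pts.mean(axis=0)
        dist = np.hypot(gx[r, c] - centroid[0], gy[r, c] - centroid[1])
        assert dist <= np.sqrt(2) * d.grid.cell_size  # within one cell

    def test_brute_force_kernel_sum_oracle(self, rng):
        """Surface equals the naive double loop over points x cells."""
        pts = rng.uniform(0, 20_000, size=(12, 2))
        r_km = 4.0
        spec = fine_spec(pts, r_km, cells_per_radius=5)
        d = kernel_density(pts, r_km, raster_spec=spec)
        gx, gy = spec.cell_centers()
        r = r_km * 1000
        expected = np.zeros(spec.shape)
        for px, py in pts:
            dist = np.hypot(gx - px, gy - py)
            k = np.where(dist < r,
                         3 / (np.pi * r**2) * (1 - (dist / r) ** 2) ** 2, 0.0)
            k[dist >= r] = 0.0
            expected += k
        np.testing.assert_allclose(d.values, expected, atol=1e-18)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least one point"):
            kernel_density(np.empty((0, 2)), 19.0)
        pt = np.array([[0.0, 0.0]])
        coarse = density_raster_spec(pt, 100.0, cells_per_radius=4)
        with pytest.raises(ValueError, match="smaller than one raster cell"):
            kernel_density(pt, 1.0, raster_spec=coarse)


class TestUpperQuartileHua:
    def grid_with(self, vals):
        vals = np.asarray(vals, dtype=float)
        g = PlanningGrid(n_rows=vals.shape[0], n_cols=vals.shape[1],
                         cell_area_ac=10.0,
                         origin=(0.0, vals.shape[0] * 201.168))
        from seaplan.habitat import DensitySurface

        return DensitySurface(grid=g, values=vals, bandwidth_km=1.0,
                              total_mass=float(vals.sum() * g.cell_area_m2))

    def test_hundred_distinct_values_selects_fifty(self, rng):
        vals = rng.permutation(np.arange(1.0, 101.0)).reshape(10, 10)
        hua = upper_quartile_hua(self.grid_with(vals))
        g = self.grid_with(vals).grid
        assert hua.polygons.area == pytest.approx(50 * g.cell_area_m2,
                                                  rel=1e-9)

    def test_all_equal_selects_all(self):
        d = self.grid_with(np.full((5, 5), 2.0))
        hua = upper_quartile_hua(d)
        assert hua.polygons.area == pytest.approx(
            25 * d.grid.cell_area_m2, rel=1e-9
        )

    def test_checkerboard_matches_quantile_oracle(self):
        vals = np.indices((6, 6)).sum(axis=0) % 2 + 1.0  # values {1, 2}
        d = self.grid_with(vals)
        hua = upper_quartile_hua(d)
        med = np.median(vals[vals > 0])
        n_expected = int((vals >= med).sum())
        assert hua.polygons.area == pytest.approx(
            n_expected * d.grid.cell_area_m2, rel=1e-9
        )

    def test_never_selects_zero_density(self, rng):
        vals = rng.uniform(0, 1, (8, 8))
        vals[vals < 0.5] = 0.0
        d = self.grid_with(vals)
        hua = upper_quartile_hua(d)
        n_pos = int((vals > 0).sum())
        max_cells = hua.polygons.area / d.grid.cell_area_m2
        assert max_cells <= n_pos

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no positive"):
            upper_quartile_hua(self.grid_with(np.zeros((5, 5))))


class TestVolumeContour:
    grid_with = TestUpperQuartileHua.grid_with

    def test_single_positive_cell(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 3.0
        vc = volume_contour(self.grid_with(vals), 0.5)
        assert vc.polygons.area == pytest.approx(
            self.grid_with(vals).grid.cell_area_m2, rel=1e-9
        )

    def test_two_cells_forced_by_threshold(self):
        vals = np.zeros((2, 2))
        vals[0, 0], vals[0, 1] = 0.9, 0.1
        vc = volume_contour(self.grid_with(vals), 0.95)
        g = self.grid_with(vals).grid
        assert vc.polygons.area == pytest.approx(2 * g.cell_area_m2, rel=1e-9)

    def test_gaussian_surface_mass_bracket(self, rng):
        x, y = np.meshgrid(np.linspace(-3, 3, 40), np.linspace(-3, 3, 40))
        vals = np.exp(-(x**2 + y**2) / 2)
        d = self.grid_with(vals)
        vc = volume_contour(d, 0.95)
        frac = vc.params["mass_fraction"]
        one_cell = vals.max() * d.grid.cell_area_m2 / d.mass()
        assert 0.95 <= frac <= 0.95 + one_cell

    def test_monotone_in_level(self, rng):
        vals = rng.uniform(0, 1, (15, 15))
        d = self.grid_with(vals)
        a = volume_contour(d, 0.5).polygons
        b = volume_contour(d, 0.9).polygons
        assert a.within(b.buffer(1e-6))


class TestBufferedResidence:
    def test_isolated_point_area(self):
        hp = buffered_residence_areas(np.array([[1e6, 1e6]]))
        assert round(polygon_area(hp.polygons)) == 1132

    def test_zero_points_empty(self):
        hp = buffered_residence_areas(np.empty((0, 2)))
        assert hp.polygons.is_empty

    def test_nearby_points_merge(self):
        r = 18.983
        hp = buffered_residence_areas(
            np.array([[0.0, 0.0], [10_000.0, 0.0]]), radius_km=r
        )
        area = polygon_area(hp.polygons)
        assert area < 2 * np.pi * r**2
        # stadium-union closed form: 2*pi*r^2 - 2*(r^2*acos(d/2r) - (d/4)*sqrt(4r^2-d^2))
        d = 10.0
        lens = 2 * (r**2 * np.arccos(d / (2 * r))
                    - (d / 4) * np.sqrt(4 * r**2 - d**2))
        assert area == pytest.approx(2 * np.pi * r**2 - lens, rel=1e-3)


def flat_bathy(depth=50.0, n=120, cell_km=1.0):
    g = PlanningGrid(n_rows=n, n_cols=n,
                     cell_area_ac=cell_km**2 * 1e6 / ACRE_M2,
                     origin=(-n / 2 * cell_km * 1000, n / 2 * cell_km * 1000))
    return Bathymetry(grid=g, depth_m=np.full((n, n), depth))


class TestBufferedHull:
    def test_stadium_area(self):
        """Two points L apart buffered by r give area 2*L*r + pi*r^2."""
        L, r = 20_000.0, 5_000.0
        pts = np.array([[-L / 2, 0.0], [L / 2, 0.0]])
        hp = buffered_hull_habitat(pts, flat_bathy(), buffer_km=r / 1000,
                                   max_depth_m=410)
        assert hp.polygons.area == pytest.approx(2 * L * r + np.pi * r**2,
                                                 rel=1e-3)

    def test_zero_buffer_returns_hull(self):
        pts = np.array([[0.0, 0.0], [10_000.0, 0.0], [0.0, 10_000.0]])
        hp = buffered_hull_habitat(pts, flat_bathy(), buffer_km=0.0)
        assert hp.polygons.area == pytest.approx(0.5 * 10_000**2, rel=1e-6)

    def test_isobath_trim_keeps_shallow_half(self):
        """A shelf break bisecting the buffered hull removes the deep
        side, verified cellwise against the depth mask."""
        bat = flat_bathy()
        depth = bat.depth_m.copy()
        n = depth.shape[0]
        depth[:, n // 2:] = 600.0  # deep half (east)
        bat = Bathymetry(grid=bat.grid, depth_m=depth)
        pts = np.array([[-20_000.0, 0.0], [20_000.0, 0.0], [0.0, 15_000.0]])
        hp = buffered_hull_habitat(pts, bat, buffer_km=5.0, max_depth_m=410)
        from seaplan.geometry import cells_to_polygons

        hull_only = buffered_hull_habitat(pts, flat_bathy(), buffer_km=5.0,
                                          max_depth_m=410).polygons
        shallow = cells_to_polygons(depth <= 410, bat.grid)
        assert hp.polygons.area == pytest.approx(
            hull_only.intersection(shallow).area, rel=1e-12
        )
        assert hp.polygons.area < hull_only.area

    def test_no_cell_deeper_than_cutoff(self):
        bat = flat_bathy()
        depth = bat.depth_m + np.linspace(0, 800, bat.depth_m.shape[1])[None, :]
        bat = Bathymetry(grid=bat.grid, depth_m=depth)
        pts = np.array([[-30_000.0, 0.0], [30_000.0, 0.0], [0.0, 20_000.0]])
        hp = buffered_hull_habitat(pts, bat, buffer_km=5.0, max_depth_m=410)
        gx, gy = bat.grid.cell_centers()
        import shapely

        inside = shapely.contains_xy(hp.polygons, gx.ravel(), gy.ravel())
        assert np.all(depth.ravel()[inside] <= 410)

    def test_bathymetry_coverage_error(self):
        pts = np.array([[0.0, 0.0], [500_000.0, 0.0]])
        with pytest.raises(ValueError, match="does not cover"):
            buffered_hull_habitat(pts, flat_bathy(n=20), buffer_km=30)


class TestSdmThreshold:
    def test_single_month_equals_itself(self, grid10, rng):
        month = rng.uniform(0, 1, grid10.shape)
        layer = sdm_threshold_layer([month], grid10)
        med = np.median(month)
        np.testing.assert_array_equal(layer.values == 0.4, month > med)

    def test_median_split_exact(self):
        g = PlanningGrid(n_rows=2, n_cols=5)
        month = np.arange(0.1, 1.05, 0.1).reshape(2, 5)
        layer = sdm_threshold_layer([month], g)
        # median of 0.1..1.0 is 0.55; five cells strictly above
        assert (layer.values == 0.4).sum() == 5
        assert (layer.values == 1.0).sum() == 5

    def test_dominant_month_wins(self, grid10, rng):
        m1 = rng.uniform(0, 0.4, grid10.shape)
        m2 = m1 + 0.3
        layer = sdm_threshold_layer([m1, m2], grid10)
        direct = sdm_threshold_layer([m2], grid10)
        np.testing.assert_array_equal(layer.values, direct.values)

    def test_two_valued_output(self, grid10, rng):
        stack = rng.uniform(0, 1, (12, *grid10.shape))
        layer = sdm_threshold_layer(stack, grid10, hua_score=0.4)
        assert set(np.unique(layer.values[grid10.study_mask])) <= {0.4, 1.0}

    def test_errors(self, grid10):
        with pytest.raises(ValueError, match="at least one month"):
            sdm_threshold_layer(np.empty((0, 10, 10)), grid10)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            sdm_threshold_layer([np.full(grid10.shape, 1.5)], grid10)
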