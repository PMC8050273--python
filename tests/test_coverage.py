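"""Visual field coverage: maps, density curves, fits, indices, band summaries."""

import numpy as np
import pytest
from scipy import stats as sps

from prfconn.bands import DEFAULT_BANDS, band_proportions
from prfconn.coverage import (CoverageMap, average_maps, center_band_proportions,
                              compute_vfc, density_vs_eccentricity,
                              fit_density_linear, fit_density_logistic,
                              generalized_logistic, laterality_index,
                              median_size_by_band, vertical_bias_index,
                              visual_field_grid)
from prfconn.prf_fit import FitResult, ROIVoxelSet
from prfconn.prf_model import PRFParams


def voxelset(params, hemisphere="right"):
    fits = [FitResult(params=p, variance_explained=0.9, converged=True,
                      at_sigma_floor=False) for p in params]
    return ROIVoxelSet(roi_label="test", hemisphere=hemisphere, fits=fits)


class TestComputeVFC:
    def test_single_prf_is_its_disk(self):
        gx, gy = visual_field_grid(40, 51)
        p = PRFParams(x=3, y=-4, sigma=2.0, n=0.25)       # size 4
        cmap = compute_vfc(voxelset([p]), gx, gy)
        disk = ((gx - 3) ** 2 + (gy + 4) ** 2 <= p.size ** 2).astype(float)
        assert np.array_equal(cmap.density, disk)

    def test_identical_prfs_average_to_same_map(self):
        gx, gy = visual_field_grid(40, 51)
        p = PRFParams(x=0, y=0, sigma=3.0)
        one = compute_vfc(voxelset([p]), gx, gy)
        many = compute_vfc(voxelset([p] * 7), gx, gy)
        assert np.array_equal(one.density, many.density)

    def test_matches_brute_force_counting(self, rng):
        # independent per-point point-in-disk loop, exact equality
        gx, gy = visual_field_grid(40, 51)
        params = [PRFParams(x=rng.uniform(-15, 15), y=rng.uniform(-15, 15),
                            sigma=rng.uniform(0.5, 8), n=rng.uniform(0.2, 1.0))
                  for _ in range(20)]
        cmap = compute_vfc(voxelset(params), gx, gy)
        expected = np.zeros_like(gx)
        for i in range(gx.shape[0]):
            for j in range(gx.shape[1]):
                count = sum((gx[i, j] - p.x) ** 2 + (gy[i, j] - p.y) ** 2 <= p.size ** 2
                            for p in params)
                expected[i, j] = count / len(params)
        assert np.array_equal(cmap.density, expected)

    def test_empty_set_rejected(self):
        gx, gy = visual_field_grid(40, 21)
        with pytest.raises(ValueError):
            compute_vfc(voxelset([]), gx, gy)

    def test_group_average(self):
        gx, gy = visual_field_grid(40, 21)
        a = compute_vfc(voxelset([PRFParams(x=0, y=0, sigma=2)]), gx, gy)
        b = compute_vfc(voxelset([PRFParams(x=5, y=0, sigma=2)]), gx, gy)
        avg = average_maps([a, b])
        assert np.array_equal(avg.density, (a.density + b.density) / 2)


class TestDensityCurve:
    def test_uniform_map_gives_flat_curve(self):
        gx, gy = visual_field_grid(40, 51)
        cmap = CoverageMap(grid_x=gx, grid_y=gy,
                           density=np.full_like(gx, 0.4), hemisphere="right")
        curve = density_vs_eccentricity(cmap)
        assert np.allclose(curve.mean_density, 0.4)

    def test_central_disk_vanishes_beyond_radius(self):
        gx, gy = visual_field_grid(40, 101)
        density = (np.hypot(gx, gy) <= 5.0).astype(float)
        cmap = CoverageMap(grid_x=gx, grid_y=gy, density=density, hemisphere="left")
        curve = density_vs_eccentricity(cmap)
        assert np.all(curve.mean_density[curve.ecc_bins < 4] > 0)
        assert np.all(curve.mean_density[curve.ecc_bins > 6] == 0)

    def test_matches_annulus_oracle(self, rng):
        gx, gy = visual_field_grid(40, 41)
        density = rng.uniform(0, 1, gx.shape)
        cmap = CoverageMap(grid_x=gx, grid_y=gy, density=density, hemisphere="right")
        curve = density_vs_eccentricity(cmap, bin_width=2.0)
        ecc = np.hypot(gx, gy)
        for center, mean in zip(curve.ecc_bins, curve.mean_density):
            sel = (gx < 0) & (ecc >= center - 1) & (ecc < center + 1)
            assert mean == pytest.approx(density[sel].mean())


class TestDensityFits:
    def test_exact_line(self):
        from prfconn.coverage import DensityCurve
        x = np.arange(0.5, 20.5)
        curve = DensityCurve(ecc_bins=x, mean_density=-0.02 * x + 0.9)
        fit = fit_density_linear(curve)
        assert fit.slope == pytest.approx(-0.02, abs=1e-12)
        assert fit.intercept == pytest.approx(0.9, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_flat_curve_flagged(self):
        from prfconn.coverage import DensityCurve
        curve = DensityCurve(ecc_bins=np.arange(5.0), mean_density=np.full(5, 0.3))
        assert fit_density_linear(curve).degenerate
        assert fit_density_logistic(curve).degenerate

    def test_linear_matches_normal_equations(self, rng):
        from prfconn.coverage import DensityCurve
        x = np.arange(0.5, 15.5)
        y = -0.01 * x + 0.5 + rng.normal(0, 0.02, len(x))
        fit = fit_density_linear(DensityCurve(ecc_bins=x, mean_density=y))
        # closed-form OLS via the normal equations
        X = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_logistic_recovery_on_noise_free_curve(self):
        from prfconn.coverage import DensityCurve
        x = np.arange(0.5, 25.5)
        a, b, c, d = 0.05, 0.8, 8.0, -0.3
        curve = DensityCurve(ecc_bins=x, mean_density=generalized_logistic(x, a, b, c, d))
        fit = fit_density_logistic(curve)
        assert fit.a == pytest.approx(a, rel=1e-3)
        assert fit.b == pytest.approx(b, rel=1e-3)
        assert fit.c == pytest.approx(c, rel=1e-3)
        assert fit.d == pytest.approx(d, rel=1e-3)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_logistic_midpoint_identity(self):
        from prfconn.coverage import DensityCurve
        x = np.arange(0.5, 25.5)
        curve = DensityCurve(ecc_bins=x,
                             mean_density=generalized_logistic(x, 0.1, 0.7, 10.0, -0.25))
        fit = fit_density_logistic(curve)
        assert generalized_logistic(np.array([fit.c]), fit.a, fit.b, fit.c, fit.d)[0] \
            == pytest.approx((fit.a + fit.b) / 2)
        # d < 0 here: the high-eccentricity side approaches a
        assert fit.asymptote_high_ecc == fit.a
        assert fit.asymptote_low_ecc == fit.b


class TestIndices:
    def _map(self, density, hemisphere="right"):
        gx, gy = visual_field_grid(40, 51)
        return CoverageMap(grid_x=gx, grid_y=gy, density=density(gx, gy),
                           hemisphere=hemisphere)

    def test_laterality_extremes_and_symmetry(self):
        contra_only = self._map(lambda gx, gy: (gx < 0).astype(float))
        assert laterality_index(contra_only) == 1.0
        ipsi_only = self._map(lambda gx, gy: (gx > 0).astype(float))
        assert laterality_index(ipsi_only) == -1.0
        symmetric = self._map(lambda gx, gy: np.hypot(gx, gy) <= 8.3)
        assert laterality_index(symmetric) == 0.0

    def test_laterality_formula(self):
        cmap = self._map(lambda gx, gy: np.where(gx < 0, 0.3, 0.1))
        assert laterality_index(cmap) == pytest.approx(0.5)

    def test_vertical_bias(self):
        upper = self._map(lambda gx, gy: (gy > 0).astype(float))
        assert vertical_bias_index(upper) == 1.0
        lower = self._map(lambda gx, gy: (gy < 0).astype(float))
        assert vertical_bias_index(lower) == -1.0
        symmetric = self._map(lambda gx, gy: np.hypot(gx, gy) <= 8.3)
        assert vertical_bias_index(symmetric) == 0.0
        mixed = self._map(lambda gx, gy: np.where(gy > 0, 0.2, 0.6))
        assert vertical_bias_index(mixed) == pytest.approx(-0.5)

    def test_zero_coverage_rejected(self):
        empty = self._map(lambda gx, gy: np.zeros_like(gx))
        with pytest.raises(ValueError):
            laterality_index(empty)
        with pytest.raises(ValueError):
            vertical_bias_index(empty)


class TestBandSummaries:
    def test_all_foveal(self):
        vs = voxelset([PRFParams(x=2, y=0, sigma=1)] * 5)
        bp = center_band_proportions(vs)
        assert np.array_equal(bp.fractions, [1, 0, 0, 0])

    def test_boundary_goes_to_next_band(self):
        vs = voxelset([PRFParams(x=5.0, y=0, sigma=1)])
        bp = center_band_proportions(vs)
        assert np.array_equal(bp.fractions, [0, 1, 0, 0])

    def test_outer_edge_included_beyond_excluded(self):
        vs = voxelset([PRFParams(x=40.0, y=0, sigma=1),
                       PRFParams(x=41.0, y=0, sigma=1)])
        bp = center_band_proportions(vs)
        assert np.array_equal(bp.fractions, [0, 0, 0, 1])
        assert bp.n_excluded == 1

    def test_uniform_by_area_matches_annulus_ratios(self, rng):
        n = 4000
        ecc = 40.0 * np.sqrt(rng.uniform(size=n))
        expected = np.array([25, 75, 300, 1200]) / 1600
        bp = band_proportions(ecc)
        half = sps.norm.ppf(0.995) * np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(bp.fractions - expected) <= half)

    def test_median_size_examples(self):
        vs = voxelset([PRFParams(x=3, y=0, sigma=2.0, n=1.0)])
        med = median_size_by_band(vs)
        assert med[0] == 2.0 and np.isnan(med[1:]).all()

        sizes = [1.0, 2.0, 9.0]
        vs = voxelset([PRFParams(x=7, y=0, sigma=s, n=1.0) for s in sizes])
        assert median_size_by_band(vs)[1] == 2.0

    def test_median_matches_sort_and_pick(self, rng):
        params = [PRFParams(x=rng.uniform(0, 39), y=0, sigma=rng.uniform(0.5, 8),
                            n=rng.uniform(0.2, 1)) for _ in range(60)]
        med = median_size_by_band(voxelset(params))
        for b in range(4):
            lo, hi = DEFAULT_BANDS.edges[b], DEFAULT_BANDS.edges[b + 1]
            sizes = sorted(p.size for p in params
                           if lo <= p.eccentricity < hi or (b == 3 and p.eccentricity == hi))
            if sizes:
                k = len(sizes)
                manual = sizes[k // 2] if k % 2 else (sizes[k // 2 - 1] + sizes[k // 2]) / 2
                assert med[b] == pytest.approx(manual)
            else:
                assert np.isnan(med[b])
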