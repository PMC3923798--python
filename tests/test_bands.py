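"""PCA over pixel spectra and loading-extremum wavelength selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eggscan import phantom as ph
from eggscan.bands import (flatten_pixels, pc_image, pca,
                           select_optimal_wavelengths)
from eggscan.envi import HyperCube, WavelengthGrid, band_index, calibrate


def _cube(values):
    values = np.asarray(values, dtype=float)
    return HyperCube(values=values,
                     grid=WavelengthGrid(np.linspace(400, 1000,
                                                     values.shape[2])),
                     kind="calibrated")


def brute_force_pca(X):
    """Independent oracle: explicit covariance matrix + eigendecomposition."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mean = X.mean(axis=0)
    cov = np.zeros((p, p))
    for row in X:
        d = row - mean
        cov += np.outer(d, d)
    cov /= n - 1
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    contributions = 100 * eigvals / eigvals.sum()
    return eigvecs, contributions


class TestFlattenPixels:
    def test_two_pixel_mask_known_entries(self):
        values = np.arange(2 * 2 * 3).reshape(2, 2, 3)
        mask = np.zeros((2, 2), bool)
        mask[0, 1] = mask[1, 0] = True
        out = flatten_pixels(_cube(values), mask)
        np.testing.assert_array_equal(out, values[[0, 1], [1, 0]])

    def test_full_frame_row_count(self):
        out = flatten_pixels(_cube(np.zeros((5, 7, 3))), np.ones((5, 7), bool))
        assert out.shape == (35, 3)

    def test_raster_order_matches_enumeration(self, rng):
        values = rng.uniform(size=(6, 6, 4))
        mask = rng.uniform(size=(6, 6)) > 0.4
        mask[0, 0] = True
        out = flatten_pixels(_cube(values), mask)
        expected = [values[r, c] for r in range(6) for c in range(6)
                    if mask[r, c]]
        np.testing.assert_array_equal(out, np.array(expected))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            flatten_pixels(_cube(np.zeros((3, 3, 3))), np.zeros((3, 3), bool))


class TestPCA:
    def test_perfectly_correlated_two_bands(self):
        t = np.linspace(-1, 1, 9)
        X = np.column_stack([t, t])  # points on y = x
        res = pca(X)
        np.testing.assert_allclose(np.abs(res.loadings[:, 0]),
                                   np.sqrt(0.5), atol=1e-12)
        assert res.variance_contributions[0] == pytest.approx(100.0)

    def test_isotropic_four_point_cloud_splits_50_50(self):
        X = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        res = pca(X)
        np.testing.assert_allclose(res.variance_contributions, [50.0, 50.0])

    def test_contributions_sum_to_100(self, rng):
        res = pca(rng.uniform(size=(30, 6)))
        assert res.variance_contributions.sum() == pytest.approx(100.0,
                                                                 abs=1e-9)
        assert (np.diff(res.variance_contributions) <= 1e-9).all()

    @given(st.integers(0, 40))
    def test_matches_brute_force_eigendecomposition(self, case):
        rng = np.random.default_rng(case)
        n = rng.integers(4, 21)
        p = rng.integers(2, 7)
        X = rng.normal(size=(int(n), int(p)))
        res = pca(X)
        vecs, contribs = brute_force_pca(X)
        k = min(res.loadings.shape[1], vecs.shape[1])
        np.testing.assert_allclose(res.variance_contributions[:k],
                                   contribs[:k], atol=1e-8)
        # any components beyond the data rank carry no variance
        assert np.all(np.abs(contribs[k:]) < 1e-8)
        for c in range(k):
            if contribs[c] < 1e-9:
                continue  # eigenvector of a ~zero eigenvalue is arbitrary
            a, b = res.loadings[:, c], vecs[:, c]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_scaling_leaves_loadings_and_percentages_unchanged(self, rng):
        X = rng.normal(size=(15, 5))
        r1, r2 = pca(X), pca(3.7 * X)
        np.testing.assert_allclose(r1.loadings, r2.loadings, atol=1e-10)
        np.testing.assert_allclose(r1.variance_contributions,
                                   r2.variance_contributions, atol=1e-10)

    def test_rank_zero_raises(self):
        with pytest.raises(ValueError, match="rank-0|identical"):
            pca(np.ones((5, 3)))


class TestPCImage:
    def test_zero_loading_zero_image(self, rng):
        cube = _cube(rng.uniform(size=(4, 5, 3)))
        mask = np.ones((4, 5), bool)
        assert not pc_image(cube, mask, np.zeros(3)).any()

    def test_one_hot_loading_recovers_centered_band(self, rng):
        values = rng.uniform(size=(6, 6, 4))
        cube = _cube(values)
        mask = rng.uniform(size=(6, 6)) > 0.3
        mask[2, 2] = True
        loading = np.zeros(4)
        loading[2] = 1.0
        img = pc_image(cube, mask, loading)
        plane = values[:, :, 2]
        expected = plane - plane[mask].mean()
        np.testing.assert_allclose(img[mask], expected[mask], atol=1e-12)

    def test_background_exactly_zero(self, rng):
        cube = _cube(rng.uniform(size=(5, 5, 3)))
        mask = np.zeros((5, 5), bool)
        mask[1:3, 1:3] = True
        img = pc_image(cube, mask, np.ones(3))
        assert (img[~mask] == 0).all()

    def test_length_mismatch_raises(self):
        cube = _cube(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="loading"):
            pc_image(cube, np.ones((3, 3), bool), np.ones(4))


class TestSelectOptimalWavelengths:
    def _result(self, loading):
        loading = np.asarray(loading, dtype=float)
        loadings = np.column_stack([loading / np.linalg.norm(loading)])
        from eggscan.bands import PCAResult

        return PCAResult(loadings=loadings,
                         variance_contributions=np.array([100.0]),
                         mean_spectrum_used=np.zeros(loading.size))

    def test_monotone_loading_picks_larger_endpoint(self):
        grid = WavelengthGrid(np.linspace(400, 1000, 5))
        out = select_optimal_wavelengths(self._result([0.1, 0.2, 0.3, 0.4, 0.9]),
                                         grid)
        assert out.wavelengths == [1000.0]

    def test_interior_peak_found_by_finite_differences(self):
        grid = WavelengthGrid(np.linspace(400, 1000, 7))
        loading = np.array([0.1, 0.2, 0.5, 0.9, 0.4, 0.2, 0.1])
        # enumerate finite differences: the single sign change sits at k=3
        diffs = np.sign(np.diff(loading))
        assert list(diffs).index(-1) == 3
        out = select_optimal_wavelengths(self._result(loading), grid)
        assert out.wavelengths == [grid.band_centers[3]]

    def test_constant_loading_raises(self):
        grid = WavelengthGrid(np.linspace(400, 1000, 4))
        with pytest.raises(ValueError, match="constant"):
            select_optimal_wavelengths(self._result([0.5, 0.5, 0.5, 0.5]),
                                       grid)

    def test_noise_free_phantom_selects_configured_peak_band(self):
        # pore speckle scales whole-pixel brightness while sensor noise is
        # off, so amplitude is the only variance source and PC1 must align
        # with the shell spectral curve
        cfg = ph.tiny(sensor_noise_sd=0.0, egg_scale_sigma=0.0,
                      embryo_fraction_jitter=0.0)
        cube, _ = ph.generate_phantom_cube(cfg, "N", 0, 5)
        cal = calibrate(cube, ph.generate_references(cfg))
        egg, _, _ = ph.render_masks(cfg, "N", 0, 5)
        res = pca(flatten_pixels(cal, egg))
        out = select_optimal_wavelengths(res, cal.grid)
        k = band_index(cal.grid, cfg.shell_peak_wavelength)
        assert out.wavelengths == [cal.grid.band_centers[k]]
        assert out.source_component == 1
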