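"""PCA over cube pixels and optimal-wavelength selection from loading extrema.

Each masked pixel's spectrum is one observation; a covariance PCA ranks
directions of spectral variance.  With transmission cubes of candled eggs
almost all variance loads on PC1 (overall brightness), and the wavelengths
where the PC1 loading curve peaks (or dips) carry the most information —
those extrema are returned as the selected bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi import HyperCube, WavelengthGrid

__all__ = ["PCAResult", "SelectedBands", "flatten_pixels", "pca",
           "pc_image", "select_optimal_wavelengths"]


@dataclass(frozen=True)
class PCAResult:
    loadings: np.ndarray                # (bands, components), orthonormal columns
    variance_contributions: np.ndarray  # percent, non-increasing, sums to 100
    mean_spectrum_used: np.ndarray      # per-band centering vector


@dataclass(frozen=True)
class SelectedBands:
    wavelengths: list[float]
    source_component: int


def flatten_pixels(cube: HyperCube, mask: np.ndarray) -> np.ndarray:
    """One row per masked pixel in deterministic (row, col) raster order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match the cube")
    if not mask.any():
        raise ValueError("empty mask")
    return cube.values[mask]  # boolean indexing is raster (row-major) order


def pca(matrix: np.ndarray) -> PCAResult:
    """Covariance PCA of a (pixels x bands) matrix via thin SVD.

    Components are ordered by explained variance (eigenvalue) descending.
    Sign convention: the largest-magnitude entry of each loading is made
    positive.  Contributions are percentages of total variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("rank-0 input: all rows identical")
    loadings = vt.T
    # deterministic sign: largest-|entry| of each column positive
    pivot = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[pivot, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    contributions = 100.0 * eigvals / total
    return PCAResult(loadings=loadings,
                     variance_contributions=contributions,
                     mean_spectrum_used=mean)


def pc_image(cube: HyperCube, mask: np.ndarray, loading: np.ndarray) -> np.ndarray:
    """Score image: per masked pixel, centered spectrum . loading; background 0."""
    mask = np.asarray(mask, dtype=bool)
    loading = np.asarray(loading, dtype=float)
    if loading.shape != (cube.shape[2],):
        raise ValueError(
            f"loading length {loading.size} does not match {cube.shape[2]} bands"
        )
    pixels = flatten_pixels(cube, mask)
    scores = (pixels - pixels.mean(axis=0)) @ loading
    image = np.zeros(cube.shape[:2], dtype=float)
    image[mask] = scores
    return image


def _local_extrema(curve: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema of a 1-D sequence, endpoints eligible."""
    n = curve.size
    idx = []
    for i in range(n):
        left = curve[i - 1] if i > 0 else None
        right = curve[i + 1] if i < n - 1 else None
        is_max = ((left is None or curve[i] > left)
                  and (right is None or curve[i] > right))
        is_min = ((left is None or curve[i] < left)
                  and (right is None or curve[i] < right))
        if is_max or is_min:
            idx.append(i)
    return np.array(idx, dtype=int)


def select_optimal_wavelengths(result: PCAResult, grid: WavelengthGrid,
                               component: int = 1,
                               max_bands: int = 1) -> SelectedBands:
    """Wavelengths at the extrema of a PC loading, ranked by |loading|.

    ``component`` is 1-based (PC1 = 1).  With ``max_bands=1`` this returns
    the wavelength of the global-|loading| extremum.
    """
    if not 1 <= component <= result.loadings.shape[1]:
        raise ValueError(f"component {component} not available")
    loading = result.loadings[:, component - 1]
    if loading.size != len(grid):
        raise ValueError("loading length does not match the wavelength grid")
    if np.allclose(loading, loading[0]):
        raise ValueError("constant loading has no extremum")
    extrema = _local_extrema(loading)
    order = extrema[np.argsort(-np.abs(loading[extrema]), kind="stable")]
    chosen = order[:max_bands]
    return SelectedBands(
        wavelengths=[float(grid.band_centers[i]) for i in chosen],
        source_component=component,
    )
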