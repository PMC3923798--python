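"""ROI selection and spectral-track feature extraction.

The spectral feature of an egg is the mean peak transmission value x̄: the
arithmetic mean, over a fixed-size region of interest (ROI, default 1000
pixels), of the per-pixel transmittance at a chosen band.  Because pore and
non-pore shell pixels transmit differently, averaging over a fixed ROI
stabilises the scalar against shell speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envi import HyperCube, WavelengthGrid

__all__ = ["ROISpec", "MeanSpectrum", "PeakFeature",
           "select_roi", "mean_spectrum", "peak_value", "mean_peak_at_band"]


@dataclass(frozen=True)
class ROISpec:
    """A fixed-size set of (row, col) pixel positions inside the egg mask."""

    pixels: np.ndarray  # (k, 2) int array of (row, col)
    target_size: int

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2:
            raise ValueError("pixels must be a (k, 2) array of (row, col)")
        if px.shape[0] != self.target_size:
            raise ValueError(
                f"ROI holds {px.shape[0]} pixels, expected {self.target_size}"
            )
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class MeanSpectrum:
    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != len(self.grid):
            raise ValueError("mean spectrum length must equal the band count")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class PeakFeature:
    peak_wavelength: float
    peak_value: float
    mean_peak: float


def select_roi(cube: HyperCube, egg_mask: np.ndarray,
               target_size: int = 1000) -> ROISpec:
    """The ``target_size`` egg-mask pixels nearest the mask centroid.

    Distance is Euclidean in pixel coordinates; ties are broken by (row,
    col) order, so the selection is deterministic for any mask shape.
    """
    mask = np.asarray(egg_mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("egg mask shape does not match the cube")
    rows, cols = np.nonzero(mask)
    if rows.size < target_size:
        raise ValueError(
            f"egg mask has {rows.size} pixels; ROI needs {target_size}"
        )
    cr, cc = rows.mean(), cols.mean()
    dist2 = (rows - cr) ** 2 + (cols - cc) ** 2
    # lexsort: last key is primary -> (distance, row, col)
    order = np.lexsort((cols, rows, dist2))[:target_size]
    pixels = np.column_stack((rows[order], cols[order]))
    return ROISpec(pixels=pixels, target_size=target_size)


def mean_spectrum(cube: HyperCube, roi: ROISpec) -> MeanSpectrum:
    """Per-band arithmetic mean of transmittance over the ROI pixels."""
    r, c = roi.pixels[:, 0], roi.pixels[:, 1]
    if roi.pixels.shape[0] == 0:
        raise ValueError("empty ROI")
    if (r.min() < 0 or c.min() < 0
            or r.max() >= cube.shape[0] or c.max() >= cube.shape[1]):
        raise ValueError("ROI pixel out of cube bounds")
    return MeanSpectrum(values=cube.values[r, c, :].mean(axis=0), grid=cube.grid)


def peak_value(spectrum: MeanSpectrum) -> tuple[float, float]:
    """(wavelength, value) of the global maximum; ties go to the lowest band."""
    vals = spectrum.values
    if vals.size == 0:
        raise ValueError("empty spectrum")
    k = int(np.argmax(vals))  # first maximiser = lowest wavelength on ties
    return float(spectrum.grid.band_centers[k]), float(vals[k])


def mean_peak_at_band(cube: HyperCube, roi: ROISpec, band: int) -> float:
    """x̄ = (1/n) Σ x_i over the n ROI pixels at the given band index."""
    if roi.pixels.shape[0] == 0:
        raise ValueError("empty ROI")
    if not 0 <= band < cube.shape[2]:
        raise ValueError(f"band {band} outside cube with {cube.shape[2]} bands")
    r, c = roi.pixels[:, 0], roi.pixels[:, 1]
    return float(cube.values[r, c, band].mean())
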