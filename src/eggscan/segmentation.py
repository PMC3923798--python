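"""Two-stage embryo segmentation and the morphologic characteristic rate W.

Stage 1 — 'Mask': a global threshold (default 0.125) on the calibrated
825 nm plane separates the bright egg silhouette from the near-zero
background; the largest 8-connected component is kept and interior holes
(an absorbing embryo can fall below the global threshold) are filled.

Stage 2 — embryo: inside the mask, a pixel belongs to the embryo when its
825 nm transmittance sits below the local mean (computed over mask pixels
only, square window) minus an offset — developed tissue and blood absorb,
so the embryo is the locally dark region.  Small components are speckle
and are dropped; interior holes of the remaining embryo blobs are filled,
since a large embryo is detected by its rim once it outgrows the window.

W = X1 / X2: embryo pixels over egg-mask pixels.  Normalising by the mask
area makes the feature insensitive to egg size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .envi import HyperCube, band_index

__all__ = ["BinaryMask", "MorphRate", "NoEggFoundError",
           "egg_mask", "adaptive_embryo_threshold", "morph_rate"]


class NoEggFoundError(ValueError):
    """No pixel exceeded the egg threshold."""


@dataclass(frozen=True)
class BinaryMask:
    values: np.ndarray
    kind: str  # "egg" | "embryo"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=bool)
        if vals.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.kind not in ("egg", "embryo"):
            raise ValueError("kind must be 'egg' or 'embryo'")
        object.__setattr__(self, "values", vals)

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class MorphRate:
    W: float
    X1: int  # embryo pixel count
    X2: int  # egg-mask pixel count


def egg_mask(cube: HyperCube, band_wavelength: float = 825.0,
             threshold: float = 0.125) -> BinaryMask:
    """Global-threshold egg silhouette at the given band.

    Pixels strictly above ``threshold`` are candidates; the largest
    8-connected component is kept and its holes filled, so the mask
    contains only the egg.
    """
    if cube.kind != "calibrated":
        raise ValueError("egg_mask expects a calibrated cube")
    plane = cube.values[:, :, band_index(cube.grid, band_wavelength)]
    binary = plane > threshold
    if not binary.any():
        raise NoEggFoundError(
            f"no pixel above {threshold} at {band_wavelength} nm: no egg found"
        )
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == int(np.argmax(counts))
    filled = ndimage.binary_fill_holes(keep)
    return BinaryMask(values=filled, kind="egg")


def adaptive_embryo_threshold(cube: HyperCube, egg: BinaryMask,
                              band_wavelength: float = 825.0,
                              window: int = 51, offset: float = 0.02,
                              min_size: int = 25) -> BinaryMask:
    """Mask-restricted local-mean thresholding of the embryo region.

    A pixel is embryo iff it lies in the egg mask and its band value is
    below (local mean over egg-mask pixels within a ``window`` x ``window``
    square) − ``offset``.  Components smaller than ``min_size`` pixels are
    removed as pore speckle; interior holes of surviving components are
    then filled (restricted to the egg mask).
    """
    mask = egg.values
    if not mask.any():
        raise ValueError("empty egg mask")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(mask.shape):
        raise ValueError(
            f"window {window} larger than image {mask.shape}"
        )
    if offset < 0:
        raise ValueError("offset must be non-negative")
    plane = cube.values[:, :, band_index(cube.grid, band_wavelength)]

    weighted = ndimage.uniform_filter(np.where(mask, plane, 0.0), size=window)
    coverage = ndimage.uniform_filter(mask.astype(float), size=window)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_mean = np.where(coverage > 0, weighted / coverage, 0.0)

    embryo = mask & (plane < local_mean - offset)
    if min_size > 0:
        # drop components with fewer than min_size pixels
        embryo = morphology.remove_small_objects(
            embryo, max_size=min_size - 1, connectivity=2
        )
    embryo = ndimage.binary_fill_holes(embryo) & mask
    return BinaryMask(values=embryo, kind="embryo")


def morph_rate(embryo: BinaryMask, egg: BinaryMask) -> MorphRate:
    """W = X1 / X2 with X1 = embryo pixels, X2 = egg-mask pixels."""
    x2 = egg.pixel_count
    if x2 == 0:
        raise ValueError("empty egg mask")
    if np.any(embryo.values & ~egg.values):
        raise ValueError("embryo mask extends outside the egg mask")
    x1 = embryo.pixel_count
    return MorphRate(W=x1 / x2, X1=x1, X2=x2)
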