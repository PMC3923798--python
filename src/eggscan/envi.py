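"""ENVI-style hyperspectral cube I/O and dark/white transmittance calibration.

A cube is stored as a raw binary file plus a plain-text ``.hdr`` sidecar
(the format written by most imaging-spectrometer acquisition software).
Supported layouts are band-sequential (BSQ) and band-interleaved-by-line
(BIL); supported on-disk types are 32-bit float and 16-bit unsigned.

Calibration converts raw sensor counts ``R_o`` to relative transmittance

    R = (R_o - R_d) / (R_t - R_d)

using a dark frame ``R_d`` (shutter closed, 0 % transmittance) and a white
frame ``R_t`` (open light path, ~100 % transmittance).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "ReferencePair",
    "read_envi",
    "write_envi",
    "calibrate",
    "band_index",
]

# ENVI data-type codes -> numpy dtypes (little-endian on disk, byte order 0)
_DTYPE_CODES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_NAMES = {np.dtype("float32"): 4, np.dtype("uint16"): 12}
_INTERLEAVES = ("bsq", "bil")


class EnviFormatError(ValueError):
    """Raised for malformed headers or header/data disagreements."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers in nanometres."""

    band_centers: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.band_centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("band_centers must be a non-empty 1-D sequence")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        object.__setattr__(self, "band_centers", centers)

    def __len__(self) -> int:
        return int(self.band_centers.size)


@dataclass
class HyperCube:
    """A (rows, cols, bands) stack of images with its wavelength grid.

    ``kind`` distinguishes raw sensor counts from calibrated relative
    transmittance; calibrated values are non-negative by contract.
    """

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.values.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.kind not in ("raw", "calibrated"):
            raise ValueError("kind must be 'raw' or 'calibrated'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band_plane(self, wavelength: float) -> np.ndarray:
        """2-D image at the band nearest ``wavelength`` (nm)."""
        return self.values[:, :, band_index(self.grid, wavelength)]


@dataclass
class ReferencePair:
    """Dark (R_d) and white (R_t) reference frames matching a cube's geometry."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self):
        # preserve float32 frames; promote integer frames to float64
        self.dark = np.asarray(self.dark)
        self.white = np.asarray(self.white)
        if not np.issubdtype(self.dark.dtype, np.floating):
            self.dark = self.dark.astype(float)
        if not np.issubdtype(self.white.dtype, np.floating):
            self.white = self.white.astype(float)
        if self.dark.shape != self.white.shape:
            raise ValueError("dark and white frames must share a shape")
        if self.dark.ndim != 3:
            raise ValueError("reference frames must be 3-D (rows, cols, bands)")


def band_index(grid: WavelengthGrid, wavelength: float) -> int:
    """Index of the band center nearest ``wavelength``; ties go to the lower band.

    The query must lie within the grid extended by half the edge band spacing.
    """
    centers = grid.band_centers
    if len(centers) == 1:
        lo = hi = 0.0
    else:
        lo = (centers[1] - centers[0]) / 2.0
        hi = (centers[-1] - centers[-2]) / 2.0
    if wavelength < centers[0] - lo or wavelength > centers[-1] + hi:
        raise ValueError(
            f"wavelength {wavelength} nm outside grid "
            f"[{centers[0]}, {centers[-1]}] nm (± half spacing)"
        )
    # argmin returns the first minimiser, i.e. the lower wavelength on a tie
    return int(np.argmin(np.abs(centers - wavelength)))


def _header_path(path: str) -> str:
    return path + ".hdr"


def write_envi(cube: HyperCube, path: str, interleave: str = "bsq",
               dtype: str = "float32") -> None:
    """Write ``cube`` to ``path`` (binary) plus ``path + '.hdr'`` (text header)."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}; use bsq or bil")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _DTYPE_NAMES:
        raise EnviFormatError(f"unsupported data type {dtype!r}; use float32 or uint16")

    rows, cols, bands = cube.shape
    if interleave == "bsq":
        arr = np.transpose(cube.values, (2, 0, 1))  # (bands, lines, samples)
    else:  # bil
        arr = np.transpose(cube.values, (0, 2, 1))  # (lines, bands, samples)
    arr = np.ascontiguousarray(arr, dtype=np_dtype.newbyteorder("<"))

    wl = ", ".join(f"{w:.6f}" for w in cube.grid.band_centers)
    header = (
        "ENVI\n"
        "file type = ENVI Standard\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_NAMES[np_dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(_header_path(path), "w") as fh:
        fh.write(header)
    arr.tofile(path)


def _parse_header(text: str) -> dict:
    """Parse the ``key = value`` lines of an ENVI header, honouring {...} blocks."""
    fields: dict[str, str] = {}
    # fold brace-delimited multi-line values onto one line
    folded = []
    buf = None
    for line in text.splitlines():
        if buf is not None:
            buf += " " + line.strip()
            if "}" in line:
                folded.append(buf)
                buf = None
            continue
        if "{" in line and "}" not in line:
            buf = line.strip()
        else:
            folded.append(line.strip())
    if buf is not None:
        raise EnviFormatError("unterminated '{' block in header")
    for line in folded:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi(path: str) -> HyperCube:
    """Read an ENVI cube written by :func:`write_envi` (or compatible)."""
    hdr_path = _header_path(path)
    if not os.path.exists(hdr_path):
        raise FileNotFoundError(hdr_path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(hdr_path) as fh:
        fields = _parse_header(fh.read())

    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    if dtype_code not in _DTYPE_CODES:
        raise EnviFormatError(f"unsupported data type code {dtype_code}")
    if interleave not in _INTERLEAVES:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    offset = int(fields.get("header offset", "0"))

    wl_field = fields.get("wavelength", "")
    wl_text = wl_field.strip().strip("{}").strip()
    if not wl_text:
        raise EnviFormatError("header carries no wavelength list")
    centers = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    if centers.size != bands:
        raise EnviFormatError(
            f"wavelength list has {centers.size} entries for {bands} bands"
        )

    np_dtype = _DTYPE_CODES[dtype_code]
    expected = rows * cols * bands
    data = np.fromfile(path, dtype=np_dtype, offset=offset)
    if data.size != expected:
        raise EnviFormatError(
            f"data file holds {data.size} values; header declares {expected} "
            f"({rows}x{cols}x{bands})"
        )
    if interleave == "bsq":
        values = data.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:  # bil
        values = data.reshape(rows, bands, cols).transpose(0, 2, 1)
    return HyperCube(values=np.ascontiguousarray(values),
                     grid=WavelengthGrid(centers), kind="raw")


def calibrate(raw: HyperCube, refs: ReferencePair, *,
              white_transmittance_scale: float | None = None,
              denominator_tol: float = 1e-9) -> HyperCube:
    """Two-point transmittance correction R = (R_o − R_d) / (R_t − R_d).

    Negative corrected values (sensor noise below the dark level) are clipped
    to zero: transmittance is physically non-negative.  ``white_transmittance_scale``
    optionally multiplies the result (e.g. 0.99 for a 99 %-transmittance white
    board); by default no scale is applied.
    """
    if refs.dark.shape != raw.shape:
        raise ValueError(
            f"reference shape {refs.dark.shape} does not match cube shape {raw.shape}"
        )
    denom = refs.white - refs.dark
    bad = int(np.count_nonzero(denom <= denominator_tol))
    if bad:
        raise ValueError(
            f"white - dark <= {denominator_tol} at {bad} pixel-band(s); "
            "cannot calibrate"
        )
    values = raw.values
    if not np.issubdtype(values.dtype, np.floating):
        values = values.astype(refs.dark.dtype)
    corrected = (values - refs.dark) / denom
    if white_transmittance_scale is not None:
        corrected = corrected * float(white_transmittance_scale)
    np.clip(corrected, 0.0, None, out=corrected)
    return HyperCube(values=corrected, grid=raw.grid, kind="calibrated")
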