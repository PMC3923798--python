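"""Synthetic (phantom) hyperspectral egg generator.

Candling a green-shell egg in transmission mode gives a spectrum that is
essentially zero below ~650 nm and above ~950 nm with a single transmission
peak near 825 nm.  During incubation the peak transmittance declines —
slowly for eggs whose embryo never develops (group N), markedly for eggs
with a developing embryo (group D, blood strongly absorbs), and at an
intermediate rate for weakly developing embryos (group W).  From about
day 3 a developing embryo also appears as a growing low-transmittance
region inside the egg silhouette; weak embryos lag by roughly a day.

The generator renders that structure deterministically from a seed:

* an elliptical egg on a near-zero background, every shell pixel carrying
  an asymmetric Gaussian-like spectral bump peaking at the configured
  wavelength, scaled per group/day by a multiplicative decay;
* an off-centre elliptical embryo (area fraction set per group and day)
  with strongly reduced transmittance and a perturbed boundary;
* multiplicative lognormal pore speckle shared across bands (pores are a
  spatial property of the shell) and additive sensor noise;
* dark/white reference frames emulating the camera offset and open path.

Cubes are emitted as *raw counts* so the downstream dark/white calibration
is exercised; a :class:`PhantomTruth` sidecar records the rendered masks'
pixel counts for parameter-recovery tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .envi import HyperCube, ReferencePair, WavelengthGrid, write_envi

__all__ = [
    "GROUPS",
    "DAYS",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom_cube",
    "generate_references",
    "generate_cohort",
    "write_truth",
    "read_truth",
]

GROUPS = ("N", "D", "W")
DAYS = (0, 1, 2, 3, 4)


def _default_embryo_growth() -> dict:
    # D: visible development from day 3, obvious by day 4.
    # W: the D curve delayed one day and halved in amplitude.
    d = {0: 0.0, 1: 0.01, 2: 0.03, 3: 0.10, 4: 0.20}
    w = {0: 0.0, 1: d[0] / 2, 2: d[1] / 2, 3: d[2] / 2, 4: d[3] / 2}
    n = {day: 0.0 for day in DAYS}
    return {"N": n, "D": d, "W": w}


def _default_group_decay() -> dict:
    # per-day multiplicative decline of peak transmittance; decline D >= W >= N
    return {"N": 0.98, "W": 0.90, "D": 0.82}


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic cohort.

    Geometry defaults to half the acquisition frame of the emulated rig
    (220x400 px, 111 bands over 400-1000 nm) for speed; :func:`full_scale`
    restores the native 440x804 / 440-band frame.
    """

    image_rows: int = 220
    image_cols: int = 400
    n_bands: int = 111
    wavelength_min: float = 400.0
    wavelength_max: float = 1000.0
    egg_axes: tuple[float, float] = (80.0, 150.0)  # (row, col) semi-axes, px
    shell_peak_wavelength: float = 825.0
    shell_peak_transmittance: float = 0.5
    peak_sigma_below: float = 60.0  # nm, width of the bump toward the blue
    peak_sigma_above: float = 40.0  # nm, width toward the NIR
    egg_scale_sigma: float = 0.15   # lognormal sigma of per-egg brightness
    pore_speckle_sd: float = 0.05   # lognormal sigma of the pore field
    sensor_noise_sd: float = 0.005  # additive noise, fraction of white-dark span
    embryo_attenuation: float = 0.25  # transmittance multiplier inside the embryo
    embryo_offset_frac: float = 0.25  # embryo centre offset, fraction of egg axes
    embryo_boundary_amp: float = 0.05  # radial boundary perturbation amplitude
    embryo_fraction_jitter: float = 0.15  # lognormal sigma on the area fraction
    dark_level: float = 30.0
    white_level: float = 1000.0
    embryo_growth: dict = field(default_factory=_default_embryo_growth)
    group_decay: dict = field(default_factory=_default_group_decay)
    cohort: dict = field(default_factory=lambda: {"N": 30, "D": 60, "W": 60})
    seed: int = 0

    def __post_init__(self):
        if self.n_bands < 3:
            raise ValueError("n_bands must be >= 3")
        if not self.wavelength_min < self.wavelength_max:
            raise ValueError("wavelength_min must be < wavelength_max")
        if not 0 < self.shell_peak_transmittance <= 1:
            raise ValueError("shell_peak_transmittance must lie in (0, 1]")
        for group in GROUPS:
            if group not in self.embryo_growth or group not in self.group_decay:
                raise ValueError(f"embryo_growth/group_decay must cover group {group}")
        for group, curve in self.embryo_growth.items():
            for day, frac in curve.items():
                if not 0 <= frac < 1:
                    raise ValueError(
                        f"embryo area fraction {frac} for {group} day {day} "
                        "outside [0, 1)"
                    )
        if any(self.embryo_growth["N"][d] != 0.0 for d in DAYS):
            raise ValueError("group N must have zero embryo fraction on every day")
        gd = self.group_decay
        if not gd["D"] <= gd["W"] <= gd["N"]:
            raise ValueError("peak decline must order D >= W >= N "
                             "(decay factors D <= W <= N)")
        if any(c < 0 for c in self.cohort.values()):
            raise ValueError("cohort counts must be >= 0")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.linspace(self.wavelength_min, self.wavelength_max, self.n_bands)
        )

    def noise_free(self) -> "PhantomConfig":
        """Copy with every stochastic amplitude set to zero."""
        return replace(self, egg_scale_sigma=0.0, pore_speckle_sd=0.0,
                       sensor_noise_sd=0.0, embryo_fraction_jitter=0.0)


def full_scale(**overrides) -> PhantomConfig:
    """Native acquisition frame: 440x804 px, 440 bands over 400-1000 nm."""
    base = dict(image_rows=440, image_cols=804, n_bands=440,
                egg_axes=(160.0, 300.0))
    base.update(overrides)
    return PhantomConfig(**base)


def small(**overrides) -> PhantomConfig:
    """Quarter-frame preset for quick exploratory runs."""
    base = dict(image_rows=110, image_cols=200, n_bands=56,
                egg_axes=(40.0, 75.0))
    base.update(overrides)
    return PhantomConfig(**base)


def tiny(**overrides) -> PhantomConfig:
    """Smallest geometry whose egg still holds a 1000-px ROI; for bookkeeping
    and fast property tests."""
    base = dict(image_rows=44, image_cols=80, n_bands=21,
                egg_axes=(16.0, 30.0))
    base.update(overrides)
    return PhantomConfig(**base)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth recorded alongside each rendered cube."""

    egg_pixel_count: int
    embryo_pixel_count: int
    true_morph_rate: float
    true_peak_transmittance: float
    group: str
    day: int

    def __post_init__(self):
        expected = (self.embryo_pixel_count / self.egg_pixel_count
                    if self.egg_pixel_count else 0.0)
        if abs(self.true_morph_rate - expected) > 1e-12:
            raise ValueError("true_morph_rate inconsistent with pixel counts")
        if not 0 <= self.true_morph_rate < 1:
            raise ValueError("true_morph_rate must lie in [0, 1)")


def _spectral_bump(grid: WavelengthGrid, cfg: PhantomConfig) -> np.ndarray:
    """Unit-peak asymmetric Gaussian around the shell peak wavelength."""
    wl = grid.band_centers
    sigma = np.where(wl < cfg.shell_peak_wavelength,
                     cfg.peak_sigma_below, cfg.peak_sigma_above)
    return np.exp(-0.5 * ((wl - cfg.shell_peak_wavelength) / sigma) ** 2)


def _ellipse_mask(rows: int, cols: int, center: tuple[float, float],
                  axes: tuple[float, float],
                  boundary: tuple[float, float, float] | None = None) -> np.ndarray:
    """Boolean ellipse; ``boundary=(amp, lobes, phase)`` perturbs the radius."""
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = (rr - center[0]) / axes[0]
    dc = (cc - center[1]) / axes[1]
    radius = np.hypot(dr, dc)
    limit = 1.0
    if boundary is not None:
        amp, lobes, phase = boundary
        theta = np.arctan2(dr, dc)
        limit = 1.0 + amp * np.sin(lobes * theta + phase)
    return radius <= limit


def render_masks(cfg: PhantomConfig, group: str, day: int,
                 sample_seed: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Egg and embryo boolean masks plus the jittered embryo area fraction.

    The embryo mask returned here is, by construction, the mask painted into
    the cube — the truth sidecar counts these exact pixels.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if day not in DAYS:
        raise ValueError(f"unknown day {day!r}; expected one of {DAYS}")
    rows, cols = cfg.image_rows, cfg.image_cols
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    egg = _ellipse_mask(rows, cols, center, cfg.egg_axes)

    rng_egg = np.random.default_rng([int(sample_seed), 11])
    # per-egg draws, in a fixed order so trajectories are day-consistent
    _scale = rng_egg.lognormal(0.0, cfg.egg_scale_sigma) if cfg.egg_scale_sigma else 1.0
    angle = rng_egg.uniform(0, 2 * np.pi)
    phase = rng_egg.uniform(0, 2 * np.pi)
    jitter = (rng_egg.lognormal(0.0, cfg.embryo_fraction_jitter)
              if cfg.embryo_fraction_jitter else 1.0)

    frac = cfg.embryo_growth[group][day] * jitter
    if frac <= 0:
        return egg, np.zeros_like(egg), 0.0
    off = (cfg.embryo_offset_frac * cfg.egg_axes[0] * np.sin(angle),
           cfg.embryo_offset_frac * cfg.egg_axes[1] * np.cos(angle))
    semi = np.sqrt(frac)
    if cfg.embryo_offset_frac + semi * (1 + cfg.embryo_boundary_amp) > 1.0:
        raise ValueError(
            f"embryo area fraction {frac:.3f} cannot fit inside the egg ellipse"
        )
    embryo_axes = (semi * cfg.egg_axes[0], semi * cfg.egg_axes[1])
    embryo = _ellipse_mask(rows, cols,
                           (center[0] + off[0], center[1] + off[1]),
                           embryo_axes,
                           boundary=(cfg.embryo_boundary_amp, 3.0, phase))
    embryo &= egg
    return egg, embryo, frac


def _egg_scale(cfg: PhantomConfig, sample_seed: int) -> float:
    if not cfg.egg_scale_sigma:
        return 1.0
    rng_egg = np.random.default_rng([int(sample_seed), 11])
    return rng_egg.lognormal(0.0, cfg.egg_scale_sigma)


def generate_phantom_cube(cfg: PhantomConfig, group: str, day: int,
                          sample_seed: int) -> tuple[HyperCube, PhantomTruth]:
    """Render one raw-counts cube for (group, day) and its ground truth.

    Deterministic: identical (cfg, group, day, sample_seed) yield bitwise
    identical cubes.  Per-egg draws (brightness, embryo placement, growth
    jitter) depend only on ``sample_seed``, so one egg is self-consistent
    across its five imaging days; noise fields depend on (seed, day).
    """
    egg, embryo, _frac = render_masks(cfg, group, day, sample_seed)
    scale = _egg_scale(cfg, sample_seed)
    grid = cfg.grid

    peak_today = (cfg.shell_peak_transmittance * scale
                  * cfg.group_decay[group] ** day)
    bump = _spectral_bump(grid, cfg)

    # float32 throughout: a full-scale cohort is hundreds of cubes and the
    # extra float64 precision is far below the modelled sensor noise
    rng_day = np.random.default_rng([int(sample_seed), 13, int(day)])
    amplitude = np.where(egg, np.float32(peak_today), np.float32(0.0))
    if embryo.any():
        amplitude[embryo] *= np.float32(cfg.embryo_attenuation)
    if cfg.pore_speckle_sd:
        speckle = np.exp(rng_day.standard_normal(egg.shape, dtype=np.float32)
                         * np.float32(cfg.pore_speckle_sd))
        amplitude *= speckle
    raw = amplitude[:, :, None] * bump.astype(np.float32)[None, None, :]

    span = cfg.white_level - cfg.dark_level
    raw *= np.float32(span)
    raw += np.float32(cfg.dark_level)
    if cfg.sensor_noise_sd:
        noise = rng_day.standard_normal(raw.shape, dtype=np.float32)
        noise *= np.float32(cfg.sensor_noise_sd * span)
        raw += noise
    cube = HyperCube(values=raw, grid=grid, kind="raw")

    egg_px = int(egg.sum())
    embryo_px = int(embryo.sum())
    truth = PhantomTruth(
        egg_pixel_count=egg_px,
        embryo_pixel_count=embryo_px,
        true_morph_rate=embryo_px / egg_px if egg_px else 0.0,
        true_peak_transmittance=float(peak_today),
        group=group,
        day=int(day),
    )
    return cube, truth


def generate_references(cfg: PhantomConfig) -> ReferencePair:
    """Dark and white reference frames for the configured geometry.

    The dark frame sits at the sensor offset, the white frame near the
    sensor maximum; with zero sensor noise both are constant.  White
    exceeds dark at every pixel-band by construction.
    """
    shape = (cfg.image_rows, cfg.image_cols, cfg.n_bands)
    rng = np.random.default_rng([int(cfg.seed), 17])
    span = cfg.white_level - cfg.dark_level
    sd = cfg.sensor_noise_sd * span
    dark = np.full(shape, cfg.dark_level, dtype=np.float32)
    white = np.full(shape, cfg.white_level, dtype=np.float32)
    if sd:
        dark += rng.standard_normal(shape, dtype=np.float32) * np.float32(sd)
        white += rng.standard_normal(shape, dtype=np.float32) * np.float32(sd)
        floor = np.float32(cfg.dark_level + 0.5 * span)
        np.maximum(white, floor, out=white)  # keep the denominator positive
    return ReferencePair(dark=dark, white=white)


def sample_seeds(cfg: PhantomConfig, n_samples: int) -> np.ndarray:
    """Deterministic per-sample seeds derived from the master seed."""
    state = np.random.SeedSequence(int(cfg.seed)).generate_state(max(n_samples, 1))
    return (state[:n_samples].astype(np.uint64) % np.uint64(2**31)).astype(np.int64)


def write_truth(truth: PhantomTruth, path: str) -> None:
    with open(path, "w") as fh:
        for key in ("group", "day", "egg_pixel_count", "embryo_pixel_count",
                    "true_morph_rate", "true_peak_transmittance"):
            fh.write(f"{key}\t{getattr(truth, key)}\n")


def read_truth(path: str) -> PhantomTruth:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            fields[key] = value
    return PhantomTruth(
        egg_pixel_count=int(fields["egg_pixel_count"]),
        embryo_pixel_count=int(fields["embryo_pixel_count"]),
        true_morph_rate=float(fields["true_morph_rate"]),
        true_peak_transmittance=float(fields["true_peak_transmittance"]),
        group=fields["group"],
        day=int(fields["day"]),
    )


def cohort_records(cfg: PhantomConfig) -> list[tuple[str, str, int, int]]:
    """(egg id, group, sample index, sample seed) for the configured cohort."""
    total = sum(int(cfg.cohort.get(g, 0)) for g in GROUPS)
    seeds = sample_seeds(cfg, total)
    records = []
    idx = 0
    for group in GROUPS:
        for k in range(int(cfg.cohort.get(group, 0))):
            records.append((f"{group}{k + 1:03d}", group, idx, int(seeds[idx])))
            idx += 1
    return records


def generate_cohort(cfg: PhantomConfig, out_dir: str,
                    interleave: str = "bsq") -> pd.DataFrame:
    """Write one cube + truth sidecar per sample per day (days 0-4).

    Returns the manifest (id, group, day, cube, truth), also written to
    ``manifest.tsv`` in ``out_dir``.  The whole cohort is a pure function
    of (cfg, cfg.seed).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for egg_id, group, _idx, seed in cohort_records(cfg):
        for day in DAYS:
            cube, truth = generate_phantom_cube(cfg, group, day, seed)
            stem = f"{egg_id}_d{day}"
            cube_path = os.path.join(out_dir, stem + ".img")
            truth_path = os.path.join(out_dir, stem + ".truth.tsv")
            write_envi(cube, cube_path, interleave=interleave)
            write_truth(truth, truth_path)
            rows.append({"id": egg_id, "group": group, "day": day,
                         "cube": cube_path, "truth": truth_path})
    manifest = pd.DataFrame(rows, columns=["id", "group", "day", "cube", "truth"])
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest
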