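"""Synthetic Vis-NIR pineapple spectra with a planted SSC signal.

The generator emulates the statistical structure of a 100-fruit soluble
solids study on a combined visible (400-1000 nm) + near-infrared
(900-1700 nm) grid of 486 bands: Gaussian absorption features (chlorophyll
~680 nm, red-edge pigment ~710 nm, water ~980/1180/1420 nm, carbohydrate
~1360 nm), per-sample multiplicative scatter, smooth baseline drift and
iid detector noise. Absorbers flagged as SSC-linked have Beer-Lambert
depths proportional to the sample's SSC, so downstream wavelength
selection has a known ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import HyperspectralCube, ReferenceVector, SpectraMatrix, Spectrum

__all__ = [
    "SyntheticConfig",
    "default_wavelength_grid",
    "vl_instrument_grid",
    "nir_instrument_grid",
    "generate_reference_ssc",
    "generate_spectra",
    "generate_dataset",
    "generate_cube",
]

#: nm step of the NIR spectrograph.
NIR_STEP = 4.65
#: wavelength (nm) below which the fused grid uses the VL camera.
VL_NIR_CUTOFF = 1000.0
#: total band count of the fused VL+NIR grid.
N_BANDS = 486


def vl_instrument_grid(n_points: int = 336) -> np.ndarray:
    """Uniform visible-light camera grid over 400-1000 nm inclusive."""
    return np.linspace(400.0, 1000.0, n_points)


def nir_instrument_grid() -> np.ndarray:
    """Native NIR camera grid: 900 + k*4.65 nm for k = 0..171 (<= 1700 nm)."""
    return 900.0 + NIR_STEP * np.arange(172)


def default_wavelength_grid() -> np.ndarray:
    """The fused 486-band VL+NIR wavelength grid (nm).

    VL segment: 336 uniform points over 400-1000 nm. NIR segment: the 150
    native NIR wavelengths strictly above 1000 nm (1002.3 ... 1695.15 nm).
    The concatenation is strictly increasing, starts at 400 nm, ends below
    1700 nm and has exactly 486 bands.
    """
    nir = nir_instrument_grid()
    grid = np.concatenate([vl_instrument_grid(), nir[nir > VL_NIR_CUTOFF]])
    assert grid.size == N_BANDS, f"fused grid has {grid.size} bands, expected {N_BANDS}"
    return grid


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults emulate the reference dataset: 100 fruit, SSC ~ truncated
    normal with mean 17.33 / SD 3.18 % Brix on [10.37, 23.85], six
    absorbers of which 680/710/1360 nm are SSC-linked (depth in absorbance
    units per % Brix) and the water bands carry fixed depths.
    """

    n_samples: int = 100
    ssc_mean: float = 17.33
    ssc_sd: float = 3.18
    ssc_min: float = 10.37
    ssc_max: float = 23.85
    absorber_centers: tuple[float, ...] = (680.0, 710.0, 980.0, 1180.0, 1360.0, 1420.0)
    absorber_widths: tuple[float, ...] = (12.0, 9.0, 28.0, 30.0, 18.0, 30.0)
    ssc_linked_flags: tuple[bool, ...] = (True, True, False, False, True, False)
    #: absorbance per % Brix for SSC-linked absorbers, absorbance otherwise;
    #: linked depths are balanced so the three bands have comparable
    #: reflectance-domain sensitivity to SSC
    depth_coefficients: tuple[float, ...] = (0.012, 0.009, 0.30, 0.20, 0.011, 0.35)
    scatter_gain_range: tuple[float, float] = (0.95, 1.05)
    scatter_offset_sd: float = 0.005
    baseline_amplitude: float = 0.003
    noise_sd: float = 0.002
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (self.ssc_min < self.ssc_mean < self.ssc_max):
            raise ValueError("require ssc_min < ssc_mean < ssc_max")
        if self.ssc_sd < 0:
            raise ValueError("ssc_sd must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        n_abs = len(self.absorber_centers)
        for name in ("absorber_widths", "ssc_linked_flags", "depth_coefficients"):
            if len(getattr(self, name)) != n_abs:
                raise ValueError(f"{name} must have length {n_abs}")
        lo, hi = self.scatter_gain_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("scatter_gain_range must be a positive interval")

    @property
    def linked_centers(self) -> tuple[float, ...]:
        return tuple(
            c for c, f in zip(self.absorber_centers, self.ssc_linked_flags) if f
        )


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one named stream of a top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_reference_ssc(config: SyntheticConfig) -> ReferenceVector:
    """Draw per-sample SSC from a truncated normal; deterministic in the seed."""
    if config.ssc_sd == 0:
        values = np.full(config.n_samples, config.ssc_mean)
    else:
        a = (config.ssc_min - config.ssc_mean) / config.ssc_sd
        b = (config.ssc_max - config.ssc_mean) / config.ssc_sd
        values = stats.truncnorm.rvs(
            a, b, loc=config.ssc_mean, scale=config.ssc_sd,
            size=config.n_samples, random_state=_stream_rng(config.seed, 0),
        )
    return ReferenceVector(values)


def _absorbance(ssc: np.ndarray, grid: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Beer-Lambert absorbance surface: n_samples x n_bands."""
    A = np.zeros((ssc.size, grid.size))
    for c, w, linked, d in zip(
        config.absorber_centers, config.absorber_widths,
        config.ssc_linked_flags, config.depth_coefficients,
    ):
        shape = np.exp(-((grid - c) ** 2) / (2.0 * w**2))
        depth = d * ssc if linked else np.full(ssc.size, d)
        A += depth[:, None] * shape[None, :]
    return A


def generate_spectra(
    ref: ReferenceVector, grid: np.ndarray, config: SyntheticConfig
) -> SpectraMatrix:
    """Observed reflectance: gain * 10^(-A) + offset + baseline + noise.

    Per sample the multiplicative gain is uniform on ``scatter_gain_range``,
    the additive offset is N(0, scatter_offset_sd), the baseline is a random
    quadratic in the normalised wavelength with coefficient scale
    ``baseline_amplitude`` (the drift that motivates derivative
    pretreatments), and noise is iid N(0, noise_sd).
    """
    if ref.n_samples != config.n_samples:
        raise ValueError("reference vector length does not match config.n_samples")
    grid = np.asarray(grid, dtype=float)
    rng = _stream_rng(config.seed, 1)
    n, k = ref.n_samples, grid.size

    ideal = 10.0 ** (-_absorbance(ref.ssc, grid, config))

    lo, hi = config.scatter_gain_range
    gain = rng.uniform(lo, hi, size=n)
    offset = (
        rng.normal(0.0, config.scatter_offset_sd, size=n)
        if config.scatter_offset_sd > 0 else np.zeros(n)
    )
    # smooth quadratic drift on the normalised wavelength axis
    if config.baseline_amplitude > 0:
        x = (grid - grid[0]) / (grid[-1] - grid[0]) * 2.0 - 1.0
        coeffs = rng.normal(0.0, config.baseline_amplitude, size=(n, 3))
        baseline = coeffs @ np.vstack([np.ones(k), x, x**2])
    else:
        baseline = np.zeros((n, k))
    noise = rng.normal(0.0, config.noise_sd, size=(n, k)) if config.noise_sd > 0 else 0.0

    observed = gain[:, None] * ideal + offset[:, None] + baseline + noise
    return SpectraMatrix(grid, observed, list(ref.sample_ids))


def generate_dataset(
    config: SyntheticConfig, grid: np.ndarray | None = None
) -> tuple[SpectraMatrix, ReferenceVector]:
    """Convenience: reference SSC plus matching spectra on the fused grid."""
    if grid is None:
        grid = default_wavelength_grid()
    ref = generate_reference_ssc(config)
    return generate_spectra(ref, grid, config), ref


def generate_cube(
    spectrum: Spectrum,
    shape: tuple[int, int] = (24, 24),
    roi_fraction: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[HyperspectralCube, np.ndarray, np.ndarray, np.ndarray]:
    """Toy raw cube whose calibrated ROI mean reproduces ``spectrum``.

    Raw counts are built by inverting the white/dark correction:
    I = D + R*(W - D) (+ noise scaled to reflectance units), with constant
    per-band white/dark reference vectors and a centred rectangular ROI
    covering ~``roi_fraction`` of the image; background pixels hold a flat
    5 % reflectance. Returns (cube, white_ref, dark_ref, roi_mask).
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("cube shape must be positive")
    if not (0.0 < roi_fraction <= 1.0):
        raise ValueError("roi_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_bands = spectrum.n_bands

    dark = np.full(n_bands, 100.0)
    white = np.full(n_bands, 4000.0)
    span = white - dark

    mask = np.zeros((rows, cols), dtype=bool)
    if roi_fraction == 1.0:
        mask[:] = True
    else:
        r = max(1, int(round(rows * math.sqrt(roi_fraction))))
        c = max(1, int(round(cols * math.sqrt(roi_fraction))))
        r0, c0 = (rows - r) // 2, (cols - c) // 2
        mask[r0 : r0 + r, c0 : c0 + c] = True

    reflectance = np.full((rows, cols, n_bands), 0.05)
    reflectance[mask] = spectrum.values
    if noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, noise_sd, size=reflectance.shape)

    data = dark[None, None, :] + reflectance * span[None, None, :]
    cube = HyperspectralCube(data, spectrum.wavelengths, white, dark)
    return cube, white, dark, mask
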