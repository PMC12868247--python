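"""Reflectance calibration of raw cubes and ROI mean-spectrum extraction.

Raw detector counts I are converted to reflectance with the whiteboard /
dark-current correction R = (I - D)/(W - D); the sample spectrum is the
per-band arithmetic mean over the fruit's ROI pixels; VL and NIR camera
spectra are fused onto the combined 486-band grid.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import HyperspectralCube, Spectrum
from .simulate import VL_NIR_CUTOFF

__all__ = ["calibrate_reflectance", "extract_roi_mean", "fuse_vl_nir"]

logger = logging.getLogger(__name__)


def calibrate_reflectance(cube: HyperspectralCube) -> HyperspectralCube:
    """White/dark-correct a raw cube: R = (I - D)/(W - D) elementwise.

    References may be per-band vectors or per-pixel frames. Reflectance is
    deliberately not clipped to [0, 1]; specular pixels above 1 are kept
    and logged.
    """
    if cube.white_ref is None or cube.dark_ref is None:
        raise ValueError("cube must carry white_ref and dark_ref for calibration")
    white = np.broadcast_to(cube.white_ref, cube.data.shape)
    dark = np.broadcast_to(cube.dark_ref, cube.data.shape)
    denom = white - dark
    bad = np.abs(denom) < 1e-12
    if np.any(bad):
        band = int(np.argwhere(bad)[0, -1])
        raise ZeroDivisionError(
            f"white_ref - dark_ref is zero at band index {band} "
            f"({cube.wavelengths[band]:.2f} nm)"
        )
    reflectance = (cube.data - dark) / denom
    n_over = int(np.count_nonzero(reflectance > 1.0))
    if n_over:
        logger.info("calibration produced %d reflectance values > 1 (kept)", n_over)
    return HyperspectralCube(reflectance, cube.wavelengths.copy())


def extract_roi_mean(cube: HyperspectralCube, mask: np.ndarray) -> Spectrum:
    """Per-band arithmetic mean over the masked (fruit) pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.data.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty: no pixels to average")
    return Spectrum(cube.wavelengths.copy(), cube.data[mask].mean(axis=0))


def fuse_vl_nir(
    vl: Spectrum,
    nir: Spectrum,
    target: np.ndarray,
    cutoff: float = VL_NIR_CUTOFF,
    tolerance: float = 2.5,
) -> Spectrum:
    """Map VL and NIR spectra onto one target grid.

    Each target wavelength is served by the VL spectrum below ``cutoff``
    and by the NIR spectrum at/above it (the two cameras overlap over
    900-1000 nm; VL wins there because its sampling is finer). Values are
    taken from the nearest source band; a target band further than
    ``tolerance`` nm from any source band of its side is an error.
    """
    target = np.asarray(target, dtype=float)
    if not np.all(np.diff(target) > 0):
        raise ValueError("target grid must be strictly increasing")
    out = np.empty(target.size)
    for i, w in enumerate(target):
        source = vl if w < cutoff else nir
        j = int(np.argmin(np.abs(source.wavelengths - w)))
        dist = abs(source.wavelengths[j] - w)
        if dist > tolerance:
            side = "VL" if w < cutoff else "NIR"
            raise ValueError(
                f"target band {w:.2f} nm has no {side} source band within "
                f"{tolerance} nm (nearest at {source.wavelengths[j]:.2f} nm)"
            )
        out[i] = source.values[j]
    return Spectrum(target, out)
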