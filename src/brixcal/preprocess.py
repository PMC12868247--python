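"""The five spectral pretreatments.

MSC_A  - multiplicative scatter correction against a reference spectrum
SG_A   - Savitzky-Golay polynomial smoothing
dA     - first derivative with respect to wavelength
ddA    - second derivative with respect to wavelength
lgA    - absorbance-style logarithm, log10(1/R)

Functions operate on plain (n_samples x n_bands) arrays; the
``apply_preprocessing`` dispatcher works on :class:`SpectraMatrix` and
carries the fitted state (the MSC reference) from the calibration set to
the test set so that both are transformed identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_coeffs

from .containers import SpectraMatrix

__all__ = [
    "PreprocessMethod",
    "PRETREATMENTS",
    "msc",
    "savitzky_golay",
    "derivative",
    "log_transform",
    "apply_preprocessing",
]

#: minimum |slope| in the per-sample MSC regression
MSC_SLOPE_TOL = 1e-8


@dataclass(frozen=True)
class PreprocessMethod:
    """One pretreatment tag plus its parameters."""

    tag: str
    window: int = 11
    polyorder: int = 2
    epsilon: float = 1e-6

    _VALID = ("MSC_A", "SG_A", "dA", "ddA", "lgA")

    def __post_init__(self) -> None:
        if self.tag not in self._VALID:
            raise ValueError(f"unknown pretreatment tag {self.tag!r}; valid: {self._VALID}")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and greater than polyorder")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


#: the study's five pretreatments with default parameters
PRETREATMENTS: tuple[PreprocessMethod, ...] = tuple(
    PreprocessMethod(tag) for tag in ("MSC_A", "SG_A", "dA", "ddA", "lgA")
)


def msc(
    X: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction.

    Each spectrum is regressed on the reference, x_i ~ a_i + b_i * m, and
    corrected to (x_i - a_i)/b_i. The reference defaults to the column
    mean of ``X`` (the calibration set); reuse the returned reference to
    transform a test set consistently.

    Returns (corrected, reference).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("MSC needs at least 2 bands")
    m = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if m.shape != (X.shape[1],):
        raise ValueError("reference length does not match band count")
    mc = m - m.mean()
    var_m = mc @ mc
    if var_m < MSC_SLOPE_TOL:
        raise ValueError("MSC reference spectrum has (near-)zero variance")
    # closed-form simple regression per sample
    b = (X - X.mean(axis=1, keepdims=True)) @ mc / var_m
    small = np.abs(b) < MSC_SLOPE_TOL
    if np.any(small):
        i = int(np.argwhere(small)[0, 0])
        raise ValueError(f"MSC slope is (near-)zero for sample index {i}")
    a = X.mean(axis=1) - b * m.mean()
    return (X - a[:, None]) / b[:, None], m


def savitzky_golay(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing over the band-index axis.

    Interior points use the standard centred convolution weights; near the
    edges the window shrinks to the available one-sided points and a local
    least-squares polynomial (degree capped at the point count minus one)
    is fitted directly, so no data are fabricated by padding. Shape is
    preserved; a polynomial spectrum of degree <= polyorder passes through
    unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_bands = X.shape[1]
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if window > n_bands:
        raise ValueError(f"window {window} exceeds band count {n_bands}")
    half = window // 2
    coeffs = savgol_coeffs(window, polyorder)[::-1]
    out = X.copy()
    # interior: centred convolution
    if n_bands >= window:
        sw = np.lib.stride_tricks.sliding_window_view(X, window, axis=1)
        out[:, half : n_bands - half] = sw @ coeffs
    # edges: shrinking one-sided polynomial fits
    for i in range(half):
        for lo, hi, at in ((0, i + half + 1, i), (n_bands - 1 - i - half, n_bands, n_bands - 1 - i)):
            pts = np.arange(lo, hi)
            deg = min(polyorder, pts.size - 1)
            fit = np.polynomial.polynomial.polyfit(pts, X[:, pts].T, deg)
            out[:, at] = np.polynomial.polynomial.polyval(at, fit)
    return out


def derivative(X: np.ndarray, grid: np.ndarray, order: int = 1) -> np.ndarray:
    """Spectral derivative with respect to wavelength (per nm, or nm^-2).

    Finite differences on the physical wavelength axis (the fused VL+NIR
    grid is non-uniform, so index-based differencing would be wrong):
    three-point interpolating-polynomial stencils in the interior,
    one-sided stencils at the edges. Second order is the first derivative
    applied twice. Shape preserved.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid.size != X.shape[1]:
        raise ValueError("grid length does not match band count")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if X.shape[1] < order + 1:
        raise ValueError(f"need at least {order + 1} bands for order-{order} derivative")
    edge = 2 if X.shape[1] >= 3 else 1
    d = np.gradient(X, grid, axis=1, edge_order=edge)
    if order == 2:
        d = np.gradient(d, grid, axis=1, edge_order=edge)
    return d


def log_transform(X: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Absorbance-style transform lgA = log10(1 / max(R, epsilon))."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.log10(1.0 / np.maximum(X, epsilon))


def apply_preprocessing(
    spectra: SpectraMatrix,
    method: PreprocessMethod,
    fitted_state: dict[str, Any] | None = None,
) -> tuple[SpectraMatrix, dict[str, Any]]:
    """Apply one pretreatment; fit state on calibration data, reuse on test.

    For MSC the state holds the calibration-set reference spectrum; the
    stateless transforms return an empty state. Pass the state returned by
    the calibration-set call when transforming the test set.
    """
    X = spectra.values
    state: dict[str, Any] = dict(fitted_state or {})
    if method.tag == "MSC_A":
        corrected, reference = msc(X, state.get("reference"))
        state["reference"] = reference
        out = corrected
    elif method.tag == "SG_A":
        out = savitzky_golay(X, method.window, method.polyorder)
    elif method.tag == "dA":
        out = derivative(X, spectra.wavelengths, order=1)
    elif method.tag == "ddA":
        out = derivative(X, spectra.wavelengths, order=2)
    elif method.tag == "lgA":
        out = log_transform(X, method.epsilon)
    else:  # pragma: no cover - PreprocessMethod validates tags
        raise ValueError(f"unknown pretreatment tag {method.tag!r}")
    return spectra.with_values(out), state
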