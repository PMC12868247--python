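"""In-memory containers shared across the package.

A *spectrum* is a 1-D reflectance (or transformed) trace on a strictly
increasing wavelength grid in nanometres; a *spectra matrix* stacks one
spectrum per sample. Raw camera output is a rows x cols x bands cube with
white/dark reference frames attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraMatrix",
    "ReferenceVector",
    "HyperspectralCube",
]


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("wavelengths must be a non-empty 1-D array")
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return w


@dataclass
class Spectrum:
    """A single spectrum: per-band values on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = _check_wavelengths(self.wavelengths)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.wavelengths.shape} wavelengths"
            )

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectraMatrix:
    """n_samples x n_bands matrix of spectra on a common wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = _check_wavelengths(self.wavelengths)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"values have {self.values.shape[1]} bands but grid has "
                f"{self.wavelengths.size}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.values[i])

    def take_samples(self, indices) -> "SpectraMatrix":
        indices = np.asarray(indices, dtype=int)
        return SpectraMatrix(
            self.wavelengths.copy(),
            self.values[indices].copy(),
            [self.sample_ids[i] for i in indices],
        )

    def select_bands(self, band_indices) -> "SpectraMatrix":
        band_indices = np.sort(np.asarray(band_indices, dtype=int))
        return SpectraMatrix(
            self.wavelengths[band_indices].copy(),
            self.values[:, band_indices].copy(),
            list(self.sample_ids),
        )

    def with_values(self, new_values: np.ndarray) -> "SpectraMatrix":
        """Same grid and sample ids, new cell values (shape-preserving)."""
        return SpectraMatrix(self.wavelengths.copy(), new_values, list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[str(w) for w in self.wavelengths],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectraMatrix":
        wavelengths = np.array([float(c) for c in df.columns])
        return cls(wavelengths, df.to_numpy(dtype=float), [str(i) for i in df.index])


@dataclass
class ReferenceVector:
    """Per-sample reference SSC values in % Brix (the regression target).

    Values must be finite and strictly positive: they sit in MAPE
    denominators and the refractometer scale (0-53 % Brix) is positive.
    """

    ssc: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ssc = np.asarray(self.ssc, dtype=float)
        if self.ssc.ndim != 1:
            raise ValueError("ssc must be 1-D")
        if not np.all(np.isfinite(self.ssc)):
            raise ValueError("ssc values must be finite")
        if np.any(self.ssc <= 0):
            raise ValueError("ssc values must be strictly positive (% Brix)")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(self.ssc.size)]
        if len(self.sample_ids) != self.ssc.size:
            raise ValueError("sample_ids length does not match ssc length")

    @property
    def n_samples(self) -> int:
        return self.ssc.size


@dataclass
class HyperspectralCube:
    """rows x cols x bands cube plus white/dark reference data.

    ``white_ref``/``dark_ref`` may be per-band vectors (broadcast over
    pixels) or full per-pixel frames with the cube's spatial shape.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    white_ref: np.ndarray | None = None
    dark_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        self.wavelengths = _check_wavelengths(self.wavelengths)
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError("cube band count does not match wavelength grid")
        for name in ("white_ref", "dark_ref"):
            ref = getattr(self, name)
            if ref is None:
                continue
            ref = np.asarray(ref, dtype=float)
            if ref.shape not in ((self.wavelengths.size,), self.data.shape):
                raise ValueError(
                    f"{name} must be a (bands,) vector or a full rows x cols x "
                    f"bands frame; got shape {ref.shape}"
                )
            setattr(self, name, ref)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size
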