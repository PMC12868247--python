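"""Quick-look plots for spectra, SPA searches and calibration fits."""

from __future__ import annotations

import numpy as np

from .bands import SPAResult
from .containers import SpectraMatrix
from .models import CalibrationResults

__all__ = ["plot_spectra", "plot_rmse_curve", "plot_predictions"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_spectra(spectra: SpectraMatrix, ax=None, max_lines: int = 50, **kw):
    """Overlay sample spectra against wavelength."""
    ax = _get_ax(ax)
    step = max(1, spectra.n_samples // max_lines)
    for row in spectra.values[::step]:
        ax.plot(spectra.wavelengths, row, lw=0.6, alpha=0.6, **kw)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("reflectance")
    return ax

def plot_rmse_curve(result: SPAResult, ax=None, **kw):
    """Validation RMSE against SPA subset size; marks the chosen size."""
    ax = _get_ax(ax)
    sizes = sorted(result.rmse_by_size)
    ax.plot(sizes, [result.rmse_by_size[s] for s in sizes], marker="o", **kw)
    ax.axvline(result.chosen_size, ls="--", color="grey")
    ax.set_xlabel("number of selected bands")
    ax.set_ylabel("validation RMSE (% Brix)")
    return ax

def plot_predictions(results: CalibrationResults, X, y, ax=None, **kw):
    """Predicted vs measured SSC with the 1:1 line."""
    ax = _get_ax(ax)
    y = np.asarray(y, dtype=float)
    pred = results.predict(X)
    ax.scatter(y, pred, s=18, **kw)
    lims = [min(y.min(), pred.min()), max(y.max(), pred.max())]
    ax.plot(lims, lims, color="grey", lw=1)
    ax.set_xlabel("measured SSC (% Brix)")
    ax.set_ylabel("predicted SSC (% Brix)")
    return ax
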