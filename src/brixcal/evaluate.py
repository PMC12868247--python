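"""Seeded random splitting and the calibration metrics R2 / MAPE / RMSEP.

R2   = 1 - SS_res / SS_tot              (reported as a fraction)
MAPE = mean(|y_i - yhat_i| / y_i)       (fraction; y_i must be nonzero)
RMSEP = sqrt(mean((yhat_i - y_i)^2))    (% Brix)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SplitSpec",
    "random_split",
    "r_squared",
    "mape",
    "rmsep",
    "characteristic_proportion",
    "evaluate_predictions",
    "EvaluationReport",
]


@dataclass(frozen=True)
class SplitSpec:
    """A seeded random train/test partition of ``n`` samples."""

    seed: int
    n: int
    train_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n < 2:
            raise ValueError("need at least 2 samples to split")


def random_split(spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint exhaustive (train, test) index arrays, deterministic in the seed.

    The train size is round(train_fraction * n): 100 samples at 9:1 give
    exactly 90 calibration and 10 prediction samples.
    """
    n_train = int(round(spec.train_fraction * spec.n))
    if n_train >= spec.n:
        raise ValueError("test set would be empty")
    if n_train < 1:
        raise ValueError("train set would be empty")
    perm = np.random.default_rng(spec.seed).permutation(spec.n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _as_arrays(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same length")
    return y, y_hat


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot (fraction)."""
    y, y_hat = _as_arrays(y, y_hat)
    if y.size < 2:
        raise ValueError("R2 needs at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined: reference values have zero variance")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mape(y, y_hat) -> float:
    """Mean absolute percentage error as a fraction."""
    y, y_hat = _as_arrays(y, y_hat)
    if np.any(y == 0):
        raise ValueError("MAPE undefined: reference contains zero values")
    return float(np.mean(np.abs(y - y_hat) / np.abs(y)))


def rmsep(y, y_hat) -> float:
    """Root mean square error of prediction (% Brix)."""
    y, y_hat = _as_arrays(y, y_hat)
    if y.size < 1:
        raise ValueError("RMSEP needs at least 1 observation")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def characteristic_proportion(n_selected: int, n_total: int) -> float:
    """Selected-band share of the full grid, in percent (7/486 -> 1.440...)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_selected <= n_total):
        raise ValueError("n_selected must be in [0, n_total]")
    return 100.0 * n_selected / n_total


def evaluate_predictions(y, y_hat) -> dict[str, float]:
    """The metric triple on one prediction set."""
    return {"r2": r_squared(y, y_hat), "mape": mape(y, y_hat), "rmsep": rmsep(y, y_hat)}


@dataclass
class EvaluationReport:
    """Grid of (pretreatment x model x band set) metric triples.

    ``rows`` hold dicts with keys pretreatment, model, band_set, r2, mape,
    rmsep plus any per-cell extras (chosen hyperparameters, failure notes);
    ``metadata`` records the split and settings that produced them.
    """

    rows: list[dict[str, Any]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def add(self, **row: Any) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        cols = ["pretreatment", "model", "band_set", "r2", "mape", "rmsep"]
        df = pd.DataFrame(self.rows)
        extras = [c for c in df.columns if c not in cols]
        return df.reindex(columns=[c for c in cols if c in df.columns] + extras)

    def to_csv(self, path) -> None:
        # fixed float format keeps repeated runs byte-identical
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        payload = {"metadata": self.metadata, "rows": self.rows}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)

    def cell(self, pretreatment: str, model: str) -> dict[str, Any]:
        for row in self.rows:
            if row.get("pretreatment") == pretreatment and row.get("model") == model:
                return row
        raise KeyError((pretreatment, model))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
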