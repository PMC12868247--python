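"""Calibration models, implemented from first principles.

Three regression families map a spectra matrix X (n_samples x n_bands) to
SSC in % Brix, in the statsmodels idiom: a model object is built from data
and ``fit()`` returns a :class:`CalibrationResults` carrying the affine
coefficients, hyperparameters, diagnostics and a ``summary()`` table.

* :class:`PLSRegression` - PLS1 via the NIPALS algorithm on centred data:
  iterate w = X'y/||X'y||, t = Xw, p = X't/t't, q = y't/t't, deflate
  X <- X - t p', y <- y - q t; the affine coefficient vector is
  B = W (P'W)^-1 q.
* :class:`LassoRegression` - minimises (1/2n)||y - Xb - b0||^2 + alpha*||b||_1
  by cyclic coordinate descent on internally standardised columns;
  coefficients are returned on the original scale.
* :class:`RidgeRegression` - b = (Xc'Xc + alpha*I)^-1 Xc'yc on centred data
  with an unpenalised intercept, via a stable linear solve.

Centring conventions follow chemometrics practice: PLSR and Ridge centre
only; Lasso standardises internally and back-transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .evaluate import SplitSpec, random_split, rmsep

__all__ = [
    "CalibrationResults",
    "PLSRegression",
    "LassoRegression",
    "RidgeRegression",
    "LassoConvergenceError",
    "fit_plsr",
    "fit_lasso",
    "fit_ridge",
    "predict",
    "select_plsr_components",
    "search_lasso_alpha",
]


class LassoConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within ``max_iter`` cycles."""

    def __init__(self, max_iter: int, max_delta: float):
        self.max_iter = max_iter
        super().__init__(
            f"lasso coordinate descent did not converge in {max_iter} cycles "
            f"(last max coefficient change {max_delta:.3e})"
        )


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} values")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return X, y


@dataclass
class CalibrationResults:
    """Fitted affine calibration: yhat = X @ coefficients + intercept."""

    method: str
    coefficients: np.ndarray
    intercept: float
    hyperparams: dict[str, Any]
    nobs: int
    #: training-set fitted values, for residual diagnostics
    fittedvalues: np.ndarray
    #: centring/scaling state used internally by the fit
    scaling: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    #: method-specific extras (PLSR weights/loadings/scores, iteration counts)
    extras: dict[str, Any] = field(default_factory=dict, repr=False)
    wavelengths: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coefficients.size:
            raise ValueError(
                f"X has {X.shape[1]} bands but model expects {self.coefficients.size}"
            )
        return X @ self.coefficients + self.intercept

    @property
    def n_bands(self) -> int:
        return self.coefficients.size

    def summary(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in self.hyperparams.items())
        nz = int(np.count_nonzero(self.coefficients))
        lines = [
            f"{self.method} calibration results",
            "=" * 34,
            f"  observations : {self.nobs}",
            f"  bands        : {self.n_bands} ({nz} nonzero coefficients)",
            f"  hyperparams  : {hp}",
            f"  intercept    : {self.intercept:.6g} % Brix",
        ]
        for key, value in self.extras.items():
            if np.isscalar(value):
                lines.append(f"  {key:<13}: {value}")
        return "\n".join(lines)


class _SpectralModel:
    """Base model: holds (X, y) and optional band wavelengths."""

    method = "base"

    def __init__(self, X, y, wavelengths=None):
        self.X, self.y = _validate_xy(X, y)
        self.wavelengths = None if wavelengths is None else np.asarray(wavelengths, float)
        if self.wavelengths is not None and self.wavelengths.size != self.X.shape[1]:
            raise ValueError("wavelengths length does not match X band count")

    @classmethod
    def from_spectra(cls, spectra, reference, **kw):
        """Build from a SpectraMatrix and a ReferenceVector."""
        return cls(spectra.values, reference.ssc, wavelengths=spectra.wavelengths, **kw)

    def _results(self, coefficients, intercept, hyperparams, **kw) -> CalibrationResults:
        coefficients = np.asarray(coefficients, dtype=float)
        fitted = self.X @ coefficients + intercept
        return CalibrationResults(
            method=self.method,
            coefficients=coefficients,
            intercept=float(intercept),
            hyperparams=hyperparams,
            nobs=self.X.shape[0],
            fittedvalues=fitted,
            wavelengths=self.wavelengths,
            **kw,
        )


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int, tol: float = 1e-12):
    """NIPALS PLS1 on centred data; returns (W, P, q, T), possibly truncated."""
    n, p = Xc.shape
    Xr, yr = Xc.copy(), yc.copy()
    W, P, Q, T = [], [], [], []
    scale = max(float(np.linalg.norm(Xc)) * float(np.linalg.norm(yc)), 1.0)
    for _ in range(n_components):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= tol * scale:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= tol * scale:
            break
        p_vec = Xr.T @ t / tt
        q = float(yr @ t) / tt
        Xr -= np.outer(t, p_vec)
        yr -= q * t
        W.append(w)
        P.append(p_vec)
        Q.append(q)
        T.append(t)
    return (
        np.array(W).T.reshape(p, -1),
        np.array(P).T.reshape(p, -1),
        np.array(Q),
        np.array(T).T.reshape(n, -1),
    )


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Affine coefficients for the first k components: W_k (P_k'W_k)^-1 q_k."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


class PLSRegression(_SpectralModel):
    """PLS1 partial least squares regression (NIPALS), centred data."""

    method = "PLSR"

    def fit(self, n_components: int = 10) -> CalibrationResults:
        n, p = self.X.shape
        bound = min(n - 1, p)
        if not (1 <= n_components <= bound):
            raise ValueError(f"n_components must be in [1, {bound}]")
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        yc = self.y - y_mean
        if np.allclose(yc, 0.0):
            raise ValueError("y has zero variance; PLSR is undefined")
        W, P, q, T = _nipals_pls1(self.X - x_mean, yc, n_components)
        k = q.size
        if k < n_components:
            warnings.warn(
                f"PLSR components truncated from {n_components} to {k} "
                "(X/y residual exhausted)", stacklevel=2,
            )
        beta = _pls_coefficients(W, P, q, k)
        intercept = y_mean - float(x_mean @ beta)
        return self._results(
            beta, intercept, {"n_components": k},
            scaling={"x_mean": x_mean, "y_mean": np.array([y_mean])},
            extras={"x_weights": W, "x_loadings": P, "y_loadings": q, "x_scores": T},
        )


def _soft_threshold(z: float, alpha: float) -> float:
    return np.sign(z) * max(abs(z) - alpha, 0.0)


def _cd_kernel(Xs, yc, alpha, tol, max_iter):
    """Cyclic coordinate descent with active-set refinement.

    Returns (beta, n_iter, max_delta); convergence is max|delta beta| < tol
    over a full cycle. Plain nested loops so numba can compile it.
    """
    n, p = Xs.shape
    col_sq = np.zeros(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xs[i, j] * Xs[i, j]
        col_sq[j] = s / n
    beta = np.zeros(p)
    resid = yc.copy()
    n_iter = 0
    max_delta = np.inf
    while n_iter < max_iter:
        # full sweep over all coordinates
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] <= 0.0:
                continue
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += Xs[i, j] * resid[i]
            rho = rho / n + col_sq[j] * bj
            z = abs(rho) - alpha
            bn = (z / col_sq[j]) * (1.0 if rho > 0 else -1.0) if z > 0.0 else 0.0
            if bn != bj:
                d = bn - bj
                for i in range(n):
                    resid[i] -= Xs[i, j] * d
                beta[j] = bn
                if abs(d) > max_delta:
                    max_delta = abs(d)
        n_iter += 1
        if max_delta < tol:
            return beta, n_iter, max_delta
        # refine on the current active set before the next full sweep
        while n_iter < max_iter:
            d_max = 0.0
            any_active = False
            for j in range(p):
                if beta[j] == 0.0 or col_sq[j] <= 0.0:
                    continue
                any_active = True
                bj = beta[j]
                rho = 0.0
                for i in range(n):
                    rho += Xs[i, j] * resid[i]
                rho = rho / n + col_sq[j] * bj
                z = abs(rho) - alpha
                bn = (z / col_sq[j]) * (1.0 if rho > 0 else -1.0) if z > 0.0 else 0.0
                if bn != bj:
                    d = bn - bj
                    for i in range(n):
                        resid[i] -= Xs[i, j] * d
                    beta[j] = bn
                    if abs(d) > d_max:
                        d_max = abs(d)
            n_iter += 1
            if d_max < tol or not any_active:
                break
    return beta, n_iter, max_delta


try:  # compiled kernel when numba is available; the pure-Python loop otherwise
    from numba import njit as _njit

    _cd_kernel = _njit(cache=False, fastmath=False)(_cd_kernel)
except ImportError:  # pragma: no cover
    pass


class LassoRegression(_SpectralModel):
    """L1-penalised linear regression via cyclic coordinate descent.

    Objective (on internally standardised columns, centred y):
    (1/2n)||y - Xb||^2 + alpha*||b||_1. Convergence: max coefficient
    change below ``tol`` over a full cycle; an active-set strategy
    iterates the nonzero coordinates between full sweeps. The default
    iteration cap is sized for near-unregularised fits on hundreds of
    collinear spectral bands, which converge slowly.
    """

    method = "LASSO"

    def fit(self, alpha: float = 1e-3, tol: float = 1e-6, max_iter: int = 300_000
            ) -> CalibrationResults:
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        n, p = self.X.shape
        x_mean = self.X.mean(axis=0)
        x_sd = self.X.std(axis=0)
        x_sd = np.where(x_sd < 1e-12, 1.0, x_sd)
        Xs = (self.X - x_mean) / x_sd
        y_mean = float(self.y.mean())
        yc = self.y - y_mean

        beta, n_iter, max_delta = _cd_kernel(Xs, yc, alpha, float(tol), int(max_iter))
        if max_delta >= tol:
            raise LassoConvergenceError(max_iter, max_delta)

        coef = beta / x_sd
        intercept = y_mean - float(x_mean @ coef)
        return self._results(
            coef, intercept, {"alpha": alpha},
            scaling={"x_mean": x_mean, "x_sd": x_sd, "y_mean": np.array([y_mean])},
            extras={"n_iter": n_iter, "beta_standardized": beta},
        )

class RidgeRegression(_SpectralModel):
    """L2-penalised linear regression, closed form on centred data."""

    method = "RIDGE"

    def fit(self, alpha: float = 1e-3) -> CalibrationResults:
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        n, p = self.X.shape
        x_mean = self.X.mean(axis=0)
        y_mean = float(self.y.mean())
        Xc = self.X - x_mean
        yc = self.y - y_mean
        G = Xc.T @ Xc + alpha * np.eye(p)
        if alpha == 0 and np.linalg.matrix_rank(Xc) < p:
            raise np.linalg.LinAlgError(
                "X'X is singular at alpha=0 (rank-deficient design); "
                "use alpha > 0"
            )
        beta = np.linalg.solve(G, Xc.T @ yc)
        intercept = y_mean - float(x_mean @ beta)
        return self._results(
            beta, intercept, {"alpha": alpha},
            scaling={"x_mean": x_mean, "y_mean": np.array([y_mean])},
        )


# ---------------------------------------------------------------------------
# functional interface and hyperparameter searches


def fit_plsr(X, y, n_components: int = 10) -> CalibrationResults:
    return PLSRegression(X, y).fit(n_components=n_components)


def fit_lasso(X, y, alpha: float = 1e-3, **kw) -> CalibrationResults:
    return LassoRegression(X, y).fit(alpha=alpha, **kw)


def fit_ridge(X, y, alpha: float = 1e-3) -> CalibrationResults:
    return RidgeRegression(X, y).fit(alpha=alpha)


def predict(results: CalibrationResults, X) -> np.ndarray:
    return results.predict(X)


def _resolve_validation(validation, n: int) -> tuple[np.ndarray, np.ndarray]:
    """An internal train/validation split of the calibration set."""
    if isinstance(validation, SplitSpec):
        spec = validation
    else:
        spec = SplitSpec(seed=int(validation), n=n, train_fraction=0.8)
    if spec.n != n:
        raise ValueError("validation SplitSpec.n does not match sample count")
    train, val = random_split(spec)
    if val.size < 2:
        raise ValueError("validation split too small for a stable RMSE (<2 samples)")
    return train, val


def select_plsr_components(
    X, y, n_min: int = 2, n_max: int = 30, validation=0
) -> int:
    """Latent-variable count minimising validation RMSE over [n_min, n_max].

    One NIPALS run at the largest count supplies the whole coefficient
    path; ties pick the smaller count.
    """
    X, y = _validate_xy(X, y)
    tr, va = _resolve_validation(validation, X.shape[0])
    bound = min(tr.size - 1, X.shape[1])
    if n_min > n_max:
        raise ValueError("n_min must not exceed n_max")
    if n_min > bound:
        raise ValueError(f"n_min={n_min} exceeds the rank bound {bound}")
    hi = min(n_max, bound)
    Xtr, ytr = X[tr], y[tr]
    x_mean, y_mean = Xtr.mean(axis=0), float(ytr.mean())
    W, P, q, _ = _nipals_pls1(Xtr - x_mean, ytr - y_mean, hi)
    best_k, best_rmse = None, np.inf
    for k in range(n_min, hi + 1):
        kk = min(k, q.size)
        beta = _pls_coefficients(W, P, q, kk)
        pred = (X[va] - x_mean) @ beta + y_mean
        err = rmsep(y[va], pred)
        if err < best_rmse - 1e-12:
            best_k, best_rmse = k, err
    return int(best_k)


def lasso_alpha_grid(grid_lo: float = 1e-5, grid_hi: float = 1.0, n_grid: int = 50
                     ) -> np.ndarray:
    """Log-spaced candidate alphas including both endpoints exactly."""
    if not (0 < grid_lo < grid_hi):
        raise ValueError("require 0 < grid_lo < grid_hi")
    if n_grid < 1:
        raise ValueError("n_grid must be positive")
    if n_grid == 1:
        return np.array([grid_lo])
    return np.geomspace(grid_lo, grid_hi, n_grid)


def search_lasso_alpha(
    X, y, grid_lo: float = 1e-5, grid_hi: float = 1.0, n_grid: int = 50, validation=0,
    tol: float = 1e-6, max_iter: int = 10_000,
) -> float:
    """Alpha minimising validation RMSE over a log-spaced grid.

    Ties prefer the larger (sparser) alpha; the grid is traversed from the
    sparse end downward so the first minimiser found is the sparsest.
    """
    X, y = _validate_xy(X, y)
    tr, va = _resolve_validation(validation, X.shape[0])
    grid = lasso_alpha_grid(grid_lo, grid_hi, n_grid)
    model = LassoRegression(X[tr], y[tr])
    best_alpha, best_rmse = None, np.inf
    for alpha in grid[::-1]:  # large -> small, ties keep the first (larger) alpha
        try:
            res = model.fit(alpha=float(alpha), tol=tol, max_iter=max_iter)
        except LassoConvergenceError:
            continue
        err = rmsep(y[va], res.predict(X[va]))
        if err < best_rmse - 1e-12:
            best_alpha, best_rmse = float(alpha), err
    if best_alpha is None:
        raise LassoConvergenceError(max_iter, np.nan)
    return best_alpha
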