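"""Characteristic-wavelength selection.

The Successive Projections Algorithm (SPA) grows a chain of bands with
minimal collinearity: starting from one column, each step projects every
unselected column onto the orthogonal complement of the span of the
selected ones and appends the column with the largest projected norm.
Candidate chains (every start column, subset sizes 3-10 by default) are
scored by the validation RMSE of an ordinary multiple linear regression on
the selected bands; the winner is the (start, size) with the lowest RMSE.

Selections from the five pretreatments are then merged by single-linkage
clustering along the wavelength axis into consensus intervals, capped at
10 % of the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectraMatrix
from .evaluate import SplitSpec, random_split, rmsep

__all__ = [
    "SPAResult",
    "WavelengthInterval",
    "WavelengthIntervalSet",
    "spa_chain",
    "spa_select",
    "consensus_intervals",
]

_NORM_TOL = 1e-10


@dataclass
class SPAResult:
    """Outcome of an SPA subset-size search."""

    start_index: int
    chain: np.ndarray
    rmse_by_size: dict[int, float]
    chosen_size: int
    selected: np.ndarray
    wavelengths: np.ndarray | None = None

    @property
    def selected_wavelengths(self) -> np.ndarray:
        if self.wavelengths is None:
            raise ValueError("no wavelength grid attached")
        return self.wavelengths[np.sort(self.selected)]


@dataclass
class WavelengthInterval:
    low: float
    high: float
    members: np.ndarray
    sources: tuple[str, ...]


@dataclass
class WavelengthIntervalSet:
    """Disjoint, sorted consensus intervals with their member wavelengths."""

    intervals: list[WavelengthInterval] = field(default_factory=list)
    cap: int = 0

    @property
    def member_wavelengths(self) -> np.ndarray:
        if not self.intervals:
            return np.array([])
        return np.sort(np.concatenate([iv.members for iv in self.intervals]))

    @property
    def n_members(self) -> int:
        return int(sum(iv.members.size for iv in self.intervals))

    def covers(self, wavelength: float, tolerance: float = 0.0) -> bool:
        return any(
            iv.low - tolerance <= wavelength <= iv.high + tolerance
            for iv in self.intervals
        )

    def bounds(self) -> list[tuple[float, float]]:
        return [(iv.low, iv.high) for iv in self.intervals]


def _standardize(X: np.ndarray, center: bool, scale: bool) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd < 1e-12, 1.0, sd)
    return X


def spa_chain(
    X: np.ndarray, start_index: int, max_size: int, tol: float = _NORM_TOL
) -> np.ndarray:
    """The classic SPA projection chain from one start column.

    ``X`` should be column-centred (and typically unit-scaled) by the
    caller. The chain stops early when the largest projected norm falls
    below ``tol`` times the start column's norm.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not (0 <= start_index < p):
        raise IndexError(f"start_index {start_index} out of range [0, {p})")
    if max_size < 1:
        raise ValueError("max_size must be positive")
    max_size = min(max_size, n, p)

    R = X.copy()  # residuals after projecting out the selected span
    start_norm = np.linalg.norm(R[:, start_index])
    if start_norm < tol:
        raise ValueError(f"start column {start_index} has (near-)zero norm")
    chain = [start_index]
    selected = np.zeros(p, dtype=bool)
    selected[start_index] = True
    for _ in range(max_size - 1):
        u = R[:, chain[-1]].copy()
        R -= np.outer(u, u @ R) / (u @ u)
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < tol * start_norm:
            break
        chain.append(j)
        selected[j] = True
    return np.array(chain, dtype=int)


def _chains_all_starts(X: np.ndarray, starts: np.ndarray, max_size: int) -> np.ndarray:
    """SPA chains for many start columns at once (batched projections).

    Returns an (n_starts, max_size) index array; -1 marks an early stop.
    Matches :func:`spa_chain` column-for-column.
    """
    n, p = X.shape
    s = starts.size
    R = np.broadcast_to(X, (s, n, p)).copy()
    chains = np.full((s, max_size), -1, dtype=int)
    chains[:, 0] = starts
    selected = np.zeros((s, p), dtype=bool)
    selected[np.arange(s), starts] = True
    alive = np.ones(s, dtype=bool)
    start_norms = np.linalg.norm(X[:, starts], axis=0)
    last = starts.copy()
    for step in range(1, max_size):
        u = R[np.arange(s), :, last]                      # (s, n)
        uu = np.einsum("sn,sn->s", u, u)
        uu = np.where(uu < _NORM_TOL**2, 1.0, uu)
        coef = np.einsum("sn,snp->sp", u, R) / uu[:, None]
        R -= u[:, :, None] * coef[:, None, :]
        norms = np.sqrt(np.einsum("snp,snp->sp", R, R))
        norms[selected] = -1.0
        nxt = np.argmax(norms, axis=1)
        good = alive & (norms[np.arange(s), nxt] >= _NORM_TOL * start_norms)
        chains[good, step] = nxt[good]
        selected[good, nxt[good]] = True
        alive = good
        last = np.where(good, nxt, last)
        if not alive.any():
            break
    return chains


def _ols_val_rmse(Xtr, ytr, Xva, yva, cols) -> float:
    A = np.column_stack([np.ones(Xtr.shape[0]), Xtr[:, cols]])
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    pred = np.column_stack([np.ones(Xva.shape[0]), Xva[:, cols]]) @ coef
    return rmsep(yva, pred)


def spa_select(
    X,
    y,
    size_min: int = 3,
    size_max: int = 10,
    validation=0,
    wavelengths: np.ndarray | None = None,
    start_indices: np.ndarray | None = None,
    center: bool = True,
    scale: bool = False,
) -> SPAResult:
    """Full SPA search over start columns and subset sizes.

    Chains are grown on the column-centred calibration matrix (classic SPA
    geometry: variance-rich bands keep large projected norms; optional
    unit-variance scaling is available but makes every column's norm equal,
    which lets noise bands dominate the projections);
    each (start, size) candidate is scored by the RMSE of an
    intercept-included OLS fit on an internal seeded 80/20 split of the
    calibration set. Ties break to the smaller size, then the smaller
    start index. ``start_indices`` defaults to every column; pass a
    subsample for speed.
    """
    if isinstance(X, SpectraMatrix):
        wavelengths = X.wavelengths if wavelengths is None else wavelengths
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y length does not match X rows")
    if not (1 <= size_min <= size_max):
        raise ValueError("require 1 <= size_min <= size_max")
    size_max = min(size_max, n - 1, p)
    if size_min > size_max:
        raise ValueError(f"size_min {size_min} exceeds feasible maximum {size_max}")

    if isinstance(validation, SplitSpec):
        spec = validation
    else:
        spec = SplitSpec(seed=int(validation), n=n, train_fraction=0.8)
    tr, va = random_split(spec)
    if va.size < 2:
        raise ValueError("validation split too small for a stable RMSE (<2 samples)")

    Xs = _standardize(X, center, scale)
    if start_indices is None:
        starts = np.flatnonzero(np.linalg.norm(Xs, axis=0) >= _NORM_TOL)
    else:
        starts = np.asarray(start_indices, dtype=int)
    if starts.size == 0:
        raise ValueError("no usable start columns")

    chains = _chains_all_starts(Xs, starts, size_max)

    best = None  # (rmse, size, start_pos)
    rmse_curves: dict[int, dict[int, float]] = {}
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]
    for si in range(starts.size):
        chain = chains[si]
        valid_len = int(np.count_nonzero(chain >= 0))
        for size in range(size_min, size_max + 1):
            if size > valid_len:
                break
            err = _ols_val_rmse(Xtr, ytr, Xva, yva, chain[:size])
            rmse_curves.setdefault(si, {})[size] = err
            key = (err, size, si)
            if best is None or key < best:
                best = key

    if best is None:
        raise ValueError("no candidate subset reached the minimum size")
    err, size, si = best
    chain = chains[si][: int(np.count_nonzero(chains[si] >= 0))]
    return SPAResult(
        start_index=int(starts[si]),
        chain=chain.copy(),
        rmse_by_size=dict(sorted(rmse_curves[si].items())),
        chosen_size=int(size),
        selected=chain[:size].copy(),
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def consensus_intervals(
    selections: dict[str, np.ndarray],
    gap_tolerance: float = 15.0,
    cap: int | None = None,
    n_samples: int | None = None,
) -> WavelengthIntervalSet:
    """Merge per-pretreatment selections into capped consensus intervals.

    Pools all selected wavelengths, single-linkage clusters them along the
    nm axis (a new cluster starts where a gap exceeds ``gap_tolerance``),
    ranks clusters by the number of contributing pretreatments, then by
    pooled selection count, then by position, and retains unique
    wavelengths greedily in that order until ``cap`` (default
    floor(0.10 * n_samples)) is reached. Within a truncated cluster,
    wavelengths selected by more pretreatments are kept first.
    """
    if cap is None:
        if n_samples is None:
            raise ValueError("provide cap or n_samples")
        cap = int(np.floor(0.10 * n_samples))
    if cap < 1:
        raise ValueError("cap must be at least 1")

    pool: list[tuple[float, str]] = []
    for tag in sorted(selections):  # sorted: permutation invariance of the input dict
        for w in np.asarray(selections[tag], dtype=float).ravel():
            pool.append((float(w), tag))
    if not pool:
        raise ValueError("no selected wavelengths to merge")
    pool.sort()

    clusters: list[list[tuple[float, str]]] = [[pool[0]]]
    for item in pool[1:]:
        if item[0] - clusters[-1][-1][0] > gap_tolerance:
            clusters.append([])
        clusters[-1].append(item)

    def rank_key(cluster):
        sources = {tag for _, tag in cluster}
        return (-len(sources), -len(cluster), cluster[0][0])

    ranked = sorted(clusters, key=rank_key)

    retained: list[WavelengthInterval] = []
    budget = cap
    for cluster in ranked:
        if budget <= 0:
            break
        # unique wavelengths, most-supported first, then ascending nm
        support: dict[float, set[str]] = {}
        for w, tag in cluster:
            support.setdefault(w, set()).add(tag)
        uniq = sorted(support, key=lambda w: (-len(support[w]), w))
        keep = np.array(sorted(uniq[:budget]))
        budget -= keep.size
        retained.append(
            WavelengthInterval(
                low=float(keep.min()),
                high=float(keep.max()),
                members=keep,
                sources=tuple(sorted({t for w, t in cluster if w in set(keep)})),
            )
        )
    retained.sort(key=lambda iv: iv.low)
    return WavelengthIntervalSet(intervals=retained, cap=cap)
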