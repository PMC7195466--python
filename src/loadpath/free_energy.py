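"""MBAR and WHAM estimators turning biased window samples into a 2D PMF.

Because every umbrella window shares the same unbiased surface, the reduced
potentials entering MBAR are just the window biases u_k(x) = V_k(x)/kT; the
unbiased part cancels from the self-consistent equations

    exp(-f_k) = sum_n exp(-u_k(x_n)) / sum_j N_j exp(f_j - u_j(x_n)).

The solver minimizes the standard convex MBAR objective (L-BFGS on the
gauge-fixed free energies, f_0 = 0), then polishes with self-consistent
iteration and reports the final residual.  Unbiased per-sample weights are
w_n proportional to 1 / sum_k N_k exp(f_k - u_k(x_n)), normalized to 1.

A binned WHAM solver is provided as an independent oracle for the same
landscape, and ``pmf_2d`` turns weights into the gridded free-energy surface
F(cell) = -kT ln sum_{n in cell} w_n, shifted so the occupied minimum is 0.
Unoccupied cells are flagged (NaN) and never interpolated silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .reus import UmbrellaWindow, WindowSamples

__all__ = [
    "GridSpec",
    "MBARResult",
    "PMFGrid",
    "mbar_solve",
    "wham_solve",
    "pmf_2d",
    "pmf_offset",
    "grid_from_potential",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform 2D grid: cell (i, j) spans origin + [i, i+1) x [j, j+1) * spacing."""

    origin: tuple[float, float]
    spacing: tuple[float, float]
    shape: tuple[int, int]

    @classmethod
    def from_samples(
        cls, x: np.ndarray, shape: tuple[int, int] = (60, 60), padding: float = 0.05
    ) -> "GridSpec":
        """Bounding box of the samples plus fractional padding per side."""
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        span = np.maximum(hi - lo, 1e-9)
        lo = lo - padding * span
        hi = hi + padding * span
        spacing = (hi - lo) / np.asarray(shape, dtype=float)
        return cls(
            origin=(float(lo[0]), float(lo[1])),
            spacing=(float(spacing[0]), float(spacing[1])),
            shape=(int(shape[0]), int(shape[1])),
        )

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin
        dx, dy = self.spacing
        nx, ny = self.shape
        return (
            ox + dx * (np.arange(nx) + 0.5),
            oy + dy * (np.arange(ny) + 0.5),
        )

    def cell_of(self, point) -> tuple[int, int]:
        p = np.asarray(point, dtype=float)
        i = int(np.floor((p[0] - self.origin[0]) / self.spacing[0]))
        j = int(np.floor((p[1] - self.origin[1]) / self.spacing[1]))
        if not (0 <= i < self.shape[0] and 0 <= j < self.shape[1]):
            raise ValueError(f"point {p.tolist()} lies outside the grid")
        return i, j

    def cells_of(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized cell indices plus an in-bounds mask."""
        p = np.asarray(x, dtype=float)
        i = np.floor((p[:, 0] - self.origin[0]) / self.spacing[0]).astype(int)
        j = np.floor((p[:, 1] - self.origin[1]) / self.spacing[1]).astype(int)
        ok = (i >= 0) & (i < self.shape[0]) & (j >= 0) & (j < self.shape[1])
        return i, j, ok


@dataclass
class MBARResult:
    """Per-window reduced free energies and normalized unbiased weights."""

    f_k: np.ndarray  # gauge f_0 = 0
    weights: np.ndarray  # per sample, sum to 1
    n_iterations: int
    final_residual: float
    converged: bool
    kT: float
    metadata: dict[str, Any] = field(default_factory=dict)


@dataclass
class PMFGrid:
    """Gridded free-energy surface, min over occupied cells shifted to 0."""

    grid: GridSpec
    values: np.ndarray  # (nx, ny), NaN on unoccupied cells
    counts: np.ndarray  # (nx, ny) occupancy
    kT: float
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def value_at(self, point) -> float:
        i, j = self.grid.cell_of(point)
        v = self.values[i, j]
        if not np.isfinite(v):
            raise ValueError(f"cell {(i, j)} at {point} is unoccupied")
        return float(v)

    def local_min_value(self, point, radius: int = 1) -> float:
        """Minimum over the (2r+1)x(2r+1) occupied neighborhood of the cell."""
        i, j = self.grid.cell_of(point)
        nx, ny = self.grid.shape
        block = self.values[
            max(i - radius, 0) : min(i + radius + 1, nx),
            max(j - radius, 0) : min(j + radius + 1, ny),
        ]
        finite = block[np.isfinite(block)]
        if finite.size == 0:
            raise ValueError(f"no occupied cell near {point}")
        return float(finite.min())


def _reduced_bias_matrix(
    x: np.ndarray, windows: list[UmbrellaWindow], kT: float
) -> np.ndarray:
    """u[k, n] = V_k(x_n) / kT."""
    u = np.empty((len(windows), x.shape[0]))
    for k, w in enumerate(windows):
        u[k] = w.energy(x) / kT
    return u


def mbar_solve(
    samples: WindowSamples,
    windows: list[UmbrellaWindow],
    kT: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> MBARResult:
    """Solve the MBAR equations for the window free energies and weights.

    Raises if any window contributed no samples, or if the self-consistency
    residual cannot be brought below ``tol``.
    """
    kT = samples.kT if kT is None else float(kT)
    counts = samples.counts()
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0]
        raise ValueError(f"windows with no samples: {empty.tolist()}")
    x, _ = samples.stacked()
    u = _reduced_bias_matrix(x, windows, kT)
    n_k = counts.astype(float)
    log_n = np.log(n_k)
    n_total = x.shape[0]

    def objective(f_free: np.ndarray):
        f = np.concatenate([[0.0], f_free])
        a = log_n[:, None] + f[:, None] - u  # (K, N)
        log_denom = logsumexp(a, axis=0)
        val = log_denom.sum() - float(n_k @ f)
        w = np.exp(a - log_denom)  # (K, N)
        grad = w.sum(axis=1) - n_k
        return val / n_total, grad[1:] / n_total

    if len(windows) > 1:
        res = minimize(
            objective,
            np.zeros(len(windows) - 1),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        f = np.concatenate([[0.0], res.x])
        it = int(res.nit)
    else:
        f = np.zeros(1)
        it = 0

    # polish with self-consistent iteration and measure the residual
    residual = np.inf
    for _ in range(200):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        f_new = f_new - f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        it += 1
        if residual < tol:
            break
    if residual >= tol:
        raise RuntimeError(
            f"MBAR failed to converge: residual {residual:.3e} after {it} iterations"
        )
    log_denom = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
    log_w = -log_denom
    log_w = log_w - logsumexp(log_w)
    weights = np.exp(log_w)
    return MBARResult(
        f_k=f,
        weights=weights,
        n_iterations=it,
        final_residual=residual,
        converged=True,
        kT=kT,
        metadata={"n_samples": int(n_total), "n_windows": len(windows)},
    )


def pmf_2d(
    samples_x: np.ndarray,
    weights: np.ndarray,
    grid: GridSpec | None = None,
    kT: float = 0.5961612,
    shape: tuple[int, int] = (60, 60),
) -> PMFGrid:
    """Weighted-histogram PMF: F(cell) = -kT ln sum_{n in cell} w_n, min = 0.

    ``weights`` need not be pre-normalized (the PMF is invariant to overall
    scale); all samples must fall inside the grid if one is given.
    """
    x = np.asarray(samples_x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != x.shape[0]:
        raise ValueError("one weight per sample is required")
    w = w / w.sum()
    if grid is None:
        grid = GridSpec.from_samples(x, shape=shape)
    i, j, ok = grid.cells_of(x)
    if not np.all(ok):
        if not np.any(ok):
            raise ValueError("all samples fall outside the grid")
        x, w, i, j = x[ok], w[ok], i[ok], j[ok]
        w = w / w.sum()
    nx, ny = grid.shape
    flat = i * ny + j
    wsum = np.bincount(flat, weights=w, minlength=nx * ny).reshape(nx, ny)
    counts = np.bincount(flat, minlength=nx * ny).reshape(nx, ny)
    with np.errstate(divide="ignore"):
        values = -kT * np.log(wsum)
    values[counts == 0] = np.nan
    values = values - np.nanmin(values)
    return PMFGrid(grid=grid, values=values, counts=counts, kT=kT)


def wham_solve(
    samples: WindowSamples,
    windows: list[UmbrellaWindow],
    grid: GridSpec,
    kT: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> PMFGrid:
    """Binned WHAM iterated to self-consistency (independent PMF oracle).

    Histogram counts are pooled over windows; bias factors are evaluated at
    cell centers.  Empty bins stay flagged (NaN).  Raises on non-convergence
    or if any sample falls outside the bin grid.
    """
    kT = samples.kT if kT is None else float(kT)
    x, _ = samples.stacked()
    i, j, ok = grid.cells_of(x)
    if not np.all(ok):
        raise ValueError("bin grid does not cover all samples")
    nx, ny = grid.shape
    flat = i * ny + j
    hist = np.bincount(flat, minlength=nx * ny).astype(float)
    occupied = hist > 0
    cx, cy = grid.centers()
    mesh = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    n_k = samples.counts().astype(float)
    log_c = np.stack([-w.energy(mesh) / kT for w in windows])  # (K, M)
    log_c = log_c[:, occupied]
    log_hist = np.log(hist[occupied])
    log_nk = np.log(n_k)
    log_f = np.zeros(len(windows))  # log of window normalization 1/Z_k
    log_p = None
    for it in range(max_iter):
        denom = logsumexp(log_nk[:, None] + log_f[:, None] + log_c, axis=0)
        log_p = log_hist - denom
        log_p = log_p - logsumexp(log_p)
        log_f_new = -logsumexp(log_c + log_p[None, :], axis=1)
        delta = float(np.max(np.abs(log_f_new - log_f)))
        log_f = log_f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"WHAM failed to converge within {max_iter} iterations")
    values = np.full(nx * ny, np.nan)
    values[occupied] = -kT * log_p
    values = values - np.nanmin(values)
    return PMFGrid(
        grid=grid,
        values=values.reshape(nx, ny),
        counts=hist.reshape(nx, ny).astype(int),
        kT=kT,
        metadata={"estimator": "wham", "iterations": it + 1},
    )


def pmf_offset(pmf: PMFGrid, point_a, point_b, neighborhood: int = 1) -> float:
    """F(b) - F(a) read as local-minimum cell values (3x3 neighborhood min).

    The neighborhood minimum suppresses single-cell binning noise at the
    basin bottoms; ``neighborhood=0`` reads the exact cells.
    """
    fa = pmf.local_min_value(point_a, radius=neighborhood)
    fb = pmf.local_min_value(point_b, radius=neighborhood)
    return fb - fa


def smooth_pmf(pmf: PMFGrid, radius: int = 1) -> PMFGrid:
    """Occupied-neighborhood box average of a sampled PMF.

    Each occupied cell is replaced by the mean of the occupied cells in its
    (2r+1)x(2r+1) neighborhood; unoccupied cells stay flagged.  This is a
    noise-reduction convention for path and barrier extraction on sampled
    grids (single-cell noise otherwise biases a path's running maximum
    upward); the systematic shift is of order Laplacian * spacing^2 / 3,
    negligible at default resolution.  The result is re-gauged to min 0.
    """
    occ = pmf.occupied.astype(float)
    vals = np.where(pmf.occupied, pmf.values, 0.0)
    nx, ny = pmf.grid.shape
    num = np.zeros_like(vals)
    den = np.zeros_like(vals)
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            sl_src = (
                slice(max(di, 0), nx + min(di, 0)),
                slice(max(dj, 0), ny + min(dj, 0)),
            )
            sl_dst = (
                slice(max(-di, 0), nx + min(-di, 0)),
                slice(max(-dj, 0), ny + min(-dj, 0)),
            )
            num[sl_dst] += vals[sl_src]
            den[sl_dst] += occ[sl_src]
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den
    smoothed[~pmf.occupied] = np.nan
    smoothed = smoothed - np.nanmin(smoothed)
    return PMFGrid(
        grid=pmf.grid,
        values=smoothed,
        counts=pmf.counts.copy(),
        kT=pmf.kT,
        metadata={**pmf.metadata, "smoothed_radius": radius},
    )


def grid_from_potential(
    potential, grid: GridSpec, kT: float = 0.5961612
) -> PMFGrid:
    """Evaluate an analytic potential on cell centers as a fully occupied PMF.

    Useful for deterministic path/barrier extraction directly on a fixture
    landscape: values are shifted so the grid minimum is zero and every cell
    counts as occupied.
    """
    cx, cy = grid.centers()
    mesh = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1)
    values = np.asarray(potential.energy_at(mesh), dtype=float)
    values = values - values.min()
    return PMFGrid(
        grid=grid,
        values=values,
        counts=np.ones(grid.shape, dtype=int),
        kT=kT,
        metadata={"source": "analytic", "potential": potential.metadata},
    )
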