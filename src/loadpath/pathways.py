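"""Minima, minimum-free-energy paths, and barrier extraction on a gridded PMF.

Minima are occupied cells strictly below all occupied 8-neighbours, filtered
by topographic prominence (the minimax saddle to any deeper minimum minus
the candidate's own value) so that single-cell sampling noise does not
register as a basin.  The MFEP is extracted with a zero-temperature string:
a discretized curve relaxed down the normal component of the interpolated
gradient with endpoints pinned at the minima and equal-arc reparameterization
at every step.  The independent oracle is an exact widest-path (minimax)
search over the 8-connected occupied grid: the minimum over connecting paths
of the maximum cell value, which lower-bounds any continuous path's peak up
to grid resolution.

The barrier convention: peak = maximum free energy along the path in the
global-minimum gauge; baseline = value at the interfacial reference minimum;
barrier = peak - baseline.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .free_energy import GridSpec, PMFGrid

__all__ = [
    "Minimum",
    "Path",
    "BarrierReport",
    "find_minima",
    "minimax_barrier",
    "mfep_on_grid",
    "barrier_from_path",
    "resample_transition_ensemble",
]


@dataclass(frozen=True)
class Minimum:
    """A detected local minimum: its cell, CV-space location, and value."""

    cell: tuple[int, int]
    point: tuple[float, float]
    value: float


@dataclass
class Path:
    """Ordered CV-space points of one extracted pathway with their energies."""

    points: np.ndarray  # (m, 2)
    energies: np.ndarray  # (m,)
    branch: str
    endpoints: tuple[Minimum, Minimum]
    converged: bool = True
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def peak(self) -> float:
        return float(np.max(self.energies))


@dataclass(frozen=True)
class BarrierReport:
    """peak - baseline barrier bookkeeping for one branch."""

    peak: float
    baseline: float
    barrier: float
    branch: str

    def __post_init__(self) -> None:
        if abs(self.barrier - (self.peak - self.baseline)) > 0.0:
            raise ValueError("barrier must equal peak - baseline exactly")


def _neighbors8(i: int, j: int, nx: int, ny: int):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny:
                yield a, b


def _minimax_value(
    pmf: PMFGrid, start: tuple[int, int], end: tuple[int, int]
) -> float:
    """Exact widest-path cost: min over paths of the max cell value."""
    occ = pmf.occupied
    nx, ny = pmf.grid.shape
    if not occ[start] or not occ[end]:
        raise ValueError("start and end cells must be occupied")
    vals = pmf.values
    best = np.full((nx, ny), np.inf)
    best[start] = vals[start]
    # heap entries (cost, i, j): lexicographic cell order breaks ties
    heap = [(float(vals[start]), start[0], start[1])]
    while heap:
        cost, i, j = heapq.heappop(heap)
        if cost > best[i, j]:
            continue
        if (i, j) == tuple(end):
            return cost
        for a, b in _neighbors8(i, j, nx, ny):
            if not occ[a, b]:
                continue
            new_cost = max(cost, float(vals[a, b]))
            if new_cost < best[a, b]:
                best[a, b] = new_cost
                heapq.heappush(heap, (new_cost, a, b))
    raise ValueError(
        f"cells {tuple(start)} and {tuple(end)} are disconnected in the occupied region"
    )


def minimax_barrier(pmf: PMFGrid, start_min, end_min) -> float:
    """Widest-path saddle height between two minima, exact on the grid.

    Accepts :class:`Minimum` objects or (i, j) cells; returns the minimax
    peak value in the PMF's global-minimum gauge (kcal/mol).
    """
    start = start_min.cell if isinstance(start_min, Minimum) else tuple(start_min)
    end = end_min.cell if isinstance(end_min, Minimum) else tuple(end_min)
    return _minimax_value(pmf, start, end)


def find_minima(
    pmf: PMFGrid, prominence: float = 0.5, min_count: int = 5
) -> list[Minimum]:
    """Local minima of the occupied grid, filtered by topographic prominence.

    A candidate is an occupied cell with no strictly lower occupied
    8-neighbour; exact-tie plateaus (which arise on symmetric analytic
    grids) are merged into one candidate, represented by their
    lexicographically first cell, and count as a minimum only if every cell
    bordering the plateau is strictly higher — so a globally flat surface
    has no minima.  Candidates are then filtered two ways: cells holding
    fewer than ``min_count`` samples are not eligible (a basin bottom is,
    by construction, among the best-sampled cells, while stray outskirt
    cells carry huge noise; analytic grids with uniform counts are
    unaffected), and a candidate is kept only if the minimax saddle
    separating it from any deeper minimum lies at least ``prominence``
    (kcal/mol) above its own value.  The deepest minimum is always kept.
    Returns minima sorted by value (may be empty on flat or monotone
    surfaces).
    """
    occ = pmf.occupied
    vals = pmf.values
    nx, ny = pmf.grid.shape
    cx, cy = pmf.grid.centers()
    count_floor = min(min_count, int(pmf.counts[occ].max()))
    # cells with no strictly lower occupied neighbour
    cand = np.zeros((nx, ny), dtype=bool)
    for i in range(nx):
        for j in range(ny):
            if not occ[i, j] or pmf.counts[i, j] < count_floor:
                continue
            v = vals[i, j]
            cand[i, j] = all(
                not occ[a, b] or vals[a, b] >= v
                for a, b in _neighbors8(i, j, nx, ny)
            )
    # merge equal-valued adjacent candidates into plateaus
    seen = np.zeros((nx, ny), dtype=bool)
    candidates: list[Minimum] = []
    for i in range(nx):
        for j in range(ny):
            if not cand[i, j] or seen[i, j]:
                continue
            v = vals[i, j]
            plateau = [(i, j)]
            seen[i, j] = True
            stack = [(i, j)]
            while stack:
                ci, cj = stack.pop()
                for a, b in _neighbors8(ci, cj, nx, ny):
                    if cand[a, b] and not seen[a, b] and vals[a, b] == v:
                        seen[a, b] = True
                        plateau.append((a, b))
                        stack.append((a, b))
            # every occupied cell bordering the plateau must be strictly higher
            border_ok = False
            is_min = True
            pset = set(plateau)
            for ci, cj in plateau:
                for a, b in _neighbors8(ci, cj, nx, ny):
                    if (a, b) in pset or not occ[a, b]:
                        continue
                    if vals[a, b] > v:
                        border_ok = True
                    else:
                        is_min = False
            if is_min and border_ok:
                ci, cj = min(plateau)
                candidates.append(
                    Minimum(
                        cell=(ci, cj),
                        point=(float(cx[ci]), float(cy[cj])),
                        value=float(v),
                    )
                )
    candidates.sort(key=lambda m: m.value)
    if not candidates:
        return []
    kept = [candidates[0]]
    for cand in candidates[1:]:
        try:
            saddle = min(_minimax_value(pmf, cand.cell, k.cell) for k in kept)
        except ValueError:
            # isolated occupied islet disconnected from every deeper basin:
            # sampling debris, not a basin of the landscape
            continue
        if saddle - cand.value >= prominence:
            kept.append(cand)
    kept.sort(key=lambda m: m.value)
    return kept


def _filled_interpolators(pmf: PMFGrid, penalty: float = 2.0):
    """Bilinear interpolators of F and grad F with unoccupied cells filled.

    Unoccupied cells are set to (max occupied value + penalty) so the string
    relaxes away from them; the fill is for evolution only — final paths are
    checked against true occupancy.
    """
    vals = pmf.values.copy()
    fill = np.nanmax(vals) + penalty
    vals[~pmf.occupied] = fill
    cx, cy = pmf.grid.centers()
    gx, gy = np.gradient(vals, cx, cy, edge_order=1)
    f = RegularGridInterpolator((cx, cy), vals, bounds_error=False, fill_value=fill)
    fgx = RegularGridInterpolator((cx, cy), gx, bounds_error=False, fill_value=0.0)
    fgy = RegularGridInterpolator((cx, cy), gy, bounds_error=False, fill_value=0.0)
    return f, fgx, fgy


def _respace(points: np.ndarray) -> np.ndarray:
    chords = np.sqrt(np.sum(np.diff(points, axis=0) ** 2, axis=-1))
    s = np.concatenate([[0.0], np.cumsum(chords)])
    if s[-1] == 0.0:
        return points
    targets = np.linspace(0.0, s[-1], points.shape[0])
    return np.stack(
        [np.interp(targets, s, points[:, k]) for k in range(points.shape[1])], axis=-1
    )


def mfep_on_grid(
    pmf: PMFGrid,
    start_min: Minimum,
    end_min: Minimum,
    branch: str = "unconstrained",
    n_points: int = 65,
    max_iter: int = 3000,
    tol: float | None = None,
) -> Path:
    """Zero-temperature string MFEP between two detected minima.

    The curve starts as the straight segment (``branch="unconstrained"``) or
    as a semicircular arc bulging into the requested half-plane
    (``"upper"``/``"lower"``, relative to the oriented segment start->end:
    "upper" is the counterclockwise side, normal (-d_y, d_x)).  Points move down the
    normal component of the interpolated gradient with endpoints pinned and
    equal-arc reparameterization each step; branch-constrained paths are
    clamped to their half-plane.  Converged when the maximum per-step point
    displacement falls below ``tol`` (default 1e-3 of a cell).

    Raises if the final path leaves the occupied region, naming the first
    unoccupied cell.
    """
    if branch not in ("upper", "lower", "unconstrained"):
        raise ValueError(f"unknown branch {branch!r}")
    a = np.asarray(start_min.point, dtype=float)
    b = np.asarray(end_min.point, dtype=float)
    cell = float(min(pmf.grid.spacing))
    if tol is None:
        tol = 1e-3 * cell
    if np.allclose(a, b):
        e = pmf.value_at(a)
        return Path(
            points=a[None, :],
            energies=np.array([e]),
            branch=branch,
            endpoints=(start_min, end_min),
        )
    t_param = np.linspace(0.0, 1.0, n_points)
    if branch == "unconstrained":
        pts = a[None, :] + t_param[:, None] * (b - a)[None, :]
        normal = None
        mid = None
    else:
        d = b - a
        normal = np.array([-d[1], d[0]])
        normal = normal / np.linalg.norm(normal)
        if branch == "lower":
            normal = -normal
        mid = 0.5 * (a + b)
        u = a - mid
        ang = np.pi * t_param
        # rotate u by `ang` towards the branch side: arc a -> b through mid + n|u|
        side = np.stack([normal[0] * np.ones_like(ang), normal[1] * np.ones_like(ang)], -1)
        pts = (
            mid[None, :]
            + np.cos(ang)[:, None] * u[None, :]
            + np.sin(ang)[:, None] * np.linalg.norm(u) * side
        )
    f_itp, gx_itp, gy_itp = _filled_interpolators(pmf)
    step = 0.2 * cell
    converged = False
    for it in range(max_iter):
        grad = np.stack([gx_itp(pts), gy_itp(pts)], axis=-1)
        tang = np.zeros_like(pts)
        tang[1:-1] = pts[2:] - pts[:-2]
        tang[0] = pts[1] - pts[0]
        tang[-1] = pts[-1] - pts[-2]
        norm = np.maximum(np.sqrt(np.sum(tang**2, axis=-1, keepdims=True)), 1e-300)
        tang = tang / norm
        g_perp = grad - np.sum(grad * tang, axis=-1, keepdims=True) * tang
        g_norm = np.sqrt(np.sum(g_perp**2, axis=-1, keepdims=True))
        move = -step * g_perp / np.maximum(np.max(g_norm), 1e-300)
        new_pts = pts + move
        new_pts[0], new_pts[-1] = a, b
        if normal is not None:
            # clamp to the closed half-plane of the branch
            signed = np.sum((new_pts - mid[None, :]) * normal[None, :], axis=-1)
            out = signed < 0.0
            new_pts[out] = new_pts[out] - signed[out, None] * normal[None, :]
            new_pts[0], new_pts[-1] = a, b
        new_pts = _respace(new_pts)
        new_pts[0], new_pts[-1] = a, b
        disp = float(np.max(np.sqrt(np.sum((new_pts - pts) ** 2, axis=-1))))
        pts = new_pts
        if disp < tol:
            converged = True
            break
        if it == max_iter // 2:
            step *= 0.25
    energies = np.asarray(f_itp(pts), dtype=float)
    # verify the path stayed on sampled ground
    for p in pts:
        i, j = pmf.grid.cell_of(p)
        if not pmf.occupied[i, j]:
            raise ValueError(f"path escaped the occupied region at cell {(i, j)}")
    return Path(
        points=pts,
        energies=energies,
        branch=branch,
        endpoints=(start_min, end_min),
        converged=converged,
        metadata={"iterations": it + 1, "tol": tol},
    )


def barrier_from_path(path: Path, reference: Minimum | None = None) -> BarrierReport:
    """Barrier report for a path, measured from the interfacial reference.

    ``reference`` must be one of the path's endpoints (default: the higher
    endpoint, i.e. the interfacial minimum in the loading geometry).  The
    peak is the maximum energy along the path in the PMF's global-minimum
    gauge; barrier = peak - baseline.
    """
    if path.points.shape[0] == 0:
        raise ValueError("empty path")
    ends = path.endpoints
    if reference is None:
        reference = max(ends, key=lambda m: m.value)
    if all(ref_pt is not reference and not np.allclose(reference.point, ref_pt.point)
           for ref_pt in ends):
        raise ValueError("reference must be one of the path endpoints")
    # baseline read from the path's own end-point energy for consistency
    if np.allclose(reference.point, ends[0].point):
        baseline = float(path.energies[0])
    else:
        baseline = float(path.energies[-1])
    peak = path.peak
    return BarrierReport(
        peak=peak, baseline=baseline, barrier=peak - baseline, branch=path.branch
    )


def resample_transition_ensemble(
    samples_x: np.ndarray,
    weights: np.ndarray,
    grid: GridSpec,
    target_cell: tuple[int, int],
    n: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Weighted resampling with replacement from one grid cell.

    Returns the indices (into ``samples_x``) of ``n`` draws taken with
    probability proportional to the unbiased weights of the samples falling
    in ``target_cell``; seed-deterministic.  Raises if the cell is empty.
    """
    if seed is None:
        raise ValueError("a seed is required")
    x = np.asarray(samples_x, dtype=float)
    w = np.asarray(weights, dtype=float)
    i, j, ok = grid.cells_of(x)
    in_cell = ok & (i == target_cell[0]) & (j == target_cell[1])
    idx = np.nonzero(in_cell)[0]
    if idx.size == 0:
        raise ValueError(f"no samples in cell {tuple(target_cell)}")
    p = w[idx] / w[idx].sum()
    rng = np.random.default_rng(seed)
    return idx[rng.choice(idx.size, size=n, replace=True, p=p)]
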