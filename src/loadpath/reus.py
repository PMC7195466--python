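"""Cyclic guiding paths, the string method, and replica-exchange umbrella sampling.

The guiding path is a closed loop of (by default) 48 points in CV space;
points 0 and 24 are pinned to the interface and active-site minima and the
edge (47, 0) closes the ring.  The string method alternates sampling each
harmonically restrained window, moving each free guiding point to its
window's sample mean, smoothing, and reparameterizing to equal arc length
with the pinned points held exactly.  Production sampling then runs one
walker per window with Hamiltonian replica exchange between ring neighbours
(Metropolis-accepted configuration swaps in alternating even/odd edge
phases), which improves mixing without changing any window's target
distribution.

Umbrella restraints use the convention V_w(x) = k * |x - center|^2 (no
factor 1/2), with k in kcal/mol/A^2; the string phase default is k = 2.39
and the production phase default k = 0.48.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .dynamics import HarmonicBias
from .potentials import Potential
from .units import kt_at

__all__ = [
    "GuidingPath",
    "UmbrellaWindow",
    "WindowSamples",
    "ExchangeLog",
    "init_guiding_path",
    "build_windows",
    "replica_exchange_sweep",
    "run_reus",
    "string_optimize",
    "StringResult",
]


@dataclass
class GuidingPath:
    """Ordered guiding points with pinned indices and cyclic topology."""

    points: np.ndarray  # (n, d)
    cyclic: bool = True
    fixed_indices: frozenset[int] = frozenset({0, 24})
    iteration: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.fixed_indices = frozenset(int(i) for i in self.fixed_indices)
        n = self.n_points
        for i in self.fixed_indices:
            if not 0 <= i < n:
                raise ValueError(f"fixed index {i} out of range 0..{n - 1}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def neighbor_indices(self, i: int) -> tuple[int, int]:
        n = self.n_points
        if self.cyclic:
            return ((i - 1) % n, (i + 1) % n)
        return (max(i - 1, 0), min(i + 1, n - 1))

    def segment_lengths(self) -> np.ndarray:
        """Consecutive chord lengths, including the closing edge if cyclic."""
        pts = self.points
        diffs = np.diff(pts, axis=0)
        lengths = np.sqrt(np.sum(diffs**2, axis=-1))
        if self.cyclic:
            close = np.sqrt(np.sum((pts[0] - pts[-1]) ** 2))
            lengths = np.append(lengths, close)
        return lengths

    def reparameterize(self, max_iter: int = 60, rel_tol: float = 1e-12) -> "GuidingPath":
        """Equal-arc-length respacing with pinned points held exactly.

        The path is cut into segments between consecutive pinned indices
        (cyclically); within each segment points are respaced to uniform
        chord-based arc length, iterated to convergence so consecutive
        chord lengths agree to near machine precision.  Idempotent.
        """
        pts = self.points.copy()
        n = self.n_points
        fixed = sorted(self.fixed_indices)
        if self.cyclic:
            anchors = fixed if fixed else [0]
            segments = [
                (anchors[i], anchors[(i + 1) % len(anchors)])
                for i in range(len(anchors))
            ]
            if len(anchors) == 1:
                segments = [(anchors[0], anchors[0])]
        else:
            anchors = sorted(set(fixed) | {0, n - 1})
            segments = list(zip(anchors[:-1], anchors[1:]))

        def seg_indices(a: int, b: int) -> np.ndarray:
            if not self.cyclic or b > a:
                return np.arange(a, b + 1)
            return np.concatenate([np.arange(a, n), np.arange(0, b + 1)])

        for a, b in segments:
            idx = seg_indices(a, b) if a != b else np.concatenate(
                [np.arange(a, n), np.arange(0, a + 1)]
            )
            seg = pts[idx % n]
            for _ in range(max_iter):
                chords = np.sqrt(np.sum(np.diff(seg, axis=0) ** 2, axis=-1))
                total = chords.sum()
                if total == 0:
                    break
                spread = (chords.max() - chords.min()) / (total / chords.size)
                if spread < rel_tol:
                    break
                s = np.concatenate([[0.0], np.cumsum(chords)])
                targets = np.linspace(0.0, total, seg.shape[0])
                seg = np.stack(
                    [np.interp(targets, s, seg[:, k]) for k in range(seg.shape[1])],
                    axis=-1,
                )
            pts[idx % n] = seg
        # pinned points are interpolation endpoints and never move
        return GuidingPath(
            points=pts,
            cyclic=self.cyclic,
            fixed_indices=self.fixed_indices,
            iteration=self.iteration,
        )


def init_guiding_path(
    n: int = 48,
    radius: float = 2.0,
    center=(0.0, 0.0),
    active_index: int = 24,
    interface_index: int = 0,
    points: np.ndarray | None = None,
) -> GuidingPath:
    """Uniform cyclic guiding path on a circle (or from explicit points).

    Index ``active_index`` sits at angle 0 (the active-site minimum) and
    ``interface_index`` at angle pi (the interface minimum); both are pinned.
    The edge (n-1, 0) is part of the ring.
    """
    if n < 4:
        raise ValueError(f"need at least 4 guiding points, got {n}")
    if active_index == interface_index:
        raise ValueError("active and interface indices must differ")
    for idx in (active_index, interface_index):
        if not 0 <= idx < n:
            raise ValueError(f"fixed index {idx} out of range 0..{n - 1}")
    if points is not None:
        pts = np.asarray(points, dtype=float)
        if pts.shape[0] != n:
            raise ValueError("explicit points must match n")
    else:
        c = np.asarray(center, dtype=float)
        i = np.arange(n)
        # interface_index at angle pi, active_index at angle 0
        theta = np.pi + 2.0 * np.pi * ((i - interface_index) % n) / n
        pts = c + radius * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return GuidingPath(
        points=pts,
        cyclic=True,
        fixed_indices=frozenset({active_index, interface_index}),
    )


@dataclass(frozen=True)
class UmbrellaWindow:
    """Harmonic umbrella window V(x) = k |x - center|^2 on the ring."""

    index: int
    center: np.ndarray
    k: float
    neighbors: tuple[int, int]

    def bias(self) -> HarmonicBias:
        return HarmonicBias(self.center, self.k)

    def energy(self, x) -> np.ndarray:
        d = np.asarray(x, dtype=float) - self.center
        return self.k * np.sum(d * d, axis=-1)


def build_windows(
    path: GuidingPath,
    k: float = 0.48,
) -> list[UmbrellaWindow]:
    """One umbrella window per guiding point, ring topology copied from the path."""
    if k <= 0:
        raise ValueError(f"force constant must be positive, got {k}")
    return [
        UmbrellaWindow(
            index=i,
            center=path.points[i].copy(),
            k=float(k),
            neighbors=path.neighbor_indices(i),
        )
        for i in range(path.n_points)
    ]


@dataclass
class ExchangeLog:
    """Per-edge attempt/acceptance counts plus a per-sweep record."""

    n_edges: int
    attempts: np.ndarray = field(default=None)  # type: ignore[assignment]
    accepts: np.ndarray = field(default=None)  # type: ignore[assignment]
    records: list[tuple[int, int, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.attempts is None:
            self.attempts = np.zeros(self.n_edges, dtype=int)
        if self.accepts is None:
            self.accepts = np.zeros(self.n_edges, dtype=int)

    def acceptance_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)


@dataclass
class WindowSamples:
    """Per-window CV samples with replica provenance and the exchange log."""

    samples: list[np.ndarray]  # window -> (n_i, d)
    replica_ids: list[np.ndarray]  # window -> (n_i,)
    times: list[np.ndarray]
    exchange_log: ExchangeLog
    kT: float
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.samples)

    def counts(self) -> np.ndarray:
        return np.array([s.shape[0] for s in self.samples], dtype=int)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All samples stacked window-by-window, plus their window labels."""
        x = np.concatenate(self.samples, axis=0)
        labels = np.concatenate(
            [np.full(s.shape[0], i, dtype=int) for i, s in enumerate(self.samples)]
        )
        return x, labels


def replica_exchange_sweep(
    windows: list[UmbrellaWindow],
    states: np.ndarray,
    kT: float,
    rng: np.random.Generator,
    log: ExchangeLog | None = None,
    sweep_index: int = 0,
    replica_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, ExchangeLog]:
    """One full exchange sweep over the cyclic ring of windows.

    Neighbour pairs are attempted in an even phase (edges (0,1), (2,3), ...)
    then an odd phase ((1,2), (3,4), ..., including the closing edge), each
    swap accepted with Metropolis probability
    min(1, exp(-[V_i(x_j) + V_j(x_i) - V_i(x_i) - V_j(x_j)] / kT)).
    ``states`` holds the configuration currently owned by each window and is
    modified in place; ``replica_ids``, if given, is permuted alongside.
    """
    n = len(windows)
    if states.shape[0] != n:
        raise ValueError("one walker per window is required")
    if log is None:
        log = ExchangeLog(n_edges=n)
    for phase in (0, 1):
        for i in range(phase, n - (0 if n % 2 == 0 else 1), 2):
            j = (i + 1) % n
            if j == i:
                continue
            wi, wj = windows[i], windows[j]
            delta = (
                wi.energy(states[j])
                + wj.energy(states[i])
                - wi.energy(states[i])
                - wj.energy(states[j])
            ) / kT
            accepted = bool(delta <= 0.0 or rng.random() < np.exp(-delta))
            log.attempts[i] += 1
            if accepted:
                log.accepts[i] += 1
                states[[i, j]] = states[[j, i]]
                if replica_ids is not None:
                    replica_ids[[i, j]] = replica_ids[[j, i]]
            log.records.append((sweep_index, i, accepted))
    return states, log


def _integrate_block(
    potential: Potential,
    centers: np.ndarray,
    ks: np.ndarray,
    x: np.ndarray,
    n_steps: int,
    dt: float,
    friction: float,
    kT: float,
    rng: np.random.Generator,
    stride: int = 0,
    step_offset: int = 0,
) -> tuple[np.ndarray, list[np.ndarray], list[int]]:
    """Vectorized Euler-Maruyama for one walker per window; records every
    ``stride`` global steps (no recording if stride == 0)."""
    noise_scale = np.sqrt(2.0 * kT * dt / friction)
    recorded: list[np.ndarray] = []
    rec_steps: list[int] = []
    for s in range(1, n_steps + 1):
        grad = np.asarray(potential.gradient_at(x), dtype=float)
        grad = grad + 2.0 * ks[:, None] * (x - centers)
        x = x - grad * dt / friction
        if kT > 0:
            x = x + noise_scale * rng.standard_normal(x.shape)
        g_step = step_offset + s
        if stride and g_step % stride == 0:
            recorded.append(x.copy())
            rec_steps.append(g_step)
    return x, recorded, rec_steps


def run_reus(
    potential: Potential,
    windows: list[UmbrellaWindow],
    kT: float | None = None,
    dt: float = 1e-3,
    friction: float = 1.0,
    n_steps: int = 20000,
    stride: int = 10,
    exchange_interval: int = 100,
    equil_steps: int = 2000,
    seed: int | None = None,
) -> WindowSamples:
    """Replica-exchange umbrella sampling: one Langevin walker per window.

    Walkers start at their window centers, equilibrate without recording,
    then run production with samples recorded every ``stride`` steps and an
    exchange sweep every ``exchange_interval`` steps.  Every sample is
    attributed to the window that owned it when it was recorded; replica
    identities are tracked through swaps.
    """
    if seed is None:
        raise ValueError("a seed is required")
    kT = kt_at(300.0) if kT is None else float(kT)
    n = len(windows)
    centers = np.stack([w.center for w in windows])
    ks = np.array([w.k for w in windows])
    rng = np.random.default_rng(seed)
    x = centers.copy()
    replica_ids = np.arange(n)
    # equilibration
    x, _, _ = _integrate_block(
        potential, centers, ks, x, equil_steps, dt, friction, kT, rng
    )
    per_window: list[list[np.ndarray]] = [[] for _ in range(n)]
    per_window_rep: list[list[int]] = [[] for _ in range(n)]
    per_window_t: list[list[float]] = [[] for _ in range(n)]
    log = ExchangeLog(n_edges=n)
    done = 0
    sweep = 0
    while done < n_steps:
        block = min(exchange_interval, n_steps - done)
        x, recorded, rec_steps = _integrate_block(
            potential, centers, ks, x, block, dt, friction, kT, rng,
            stride=stride, step_offset=done,
        )
        for frame, g_step in zip(recorded, rec_steps):
            for w in range(n):
                per_window[w].append(frame[w])
                per_window_rep[w].append(int(replica_ids[w]))
                per_window_t[w].append(g_step * dt)
        done += block
        if done < n_steps:
            x, log = replica_exchange_sweep(
                windows, x, kT, rng, log, sweep_index=sweep, replica_ids=replica_ids
            )
            sweep += 1
    return WindowSamples(
        samples=[np.array(s) for s in per_window],
        replica_ids=[np.array(r, dtype=int) for r in per_window_rep],
        times=[np.array(t) for t in per_window_t],
        exchange_log=log,
        kT=kT,
        metadata={
            "seed": int(seed),
            "dt": dt,
            "friction": friction,
            "n_steps": n_steps,
            "stride": stride,
            "exchange_interval": exchange_interval,
            "equil_steps": equil_steps,
            "bias_convention": "V = k * |x - center|^2",
        },
    )


@dataclass
class StringResult:
    """Outcome of string-method optimization."""

    path: GuidingPath
    converged: bool
    rounds_used: int
    displacement_history: list[float]


def string_optimize(
    potential: Potential,
    path: GuidingPath,
    k_string: float = 2.39,
    rounds: int = 20,
    samples_per_round: int = 2000,
    equil_fraction: float = 0.25,
    smoothing: float = 0.1,
    tol: float | None = None,
    kT: float | None = None,
    dt: float = 1e-3,
    friction: float = 1.0,
    seed: int | None = None,
) -> StringResult:
    """Optimize the guiding path with the sampled-mean string method.

    Per round: each window (restrained at ``k_string``) is sampled with
    Langevin dynamics; every non-pinned point moves to its window's sample
    mean; smoothing  p_i <- (1-2*kappa) p_i + kappa (p_{i-1} + p_{i+1})
    is applied cyclically; the path is reparameterized to equal arc length
    with pinned points held.  Stops early when the maximum point displacement
    in a round falls below ``tol`` (default 1e-3 of the path scale); emits a
    warning and ``converged=False`` if the round budget runs out first.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not 0.0 <= smoothing < 0.5:
        raise ValueError("smoothing must satisfy 0 <= kappa < 0.5")
    kT = kt_at(300.0) if kT is None else float(kT)
    scale = float(
        np.mean(np.sqrt(np.sum((path.points - path.points.mean(axis=0)) ** 2, axis=-1)))
    )
    if tol is None:
        tol = 1e-3 * max(scale, 1.0)
    rng = np.random.default_rng(seed)
    current = path
    history: list[float] = []
    converged = False
    rounds_used = 0
    n_equil = int(samples_per_round * equil_fraction)
    free = np.array(
        [i not in current.fixed_indices for i in range(current.n_points)]
    )
    for _ in range(rounds):
        rounds_used += 1
        centers = current.points
        ks = np.full(current.n_points, k_string)
        x = centers.copy()
        x, _, _ = _integrate_block(
            potential, centers, ks, x, n_equil, dt, friction, kT, rng
        )
        x, recorded, _ = _integrate_block(
            potential, centers, ks, x, samples_per_round - n_equil,
            dt, friction, kT, rng, stride=1,
        )
        means = np.mean(np.stack(recorded), axis=0)
        new_pts = centers.copy()
        new_pts[free] = means[free]
        if smoothing > 0:
            up = np.roll(new_pts, -1, axis=0)
            down = np.roll(new_pts, 1, axis=0)
            smoothed = (1.0 - 2.0 * smoothing) * new_pts + smoothing * (up + down)
            smoothed[~free] = new_pts[~free]
            new_pts = smoothed
        trial = GuidingPath(
            points=new_pts,
            cyclic=current.cyclic,
            fixed_indices=current.fixed_indices,
            iteration=current.iteration + 1,
        ).reparameterize()
        disp = float(
            np.max(np.sqrt(np.sum((trial.points - current.points) ** 2, axis=-1)))
        )
        history.append(disp)
        current = trial
        if disp < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"string method did not converge in {rounds} rounds "
            f"(last displacement {history[-1]:.3g} vs tol {tol:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return StringResult(
        path=current,
        converged=converged,
        rounds_used=rounds_used,
        displacement_history=history,
    )
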