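"""Analytic potentials over low-dimensional collective-variable (CV) space.

The central object is the ring-shaped "loading landscape": a 2D surface with
two minima on a ring of radius R — an active-site minimum at angle 0 (energy
0 by gauge) and an interface minimum at angle pi (energy Delta) — separated by
two symmetric saddles of height H placed near +/- pi/2.  The functional form is

    F(x, y) = A*(rho - R)^2 + (Delta/2)*(1 - cos(theta))
              + c2*(1 - cos(2*theta))
              + h * [g(theta - pi/2) + g(theta + pi/2)]

with (rho, theta) polar coordinates and g a wrapped Gaussian bump of angular
width sigma.  The second harmonic (c2 = Delta/4 by default) gives the
interface point theta = pi positive angular curvature, making it a true
basin bottom with value exactly Delta above the active site (both minima
receive identical bump leakage, which cancels from the offset).  The bump
height h is calibrated by 1D root finding on the
angular profile so that the maximum along each branch sits exactly H above
the global minimum; a final constant shift puts the active-site minimum at
exactly zero.  The surface is mirror symmetric about the axis through the two
minima, so both branches carry identical barriers by construction.

Simple harmonic / flat / 1D double-well potentials are provided as oracle
substrates with closed-form partition-function ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Potential",
    "HarmonicPotential",
    "FlatPotential",
    "DoubleWell1D",
    "MimeticLandscapeSpec",
    "MimeticLandscape",
    "make_ga2ox_mimetic_landscape",
    "make_test_potential",
    "boltzmann_rejection_sample",
]


class Potential:
    """Analytic energy surface with an energy + gradient contract.

    Subclasses implement :meth:`energy_at` and :meth:`gradient_at`; both are
    vectorized over a trailing coordinate axis of length ``dimensionality``.
    Gradients must match central finite differences of the energy.
    """

    dimensionality: int
    name: str
    params: dict[str, Any]

    def energy_at(self, point: np.ndarray) -> np.ndarray | float:
        raise NotImplementedError

    def gradient_at(self, point: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def metadata(self) -> dict[str, Any]:
        return {"name": self.name, "params": dict(self.params)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(name={self.name!r}, d={self.dimensionality})"


class HarmonicPotential(Potential):
    """Isotropic harmonic well V(x) = (k/2) |x - center|^2."""

    def __init__(self, k: float = 1.0, center=(0.0, 0.0)):
        if k <= 0:
            raise ValueError(f"harmonic stiffness must be positive, got {k}")
        self.center = np.atleast_1d(np.asarray(center, dtype=float))
        self.k = float(k)
        self.dimensionality = self.center.size
        self.name = "harmonic"
        self.params = {"k": self.k, "center": self.center.tolist()}

    def energy_at(self, point):
        d = np.asarray(point, dtype=float) - self.center
        return 0.5 * self.k * np.sum(d * d, axis=-1)

    def gradient_at(self, point):
        d = np.asarray(point, dtype=float) - self.center
        return self.k * d


class FlatPotential(Potential):
    """Zero everywhere; useful for free-diffusion and exchange oracles."""

    def __init__(self, dimensionality: int = 2):
        self.dimensionality = int(dimensionality)
        self.name = "flat"
        self.params = {}

    def energy_at(self, point):
        p = np.asarray(point, dtype=float)
        return np.zeros(p.shape[:-1]) if p.ndim > 1 else 0.0

    def gradient_at(self, point):
        return np.zeros_like(np.asarray(point, dtype=float))


class DoubleWell1D(Potential):
    """1D double well with an exactly known well free-energy difference.

    V(x) = B * (x^2 - 1)^2 + dG * step(x), with step(x) = 0 for x < 0 and 1
    for x >= 0.  The quartic part is mirror symmetric, and the tilt is applied
    as a step exactly at the barrier top, so the partition functions of the
    two half-lines satisfy  Z(+)/Z(-) = exp(-dG/kT)  at *any* temperature:
    the restricted free-energy difference between the wells equals ``dG``
    exactly.  The energy is discontinuous (by dG) only at the barrier top
    x = 0; the gradient contract holds everywhere else.

    ``barrier`` is the height of the barrier top above the left (lower) well.
    """

    def __init__(self, delta_g: float = 1.0, barrier: float = 3.0):
        if barrier <= 0:
            raise ValueError(f"barrier must be positive, got {barrier}")
        if barrier <= delta_g:
            raise ValueError(
                f"barrier ({barrier}) must exceed the well offset ({delta_g})"
            )
        self.delta_g = float(delta_g)
        self.barrier = float(barrier)
        self.dimensionality = 1
        self.name = "double_well_1d"
        self.params = {"delta_g": self.delta_g, "barrier": self.barrier}

    def energy_at(self, point):
        x = np.asarray(point, dtype=float)[..., 0] if np.ndim(point) else float(point)
        x = np.asarray(x, dtype=float)
        quartic = self.barrier * (x * x - 1.0) ** 2
        return quartic + self.delta_g * (x >= 0.0)

    def gradient_at(self, point):
        p = np.asarray(point, dtype=float)
        x = p[..., 0]
        g = 4.0 * self.barrier * x * (x * x - 1.0)
        out = np.zeros_like(p)
        out[..., 0] = g
        return out


def _wrapped_gaussian(d: np.ndarray, sigma: float, n_images: int = 3) -> np.ndarray:
    """Periodic Gaussian bump sum_k exp(-(d - 2 pi k)^2 / (2 sigma^2))."""
    total = np.zeros_like(np.asarray(d, dtype=float))
    for k in range(-n_images, n_images + 1):
        dd = d - 2.0 * math.pi * k
        total = total + np.exp(-0.5 * (dd / sigma) ** 2)
    return total


def _wrapped_gaussian_dtheta(d: np.ndarray, sigma: float, n_images: int = 3) -> np.ndarray:
    total = np.zeros_like(np.asarray(d, dtype=float))
    for k in range(-n_images, n_images + 1):
        dd = d - 2.0 * math.pi * k
        total = total + (-dd / sigma**2) * np.exp(-0.5 * (dd / sigma) ** 2)
    return total


@dataclass
class MimeticLandscapeSpec:
    """Parameters of the two-minimum ring landscape.

    Attributes
    ----------
    ring_radius:
        Radius R of the low-energy ring, in length units (nominally A).
    radial_stiffness:
        A, the stiffness of the radial confinement, kcal/mol per length^2.
    minima_offset:
        Delta, interface-minus-active-site free-energy offset (kcal/mol).
    saddle_height:
        H, the height of each branch maximum above the global minimum.
    bump_width:
        Angular width sigma of the saddle bumps, radians.
    bump_height:
        Calibrated bump amplitude h; ``None`` triggers calibration.
    interface_curvature:
        c2, amplitude of the second angular harmonic (1 - cos 2*theta) that
        makes theta = pi a true basin bottom; ``None`` means Delta/4
        (any c2 > Delta/8 gives the interface positive curvature).
    bump_asymmetry:
        Optional relative height difference between the two bumps (the upper
        bump is scaled by 1 + a/2, the lower by 1 - a/2).  Zero keeps the two
        branches exactly symmetric.
    """

    ring_radius: float = 2.0
    radial_stiffness: float = 5.0
    minima_offset: float = 2.5
    saddle_height: float = 4.2
    bump_width: float = 0.35
    bump_height: float | None = None
    interface_curvature: float | None = None
    bump_asymmetry: float = 0.0

    @property
    def c2(self) -> float:
        return (
            self.minima_offset / 4.0
            if self.interface_curvature is None
            else self.interface_curvature
        )


class MimeticLandscape(Potential):
    """Calibrated two-minimum ring landscape (see module docstring)."""

    def __init__(self, spec: MimeticLandscapeSpec, bump_height: float, shift: float):
        self.spec = spec
        self.h = float(bump_height)
        self.shift = float(shift)
        self.dimensionality = 2
        self.name = "mimetic_landscape"
        self.params = {
            "ring_radius": spec.ring_radius,
            "radial_stiffness": spec.radial_stiffness,
            "minima_offset": spec.minima_offset,
            "saddle_height": spec.saddle_height,
            "bump_width": spec.bump_width,
            "interface_curvature": spec.c2,
            "bump_height": self.h,
            "bump_asymmetry": spec.bump_asymmetry,
            "shift": self.shift,
        }

    # -- angular profile on the ring (rho = R) -------------------------------
    def angular_profile(self, theta: np.ndarray) -> np.ndarray:
        s = self.spec
        up = self.h * (1.0 + 0.5 * s.bump_asymmetry)
        lo = self.h * (1.0 - 0.5 * s.bump_asymmetry)
        return (
            0.5 * s.minima_offset * (1.0 - np.cos(theta))
            + s.c2 * (1.0 - np.cos(2.0 * np.asarray(theta)))
            + up * _wrapped_gaussian(np.asarray(theta) - math.pi / 2, s.bump_width)
            + lo * _wrapped_gaussian(np.asarray(theta) + math.pi / 2, s.bump_width)
            + self.shift
        )

    def _dprofile_dtheta(self, theta: np.ndarray) -> np.ndarray:
        s = self.spec
        up = self.h * (1.0 + 0.5 * s.bump_asymmetry)
        lo = self.h * (1.0 - 0.5 * s.bump_asymmetry)
        return (
            0.5 * s.minima_offset * np.sin(theta)
            + 2.0 * s.c2 * np.sin(2.0 * np.asarray(theta))
            + up * _wrapped_gaussian_dtheta(np.asarray(theta) - math.pi / 2, s.bump_width)
            + lo * _wrapped_gaussian_dtheta(np.asarray(theta) + math.pi / 2, s.bump_width)
        )

    def energy_at(self, point):
        p = np.asarray(point, dtype=float)
        x, y = p[..., 0], p[..., 1]
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        s = self.spec
        return s.radial_stiffness * (rho - s.ring_radius) ** 2 + self.angular_profile(theta)

    def gradient_at(self, point):
        p = np.asarray(point, dtype=float)
        x, y = p[..., 0], p[..., 1]
        rho = np.maximum(np.hypot(x, y), 1e-12)
        theta = np.arctan2(y, x)
        s = self.spec
        dfdrho = 2.0 * s.radial_stiffness * (rho - s.ring_radius)
        dfdtheta = self._dprofile_dtheta(theta)
        gx = dfdrho * (x / rho) + dfdtheta * (-y / rho**2)
        gy = dfdrho * (y / rho) + dfdtheta * (x / rho**2)
        return np.stack([gx, gy], axis=-1)

    # -- landmark geometry ----------------------------------------------------
    @property
    def active_site_minimum(self) -> np.ndarray:
        """Location of the active-site minimum (theta = 0) on the ring."""
        return np.array([self.spec.ring_radius, 0.0])

    @property
    def interface_minimum(self) -> np.ndarray:
        """Location of the interface minimum (theta = pi) on the ring."""
        return np.array([-self.spec.ring_radius, 0.0])

    def saddle_angles(self) -> tuple[float, float]:
        """Angles of the two branch maxima, found by a dense 1D scan + polish."""
        theta = np.linspace(0.0, math.pi, 20001)
        prof = self.angular_profile(theta)
        t_up = float(theta[np.argmax(prof)])
        # lower branch by mirror symmetry when symmetric, by a scan otherwise
        theta_lo = np.linspace(-math.pi, 0.0, 20001)
        prof_lo = self.angular_profile(theta_lo)
        t_lo = float(theta_lo[np.argmax(prof_lo)])
        return t_up, t_lo


def _calibrate_bump_height(spec: MimeticLandscapeSpec) -> float:
    """Root-find h so max(angular profile) - min(angular profile) = H."""
    theta = np.linspace(-math.pi, math.pi, 40001)

    def range_minus_target(h: float) -> float:
        trial = MimeticLandscape(spec, bump_height=h, shift=0.0)
        prof = trial.angular_profile(theta)
        return float(prof.max() - prof.min()) - spec.saddle_height

    if spec.saddle_height < spec.minima_offset:
        raise ValueError(
            "infeasible landscape: saddle height "
            f"H={spec.saddle_height} is below the minima offset "
            f"Delta={spec.minima_offset}; no bump height can satisfy both"
        )
    lo = 0.0
    hi = max(1.0, 4.0 * spec.saddle_height)
    f_lo = range_minus_target(lo)
    if f_lo > 1e-9:
        raise ValueError(
            "infeasible landscape: even with no bump the angular range "
            f"exceeds the requested saddle height H={spec.saddle_height}"
        )
    f_hi = range_minus_target(hi)
    while f_hi < 0.0:  # pragma: no cover - defensive widening
        hi *= 2.0
        f_hi = range_minus_target(hi)
        if hi > 1e6:
            raise ValueError("bump-height calibration failed to bracket a root")
    if abs(f_lo) <= 1e-12:
        return 0.0
    return float(brentq(range_minus_target, lo, hi, xtol=1e-12, rtol=1e-14))


def make_ga2ox_mimetic_landscape(
    spec: MimeticLandscapeSpec | None = None,
) -> MimeticLandscape:
    """Build and calibrate the two-minimum ring landscape.

    With the defaults (R=2, A=5, Delta=2.5, H=4.2, sigma=0.35) the returned
    surface carries an active-site minimum at exactly 0, an interface minimum
    at 2.5 kcal/mol, and two symmetric branch maxima at 4.2 kcal/mol —
    the printed features of the substrate-loading landscape this fixture
    stands in for.
    """
    spec = spec or MimeticLandscapeSpec()
    h = spec.bump_height if spec.bump_height is not None else _calibrate_bump_height(spec)
    # final constant shift: active-site minimum -> exactly 0
    probe = MimeticLandscape(spec, bump_height=h, shift=0.0)
    theta = np.linspace(-math.pi, math.pi, 40001)
    prof_min = float(probe.angular_profile(theta).min())
    land = MimeticLandscape(spec, bump_height=h, shift=-prof_min)
    return land


def make_test_potential(kind: str, **params) -> Potential:
    """Factory for oracle substrate potentials.

    kind:
        ``"harmonic"`` (params ``k``, ``center``), ``"flat"`` (``dim``), or
        ``"double_well_1d"`` (``delta_g``, ``barrier``).
    """
    if kind == "harmonic":
        return HarmonicPotential(**params)
    if kind == "flat":
        return FlatPotential(params.get("dim", 2))
    if kind == "double_well_1d":
        return DoubleWell1D(**params)
    raise ValueError(f"unknown test-potential kind {kind!r}")


def boltzmann_rejection_sample(
    potential: Potential,
    bounds: tuple[np.ndarray, np.ndarray],
    kT: float,
    n_samples: int,
    seed: int,
    batch: int = 65536,
    max_batches: int = 20000,
) -> np.ndarray:
    """Exact samples from exp(-F/kT) on a box, by rejection from uniform.

    An independent sampling oracle: proposals are uniform on the box
    ``bounds = (lo, hi)`` and accepted with probability
    exp(-(F - F_min)/kT), where F_min is estimated on a coarse scan of the
    box.  Returns an (n_samples, d) array; deterministic for a given seed.
    """
    lo = np.atleast_1d(np.asarray(bounds[0], dtype=float))
    hi = np.atleast_1d(np.asarray(bounds[1], dtype=float))
    d = lo.size
    rng = np.random.default_rng(seed)
    # conservative lower bound for the energy on the box
    grid_1d = [np.linspace(lo[i], hi[i], 101) for i in range(d)]
    mesh = np.meshgrid(*grid_1d, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    e_min = float(np.min(potential.energy_at(pts)))
    out = np.empty((n_samples, d))
    filled = 0
    for _ in range(max_batches):
        proposal = rng.uniform(lo, hi, size=(batch, d))
        e = np.asarray(potential.energy_at(proposal), dtype=float)
        accept = rng.random(batch) < np.exp(-(e - e_min) / kT)
        take = proposal[accept]
        k = min(take.shape[0], n_samples - filled)
        out[filled : filled + k] = take[:k]
        filled += k
        if filled >= n_samples:
            return out
    raise RuntimeError(
        "rejection sampling failed to reach the requested sample count; "
        "acceptance rate too low on this box"
    )
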