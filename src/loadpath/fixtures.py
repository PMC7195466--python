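"""Synthetic rate tables and coordinate ensembles.

Two fixture families stand in for the measurements the package analyses:

* seeded Michaelis-Menten rate tables for monomer/multimer enzyme pairs,
  whose ground-truth parameters carry the printed fold-changes (a dimer with
  22-fold higher Vmax and 5-fold lower Km than its monomer; a tetramer with
  10-fold lower Km and 3.5-fold higher Vmax);
* coordinate ensembles with a localized "gate" stretch of sites whose
  fluctuation is amplified in the later half of the trajectory, emulating the
  destabilization of a gate loop as a ligand exits a binding site.

Ground-truth values always live in metadata, never in filenames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .ensembles import ResidueSelection, parse_residue_selection

__all__ = [
    "KineticsDataset",
    "CoordinateEnsemble",
    "make_kinetics_fixture",
    "make_gate_ensemble",
    "KINETICS_SCHEMES",
]


@dataclass
class KineticsDataset:
    """Substrate-rate table for one enzyme species.

    ``rates`` has shape (replicates, n_concentrations); concentrations are in
    molar and strictly increasing; rates are non-negative.
    """

    concentrations: np.ndarray  # molar, strictly increasing
    rates: np.ndarray  # (replicates, n_conc)
    species: str
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.concentrations.ndim != 1 or self.concentrations.size < 5:
            raise ValueError("need >= 5 distinct substrate concentrations")
        if np.any(self.concentrations <= 0) or np.any(
            np.diff(self.concentrations) <= 0
        ):
            raise ValueError("concentrations must be strictly positive and increasing")
        if self.rates.shape[1] != self.concentrations.size:
            raise ValueError("rates must have one column per concentration")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.rates.shape[0]

    def replicate_mean_rates(self) -> np.ndarray:
        return self.rates.mean(axis=0)


#: Ground-truth (Km [M], Vmax [arb. rate units]) per scheme and species.
KINETICS_SCHEMES: dict[str, dict[str, tuple[float, float]]] = {
    "dao_mimetic": {"monomer": (10e-6, 1.0), "dimer": (2e-6, 22.0)},
    "ga2ox_mimetic": {"monomer": (10e-6, 1.0), "tetramer": (1e-6, 3.5)},
}


def make_kinetics_fixture(
    scheme: str = "dao_mimetic",
    seed: int | None = None,
    n_conc: int = 8,
    replicates: int = 3,
    cv: float = 0.02,
    truth: dict[str, tuple[float, float]] | None = None,
    conc_range: tuple[float, float] = (0.5e-6, 100e-6),
) -> list[KineticsDataset]:
    """Generate seeded monomer/multimer Michaelis-Menten rate tables.

    Rates follow v = Vmax*S/(Km+S) times mean-one lognormal multiplicative
    noise with coefficient of variation ``cv``; concentrations are log-spaced
    over ``conc_range`` (default 0.5-100 uM).  ``scheme`` selects the
    ground-truth pair (see :data:`KINETICS_SCHEMES`) or ``"custom"`` with an
    explicit ``truth`` mapping ``species -> (Km, Vmax)``.
    """
    if seed is None:
        raise ValueError("a seed is required for the kinetics fixture")
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if scheme == "custom":
        if not truth:
            raise ValueError("scheme='custom' requires a truth mapping")
        scheme_truth = dict(truth)
    else:
        try:
            scheme_truth = dict(KINETICS_SCHEMES[scheme])
        except KeyError:
            raise ValueError(f"unknown kinetics scheme {scheme!r}") from None

    conc = np.geomspace(conc_range[0], conc_range[1], n_conc)
    rng = np.random.default_rng(seed)
    sigma_ln = float(np.sqrt(np.log1p(cv * cv)))
    datasets = []
    for species, (km, vmax) in scheme_truth.items():
        clean = vmax * conc / (km + conc)
        if cv > 0:
            noise = np.exp(
                -0.5 * sigma_ln**2
                + sigma_ln * rng.standard_normal((replicates, n_conc))
            )
        else:
            noise = np.ones((replicates, n_conc))
        datasets.append(
            KineticsDataset(
                concentrations=conc,
                rates=clean[None, :] * noise,
                species=species,
                metadata={
                    "scheme": scheme,
                    "truth_Km_M": km,
                    "truth_Vmax": vmax,
                    "cv": cv,
                    "seed": seed,
                },
            )
        )
    return datasets


@dataclass
class CoordinateEnsemble:
    """Time-ordered frames of site coordinates for one run.

    ``coords`` has shape (n_frames, n_sites, 3); site labels are 1-based
    residue-like indices; ``time_per_frame`` maps frame index to time.
    """

    coords: np.ndarray
    site_labels: np.ndarray
    time_per_frame: float
    run_index: int = 0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, sites, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.site_labels = np.asarray(self.site_labels, dtype=int)
        if self.site_labels.size != self.coords.shape[1]:
            raise ValueError("one site label per site is required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_per_frame


def _reference_layout(n_sites: int) -> np.ndarray:
    """Deterministic, non-degenerate helical layout of reference positions."""
    i = np.arange(n_sites, dtype=float)
    return np.stack(
        [10.0 * np.cos(0.3 * i), 10.0 * np.sin(0.3 * i), 0.5 * i], axis=-1
    )


def make_gate_ensemble(
    n_sites: int = 330,
    gate_range: str = "96-106",
    n_runs: int = 8,
    frames_per_window: int = 20,
    n_windows: int = 4,
    sigma_base: float = 0.5,
    gate_amplification: float = 3.0,
    seed: int | None = None,
    time_per_frame: float = 1.0,
) -> list[CoordinateEnsemble]:
    """Coordinate ensembles with a gate stretch destabilized in late windows.

    Every site jitters isotropically around a fixed reference position with
    per-axis standard deviation ``sigma_base``.  Sites inside ``gate_range``
    have their s.d. multiplied by ``gate_amplification`` during the later
    half of the ``n_windows`` analysis windows, emulating the loosening of
    the gate as the ligand leaves.  Per-axis jitter is iid Gaussian, so the
    closed-form per-site fluctuation is RMSF = sigma * sqrt(3).

    Run-to-run variation enters only through the seed; the reference layout
    is fixed.
    """
    if seed is None:
        raise ValueError("a seed is required for the gate ensemble")
    if gate_amplification < 1.0:
        raise ValueError("gate_amplification must be >= 1")
    selection: ResidueSelection = parse_residue_selection(gate_range)
    if selection.indices.min() < 1 or selection.indices.max() > n_sites:
        raise ValueError(
            f"gate_range {gate_range!r} falls outside sites 1..{n_sites}"
        )
    reference = _reference_layout(n_sites)
    gate_mask = np.zeros(n_sites, dtype=bool)
    gate_mask[selection.indices - 1] = True

    n_frames = frames_per_window * n_windows
    late_start = frames_per_window * (n_windows // 2)
    sigma = np.full((n_frames, n_sites), sigma_base)
    sigma[late_start:, gate_mask] *= gate_amplification

    root = np.random.SeedSequence(seed)
    ensembles = []
    for run, child in enumerate(root.spawn(n_runs)):
        rng = np.random.default_rng(child)
        jitter = rng.standard_normal((n_frames, n_sites, 3)) * sigma[..., None]
        ensembles.append(
            CoordinateEnsemble(
                coords=reference[None, :, :] + jitter,
                site_labels=np.arange(1, n_sites + 1),
                time_per_frame=time_per_frame,
                run_index=run,
                metadata={
                    "gate_range": selection.to_string(),
                    "sigma_base": sigma_base,
                    "gate_amplification": gate_amplification,
                    "frames_per_window": frames_per_window,
                    "n_windows": n_windows,
                    "late_window_start_frame": late_start,
                    "seed": seed,
                },
            )
        )
    return ensembles
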