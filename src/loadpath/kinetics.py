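"""Michaelis-Menten kinetics: Lineweaver-Burk fits and oligomer comparisons.

The primary fit is the double-reciprocal (Lineweaver-Burk) regression used
for the monomer-vs-multimer comparisons: ordinary least squares of 1/v on
1/S over replicate-mean rates, with slope = Km/Vmax and intercept = 1/Vmax.
A direct nonlinear least-squares fit of v = Vmax*S/(Km+S) is provided as a
cross-check.  Fold-changes are computed exactly from the two fits:
Km fold = Km(monomer)/Km(multimer), Vmax fold = Vmax(multimer)/Vmax(monomer).

The Hill dose-response and first-order activation time course are simple
phenomenological models of substrate-driven multimerization (they are
INVENTED plumbing, labelled as such in their metadata): a Hill function of
substrate concentration for the equilibrium multimer fraction, and an
exponential approach to it in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, stats

from .fixtures import KineticsDataset

__all__ = [
    "MMFit",
    "OligomerComparison",
    "michaelis_menten",
    "fit_lineweaver_burk",
    "fit_mm_nls",
    "compare_oligomers",
    "compare_rates",
    "multimer_dose_response",
    "activation_time_course",
    "effective_activity",
]


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters with provenance."""

    Km: float  # molar
    Vmax: float  # rate units
    se_Km: float
    se_Vmax: float
    method: str  # "LB" (Lineweaver-Burk on replicate means) or "NLS"
    species: str = ""
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.Km > 0 and self.Vmax > 0):
            raise ValueError("a successful fit requires Km > 0 and Vmax > 0")


@dataclass(frozen=True)
class OligomerComparison:
    """Fold-changes between a monomer fit and a multimer fit."""

    km_fold: float  # Km(monomer) / Km(multimer): > 1 means higher affinity
    vmax_fold: float  # Vmax(multimer) / Vmax(monomer): > 1 means faster
    monomer: str
    multimer: str


def michaelis_menten(s, km: float, vmax: float):
    """v = Vmax * S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_lineweaver_burk(dataset: KineticsDataset) -> MMFit:
    """Double-reciprocal fit on replicate-mean rates.

    Requires >= 3 distinct concentrations and strictly positive mean rates
    (the reciprocal transform must be defined); a non-positive fitted
    intercept (which would imply Vmax <= 0) raises.
    """
    s = dataset.concentrations
    if s.size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.any(dataset.rates <= 0):
        raise ValueError("all rates must be positive for LB fitting")
    v = dataset.replicate_mean_rates()
    inv_s = 1.0 / s
    inv_v = 1.0 / v
    res = stats.linregress(inv_s, inv_v)
    if res.intercept <= 0:
        raise ValueError(
            "Lineweaver-Burk intercept is non-positive; data are inconsistent "
            "with saturating Michaelis-Menten kinetics"
        )
    vmax = 1.0 / res.intercept
    km = res.slope / res.intercept
    # delta-method standard errors from the regression errors
    se_vmax = res.intercept_stderr / res.intercept**2
    se_km = km * float(
        np.hypot(res.stderr / res.slope, res.intercept_stderr / res.intercept)
    )
    return MMFit(
        Km=km,
        Vmax=vmax,
        se_Km=se_km,
        se_Vmax=se_vmax,
        method="LB",
        species=dataset.species,
        diagnostics={
            "r_squared": res.rvalue**2,
            "slope": res.slope,
            "intercept": res.intercept,
            "n_concentrations": int(s.size),
            "on_replicate_means": True,
        },
    )


def fit_mm_nls(dataset: KineticsDataset) -> MMFit:
    """Direct nonlinear least squares on v = Vmax*S/(Km+S) (cross-check fit).

    Initialized from the Lineweaver-Burk fit where possible; pools all
    replicate points.
    """
    s = np.tile(dataset.concentrations, dataset.n_replicates)
    v = dataset.rates.ravel()
    try:
        lb = fit_lineweaver_burk(dataset)
        p0 = (lb.Km, lb.Vmax)
    except ValueError:
        p0 = (float(np.median(dataset.concentrations)), float(v.max()) or 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            lambda ss, km, vmax: michaelis_menten(ss, km, vmax),
            s,
            v,
            p0=p0,
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"NLS Michaelis-Menten fit failed to converge: {exc}")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    resid = v - michaelis_menten(s, *popt)
    return MMFit(
        Km=float(popt[0]),
        Vmax=float(popt[1]),
        se_Km=float(perr[0]),
        se_Vmax=float(perr[1]),
        method="NLS",
        species=dataset.species,
        diagnostics={"rss": float(resid @ resid), "n_points": int(v.size)},
    )


def compare_oligomers(monomer: MMFit, multimer: MMFit) -> OligomerComparison:
    """Fold-changes computed exactly from the two fits."""
    return OligomerComparison(
        km_fold=monomer.Km / multimer.Km,
        vmax_fold=multimer.Vmax / monomer.Vmax,
        monomer=monomer.species or "monomer",
        multimer=multimer.species or "multimer",
    )


def compare_rates(rate_a: float, rate_b: float) -> float:
    """Simple rate ratio rate_a / rate_b (rate_b must be positive)."""
    if rate_b <= 0:
        raise ZeroDivisionError("reference rate must be positive")
    return float(rate_a) / float(rate_b)


def multimer_dose_response(s, k_half: float = 5e-6, n_hill: float = 1.5):
    """Equilibrium multimer fraction as a Hill function of substrate (INVENTED).

    f(S) = S^n / (K^n + S^n); monotone, f(0) = 0, f(K) = 1/2.  Defaults put
    the onset below 1e-6 M and saturation near 1e-4 M.
    """
    scalar = np.ndim(s) == 0
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = np.zeros_like(s_arr)
    pos = s_arr > 0
    sn = s_arr[pos] ** n_hill
    out[pos] = sn / (k_half**n_hill + sn)
    return float(out[0]) if scalar else out


def activation_time_course(t, tau: float = 6.0, m_inf: float = 1.0):
    """First-order approach of the multimer fraction to m_inf (INVENTED).

    m(t) = m_inf * (1 - exp(-t/tau)) with t and tau in hours; m(0) = 0,
    monotone, saturating.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = m_inf * (1.0 - np.exp(-t / tau))
    return out if out.ndim else float(out)


def effective_activity(
    s,
    monomer: MMFit,
    multimer: MMFit,
    k_half: float = 5e-6,
    n_hill: float = 1.5,
):
    """Population-level rate with a substrate-dependent multimer fraction.

    v_eff(S) = (1 - f(S)) v_mono(S) + f(S) v_multi(S) with
    f = :func:`multimer_dose_response`.
    """
    s = np.asarray(s, dtype=float)
    f = multimer_dose_response(s, k_half=k_half, n_hill=n_hill)
    return (1.0 - f) * michaelis_menten(s, monomer.Km, monomer.Vmax) + f * (
        michaelis_menten(s, multimer.Km, multimer.Vmax)
    )
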