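"""Thermodynamic constants and unit conversions.

The toy collective-variable space is nominally in angstroms and energies in
kcal/mol; the conversions here are exact and carry the constants used
throughout the package (Boltzmann constant in kcal/mol/K, the kcal/kJ
definition, nm/angstrom).
"""

from __future__ import annotations

import math

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_PER_MOL_K: float = 1.9872041e-3

#: Thermochemical calorie: 1 kcal = 4.184 kJ, exactly.
KJ_PER_KCAL: float = 4.184

#: 1 nm = 10 angstrom, so 1 nm^2 = 100 A^2.
A2_PER_NM2: float = 100.0

_ZERO_CELSIUS_K = 273.15


def thermal_energy(temperature: float, unit: str = "K") -> float:
    """Thermal energy k_B*T in kcal/mol.

    Parameters
    ----------
    temperature:
        Temperature value. The unit is never guessed: pass ``unit="K"`` for
        kelvin or ``unit="C"`` for degrees Celsius.
    unit:
        ``"K"`` (default) or ``"C"``.

    Returns
    -------
    float
        k_B * T in kcal/mol. At 25 C this is 0.593 kcal/mol, which rounds
        to the 0.6 kcal/mol thermal-fluctuation scale quoted for ambient
        conditions.

    Raises
    ------
    ValueError
        If the absolute temperature is not positive or the unit is unknown.
    """
    unit_norm = unit.strip().upper().replace("°", "")
    if unit_norm in ("K", "KELVIN"):
        t_kelvin = float(temperature)
    elif unit_norm in ("C", "CELSIUS"):
        t_kelvin = float(temperature) + _ZERO_CELSIUS_K
    else:
        raise ValueError(f"unknown temperature unit {unit!r}; use 'K' or 'C'")
    if not t_kelvin > 0.0:
        raise ValueError(f"absolute temperature must be > 0 K, got {t_kelvin} K")
    return KB_KCAL_PER_MOL_K * t_kelvin


# Canonical names for the two supported force-constant units and the spellings
# accepted for each.
_UNIT_ALIASES = {
    "kJ/mol/nm^2": {
        "kj/mol/nm^2", "kj/mol/nm2", "kj mol-1 nm-2", "kjoule/mol/nm^2",
    },
    "kcal/mol/A^2": {
        "kcal/mol/a^2", "kcal/mol/a2", "kcal/mol/ang^2", "kcal/mol/angstrom^2",
        "kcal mol-1 a-2",
    },
}


def _canonical_unit(unit: str) -> str:
    key = unit.strip().lower().replace("å", "a").replace("²", "^2").replace("Å", "a")
    for canonical, aliases in _UNIT_ALIASES.items():
        if key == canonical.lower() or key in aliases:
            return canonical
    raise ValueError(
        f"unknown force-constant unit {unit!r}; "
        f"supported: {sorted(_UNIT_ALIASES)}"
    )


def convert_force_constant(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a harmonic force constant between kJ/mol/nm^2 and kcal/mol/A^2.

    Exact conversion using 1 kcal = 4.184 kJ and 1 nm = 10 A, so
    1000 kJ/mol/nm^2 = 2.39 kcal/mol/A^2 and 200 kJ/mol/nm^2 = 0.48
    kcal/mol/A^2 (2 d.p.). Round-trips are the identity up to floating point.
    """
    src = _canonical_unit(from_unit)
    dst = _canonical_unit(to_unit)
    if src == dst:
        return float(value)
    factor = 1.0 / (KJ_PER_KCAL * A2_PER_NM2)  # kJ/mol/nm^2 -> kcal/mol/A^2
    if src == "kJ/mol/nm^2":
        return float(value) * factor
    return float(value) / factor


def kt_at(temperature_k: float = 300.0) -> float:
    """Shorthand for thermal energy at a kelvin temperature (default 300 K)."""
    return thermal_energy(temperature_k, "K")


def round_sig(x: float, sig: int) -> float:
    """Round to a number of significant digits (helper for report printing)."""
    if x == 0.0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
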