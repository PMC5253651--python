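"""Unit conventions and conversion helpers.

Canonical internal units throughout the package:

========================  =========================
quantity                  unit
========================  =========================
concentration             mol L⁻¹
time                      s
volume                    L
thermal power             μcal s⁻¹ (interface only)
heat                      cal
molar enthalpy / energy   kcal mol⁻¹
temperature               K
========================  =========================

μ-prefixed values are accepted at the interfaces (CSV headers, CLI flags)
and converted on read. Keeping a single internal convention eliminates
silent μ/m prefix mistakes when chaining heat → concentration → rate.
"""

from __future__ import annotations

#: Gas constant in kcal mol⁻¹ K⁻¹ (energies throughout are in kcal mol⁻¹).
R_KCAL = 1.98720e-3

#: calories per kilocalorie
CAL_PER_KCAL = 1000.0

#: microcalories per calorie
UCAL_PER_CAL = 1.0e6


def celsius_to_kelvin(temp_c: float) -> float:
    """Convert °C to K."""
    return temp_c + 273.15


def kelvin_to_celsius(temp_k: float) -> float:
    return temp_k - 273.15


def uM(x: float) -> float:
    """Micromolar → mol L⁻¹."""
    return x * 1e-6


def to_uM(x: float) -> float:
    """mol L⁻¹ → micromolar."""
    return x * 1e6


def uL(x: float) -> float:
    """Microlitre → L."""
    return x * 1e-6


def to_uL(x: float) -> float:
    return x * 1e6
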