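"""Closed-form rate laws and binding thermodynamics.

The central kinetic model is the steady-state Michaelis–Menten rate law
extended with competitive-type product inhibition,

    v = Vmax · [S] / ( Km · (1 + [P]/Kp) + [S] ),

which describes an enzyme whose product, by binding with affinity Kp,
diverts a fraction of the enzyme population into an inactive state. With
[P] = 0 (or Kp → ∞) it reduces to the plain Michaelis–Menten form. A
substrate-inhibition variant — the free-substrate term [S] replaced by
[S]·(1 + [S]/Ksi) in the denominator — is available for forward
simulation only; it reproduces the qualitative rate depression seen when
the homoallylic substrate is supplied in large excess, but no Ksi value
is ever fitted.

Binding thermodynamics follow the standard decomposition
ΔG = R·T·ln(Kd), TΔS = ΔH − ΔG (standard state 1 mol L⁻¹, energies in
kcal mol⁻¹).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .units import R_KCAL

__all__ = [
    "KineticParams",
    "BindingParams",
    "rate_product_inhibition",
    "michaelis_menten",
    "delta_g_from_kd",
    "tds_from",
]

_KCAT_RTOL = 1e-6  # consistency tolerance for kcat·[E] = Vmax


@dataclass(frozen=True)
class KineticParams:
    """Steady-state kinetic parameters of a single-substrate reduction.

    Parameters
    ----------
    vmax : float
        Maximal rate, mol L⁻¹ s⁻¹.
    km : float
        Michaelis constant of the limiting substrate, mol L⁻¹.
    kp : float
        Product affinity term, mol L⁻¹. ``math.inf`` disables product
        inhibition.
    dh_rxn : float, optional
        Molar reaction enthalpy, kcal mol⁻¹ (negative = exothermic).
    kcat : float, optional
        Turnover number, s⁻¹. When both ``kcat`` and ``enzyme`` are
        supplied, ``kcat·enzyme`` must equal ``vmax`` to 1 part in 10⁶.
    enzyme : float, optional
        Total enzyme concentration (monomers), mol L⁻¹.
    ksi : float, optional
        Substrate-inhibition constant, mol L⁻¹; ``None`` = no substrate
        inhibition. Simulation-only.
    """

    vmax: float
    km: float
    kp: float = math.inf
    dh_rxn: float | None = None
    kcat: float | None = None
    enzyme: float | None = None
    ksi: float | None = None

    def __post_init__(self):
        if self.vmax < 0:
            raise InvalidInputError(f"Vmax must be >= 0, got {self.vmax}")
        if self.km <= 0:
            raise InvalidInputError(f"Km must be > 0, got {self.km}")
        if self.kp <= 0:
            raise InvalidInputError(f"Kp must be > 0, got {self.kp}")
        if self.ksi is not None and self.ksi <= 0:
            raise InvalidInputError(f"Ksi must be > 0 when present, got {self.ksi}")
        if self.kcat is not None and self.enzyme is not None:
            implied = self.kcat * self.enzyme
            if not math.isclose(implied, self.vmax, rel_tol=_KCAT_RTOL):
                raise InvalidInputError(
                    f"inconsistent parameters: kcat*[E] = {implied:g} but "
                    f"Vmax = {self.vmax:g} (must agree to 1e-6 relative)")
        elif self.kcat is None and self.enzyme is not None and self.enzyme > 0:
            object.__setattr__(self, "kcat", self.vmax / self.enzyme)

    @classmethod
    def from_kcat(cls, kcat: float, enzyme: float, km: float,
                  kp: float = math.inf, dh_rxn: float | None = None,
                  ksi: float | None = None) -> "KineticParams":
        """Build from turnover number and enzyme concentration."""
        if kcat < 0 or enzyme < 0:
            raise InvalidInputError("kcat and enzyme concentration must be >= 0")
        return cls(vmax=kcat * enzyme, km=km, kp=kp, dh_rxn=dh_rxn,
                   kcat=kcat, enzyme=enzyme, ksi=ksi)


@dataclass(frozen=True)
class BindingParams:
    """Single-site binding thermodynamics.

    ``dg`` and ``tds`` are derived quantities, so ΔG = ΔH − TΔS holds
    exactly by construction.

    Attributes
    ----------
    n : float
        Binding stoichiometry, sites per monomer.
    kd : float
        Dissociation constant, mol L⁻¹.
    dh : float
        Molar binding enthalpy, kcal mol⁻¹.
    T : float
        Absolute temperature, K.
    """

    n: float
    kd: float
    dh: float
    T: float

    def __post_init__(self):
        if self.n <= 0:
            raise InvalidInputError(f"stoichiometry n must be > 0, got {self.n}")
        if self.kd <= 0:
            raise InvalidInputError(f"Kd must be > 0, got {self.kd}")
        if self.T <= 0:
            raise InvalidInputError(f"temperature must be > 0 K, got {self.T}")

    @property
    def dg(self) -> float:
        """Binding free energy R·T·ln(Kd), kcal mol⁻¹."""
        return delta_g_from_kd(self.kd, self.T)

    @property
    def tds(self) -> float:
        """Entropic term TΔS = ΔH − ΔG, kcal mol⁻¹."""
        return self.dh - self.dg


def _as_nonneg(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError(f"{name} must be non-negative")
    return arr


def rate_product_inhibition(S, P, params: KineticParams):
    """Product-inhibited steady-state rate v(S, P).

    Evaluates ``Vmax·S / (Km·(1 + P/Kp) + S)``; if ``params.ksi`` is set
    the free-substrate denominator term becomes ``S·(1 + S/Ksi)``
    (substrate-inhibition extension, used only by the simulator).

    Accepts scalars or arrays; returns the same shape. Negative
    concentrations raise :class:`InvalidInputError`.
    """
    S = _as_nonneg(S, "substrate concentration")
    P = _as_nonneg(P, "product concentration")
    if np.isinf(params.kp):
        inhibition = 1.0
    else:
        inhibition = 1.0 + P / params.kp
    s_term = S if params.ksi is None else S * (1.0 + S / params.ksi)
    v = params.vmax * S / (params.km * inhibition + s_term)
    if v.ndim == 0:
        return float(v)
    return v


def michaelis_menten(S, vmax: float, km: float):
    """Plain Michaelis–Menten rate Vmax·S/(Km+S)."""
    return rate_product_inhibition(S, 0.0, KineticParams(vmax=vmax, km=km))


def delta_g_from_kd(kd: float, T: float) -> float:
    """Binding free energy from the dissociation constant.

    ΔG = R·T·ln(Kd / 1 mol L⁻¹), in kcal mol⁻¹ (R = 1.98720×10⁻³
    kcal mol⁻¹ K⁻¹); negative for sub-molar Kd.
    """
    if kd <= 0:
        raise InvalidInputError(f"Kd must be > 0, got {kd}")
    if T <= 0:
        raise InvalidInputError(f"temperature must be > 0 K, got {T}")
    return R_KCAL * T * math.log(kd)


def tds_from(dh: float, kd: float, T: float) -> float:
    """Entropic term TΔS = ΔH − R·T·ln(Kd), kcal mol⁻¹."""
    return dh - delta_g_from_kd(kd, T)
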