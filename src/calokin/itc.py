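"""Single-site ITC binding analysis (Wiseman isotherm).

An isothermal titration consists of a series of ligand injections into a
fixed-volume cell containing the macromolecule. For a single class of
``n`` identical sites, the fraction of sites occupied after injection i,
Θᵢ, solves the quadratic in total concentrations

    Θ² − Θ·(1 + Xᵢ/(n·Mᵢ) + Kd/(n·Mᵢ)) + Xᵢ/(n·Mᵢ) = 0,

with the physical root in [0, 1]; the cumulative heat evolved is
Qᵢ = n·Θᵢ·Mᵢ·ΔH·V₀. Because the cell is a perfusion (overflow) cell,
each injection displaces liquid of intermediate composition, handled by
the standard volume-displacement corrections: concentration dilution via
the (1 ± ΔV/2V₀) factors and a per-injection heat correction using the
volume-weighted mean of adjacent cumulative heats.

Fitting recovers (n, Kd, ΔH) from dilution-subtracted per-injection
heats. When the Wiseman c value (n·M₀/Kd) is below ``c_min`` the
isotherm has no usable inflection and the stoichiometry is held at
n = 1, with only (Kd, ΔH) floating — the standard low-c rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .errors import FitFailureError, InvalidInputError
from .rate_models import BindingParams
from .units import CAL_PER_KCAL, UCAL_PER_CAL, uL

__all__ = [
    "Titration",
    "paper_schedule",
    "injection_concentrations",
    "wiseman_theta",
    "wiseman_heats",
    "subtract_dilution",
    "BindingFitResult",
    "fit_binding",
    "DEFAULT_C_MIN",
]

DEFAULT_C_MIN = 5.0


@dataclass(frozen=True)
class Titration:
    """An ITC titration record.

    ``injection_volumes`` in L, ``heats`` (integrated per-injection
    heats) in μcal or None for a bare schedule; concentrations in
    mol L⁻¹ (macromolecule in monomers), volume in L, temperature in K.
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: np.ndarray
    heats: np.ndarray | None = None
    temperature: float = 303.15
    label: str = ""

    def __post_init__(self):
        vols = np.asarray(self.injection_volumes, dtype=float)
        object.__setattr__(self, "injection_volumes", vols)
        if self.cell_volume <= 0:
            raise InvalidInputError("cell volume must be > 0")
        if np.any(vols <= 0):
            raise InvalidInputError("injection volumes must be positive")
        if self.heats is not None:
            h = np.asarray(self.heats, dtype=float)
            object.__setattr__(self, "heats", h)
            if h.shape != vols.shape:
                raise InvalidInputError(
                    f"{h.size} heats for {vols.size} injections")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes.size


def paper_schedule(cell_volume: float = uL(204.1),
                   cell_conc: float = 100e-6,
                   syringe_conc: float = 1.5e-3,
                   temperature: float = 303.15) -> Titration:
    """The canonical schedule: one 1 μl injection then 18 × 2 μl,
    into a 204.1 μl cell (19 injections, 37 μl total)."""
    vols = np.array([1.0] + [2.0] * 18) * 1e-6
    return Titration(cell_volume=cell_volume, cell_conc=cell_conc,
                     syringe_conc=syringe_conc, injection_volumes=vols)


def injection_concentrations(t: Titration) -> tuple[np.ndarray, np.ndarray]:
    """Cell concentrations after each injection.

    Standard fixed-volume displacement bookkeeping: with cumulative
    injected volume ΔV,

        M = M₀·(1 − ΔV/2V₀)/(1 + ΔV/2V₀)
        X = X_syr·(ΔV/V₀)/(1 + ΔV/2V₀)

    Returns (macromolecule, total ligand) arrays, one entry per
    injection.
    """
    dv = np.cumsum(t.injection_volumes)
    if dv[-1] >= t.cell_volume:
        raise InvalidInputError(
            f"cumulative injected volume {dv[-1]:g} L exceeds cell volume")
    r = dv / t.cell_volume
    M = t.cell_conc * (1.0 - r / 2.0) / (1.0 + r / 2.0)
    X = t.syringe_conc * r / (1.0 + r / 2.0)
    return M, X


def wiseman_theta(M, X, n: float, kd: float):
    """Fraction of sites bound from the single-site quadratic.

    Physical root Θ = (b − sqrt(b² − 4c))/2 with b = 1 + X/(nM) + Kd/(nM)
    and c = X/(nM); guaranteed in [0, 1] for positive inputs.
    """
    M = np.asarray(M, dtype=float)
    X = np.asarray(X, dtype=float)
    xr = X / (n * M)
    kr = kd / (n * M)
    b = 1.0 + xr + kr
    disc = b * b - 4.0 * xr
    disc = np.maximum(disc, 0.0)  # guard roundoff at the stoichiometric point
    theta = (b - np.sqrt(disc)) / 2.0
    if np.any((theta < -1e-12) | (theta > 1.0 + 1e-12)):
        raise FitFailureError("no physical root in [0,1] for binding quadratic")
    return np.clip(theta, 0.0, 1.0)


def wiseman_heats(t: Titration, b: BindingParams,
                  displacement_correction: bool = True) -> np.ndarray:
    """Predicted per-injection heats (μcal) for a single-site isotherm.

    Cumulative heat Qᵢ = n·Θᵢ·Mᵢ·ΔH·V₀; the injection heat is the
    increment Qᵢ − Qᵢ₋₁ plus, when ``displacement_correction`` is on,
    the heat carried out by the displaced volume,
    (dVᵢ/V₀)·(Qᵢ + Qᵢ₋₁)/2.
    """
    M, X = injection_concentrations(t)
    theta = wiseman_theta(M, X, b.n, b.kd)
    Q = b.n * theta * M * (b.dh * CAL_PER_KCAL) * t.cell_volume  # cal
    Qprev = np.concatenate(([0.0], Q[:-1]))
    dQ = Q - Qprev
    if displacement_correction:
        dQ = dQ + (t.injection_volumes / t.cell_volume) * (Q + Qprev) / 2.0
    return dQ * UCAL_PER_CAL


def subtract_dilution(t: Titration, blank: Titration) -> Titration:
    """Subtract a buffer-only blank titration's heats injection-wise.

    The blank must follow the same schedule (same count, volumes within
    1%); metadata of ``t`` is preserved.
    """
    if t.heats is None or blank.heats is None:
        raise InvalidInputError("both titrations must carry heats")
    if blank.n_injections != t.n_injections:
        raise InvalidInputError(
            f"schedule mismatch: {t.n_injections} vs {blank.n_injections} injections")
    rel = np.abs(blank.injection_volumes - t.injection_volumes) / t.injection_volumes
    if np.any(rel > 0.01):
        raise InvalidInputError("schedule mismatch: injection volumes differ by > 1%")
    return replace(t, heats=t.heats - blank.heats)


@dataclass(frozen=True)
class BindingFitResult:
    """Outcome of a single-site fit, with derived thermodynamics."""

    params: BindingParams
    c: float                      # Wiseman c = n·M₀/Kd at the fitted values
    n_fixed: bool                 # low-c rule (or fix_n) engaged
    kd_se: float | None
    dh_se: float | None
    n_se: float | None
    rss: float                    # μcal²
    n_points: int
    converged: bool
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "n": p.n, "n_fixed": self.n_fixed, "n_se": self.n_se,
            "kd_uM": p.kd * 1e6, "kd_se_uM": None if self.kd_se is None else self.kd_se * 1e6,
            "dh_kcal_mol": p.dh, "dh_se_kcal_mol": self.dh_se,
            "dg_kcal_mol": p.dg, "tds_kcal_mol": p.tds,
            "c_value": self.c, "rss_ucal2": self.rss,
            "n_points": self.n_points, "converged": self.converged,
        }


def _residual(pars, t: Titration, heats_obs, mask):
    b = BindingParams(n=math.exp(pars["ln_n"].value),
                      kd=math.exp(pars["ln_kd"].value),
                      dh=pars["dh"].value, T=t.temperature)
    pred = wiseman_heats(t, b)
    return pred[mask] - heats_obs[mask]


def _run_fit(t, heats, mask, n0, kd0, dh0, float_n):
    pars = lmfit.Parameters()
    pars.add("ln_n", value=math.log(n0), vary=float_n, min=math.log(1e-3),
             max=math.log(1e3))
    pars.add("ln_kd", value=math.log(kd0), min=math.log(1e-12), max=math.log(1.0))
    pars.add("dh", value=dh0)
    return lmfit.minimize(_residual, pars, args=(t, heats, mask), method="leastsq")


def fit_binding(t: Titration, fix_n: bool = False,
                c_min: float = DEFAULT_C_MIN,
                skip_first: bool = True) -> BindingFitResult:
    """Least-squares fit of (n, Kd, ΔH) to dilution-subtracted heats.

    The customary small first injection is excluded by default. After an
    initial fit with n floating, the Wiseman c value n·M₀/Kd is checked:
    if c < ``c_min`` (weak inflection) the fit is repeated with n held at
    1 and only (Kd, ΔH) floating. ``fix_n`` forces that behaviour. ΔG and
    TΔS are derived from the fitted Kd and ΔH.
    """
    if t.heats is None:
        raise InvalidInputError("titration carries no heats")
    mask = np.ones(t.n_injections, dtype=bool)
    if skip_first:
        mask[0] = False
    n_used = int(mask.sum())
    if n_used < 6:
        raise InvalidInputError(f"only {n_used} usable injections; need >= 6")
    heats = np.asarray(t.heats, dtype=float)
    if np.max(np.abs(heats[mask])) < 1e-9:
        raise FitFailureError("all heats are (near) zero: no binding signal")

    # deterministic initial guesses
    first = int(np.argmax(mask))
    moles_inj = t.syringe_conc * t.injection_volumes[first]
    dh0 = (heats[first] / UCAL_PER_CAL) / moles_inj / CAL_PER_KCAL
    if dh0 == 0:
        dh0 = -1.0
    kd0 = t.cell_conc / 10.0
    n0 = 1.0

    warnings: list[str] = []
    res = _run_fit(t, heats, mask, n0, kd0, dh0, float_n=not fix_n)
    n_fixed = fix_n
    if not fix_n:
        c_hat = math.exp(res.params["ln_n"].value) * t.cell_conc / math.exp(
            res.params["ln_kd"].value)
        if c_hat < c_min:
            warnings.append(f"c = {c_hat:.2f} < {c_min:g}: n held at 1 (low-c rule)")
            res = _run_fit(t, heats, mask, 1.0, kd0, dh0, float_n=False)
            n_fixed = True
    if not res.success:
        raise FitFailureError("binding fit did not converge",
                              details={"message": res.message})

    n_hat = math.exp(res.params["ln_n"].value)
    kd_hat = math.exp(res.params["ln_kd"].value)
    dh_hat = res.params["dh"].value
    bp = BindingParams(n=n_hat, kd=kd_hat, dh=dh_hat, T=t.temperature)

    def _se(name, scale=1.0):
        err = res.params[name].stderr
        return None if err is None else err * scale

    return BindingFitResult(
        params=bp,
        c=n_hat * t.cell_conc / kd_hat,
        n_fixed=n_fixed,
        kd_se=_se("ln_kd", kd_hat),  # delta method: se(Kd) = Kd·se(ln Kd)
        dh_se=_se("dh"),
        n_se=None if n_fixed else _se("ln_n", n_hat),
        rss=float(np.sum(res.residual ** 2)),
        n_points=n_used,
        converged=bool(res.success),
        warnings=tuple(warnings),
    )
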