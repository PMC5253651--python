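"""Nonlinear least-squares estimation of Km and Vmax under product inhibition.

The model fitted is the product-inhibition rate law

    v = Vmax·S / ( Km·(1 + P/Kp) + S )

with the product affinity term Kp held FIXED (here, at an independently
measured product dissociation constant) and the product concentration
reconstructed from 1:1 stoichiometry, P = P₀ + (S₀ − S). Only (Km, Vmax)
float; kcat is derived as Vmax/[E]. Setting ``kp = inf`` reduces the fit
to plain Michaelis–Menten.

Profiles tagged as excess-limiting-substrate designs are refused unless
forced: at high homoallylic-substrate excess the rate data show apparent
substrate inhibition and the two-parameter model is misspecified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .errors import FitFailureError, InvalidInputError
from .thermogram import RateProfile

__all__ = ["KineticFitResult", "fit_kinetics"]

#: warn when the fitted S values span less than this fraction of S0
NARROW_RANGE_FRAC = 0.2


@dataclass(frozen=True)
class KineticFitResult:
    km: float                    # mol L⁻¹
    km_se: float | None
    vmax: float                  # mol L⁻¹ s⁻¹
    vmax_se: float | None
    kcat: float                  # s⁻¹ = vmax / enzyme
    kp_fixed: float              # mol L⁻¹ (inf = Michaelis–Menten)
    rss: float
    n_points: int
    converged: bool
    warnings: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "km_uM": self.km * 1e6,
            "km_se_uM": None if self.km_se is None else self.km_se * 1e6,
            "vmax_uM_per_s": self.vmax * 1e6,
            "vmax_se_uM_per_s": None if self.vmax_se is None else self.vmax_se * 1e6,
            "kcat_per_s": self.kcat,
            "kp_fixed_uM": None if math.isinf(self.kp_fixed) else self.kp_fixed * 1e6,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }


def _model(S, P, km, vmax, kp):
    inhib = 1.0 if math.isinf(kp) else 1.0 + P / kp
    return vmax * S / (km * inhib + S)


def _fit_once(S, P, v, kp, km0, vmax0, weights):
    pars = lmfit.Parameters()
    pars.add("km", value=km0, min=1e-15)
    pars.add("vmax", value=vmax0, min=1e-30)

    def resid(p):
        r = _model(S, P, p["km"].value, p["vmax"].value, kp) - v
        return r if weights is None else r * weights

    return lmfit.minimize(resid, pars, method="leastsq")


def fit_kinetics(p: RateProfile, enzyme: float, s0: float, p0: float,
                 kp: float, force: bool = False,
                 weights: np.ndarray | None = None) -> KineticFitResult:
    """Fit (Km, Vmax) to a rate-vs-substrate profile with Kp fixed.

    Parameters
    ----------
    p : RateProfile
        Induction-trimmed (S, v) data, concentrations in mol L⁻¹.
    enzyme, s0, p0 : float
        Enzyme concentration, limiting-substrate start and product start
        (mol L⁻¹); the product at each point is P = p0 + (s0 − S).
    kp : float
        Fixed product affinity term (mol L⁻¹); ``inf`` for the plain
        Michaelis–Menten reduction.
    force : bool
        Fit even a profile tagged ``design='excess_limiting'``.
    weights : array, optional
        Per-point weights (e.g. inverse s.d. from replicate profiles);
        default unweighted.
    """
    if p.meta.get("design") == "excess_limiting" and not force:
        raise InvalidInputError(
            "profile comes from an excess-limiting-substrate design (apparent "
            "substrate inhibition); pass force=True to fit anyway")
    if len(p) < 5:
        raise InvalidInputError(f"need at least 5 points, got {len(p)}")
    if enzyme <= 0 or s0 <= 0:
        raise InvalidInputError("enzyme and S0 must be > 0")
    if kp <= 0:
        raise InvalidInputError("Kp must be > 0 (use inf for no product term)")

    S, v = p.s, p.v
    P = p0 + (s0 - S)

    warnings = []
    if (S.max() - S.min()) < NARROW_RANGE_FRAC * s0:
        warnings.append("narrow_s_range")

    # deterministic start: Vmax slightly above the observed maximum, Km at
    # the substrate level closest to half that rate
    vmax0 = 1.05 * float(v.max())
    km0 = float(S[np.argmin(np.abs(v - v.max() / 2.0))])
    km0 = max(km0, 1e-9 * s0)

    res = _fit_once(S, P, v, kp, km0, vmax0, weights)
    if not res.success:
        # bounded restarts from log-spaced Km starting values
        for km_try in np.logspace(math.log10(0.01 * s0), math.log10(10 * s0), 5):
            res = _fit_once(S, P, v, kp, float(km_try), vmax0, weights)
            if res.success:
                break
        else:
            raise FitFailureError("kinetic fit did not converge after restarts",
                                  details={"message": res.message,
                                           "km0": km0, "vmax0": vmax0})

    km_hat = float(res.params["km"].value)
    vmax_hat = float(res.params["vmax"].value)
    if km_hat <= 0 or vmax_hat <= 0:
        raise FitFailureError("kinetic fit converged to a non-positive parameter",
                              details={"km": km_hat, "vmax": vmax_hat})

    return KineticFitResult(
        km=km_hat,
        km_se=res.params["km"].stderr,
        vmax=vmax_hat,
        vmax_se=res.params["vmax"].stderr,
        kcat=vmax_hat / enzyme,
        kp_fixed=kp,
        rss=float(np.sum(res.residual ** 2)),
        n_points=len(p),
        converged=bool(res.success),
        warnings=tuple(warnings),
    )
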