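"""Synthetic calorimetry data with ground-truth labels.

This module emulates the two experiment types the pipeline consumes:

* **single-injection enzyme assays** — the reaction progress ODE
  dS/dt = −v(S, P₀ + S₀ − S) is integrated under the product-inhibition
  rate law (optionally with first-order Vmax decay to mimic catalyst
  deactivation, or with substrate inhibition), converted to ideal
  thermal power P = v·V·ΔH, decorated with a zero-net-heat mixing
  transient at the injection, blurred by the calorimeter's first-order
  response (time constant τ) and overlaid with Gaussian power noise;
* **ITC titrations** — per-injection heats from the Wiseman single-site
  forward model, plus an optional constant dilution offset and
  multiplicative heat noise; a matched buffer-only blank is emitted for
  dilution-subtraction testing.

Every generator returns a :class:`GroundTruth` sidecar naming the
mechanism and true parameters, so parameter-recovery and
mechanism-classification tests have an oracle. Identical seeds give
bit-identical outputs.

Default conditions mirror the emulated experiments: 204.1 μl cell,
450 nM enzyme (midpoint of the 400–500 nM assay range), 30 °C, 10 μl
assay injection, 1 s sampling, τ = 10 s, and the 1 μl + 18 × 2 μl
titration schedule into 100 μM enzyme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidInputError
from .itc import Titration, wiseman_heats
from .rate_models import BindingParams, KineticParams, rate_product_inhibition
from .rpka import AssayDesign, SameExcessPair, spiked_control_design
from .thermogram import ProgressCurve, Thermogram, ThermogramMeta
from .units import CAL_PER_KCAL, UCAL_PER_CAL

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "progress_ode",
    "simulate_assay",
    "simulate_same_excess",
    "simulate_titration",
    "dilute_injection",
]

#: default mixing-transient width (s) and amplitude as a fraction of peak power
DEFAULT_TRANSIENT_S = 20.0
DEFAULT_TRANSIENT_FRAC = 0.5

#: default completion: integrate until this fraction of S0 remains
DEFAULT_REMAINING_FRAC = 1e-3


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise description; ``seed`` makes it reproducible.

    ``power_sd``: additive Gaussian s.d. on thermal power, μcal s⁻¹
    (roughly 1% of a typical assay's peak power at the default).
    ``heat_frac``: multiplicative Gaussian fraction on injection heats.
    """

    power_sd: float = 0.02
    heat_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.power_sd < 0 or self.heat_frac < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: a silent noise model, for noiseless simulations
NOISELESS = NoiseModel(power_sd=0.0, heat_frac=0.0, seed=0)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    mechanism: str               # product_inhibition | none | deactivation | substrate_inhibition
    kinetic_params: KineticParams | None = None
    binding_params: BindingParams | None = None
    transient_window: tuple[float, float] | None = None
    tau: float | None = None
    decay_rate: float = 0.0
    design: AssayDesign | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mechanism == "deactivation" and self.decay_rate <= 0:
            raise InvalidInputError("deactivation label requires decay_rate > 0")
        if self.mechanism == "substrate_inhibition" and (
                self.kinetic_params is None or self.kinetic_params.ksi is None):
            raise InvalidInputError("substrate_inhibition label requires Ksi")

    def to_dict(self) -> dict:
        out = {"mechanism": self.mechanism, "decay_rate_per_s": self.decay_rate}
        if self.kinetic_params is not None:
            k = self.kinetic_params
            out["kinetic_params"] = {
                "vmax_uM_per_s": k.vmax * 1e6, "km_uM": k.km * 1e6,
                "kp_uM": None if math.isinf(k.kp) else k.kp * 1e6,
                "dh_kcal_mol": k.dh_rxn, "kcat_per_s": k.kcat,
                "ksi_uM": None if k.ksi is None else k.ksi * 1e6,
            }
        if self.binding_params is not None:
            b = self.binding_params
            out["binding_params"] = {"n": b.n, "kd_uM": b.kd * 1e6,
                                     "dh_kcal_mol": b.dh, "T_K": b.T}
        if self.transient_window is not None:
            out["transient_window_s"] = list(self.transient_window)
        if self.tau is not None:
            out["tau_s"] = self.tau
        out.update(self.extras)
        return out


def _mechanism_label(params: KineticParams, decay_rate: float) -> str:
    if decay_rate > 0:
        return "deactivation"
    if params.ksi is not None:
        return "substrate_inhibition"
    if math.isfinite(params.kp):
        return "product_inhibition"
    return "none"


def dilute_injection(syringe_conc: float, cell_volume: float,
                     injection_volume: float) -> float:
    """Post-injection cell concentration of an injected species,
    C·V_inj/(V_cell + V_inj); the matching factor V_cell/(V_cell+V_inj)
    dilutes species already in the cell."""
    return syringe_conc * injection_volume / (cell_volume + injection_volume)


# ---------------------------------------------------------------------------
# reaction progress


def _rate_at(t, S, d: AssayDesign, k: KineticParams, decay_rate: float):
    P = d.p0 + (d.b0 - S)
    v = rate_product_inhibition(max(S, 0.0), max(P, 0.0), k)
    if decay_rate > 0:
        v *= math.exp(-decay_rate * t)
    return v


def progress_ode(d: AssayDesign, k: KineticParams,
                 decay_rate: float = 0.0,
                 remaining_frac: float = DEFAULT_REMAINING_FRAC,
                 rtol: float = 1e-9,
                 t_grid: np.ndarray | None = None
                 ) -> tuple[ProgressCurve, GroundTruth]:
    """Integrate the progress ODE dS/dt = −v(S, P) for the limiting substrate.

    The limiting species is B (A is assumed saturating so the rate law is
    single-substrate); for an excess-limiting design the allylic substrate
    runs out first and min(A₀, B₀) is integrated instead. Integration runs
    until ``remaining_frac`` of the start remains (default 0.1%, so that a
    "complete" run biases the Eq.-1 enthalpy by no more than ~0.1%), with
    adaptive stepping at relative tolerance 1e-9.

    Returns the progress curve on the solver grid (or ``t_grid``) and the
    ground truth.
    """
    s_start = min(d.a0, d.b0)
    if s_start <= 0:
        raise InvalidInputError("limiting substrate start must be > 0")
    d_eff = d if d.b0 <= d.a0 else replace(d, b0=s_start)

    def rhs(t, y):
        return [-_rate_at(t, y[0], d_eff, k, decay_rate)]

    s_floor = remaining_frac * s_start

    def done(t, y):
        return y[0] - s_floor
    done.terminal = True
    done.direction = -1

    # crude duration bound: zero-order burn time plus first-order tails
    if k.vmax > 0:
        t_max = 20.0 * (s_start / k.vmax
                        + (k.km / k.vmax)
                        * (1.0 + (d.p0 + s_start) / k.kp if math.isfinite(k.kp) else 1.0)
                        * max(-math.log(remaining_frac), 1.0))
    else:
        t_max = 300.0
    if decay_rate > 0:
        t_max = min(t_max * 5.0, t_max + 20.0 / decay_rate)

    sol = solve_ivp(rhs, (0.0, t_max), [s_start], method="RK45",
                    rtol=rtol, atol=1e-15, events=done, dense_output=True,
                    max_step=t_max / 50.0)
    if not sol.success:
        raise RuntimeError(f"progress ODE integration failed: {sol.message}")

    if t_grid is None:
        t = sol.t
        S = sol.y[0]
    else:
        t = np.asarray(t_grid, dtype=float)
        t_end = sol.t[-1]
        S = np.empty_like(t)
        inside = t <= t_end
        S[inside] = sol.sol(t[inside])[0]
        if np.any(~inside):
            # past the solver's end the reaction is exhausted: decay the
            # residual substrate with its terminal first-order constant
            s_end = float(sol.y[0][-1])
            k_tail = _rate_at(t_end, s_end, d_eff, k, decay_rate) / s_end \
                if s_end > 0 else 0.0
            S[~inside] = s_end * np.exp(-k_tail * (t[~inside] - t_end))
    S = np.clip(S, 0.0, s_start)
    v = np.array([_rate_at(ti, si, d_eff, k, decay_rate) for ti, si in zip(t, S)])

    dh = k.dh_rxn if k.dh_rxn is not None else 0.0
    Q = (s_start - S) * d.cell_volume * dh * CAL_PER_KCAL
    meta = ThermogramMeta(cell_volume=d.cell_volume, enzyme=d.enzyme,
                          s0=s_start, cosubstrate=max(d.a0, d.b0), p0=d.p0,
                          temperature=d.temperature, injection_end=0.0)
    curve = ProgressCurve(t=t, Q=Q, S=S, P_prod=d.p0 + (s_start - S), v=v,
                          meta=meta, source_id=d.label)
    truth = GroundTruth(mechanism=_mechanism_label(k, decay_rate),
                        kinetic_params=k, decay_rate=decay_rate, design=d)
    return curve, truth


def _first_order_filter(t: np.ndarray, u: np.ndarray, tau: float) -> np.ndarray:
    """Exact response of τ·y' = u − y to a piecewise-linear input, y(0)=0."""
    if tau == 0:
        return u.copy()
    y = np.empty_like(u)
    y[0] = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        r = (u[i + 1] - u[i]) / dt
        e = math.exp(-dt / tau)
        y[i + 1] = u[i + 1] - r * tau + (y[i] - u[i] + r * tau) * e
    return y


def _mixing_transient(t: np.ndarray, width: float, amplitude: float) -> np.ndarray:
    """Zero-net-heat injection artefact: a demeaned damped oscillation."""
    a = np.zeros_like(t)
    if width <= 0 or amplitude == 0:
        return a
    w = (t >= 0) & (t < width)
    if not np.any(w):
        return a
    x = t[w] / width
    burst = amplitude * np.sin(2.0 * np.pi * x) * (1.0 - x)
    a[w] = burst - burst.mean()   # exact zero net area on the window
    return a


def simulate_assay(d: AssayDesign, k: KineticParams,
                   tau: float = 10.0,
                   noise: NoiseModel | None = None,
                   decay_rate: float = 0.0,
                   transient_s: float = DEFAULT_TRANSIENT_S,
                   transient_frac: float = DEFAULT_TRANSIENT_FRAC,
                   dt: float = 1.0,
                   tail_s: float = 60.0) -> tuple[Thermogram, GroundTruth]:
    """Simulate a single-injection assay thermogram.

    The ideal power v(t)·V·ΔH is decorated with a mixing transient (a
    zero-net-heat burst over ``transient_s`` seconds, amplitude
    ``transient_frac`` × the ideal peak), filtered through the
    instrument's first-order response τ, sampled at ``dt``, extended by
    ``tail_s`` (at least 5τ) past completion so the response decays, and
    overlaid with Gaussian noise. Before noise, the integrated heat
    equals S₀·V·ΔH to within the completion tolerance (<0.5%).
    """
    if k.dh_rxn is None or k.dh_rxn == 0:
        raise InvalidInputError("simulate_assay needs a nonzero dh_rxn")
    if tau < 0 or dt <= 0:
        raise InvalidInputError("tau must be >= 0 and dt > 0")

    # duration: find completion with the adaptive solver, then resample
    if k.vmax > 0 and d.enzyme > 0:
        probe, _ = progress_ode(d, k, decay_rate=decay_rate)
        t_end = probe.t[-1]
    else:
        t_end = 240.0
    t_total = t_end + max(tail_s, 5.0 * tau, transient_s)
    t = np.arange(0.0, t_total + dt / 2.0, dt)

    if k.vmax > 0 and d.enzyme > 0:
        curve, truth = progress_ode(d, k, decay_rate=decay_rate, t_grid=t)
        v = curve.v
    else:
        v = np.zeros_like(t)
        truth = GroundTruth(mechanism=_mechanism_label(k, decay_rate),
                            kinetic_params=k, decay_rate=decay_rate, design=d)

    p_ideal = v * d.cell_volume * (k.dh_rxn * CAL_PER_KCAL) * UCAL_PER_CAL
    peak = float(np.max(np.abs(p_ideal)))
    p_ideal = p_ideal + _mixing_transient(t, transient_s, transient_frac * peak)
    p_meas = _first_order_filter(t, p_ideal, tau)
    if noise is not None and noise.power_sd > 0:
        p_meas = p_meas + noise.rng().normal(0.0, noise.power_sd, size=p_meas.size)

    s_start = min(d.a0, d.b0)
    meta = ThermogramMeta(cell_volume=d.cell_volume, enzyme=d.enzyme,
                          s0=s_start, cosubstrate=max(d.a0, d.b0), p0=d.p0,
                          temperature=d.temperature, injection_end=transient_s)
    g = Thermogram(t=t, power=p_meas, meta=meta, source_id=d.label)
    truth = replace(truth, transient_window=(0.0, transient_s), tau=tau,
                    design=d)
    return g, truth


def simulate_same_excess(pair: SameExcessPair, k: KineticParams,
                         spiked: bool = True,
                         **kwargs) -> dict[str, tuple[Thermogram, GroundTruth]]:
    """Simulate a same-excess pair and (optionally) its product-spiked
    control; keys are 'high', 'low' and 'spiked'."""
    out = {
        "high": simulate_assay(pair.run_high, k, **kwargs),
        "low": simulate_assay(pair.run_low, k, **kwargs),
    }
    if spiked:
        out["spiked"] = simulate_assay(spiked_control_design(pair), k, **kwargs)
    return out


# ---------------------------------------------------------------------------
# titrations


def simulate_titration(schedule: Titration, b: BindingParams,
                       noise: NoiseModel | None = None,
                       dilution_offset_ucal: float = 0.0
                       ) -> tuple[Titration, Titration, GroundTruth]:
    """Simulate an ITC titration and its buffer-only blank.

    Heats come from the Wiseman single-site forward model, plus a
    constant per-injection dilution offset and multiplicative Gaussian
    noise. The blank carries the offset (and noise) only, so
    ``subtract_dilution(titration, blank)`` recovers the binding heats.
    Returns (titration, blank, truth); deterministic per seed.
    """
    heats = wiseman_heats(schedule, b)
    blank_heats = np.full_like(heats, dilution_offset_ucal)
    if noise is not None and noise.heat_frac > 0:
        rng = noise.rng()
        heats = heats * (1.0 + rng.normal(0.0, noise.heat_frac, heats.size))
        blank_heats = blank_heats * (
            1.0 + rng.normal(0.0, noise.heat_frac, blank_heats.size))
    titration = replace(schedule, heats=heats + blank_heats,
                        label=schedule.label or "titration")
    blank = replace(schedule, heats=blank_heats, label="blank")
    truth = GroundTruth(mechanism="none", binding_params=b,
                        extras={"dilution_offset_ucal": dilution_offset_ucal})
    return titration, blank, truth
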