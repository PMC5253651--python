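# Methods

This note documents the models behind `calokin`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for interpreting its
output.

## Units and constants

Internally everything is SI-flavoured: mol L⁻¹, seconds, litres,
calories (heats), kcal mol⁻¹ (molar energies), kelvin. μ-prefixed
values appear only at interfaces (CSV headers, CLI flags, reports) and
are converted on read. The gas constant is fixed at
R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹; temperatures given in °C convert as
K = °C + 273.15. Sign convention: exothermic processes carry negative
ΔH, negative power and negative Q, which makes the substrate and rate
formulas return positive values without special-casing.

## Thermogram processing

A single-injection assay trace is processed as: baseline subtraction →
instrument-response correction → heat integration → enthalpy →
substrate series → rate series → induction trim → (optional) binning.

**Baseline.** A constant offset estimated from pre-injection samples
(t < 0, or an explicit window); with no pre-injection samples the trace
is treated as already baseline-compensated. Drift beyond a constant is
out of scope.

**Instrument response.** The calorimeter low-pass filters true heat
flow with a first-order time constant τ; the correction inverts this as
P_true = P_meas + τ·dP_meas/dt, the derivative taken by central
differences on a 5-point moving-average-smoothed trace. Fourier
deconvolution was rejected as over-engineering for smooth enzyme-assay
signals. τ defaults to 10 s for both simulation and correction
(config-overridable); instrument vendors do not publish the response
time of the emulated cell, and 10 s is typical of small-cell
perfusion calorimeters.

**Enthalpy and the cumulative heat.** Two numerical choices matter.
(1) The total heat in ΔH = Q/([S]₀·V) is integrated from the
*uncorrected* baseline-subtracted trace: the instrument response is a
unit-DC-gain linear filter and conserves heat exactly, whereas
differentiating across the sharp power onset at the injection makes the
corrected trace lose a fraction of a percent of the total. (2) The
cumulative heat feeding [S](t) = [S]₀ − Q(t)/(ΔH·V) is end-anchored — a
constant shift makes Q(t_end) equal the conserved total — so that for a
run-to-completion trace the remaining substrate is proportional to the
heat still to be evolved, which depends only on the corrected power
after the transient, where it is accurate. With these choices a
noiseless simulated run returns ΔH to ~0.1% and the full loop recovers
Km and Vmax to ~0.1%.

**Induction trim.** The mixing/thermal transient after injection is
excluded. Default cutoff: injection end + 30 s, a conservative
steady-state margin for parameter fitting. An `auto` rule (first time
the corrected power joins its monotone decaying envelope within 2%) is
available. The overlay analysis (below) instead trims injection end
+ 5 s: the correction is algebraic and local, so data are valid a few
samples past the transient, and the overlay needs the informative
high-rate range — at the default conditions the low-concentration run
is nearly exhausted 30 s past the injection.

**Binning.** Consecutive groups of k points (default display
convention k = 5) are replaced by their mean; the trailing incomplete
group is dropped. Binned profiles are for display: binning is *not*
applied before overlay interpolation, where it introduces secant bias
in the curved low-substrate region.

## Product-inhibition fit

v = Vmax·S/(Km·(1 + P/Kp) + S) with P = P₀ + (S₀ − S) by 1:1
stoichiometry and Kp fixed (an independently measured product Kd;
Kp = ∞ gives the Michaelis–Menten reduction). Unweighted least squares
(no weighting scheme is defensible for a single trace; inverse-variance
weights can be supplied for replicates); deterministic initialisation
(Vmax₀ = 1.05·max v, Km₀ = S at half-max rate) with bounded restarts
from five log-spaced Km₀ values; asymptotic standard errors from the
Jacobian. Profiles tagged as excess-limiting-substrate designs are
refused unless forced, because high homoallylic-substrate excess shows
apparent substrate inhibition that the two-parameter model cannot
represent; the tag travels in `RateProfile.meta` (it is an experimental
design fact, not inferable from the trace itself). A warning flags
fits whose substrate coverage spans less than 20% of S₀ (poorly
constrained Km). Fits are to unbinned rates; binning is a display
convention.

## Same-excess analysis

Two runs with equal [A]₀ − [B]₀ and 1:1 stoichiometry trace the same
reaction entered at different conversions. The package forms pairs
from consecutive B₀ levels (defaults 16 and 40 μM with excess 24 μM,
chosen so the high run spans the low run's full substrate range), and a
spiked control at the low design plus product equal to the B₀
difference — exactly the product the high run has made on reaching the
low run's start, so under pure product inhibition the control
reproduces the high run's state.

The visual overlay judgement becomes a numeric rule:
`overlay_metric(reference, other)` interpolates the second profile
(piecewise linear in S) onto the reference points in the shared
substrate range and reports the rms and signed mean of
(v_other − v_ref)/v_ref; verdict `overlay` iff rms ≤ threshold
(default 0.05). Two robustness refinements: reference points whose rate
is below a floor fraction of the in-range maximum are excluded (the
exhausted tail has v → 0 and a relative metric there measures only
noise), and in `analyze_same_excess` both profiles' rate series are
Savitzky–Golay smoothed (window 23 samples, quadratic) before
comparison — the τ·dP/dt term of the response correction amplifies
power noise ~2.6×, and an rms of pointwise deviations does not average
noise away. The quadratic local fit preserves v(t) curvature to second
order, so the noiseless verdicts are unchanged.

Classification: pair overlays → `none`; pair divergent and spiked
control overlays the high run → `product_inhibition`; pair divergent
and the control still divergent → `deactivation_or_mixed`. For testing
the classifier, deactivation is simulated as first-order decay of Vmax
(default 0.005 s⁻¹, chosen to produce divergence of the same order as
the product-inhibition case at the default design).

## Single-site ITC model

Fixed-volume perfusion bookkeeping: after cumulative injected volume
ΔV, M = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀) and X = X_syr·(ΔV/V₀)/(1 + ΔV/2V₀)
— the standard vendor forms; an explicit inject-mix-expel simulation
serves as the test oracle, not the production path. Θ comes from the
single-site quadratic (physical root in [0, 1], verified in tests
against bisection on the free-ligand equation to 10⁻⁸); cumulative heat
Qᵢ = n·Θᵢ·Mᵢ·ΔH·V₀; injection heats include the displaced-volume
correction (dVᵢ/V₀)·(Qᵢ + Qᵢ₋₁)/2.

Fitting: (n, Kd, ΔH) by least squares on dilution-subtracted heats,
positivity via log-parameterisation, the customary small first
injection excluded by default. The low-c rule: if the fitted
c = n·M₀/Kd falls below c_min = 5 the stoichiometry is held at 1 and
only (Kd, ΔH) float — below c ≈ 5 the isotherm has no usable
inflection and n is not identifiable (the weak-binder case in the
bundled defaults has c ≈ 2.3). Standard errors are asymptotic;
whether reported triplicate spreads are s.d. or s.e.m. is treated as
s.d. in tests.

## Synthetic-data generator

The generator is the package's instrument stand-in and the oracle for
every recovery test. Assays: the progress ODE dS/dt = −v(S, P₀+S₀−S)
is integrated (RK45, rtol 10⁻⁹, verified against an independent
fixed-step RK4 implementation) until 0.1% of the substrate remains —
at 1% remaining the unreacted fraction alone would bias the recovered
ΔH by 1% — converted to power P = v·V·ΔH, decorated with a
zero-net-heat mixing transient (a demeaned damped oscillation over the
first 20 s, amplitude half the ideal peak; zero net area keeps the
trace's integrated heat equal to S₀·V·ΔH, which a multiplicative ramp
would not), filtered through the exact discrete first-order response,
sampled at 1 s, and overlaid with additive Gaussian power noise
(default s.d. 0.02 μcal s⁻¹, ~1% of a typical peak). Titrations:
Wiseman-model heats plus an optional constant dilution offset and
multiplicative heat noise (default 2%), with a matched buffer-only
blank. Identical seeds give byte-identical CSV output.

Default conditions mirror the emulated experiments: 204.1 μl cell,
450 nM enzyme (midpoint of the 400–500 nM assay range), kcat
0.90 s⁻¹, Km 1.1 μM, Kp 6 μM, ΔH −22.5 kcal mol⁻¹, 30 °C; titrations
into 100 μM enzyme with a 1 μl + 18 × 2 μl schedule. Syringe
concentrations are converted to post-injection cell values with the
V_cell/(V_cell + V_inj) dilution factor.

What the generator does **not** emulate: baseline drift, per-injection
power peaks (titration inputs are already-integrated heats),
temperature-jump and stirring artefacts, heat-capacity effects, and
the two-substrate mass-action mechanism (the rate law treats the
saturating allylic substrate implicitly; the substrate-inhibition
variant, S replaced by S·(1 + S/Ksi) in the denominator, is available
to the simulator only — no Ksi value is fitted, as none is
identifiable from the emulated design). Passing recovery tests
therefore demonstrates correctness of the analysis chain under the
stated noise model, not robustness to every artefact of real traces.

## Problem sizes

The statistical suites use 20–50 seeded replicates per property
(parameter recovery under noise, overlay specificity, mechanism-label
recovery over 40 runs), each replicate being a full simulate → process
→ analyse cycle at the default 1 s sampling (~300–500 samples per
trace, 19 injections per titration). These sizes give stable medians
and proportions for the asserted tolerances while keeping the whole
suite fast.

## Known limitations

* The time-constant correction assumes a single first-order response;
  real cells show weak higher-order behaviour near sharp transients,
  which is why the first ~2τ after a kink is excluded from round-trip
  guarantees.
* ΔH estimation requires a run-to-completion trace; partial progress
  curves need an externally supplied ΔH (supported via an argument,
  with the completeness judgement left to the user).
* The overlay classifier distinguishes product inhibition from
  deactivation only through the spiked control; a mixture of both maps
  to `deactivation_or_mixed` by design.
* Kp enters the kinetic fit as a fixed constant; no joint (Km, Vmax,
  Kp) fit is attempted, as a single progress curve cannot separate Kp
  from Km reliably.
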