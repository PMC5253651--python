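# calokin

Calorimetric enzyme kinetics and binding analysis for isothermal
titration calorimeters used as rate meters.

When an enzyme turns over its substrate inside an ITC cell, the
compensation power is a continuous read-out of reaction rate: every
mole of product releases the molar reaction enthalpy ΔH. A single
substrate injection therefore yields, from one trace, the complete
rate-versus-substrate curve — and, with a suitable experimental design,
a mechanistic verdict on why an enzyme slows down as product
accumulates. `calokin` implements that workflow for the case study of
farnesyl pyrophosphate synthase (FPPS), an enzyme of the mevalonate
pathway that is allosterically inhibited by its own product FPP, but
the machinery is generic to single-substrate calorimetric assays.

## What it computes

**Thermogram → rates.** With total heat Q = ∫(dQ/dt)dt over a complete
reaction, cell volume V and limiting-substrate start [S]₀:

    ΔH = Q / ([S]₀·V)                       (molar reaction enthalpy)
    [S](t) = [S]₀ − Q(t)/(ΔH·V)             (remaining substrate)
    v(t) = (dQ/dt) / (ΔH·V)                 (reaction rate)

preceded by first-order instrument-response removal,
P_true = P_meas + τ·dP_meas/dt, and followed by induction-period
trimming and optional k-point binning.

**Product-inhibition kinetics.** Rates are fitted to the steady-state
law with a competitive-type product term, the product affinity Kp held
fixed at an independently measured dissociation constant:

    v = Vmax·[S] / ( Km·(1 + [P]/Kp) + [S] ),   [P] = [P]₀ + [S]₀ − [S]

giving Km, Vmax and kcat = Vmax/[E].

**Same-excess reaction progress kinetic analysis.** Two runs sharing
[A]₀ − [B]₀ = [excess] represent one reaction entered at different
conversions; overlay of their rate-vs-substrate curves excludes product
inhibition and catalyst deactivation, divergence reveals one of them,
and a product-spiked control discriminates the two. `calokin` replaces
the visual judgement with an rms relative-deviation metric and an
explicit classifier.

**Single-site ITC binding.** The Wiseman isotherm: the fraction of
sites bound Θᵢ after injection i solves

    Θ² − Θ·(1 + Xᵢ/(nMᵢ) + Kd/(nMᵢ)) + Xᵢ/(nMᵢ) = 0

with fixed-cell displacement bookkeeping, dilution-heat subtraction,
least-squares fitting of (n, Kd, ΔH) with the low-c rule (n held at 1
when c = n·M/Kd < 5), and the derived ΔG = R·T·ln Kd and TΔS = ΔH − ΔG.

**Synthetic data.** A generator emulates both experiment types — the
progress ODE with instrument response, mixing transient and noise, and
Wiseman-model titrations with blanks — with ground-truth sidecars, so
every stage is testable without instrument data.

## Worked example

Simulate the default experiment set (a same-excess pair at
excess = 24 μM with B₀ = 16 and 40 μM, a product-spiked control, and a
1 μl + 18 × 2 μl titration) and analyse it:

```sh
calokin simulate --out runs/ --seed 7
calokin fit-kinetics runs/high.csv --design excess_allylic
```

```json
{
  "km_uM": 1.1116198684879564,
  "kcat_per_s": 0.8992010864301077,
  "vmax_uM_per_s": 0.4046404888935484,
  "kp_fixed_uM": 6.0,
  "dh_kcal_mol": -22.59289610173647,
  "n_points": 235,
  "converged": true
}
```

Km ≈ 1.11 μM and kcat ≈ 0.90 s⁻¹ recover the generator's truth
(1.1 μM, 0.90 s⁻¹) from a noisy trace. The same-excess comparison

```sh
calokin rpka --high runs/high.csv --low runs/low.csv --spiked runs/spiked.csv
```

reports `"classification": "product_inhibition"`: the pair diverges
(rms relative deviation ≈ 0.37, the high-concentration run slower)
while the spiked control overlays the high run (rms ≈ 0.02) — product
inhibition, not enzyme deactivation. Finally

```sh
calokin fit-binding runs/titration.csv --blank runs/blank.csv
calokin thermo --kd-uM 5.3 --dh-kcal-mol -5.5
```

return Kd ≈ 5.37 μM, n ≈ 1.12, ΔH ≈ −5.5 kcal/mol for the titration,
and TΔS = 1.8 kcal/mol for the thermodynamic decomposition at 30 °C —
binding driven by both enthalpy and entropy.

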