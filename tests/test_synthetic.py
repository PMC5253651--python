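"""Generator correctness: ODE integration against an independent RK4
oracle, heat conservation by construction, determinism, and full-loop
parameter recovery."""

import math

import numpy as np
import pytest

import calokin as ck
from calokin.io import write_thermogram, write_titration


def rk4_time_to_half(d, k, dt=0.001):
    """Independent fixed-step RK4 integration of dS/dt = −v; returns the
    time at which S crosses S0/2 (linear interpolation)."""
    def f(S):
        P = d.p0 + (d.b0 - S)
        return -ck.rate_product_inhibition(max(S, 0.0), max(P, 0.0), k)
    S, t = d.b0, 0.0
    target = d.b0 / 2.0
    while S > target:
        S_prev, t_prev = S, t
        k1 = f(S)
        k2 = f(S + dt / 2 * k1)
        k3 = f(S + dt / 2 * k2)
        k4 = f(S + dt * k3)
        S = S + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return t_prev + dt * (S_prev - target) / (S_prev - S)


class TestProgressOde:
    def test_zero_vmax_leaves_substrate_untouched(self):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        k = ck.KineticParams(vmax=0.0, km=1.1e-6, kp=6e-6, dh_rxn=-22.5)
        curve, _ = ck.progress_ode(d, k)
        assert np.all(curve.S == 40e-6)

    def test_saturated_zero_order_segment(self):
        # S >> Km and no product term: d[S]/dt ≈ −Vmax
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        k = ck.KineticParams(vmax=0.405e-6, km=0.01e-6, kp=math.inf)
        curve, _ = ck.progress_ode(d, k)
        seg = (curve.S > 10e-6) & (curve.S < 35e-6)
        slope = np.gradient(curve.S[seg], curve.t[seg])
        assert slope == pytest.approx(-0.405e-6, rel=1e-2)

    def test_half_completion_time_matches_rk4_oracle(self, paper_kinetics):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        curve, _ = ck.progress_ode(d, paper_kinetics)
        t_half = np.interp(-20e-6, -curve.S, curve.t)  # S decreasing
        t_half_rk4 = rk4_time_to_half(d, paper_kinetics)
        assert t_half == pytest.approx(t_half_rk4, rel=1e-3)

    def test_mechanism_labels_consistent(self, paper_kinetics, mm_kinetics):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        assert ck.progress_ode(d, paper_kinetics)[1].mechanism \
            == "product_inhibition"
        assert ck.progress_ode(d, mm_kinetics)[1].mechanism == "none"
        assert ck.progress_ode(d, mm_kinetics, decay_rate=0.005)[1].mechanism \
            == "deactivation"


class TestSimulateAssay:
    def test_no_enzyme_gives_flat_trace(self, mm_kinetics):
        from dataclasses import replace
        d = ck.AssayDesign(enzyme=0.0, a0=400e-6, b0=40e-6)
        k = replace(mm_kinetics, vmax=0.0, kcat=0.0, enzyme=0.0)
        g, _ = ck.simulate_assay(d, k, noise=None)
        assert np.abs(g.power).max() == 0.0

    def test_heat_conservation_before_noise(self, paper_kinetics):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        g, _ = ck.simulate_assay(d, paper_kinetics, tau=10.0, noise=None)
        _, q_total = ck.integrate_heat(g)
        expected = 40e-6 * 204.1e-6 * (-22.5e3)
        assert q_total == pytest.approx(expected, rel=5e-3)

    def test_enthalpy_recovered_from_noiseless_run(self, paper_kinetics):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        g, _ = ck.simulate_assay(d, paper_kinetics, tau=10.0, noise=None)
        proc = ck.process_thermogram(g, tau=10.0)
        assert proc.dh == pytest.approx(-22.5, rel=5e-3)

    def test_same_excess_pair_diverges_with_high_run_slower(
            self, same_excess_pair, paper_kinetics):
        sims = ck.simulate_same_excess(same_excess_pair, paper_kinetics,
                                       noise=None, spiked=False)
        profs = {k: ck.process_thermogram(
            g, tau=10.0, cutoff=g.meta.injection_end + 5.0).profile
            for k, (g, _) in sims.items()}
        r = ck.overlay_metric(profs["low"], profs["high"], rate_floor_frac=0.5)
        assert r.verdict == "divergent"
        assert r.signed_mean_dev < 0

    def test_excess_conserved_along_simulated_pair(self, same_excess_pair,
                                                   paper_kinetics):
        for d in (same_excess_pair.run_high, same_excess_pair.run_low):
            curve, _ = ck.progress_ode(d, paper_kinetics)
            A = d.a0 - (d.b0 - curve.S)  # 1:1 stoichiometry
            dev = np.abs((A - curve.S) - same_excess_pair.excess)
            assert dev.max() < 1e-6 * same_excess_pair.excess


class TestSimulateTitration:
    def test_zero_enthalpy_gives_noise_only_heats(self):
        b = ck.BindingParams(n=1.0, kd=5e-6, dh=1e-30, T=303.15)
        t, blank, _ = ck.simulate_titration(ck.paper_schedule(), b)
        assert np.abs(t.heats).max() < 1e-9

    def test_weak_inflection_c_value(self, fpp_binding):
        # n·M/Kd = 1.12·100/5.3 ≈ 21: sigmoidal but with a soft inflection
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        c = fpp_binding.n * sch.cell_conc / fpp_binding.kd
        assert c == pytest.approx(21.1, abs=0.1)
        t, _, _ = ck.simulate_titration(sch, fpp_binding)
        mag = np.abs(t.heats[1:])
        assert mag[0] > mag[-1]                      # isotherm decays
        assert mag.min() > 0.001 * mag.max()         # but no hard step

    def test_full_loop_binding_recovery_noiseless(self, fpp_binding):
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        t, blank, truth = ck.simulate_titration(sch, fpp_binding,
                                                dilution_offset_ucal=0.15)
        res = ck.fit_binding(ck.subtract_dilution(t, blank))
        b = truth.binding_params
        assert res.params.n == pytest.approx(b.n, rel=5e-3)
        assert res.params.kd == pytest.approx(b.kd, rel=5e-3)
        assert res.params.dh == pytest.approx(b.dh, rel=5e-3)


class TestDeterminism:
    def test_identical_seeds_give_identical_files(self, tmp_path,
                                                  paper_kinetics,
                                                  fpp_binding):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        files = []
        for i in (1, 2):
            noise = ck.NoiseModel(power_sd=0.02, heat_frac=0.02, seed=123)
            g, _ = ck.simulate_assay(d, paper_kinetics, noise=noise)
            t, blank, _ = ck.simulate_titration(
                ck.paper_schedule(syringe_conc=1.5e-3), fpp_binding,
                noise=noise)
            pg, pt = tmp_path / f"g{i}.csv", tmp_path / f"t{i}.csv"
            write_thermogram(g, pg)
            write_titration(t, pt)
            files.append((pg.read_bytes(), pt.read_bytes()))
        assert files[0] == files[1]

    def test_different_seeds_differ(self, paper_kinetics):
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        g1, _ = ck.simulate_assay(d, paper_kinetics,
                                  noise=ck.NoiseModel(seed=1))
        g2, _ = ck.simulate_assay(d, paper_kinetics,
                                  noise=ck.NoiseModel(seed=2))
        assert not np.array_equal(g1.power, g2.power)


class TestFullLoopKinetics:
    def test_noiseless_recovery_through_pipeline(self, paper_kinetics):
        # a long post-reaction tail so the trace truly runs to completion;
        # otherwise the truncated remainder (~0.002 μM) dominates the error
        d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
        g, _ = ck.simulate_assay(d, paper_kinetics, tau=10.0, noise=None,
                                 tail_s=200.0)
        proc = ck.process_thermogram(g, tau=10.0)
        res = ck.fit_kinetics(proc.profile, enzyme=450e-9, s0=g.meta.s0,
                              p0=0.0, kp=6e-6)
        assert res.km == pytest.approx(1.1e-6, rel=1e-3)
        assert res.vmax == pytest.approx(paper_kinetics.vmax, rel=1e-3)

    def test_median_recovery_under_power_noise(self, paper_kinetics):
        km_err, vmax_err = [], []
        for seed in range(50):
            d = ck.AssayDesign(enzyme=450e-9, a0=400e-6, b0=40e-6)
            noise = ck.NoiseModel(power_sd=0.0186, heat_frac=0.0, seed=seed)
            g, _ = ck.simulate_assay(d, paper_kinetics, tau=10.0, noise=noise)
            proc = ck.process_thermogram(g, tau=10.0)
            res = ck.fit_kinetics(proc.profile, enzyme=450e-9, s0=g.meta.s0,
                                  p0=0.0, kp=6e-6)
            km_err.append(abs(res.km - 1.1e-6) / 1.1e-6)
            vmax_err.append(abs(res.vmax - paper_kinetics.vmax)
                            / paper_kinetics.vmax)
        assert np.median(km_err) <= 0.05
        assert np.median(vmax_err) <= 0.05
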