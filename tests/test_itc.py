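"""ITC single-site binding: displacement bookkeeping, Wiseman forward
model vs an independent equilibrium solver, dilution subtraction and
parameter recovery."""

import numpy as np
import pytest
from scipy.optimize import brentq

import calokin as ck
from calokin.errors import FitFailureError, InvalidInputError
from calokin.itc import injection_concentrations, wiseman_theta

T_K = 303.15


def theta_by_free_ligand_bisection(M, X, n, kd):
    """Independent oracle: solve X = L + n·M·L/(Kd+L) for free ligand L."""
    if X == 0:
        return 0.0
    L = brentq(lambda L: L + n * M * L / (kd + L) - X, 0.0, X,
               xtol=1e-30, rtol=1e-15)
    return L / (kd + L)


class TestInjectionConcentrations:
    def test_small_injection_first_order_limit(self):
        t = ck.Titration(cell_volume=204.1e-6, cell_conc=100e-6,
                         syringe_conc=1.5e-3,
                         injection_volumes=np.full(10, 1e-9))
        M, X = injection_concentrations(t)
        # ligand ≈ X_syr·ΔV/V0 to first order, macromolecule ≈ M0
        assert X[0] == pytest.approx(1.5e-3 * 1e-9 / 204.1e-6, rel=1e-4)
        assert M[0] == pytest.approx(100e-6, rel=1e-5)

    def test_monotone_directions(self):
        sch = ck.paper_schedule()
        M, X = injection_concentrations(sch)
        assert np.all(np.diff(M) < 0) and np.all(np.diff(X) > 0)

    def test_against_stepwise_mixing_oracle(self):
        sch = ck.paper_schedule()
        # inject in 0.01 μl slices: add, mix, expel
        V0, M, X = sch.cell_volume, sch.cell_conc, 0.0
        for dv in sch.injection_volumes:
            n_slices = 200
            sl = dv / n_slices
            for _ in range(n_slices):
                M = M * V0 / (V0 + sl)
                X = (X * V0 + sch.syringe_conc * sl) / (V0 + sl)
        M_end, X_end = (a[-1] for a in injection_concentrations(sch))
        assert M_end == pytest.approx(M, rel=5e-3)
        assert X_end == pytest.approx(X, rel=5e-3)

    def test_overfilling_rejected(self):
        t = ck.Titration(cell_volume=10e-6, cell_conc=1e-4, syringe_conc=1e-3,
                         injection_volumes=np.full(6, 2e-6))
        with pytest.raises(InvalidInputError):
            injection_concentrations(t)


class TestWisemanForwardModel:
    def test_reference_theta(self):
        # n=1, M=100 μM, Kd=5.3 μM, X=50 μM → Θ = 0.456
        th = wiseman_theta(100e-6, 50e-6, 1.0, 5.3e-6)
        assert float(th) == pytest.approx(0.456, abs=5e-4)

    def test_zero_enthalpy_gives_zero_heats(self):
        sch = ck.paper_schedule()
        b = ck.BindingParams(n=1.0, kd=5e-6, dh=1e-30, T=T_K)
        assert np.abs(ck.wiseman_heats(sch, b)).max() < 1e-12

    def test_tight_binding_stoichiometric_limit(self):
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        b = ck.BindingParams(n=1.0, kd=1e-12, dh=-5.0, T=T_K)
        # displacement-corrected heats: dilution of the bound complex is
        # compensated, so the post-saturation heats vanish
        heats = ck.wiseman_heats(sch, b)
        # pre-saturation: each injection's heat ≈ moles injected × ΔH
        moles_2ul = 1.5e-3 * 2e-6
        expected = moles_2ul * (-5.0 * 1000.0) * 1e6  # μcal
        assert heats[1] == pytest.approx(expected, rel=2e-2)
        assert abs(heats[-1]) < 0.02 * abs(heats[1])  # post-saturation

    def test_agreement_with_bisection_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.uniform(0.5, 2.0)
            kd = 10 ** rng.uniform(-8, -3)
            M = 10 ** rng.uniform(-6, -3)
            X = 10 ** rng.uniform(-7, -2)
            th = float(wiseman_theta(M, X, n, kd))
            th_oracle = theta_by_free_ligand_bisection(M, X, n, kd)
            assert th == pytest.approx(th_oracle, rel=1e-8, abs=1e-12)

    def test_theta_bounded_and_monotone_over_titration(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            sch = ck.paper_schedule(syringe_conc=10 ** rng.uniform(-4, -2))
            n = rng.uniform(0.5, 2.0)
            kd = 10 ** rng.uniform(-8, -4)
            M, X = injection_concentrations(sch)
            th = wiseman_theta(M, X, n, kd)
            assert np.all((th >= 0) & (th <= 1))
            assert np.all(np.diff(th) >= -1e-12)

    def test_uncorrected_heats_telescope_to_final_heat(self, fpp_binding):
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        heats = ck.wiseman_heats(sch, fpp_binding,
                                 displacement_correction=False)
        M, X = injection_concentrations(sch)
        th = wiseman_theta(M, X, fpp_binding.n, fpp_binding.kd)
        q_final = (fpp_binding.n * th[-1] * M[-1]
                   * fpp_binding.dh * 1000.0 * sch.cell_volume * 1e6)
        assert heats.sum() == pytest.approx(q_final, rel=1e-9)


class TestDilutionSubtraction:
    def test_identical_blank_zeroes_heats(self, fpp_binding):
        t, _, _ = ck.simulate_titration(ck.paper_schedule(), fpp_binding)
        assert np.all(ck.subtract_dilution(t, t).heats == 0.0)

    def test_zero_blank_leaves_heats(self, fpp_binding):
        from dataclasses import replace
        t, _, _ = ck.simulate_titration(ck.paper_schedule(), fpp_binding)
        blank = replace(t, heats=np.zeros(t.n_injections))
        assert np.array_equal(ck.subtract_dilution(t, blank).heats, t.heats)

    def test_constant_offset_recovered_exactly(self, fpp_binding):
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        t, blank, _ = ck.simulate_titration(sch, fpp_binding,
                                            dilution_offset_ucal=0.2)
        clean = ck.wiseman_heats(sch, fpp_binding)
        assert ck.subtract_dilution(t, blank).heats == pytest.approx(
            clean, abs=1e-12)

    def test_schedule_mismatch_rejected(self, fpp_binding):
        from dataclasses import replace
        t, blank, _ = ck.simulate_titration(ck.paper_schedule(), fpp_binding)
        bad = replace(blank,
                      injection_volumes=blank.injection_volumes * 1.05)
        with pytest.raises(InvalidInputError):
            ck.subtract_dilution(t, bad)


class TestBindingFit:
    def test_noiseless_recovery(self, fpp_binding):
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        t, blank, _ = ck.simulate_titration(sch, fpp_binding,
                                            dilution_offset_ucal=0.1)
        res = ck.fit_binding(ck.subtract_dilution(t, blank))
        assert res.params.n == pytest.approx(1.12, rel=5e-3)
        assert res.params.kd == pytest.approx(5.3e-6, rel=5e-3)
        assert res.params.dh == pytest.approx(-5.5, rel=5e-3)
        assert not res.n_fixed

    def test_low_c_rule_fixes_stoichiometry(self, dmapp_binding):
        sch = ck.paper_schedule(syringe_conc=1.5e-3)
        t, blank, _ = ck.simulate_titration(sch, dmapp_binding)
        res = ck.fit_binding(ck.subtract_dilution(t, blank))
        assert res.n_fixed and res.params.n == 1.0
        assert res.c < 5.0
        assert res.params.kd == pytest.approx(43.7e-6, rel=5e-3)

    def test_all_zero_heats_is_fit_failure(self):
        from dataclasses import replace
        sch = ck.paper_schedule()
        t = replace(sch, heats=np.zeros(sch.n_injections))
        with pytest.raises(FitFailureError):
            ck.fit_binding(t)

    def test_too_few_injections_rejected(self, fpp_binding):
        sch = ck.Titration(cell_volume=204.1e-6, cell_conc=100e-6,
                           syringe_conc=1.5e-3,
                           injection_volumes=np.full(5, 2e-6))
        t, _, _ = ck.simulate_titration(sch, fpp_binding)
        with pytest.raises(InvalidInputError):
            ck.fit_binding(t)

    def test_recovery_under_noise_across_c_range(self):
        # 2% heat noise; c drawn in [2, 50] via Kd at fixed 100 μM cell
        errors = []
        rng = np.random.default_rng(2024)
        for seed in range(50):
            c = rng.uniform(2.0, 50.0)
            kd = 100e-6 / c
            b = ck.BindingParams(n=1.0, kd=kd, dh=-6.0, T=T_K)
            sch = ck.paper_schedule(syringe_conc=1.5e-3)
            noise = ck.NoiseModel(heat_frac=0.02, seed=seed)
            t, blank, _ = ck.simulate_titration(sch, b, noise=noise)
            res = ck.fit_binding(ck.subtract_dilution(t, blank))
            errors.append(abs(res.params.kd - kd) / kd)
        assert np.median(errors) <= 0.10

    def test_triplicate_spread_matches_reported_order(self, fpp_binding):
        # triplicate at 2% noise: s.d. of Kd of the same order as the
        # reported ±0.4 μM
        kds = []
        for seed in (1, 2, 3):
            sch = ck.paper_schedule(syringe_conc=1.5e-3)
            t, blank, _ = ck.simulate_titration(
                sch, fpp_binding, noise=ck.NoiseModel(heat_frac=0.02, seed=seed))
            kds.append(ck.fit_binding(ck.subtract_dilution(t, blank)).params.kd)
        sd_um = np.std(kds, ddof=1) * 1e6
        assert 0.0 < sd_um < 1.6  # same order as ±0.4
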