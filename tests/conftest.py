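"""Shared fixtures: the study conditions used across the suite.

The default kinetic and binding parameter sets are the ones the
synthetic generator treats as its reference conditions (enzyme 450 nM,
kcat 0.90 s⁻¹, Km 1.1 μM, Kp 6 μM, ΔH_rxn −22.5 kcal mol⁻¹; ITC at
100 μM enzyme, 30 °C, 1 μl + 18 × 2 μl schedule).
"""

import math

import pytest

import calokin as ck

T_K = 303.15  # 30 °C


@pytest.fixture(scope="session")
def paper_kinetics() -> ck.KineticParams:
    """Product-inhibited kinetics at the reference conditions."""
    return ck.KineticParams.from_kcat(kcat=0.90, enzyme=450e-9, km=1.1e-6,
                                      kp=6e-6, dh_rxn=-22.5)


@pytest.fixture(scope="session")
def mm_kinetics() -> ck.KineticParams:
    """Same conditions without the product term (Kp = inf)."""
    return ck.KineticParams.from_kcat(kcat=0.90, enzyme=450e-9, km=1.1e-6,
                                      kp=math.inf, dh_rxn=-22.5)


@pytest.fixture(scope="session")
def assay_template() -> ck.AssayDesign:
    return ck.AssayDesign(enzyme=450e-9, a0=1.0, b0=0.5, temperature=T_K)


@pytest.fixture(scope="session")
def same_excess_pair(assay_template) -> ck.SameExcessPair:
    """Default pair: excess 24 μM, B0 levels 16 and 40 μM."""
    pairs = ck.design_same_excess(24e-6, [16e-6, 40e-6], assay_template)
    return pairs[0]


@pytest.fixture(scope="session")
def fpp_binding() -> ck.BindingParams:
    """Product binding, no divalent metal: n=1.12, Kd=5.3 μM, ΔH=−5.5."""
    return ck.BindingParams(n=1.12, kd=5.3e-6, dh=-5.5, T=T_K)


@pytest.fixture(scope="session")
def gpp_mg_binding() -> ck.BindingParams:
    """Allylic substrate with Mg²⁺: n=0.79, Kd=2.1 μM, ΔH=−7.7."""
    return ck.BindingParams(n=0.79, kd=2.1e-6, dh=-7.7, T=T_K)


@pytest.fixture(scope="session")
def dmapp_binding() -> ck.BindingParams:
    """Weak binder (low c): n held at 1, Kd=43.7 μM, ΔH=−4.5."""
    return ck.BindingParams(n=1.0, kd=43.7e-6, dh=-4.5, T=T_K)
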