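"""Unit tests for the single-compartment membrane physics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pumpleak import (
    BathComposition,
    CompartmentState,
    DomainError,
    ImpermeantPool,
    MembraneParams,
    hydrostatic_pressure,
    ion_derivatives,
    kcc2_flux,
    membrane_voltage,
    nernst_potential,
    osmolarity,
    pump_flux,
    volume_flux,
)
from pumpleak.constants import CONSTANTS, MM, UM
from pumpleak.dynamics import _derivs


def _state(na=14.0, k=122.9, cl=5.2, x=None, z=-0.85, radius_um=5.0,
           length_um=25.0):
    if x is None:
        x = (na + k - cl) / -z
    return CompartmentState(
        na=na * MM, k=k * MM, cl=cl * MM,
        pool=ImpermeantPool.single(x * MM, z),
        radius=radius_um * UM, length=length_um * UM)


class TestNernstPotential:
    @pytest.mark.parametrize("c_i, c_o, valence, expected_V", [
        (122.9, 3.5, +1, -0.0951),   # potassium at the default steady state
        (5.2, 119.0, -1, -0.0837),   # chloride at the printed concentrations
    ])
    def test_reference_values(self, c_i, c_o, valence, expected_V):
        e = nernst_potential(c_i * MM, c_o * MM, valence)
        assert e == pytest.approx(expected_V, abs=2e-4)

    @given(c=st.floats(1e-4, 1.0), z=st.sampled_from([-2, -1, 1, 2]))
    @settings(max_examples=25, deadline=None)
    def test_equal_concentrations_give_zero(self, c, z):
        assert nernst_potential(c, c, z) == 0.0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            nernst_potential(0.0, 0.1, 1)
        with pytest.raises(DomainError):
            nernst_potential(0.1, -0.1, -1)
        with pytest.raises(DomainError):
            nernst_potential(0.1, 0.1, 0)


class TestMembraneVoltage:
    def test_electroneutral_state_is_zero(self):
        # zero up to the float rounding of the balancing pool concentration
        assert membrane_voltage(_state(), 2e-4) == pytest.approx(0.0, abs=1e-11)

    def test_reference_offset(self):
        # a net charge concentration of -6.03 uM over the default geometry
        # and capacitance yields the resting potential near -72.6 mV
        x = (14.0 + 122.9 - 5.2 + 6.03e-3) / 0.85
        s = _state(x=x)
        v = membrane_voltage(s, 2e-4)
        assert v == pytest.approx(-0.0727, abs=2e-4)

    def test_linearity_in_net_charge(self):
        x1 = (14.0 + 122.9 - 5.2 + 4e-3) / 0.85
        x2 = (14.0 + 122.9 - 5.2 + 8e-3) / 0.85
        v1 = membrane_voltage(_state(x=x1), 2e-4)
        v2 = membrane_voltage(_state(x=x2), 2e-4)
        assert v2 == pytest.approx(2.0 * v1, rel=1e-9)


class TestOsmolarity:
    def test_default_bath_sums_to_297(self):
        assert osmolarity(BathComposition.from_mM()) == pytest.approx(0.297)

    def test_default_intracellular_matches_bath(self):
        s = _state(x=154.9)
        assert osmolarity(s) == pytest.approx(0.2970, abs=2e-4)

    def test_counts_species_irrespective_of_valence(self):
        s = _state(x=100.0)
        s2 = _state(x=100.0, z=-0.2)
        assert osmolarity(s) == pytest.approx(osmolarity(s2))


class TestPumpFlux:
    def test_cubic_reference_value(self):
        assert pump_flux(14 * MM, 145 * MM, 0.1) == pytest.approx(9.0e-5,
                                                                  rel=1e-3)

    @pytest.mark.parametrize("na_i, expected", [(0.0, 0.0), (145 * MM, 0.1)])
    def test_edge_ratios(self, na_i, expected):
        assert pump_flux(na_i, 145 * MM, 0.1) == pytest.approx(expected)

    def test_fixed_mode_ignores_sodium(self):
        assert pump_flux(1 * MM, 145 * MM, 0.1, "fixed", 4.2e-5) == 4.2e-5
        assert pump_flux(99 * MM, 145 * MM, 0.1, "fixed", 4.2e-5) == 4.2e-5

    def test_negative_sodium_rejected(self):
        with pytest.raises(DomainError):
            pump_flux(-1e-3, 145 * MM, 0.1)


class TestKCC2Flux:
    def test_zero_at_equilibrium_and_zero_conductance(self):
        assert kcc2_flux(-0.09, -0.09, 2e-3) == 0.0
        assert kcc2_flux(-0.095, -0.080, 0.0) == 0.0

    def test_reference_value(self):
        j = kcc2_flux(-0.0951, -0.0838, 2e-3)
        assert j == pytest.approx(-2.26e-5, rel=1e-3)


class TestHydrostaticPressure:
    def test_zero_at_or_below_resting_radius(self):
        assert hydrostatic_pressure(5e-5, 5e-5, 25.0) == 0.0
        assert hydrostatic_pressure(4e-5, 5e-5, 25.0) == 0.0

    def test_reference_value(self):
        hp = hydrostatic_pressure(1.1 * 5e-5, 5e-5, 25.0)
        assert hp == pytest.approx(4 * math.pi * 25 * (1 - 1 / 1.1), rel=1e-12)
        assert hp == pytest.approx(28.56, abs=0.01)

    def test_saturates_at_large_radius(self):
        assert hydrostatic_pressure(1e3, 5e-5, 25.0) == pytest.approx(
            4 * math.pi * 25.0, rel=1e-6)


class TestVolumeFlux:
    def test_zero_at_osmotic_balance(self, default_setup):
        _, params, bath = default_setup
        s = _state(x=154.9)  # sums exactly to the bath osmolarity
        assert osmolarity(s) == pytest.approx(bath.osmolarity, abs=1e-12)
        assert volume_flux(s, bath, params) == pytest.approx(0.0, abs=1e-20)

    def test_hypertonic_cell_swells(self, default_setup):
        _, params, bath = default_setup
        assert volume_flux(_state(x=200.0), bath, params) > 0
        assert volume_flux(_state(x=100.0), bath, params) < 0

    def test_tension_balances_sustained_osmotic_excess(self, default_setup):
        # the tension term saturates at 4 pi k_m / RT ~ 12 mM, the order of
        # the ~10 mM differential the membrane is parameterized to hold
        _, params, bath = default_setup
        p = params.copy()
        p.volume_mode = "tension"
        p.r_a = 5.0 * UM / 1.1  # swollen 10% beyond rest
        saturation_mM = 4 * math.pi * p.k_m / CONSTANTS.RT_pressure * 1e3
        assert saturation_mM == pytest.approx(12.2, abs=0.1)
        s = _state(x=154.9)
        gap = (hydrostatic_pressure(s.radius, p.r_a, p.k_m)
               / CONSTANTS.RT_pressure)
        assert gap * 1e3 == pytest.approx(1.107, abs=0.01)
        s_bal = _state(x=154.9 + gap / MM)
        assert volume_flux(s_bal, bath, p) == pytest.approx(0.0, abs=1e-18)


class TestIonDerivatives:
    def test_balance_at_solved_steady_state(self, default_setup,
                                            default_steady):
        _, params, bath = default_setup
        ss = default_steady
        dna, dk, dcl = ion_derivatives(ss.state, params, bath, ss.jp,
                                       ss.jkcc2, dwdt=0.0)
        for d in (dna, dk, dcl):
            assert abs(d) < 1e-7 * MM  # well under 1e-4 mM/s

    def test_all_transport_off_is_inert(self, default_setup):
        _, params, bath = default_setup
        p = MembraneParams(g_na=0, g_k=0, g_cl=0, g_kcc2=0, pump_rate=0,
                           c_m=params.c_m)
        dna, dk, dcl = ion_derivatives(_state(), p, bath, 0.0, 0.0, 0.0)
        assert (dna, dk, dcl) == (0.0, 0.0, 0.0)

    def test_pure_dilution_is_negative(self, default_setup):
        _, params, bath = default_setup
        p = MembraneParams(g_na=0, g_k=0, g_cl=0, g_kcc2=0, pump_rate=0,
                           c_m=params.c_m)
        s = _state()
        dna, dk, dcl = ion_derivatives(s, p, bath, 0.0, 0.0,
                                       dwdt=s.volume * 1e-3)
        assert dna < 0 and dk < 0 and dcl < 0


class TestImpermeantPool:
    def test_mean_charge_is_weighted_mean(self):
        # alpha molecules of charge -1 plus beta of charge 0
        alpha, beta = 3.0, 2.0
        pool = ImpermeantPool([(alpha * MM, -1.0), (beta * MM, 0.0)])
        assert pool.mean_charge == pytest.approx(-alpha / (alpha + beta))

    def test_empty_pool_mean_charge_is_error(self):
        with pytest.raises(DomainError):
            ImpermeantPool([(0.0, -1.0)]).mean_charge

    def test_scaling_conserves_composition(self):
        pool = ImpermeantPool([(0.1, -1.0), (0.05, -0.5)])
        scaled = pool.scaled(0.5)
        assert scaled.mean_charge == pytest.approx(pool.mean_charge)
        assert scaled.total_concentration == pytest.approx(
            0.5 * pool.total_concentration)

    def test_adding_merges_matching_valence(self):
        pool = ImpermeantPool.single(0.1, -0.85)
        merged = pool.with_added(0.02, -0.85)
        assert len(merged.concentrations) == 1
        grown = pool.with_added(0.02, -1.5)
        assert len(grown.concentrations) == 2

    def test_invariants(self):
        with pytest.raises(DomainError):
            ImpermeantPool([(-0.1, -1.0)])


@given(
    na=st.floats(5.0, 50.0), k=st.floats(60.0, 160.0),
    cl=st.floats(2.0, 80.0), x=st.floats(50.0, 250.0),
    z=st.floats(-1.5, -0.3), r_um=st.floats(0.3, 8.0),
)
@settings(max_examples=60, deadline=None)
def test_fast_path_matches_reference_operations(na, k, cl, x, z, r_um,
                                                default_setup):
    """The integrator's scalar fast path must agree with the public
    physics operations composed step by step."""
    _, params, bath = default_setup
    s = _state(na=na, k=k, cl=cl, x=x, z=z, radius_um=r_um)
    c = CONSTANTS
    out = _derivs(
        s.na, s.k, s.cl, s.pool.total_concentration,
        s.pool.charge_concentration, s.radius, s.length,
        params.g_na, params.g_k, params.g_cl, params.g_kcc2,
        params.pump_rate, False, 0.0, params.c_m, params.v_w, params.p_w,
        params.k_m, params.r_a, False,
        bath.na, bath.k, bath.cl, bath.osmolarity,
        c.F, c.RTF, c.RT_pressure)
    dna_f, dk_f, dcl_f, dw_f, vm_f = out[0], out[1], out[2], out[3], out[4]
    jp = pump_flux(s.na, bath.na, params.pump_rate)
    e_k = nernst_potential(s.k, bath.k, +1)
    e_cl = nernst_potential(s.cl, bath.cl, -1)
    jk = kcc2_flux(e_k, e_cl, params.g_kcc2)
    dw = volume_flux(s, bath, params)
    dna, dk, dcl = ion_derivatives(s, params, bath, jp, jk, dw)
    assert vm_f == pytest.approx(membrane_voltage(s, params.c_m), rel=1e-12,
                                 abs=1e-15)
    assert dw_f == pytest.approx(dw, rel=1e-12, abs=1e-25)
    assert dna_f == pytest.approx(dna, rel=1e-12, abs=1e-18)
    assert dk_f == pytest.approx(dk, rel=1e-12, abs=1e-18)
    assert dcl_f == pytest.approx(dcl, rel=1e-12, abs=1e-18)
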