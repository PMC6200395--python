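"""Tests of the protocol engine: pump ramps, impermeant manipulations,
bath swaps and the experiment registry."""

import numpy as np
import pytest

from pumpleak import (
    DomainError,
    SimulationConfig,
    extracellular_swap,
    extracellular_swap_event,
    fix_pump_event,
    inject_impermeant,
    inject_impermeant_event,
    pump_ramp_event,
    pump_ramp_value,
    ramp_mean_charge_event,
    run_experiment,
    simulate,
    solve_steady_state,
    with_mean_charge,
)
from pumpleak.core import BathComposition
from pumpleak.constants import MM
from pumpleak.protocols import ProtocolEvent

_MIN = 60_000.0


def _settle(duration_min=60.0):
    return SimulationConfig(duration_ms=duration_min * _MIN,
                            record_every_ms=10_000.0)


class TestPureOperations:
    def test_injection_rate_zero_is_identity(self, default_steady):
        s = default_steady.state
        out = inject_impermeant(s, 0.0, -1.0, dt_s=1.0)
        assert out.pool.total_concentration == pytest.approx(
            s.pool.total_concentration)
        assert out.pool.mean_charge == pytest.approx(s.pool.mean_charge)

    def test_injection_moves_mean_charge_by_weighted_mean(self,
                                                          default_steady):
        s = default_steady.state
        out = inject_impermeant(s, 0.1, -1.5, dt_s=60.0)  # +6 mM
        c0 = s.pool.total_concentration
        added = 6.0 * MM
        expected = (c0 * s.pool.mean_charge + added * -1.5) / (c0 + added)
        assert out.pool.mean_charge == pytest.approx(expected, rel=1e-9)

    def test_with_mean_charge_preserves_moles(self, default_steady):
        s = default_steady.state
        out = with_mean_charge(s, -1.0)
        assert out.pool.mean_charge == pytest.approx(-1.0)
        assert out.pool.total_concentration == pytest.approx(
            s.pool.total_concentration)
        same = with_mean_charge(s, s.pool.mean_charge)
        assert same.pool.valences == pytest.approx(s.pool.valences)

    def test_extracellular_swap_preserves_bath_invariants(self):
        bath = BathComposition.from_mM()
        out = extracellular_swap(bath, 20.0)
        assert out.osmolarity == pytest.approx(bath.osmolarity)
        assert out.charge_concentration == pytest.approx(
            bath.charge_concentration)
        assert extracellular_swap(bath, 0.0).cl == bath.cl
        with pytest.raises(DomainError):
            extracellular_swap(bath, 120.0)  # would exhaust Cl_o

    def test_pump_ramp_value_limits(self):
        assert pump_ramp_value(0.1, 0.0, t_since_s=0.0, duration_s=900) == 0.1
        assert pump_ramp_value(0.1, 0.0, t_since_s=1.0, duration_s=0.0) == 0.0
        mid = pump_ramp_value(0.1, 0.0, t_since_s=180.0, duration_s=900.0)
        assert mid == pytest.approx(0.1 * np.exp(-1.0))

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(DomainError):
            ProtocolEvent(kind="teleport", start_ms=0.0)


class TestAmountOnlyManipulations:
    """Changing how much impermeant anion there is (not its mean charge)
    must not move the steady-state potentials."""

    def test_mean_charge_injection_is_reversible_in_potentials(
            self, default_setup, default_steady):
        _, params, bath = default_setup
        ev = inject_impermeant_event(0.1, start_ms=1 * _MIN,
                                     stop_ms=11 * _MIN)
        res = simulate(default_steady.state, params, bath, _settle(90.0),
                       [ev])
        assert res.steady
        for col in ("ecl_mV", "ek_mV", "vm_mV", "df_mV"):
            assert getattr(res, col)[-1] == pytest.approx(
                getattr(res, col)[0], abs=1e-2), col
        assert res.volume_pL[-1] > res.volume_pL[0] * 1.01
        # transient shifts do occur while the influx lasts
        during = np.searchsorted(res.time_ms, 6 * _MIN)
        assert abs(res.vm_mV[during] - res.vm_mV[0]) > 0.1

    def test_injection_then_removal_restores_original_fixed_point(
            self, default_setup, default_steady):
        _, params, bath = default_setup
        s0 = default_steady.state
        xm = s0.pool.total_concentration * s0.volume
        grown = solve_steady_state(params, bath, 1.3 * xm,
                                   s0.pool.mean_charge, s0.length)
        back = solve_steady_state(params, bath, xm, s0.pool.mean_charge,
                                  s0.length, guess=grown)
        assert back.vm == pytest.approx(default_steady.vm, abs=1e-9)
        assert back.state.cl == pytest.approx(s0.cl, rel=1e-7)
        assert back.state.volume == pytest.approx(s0.volume, rel=1e-7)

    def test_extracellular_swap_shifts_volume_not_potentials(
            self, default_setup, default_steady):
        _, params, bath = default_setup
        res = simulate(default_steady.state, params, bath,
                       SimulationConfig(duration_ms=150 * _MIN,
                                        record_every_ms=10_000.0,
                                        steady_tol=1e-7),
                       [extracellular_swap_event(20.0, at_ms=1 * _MIN)])
        assert res.steady
        # the bath swap leaves a ~0.014 mV residue in E_Cl and V_m (the
        # charge balance re-equilibrates against the new Cl_o); that is
        # "no persistent shift" at figure resolution, and the driving
        # force moves by an order of magnitude less still
        for col in ("ecl_mV", "vm_mV"):
            assert getattr(res, col)[-1] == pytest.approx(
                getattr(res, col)[0], abs=0.05), col
        assert res.df_mV[-1] == pytest.approx(res.df_mV[0], abs=5e-3)
        assert res.volume_pL[-1] < res.volume_pL[0]  # small shrinkage
        during = np.searchsorted(res.time_ms, 1.5 * _MIN)
        assert res.ecl_mV[during] > res.ecl_mV[0] + 1.0  # depolarizing blip


class TestMeanChargeManipulations:
    def test_charge_ramp_shifts_ecl_but_barely_df(self, default_setup,
                                                  default_steady):
        _, params, bath = default_setup
        ev = ramp_mean_charge_event(-1.0, start_ms=1 * _MIN,
                                    stop_ms=11 * _MIN)
        res = simulate(default_steady.state, params, bath, _settle(90.0),
                       [ev])
        assert res.steady
        assert res.z[-1] == pytest.approx(-1.0, abs=1e-6)
        assert res.ecl_mV[-1] - res.ecl_mV[0] < -1.5  # E_Cl hyperpolarizes
        assert res.vm_mV[-1] - res.vm_mV[0] < -1.5    # and so does V_m
        ddf = res.df_mV[-1] - res.df_mV[0]
        assert 0.05 < ddf < 0.3  # ~0.16 mV

    def test_charge_ramp_with_clamped_pump_leaves_df_unchanged(
            self, default_setup, default_steady):
        _, params, bath = default_setup
        events = [fix_pump_event(at_ms=0.0, jp=default_steady.jp),
                  ramp_mean_charge_event(-1.0, start_ms=1 * _MIN,
                                         stop_ms=11 * _MIN)]
        # relaxation is ~16x slower without the pump's Na+ feedback
        res = simulate(default_steady.state, params, bath, _settle(240.0),
                       events)
        assert res.steady
        assert abs(res.df_mV[-1] - res.df_mV[0]) < 1e-3

    def test_identity_ramp_is_identity(self, default_setup,
                                       default_steady):
        _, params, bath = default_setup
        ev = ramp_mean_charge_event(-0.85, start_ms=1000.0, stop_ms=2000.0)
        res = simulate(default_steady.state, params, bath,
                       SimulationConfig(duration_ms=5000.0,
                                        record_every_ms=1000.0,
                                        stop_when_steady=False), [ev])
        assert res.vm_mV[-1] == pytest.approx(res.vm_mV[0], abs=1e-6)


class TestPumpManipulations:
    def test_pump_off_swells_and_depolarizes_then_recovers(
            self, default_setup, default_steady):
        _, params, bath = default_setup
        off_at, ramp = 1 * _MIN, 3 * _MIN
        on_at = off_at + ramp + 10 * _MIN
        events = [pump_ramp_event("off", off_at, ramp),
                  pump_ramp_event("on", on_at, ramp)]
        res = simulate(default_steady.state, params, bath, _settle(120.0),
                       events)
        i_on = np.searchsorted(res.time_ms, on_at)
        # during the silent phase volume rises monotonically and V_m
        # depolarizes
        seg = res.volume_pL[np.searchsorted(res.time_ms, off_at + ramp):i_on]
        assert np.all(np.diff(seg) > 0)
        assert res.vm_mV[i_on - 1] > res.vm_mV[0] + 5.0
        # full recovery after reactivation
        assert res.steady
        assert res.vm_mV[-1] == pytest.approx(res.vm_mV[0], abs=1e-2)
        assert res.volume_pL[-1] == pytest.approx(res.volume_pL[0],
                                                  abs=1e-3)

    def test_sustained_pump_off_never_reaches_steady_state(
            self, default_setup, default_steady):
        _, params, bath = default_setup
        res = simulate(default_steady.state, params, bath,
                       SimulationConfig(duration_ms=30 * _MIN,
                                        record_every_ms=30_000.0,
                                        stop_when_steady=False),
                       [pump_ramp_event("off", 1 * _MIN, 3 * _MIN)])
        assert not res.steady
        assert res.volume_pL[-1] > res.volume_pL[0]
        # still growing at the end of the run
        assert res.volume_pL[-1] > res.volume_pL[-2]


class TestRegistry:
    def test_unknown_name_is_an_error(self):
        with pytest.raises(KeyError, match="teleport"):
            run_experiment("teleport")

    def test_kcc2_ramp_experiment_headline(self):
        out = run_experiment("fig3ab", ramp_min=2.0, settle_min=20.0,
                             n_grid=7)
        s = out["summary"]
        assert s["ecl_start_mV"] == pytest.approx(-83.85, abs=0.1)
        assert s["ecl_end_mV"] < -93.5  # persistent hyperpolarization
        assert abs(s["vm_change_mV"]) < 2.5
        assert s["df_change_mV"] > 7.0

    def test_dendrite_kcc2_experiment_headline(self):
        out = run_experiment("fig7b_c", transient_ms=2.0)
        s = out["summary"]
        assert s["ddf_local_mV"] > s["ddf_far_mV"] > 0
        assert s["ddf_local_low_dcl_mV"] > s["ddf_local_mV"]
        assert s["ddf_far_low_dcl_mV"] < s["ddf_far_mV"]
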