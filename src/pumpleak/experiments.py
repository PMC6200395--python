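"""Registry of the package's canned in-silico experiments.

Each entry reproduces one of the model's headline manipulations end to end
(deterministically, with no external data): chloride-initialization
convergence, ATPase off/on ramps, pump-rate and conductance sweeps, KCC2
ramps, impermeant-anion additions and mean-charge changes (with variable or
clamped pump, osmotic or tension volume handling), and the local
KCC2/impermeant manipulations in the 10-compartment virtual dendrite.

``run_experiment(name)`` returns a dict with a ``summary`` of headline
scalars plus any time series, sweeps and steady-state tables the experiment
produced; the CLI writes these to CSV. Protocol magnitudes that the
narrative descriptions leave open (injection rates and windows) default to
values that land on the described end states (for example a mean charge of
-1 after adding a valence -1.5 species) and are configurable through
keyword overrides.

Persistent (steady-state) quantities of the dendrite experiments are
computed with the chain fixed-point solver, which zeroes the integrator's
own right-hand side; transient illustrations use short fine-dt
forward-Euler segments.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .chain import (
    DiffusionParams,
    simulate_chain,
    solve_chain_steady_state,
)
from .constants import MM
from .core import MembraneParams
from .dynamics import SimulationConfig, simulate
from .io import make_default_cell, make_default_dendrite
from .protocols import (
    fix_pump_event,
    inject_impermeant_event,
    param_ramp,
    pump_ramp_event,
    ramp_mean_charge_event,
    extracellular_swap_event,
)
from .steady import SteadyState, solve_steady_state, sweep

__all__ = ["EXPERIMENTS", "run_experiment", "list_experiments",
           "baseline_steady_state"]

_MIN = 60_000.0  # ms per minute


def baseline_steady_state() -> tuple[SteadyState, MembraneParams, object]:
    """Default-cell fixed point plus the parameterization that made it."""
    state, params, bath = make_default_cell()
    x_moles = state.pool.total_concentration * state.volume
    ss = solve_steady_state(params, bath, x_moles, state.pool.mean_charge,
                            state.length)
    return ss, params, bath


def _settle_config(duration_min: float = 60.0,
                   record_s: float = 10.0) -> SimulationConfig:
    return SimulationConfig(duration_ms=duration_min * _MIN,
                            record_every_ms=record_s * 1000.0)


def fig1b(cl0_mM=(1.0, 15.0, 40.0, 60.0), duration_min: float = 60.0):
    """Convergence of [Cl-]i and volume from different chloride starts.

    Each run starts exactly electroneutral (K+ balances the altered Cl-)
    with the default impermeant pool, so every run carries the same
    impermeant mole count and must land on the same fixed point.
    """
    runs = {}
    for cl0 in cl0_mM:
        state, params, bath = make_default_cell(cl_mM=cl0)
        runs[cl0] = simulate(state, params, bath,
                             _settle_config(duration_min))
    finals_cl = np.array([r.final["cl_mM"] for r in runs.values()])
    finals_w = np.array([r.final["volume_pL"] for r in runs.values()])
    return {
        "timeseries": runs,
        "summary": {
            "final_cl_mM": float(finals_cl.mean()),
            "cl_spread_mM": float(np.ptp(finals_cl)),
            "final_volume_pL": float(finals_w.mean()),
            "volume_spread_pL": float(np.ptp(finals_w)),
        },
    }


def fig1c(pre_min: float = 5.0, ramp_min: float = 15.0,
          hold_min: float = 30.0, settle_min: float = 60.0):
    """ATPase off/on: gradients collapse, volume grows, all recovers."""
    ss, params, bath = baseline_steady_state()
    off_at = pre_min * _MIN
    on_at = off_at + (ramp_min + hold_min) * _MIN
    events = [pump_ramp_event("off", off_at, ramp_min * _MIN),
              pump_ramp_event("on", on_at, ramp_min * _MIN)]
    total = on_at + (ramp_min + settle_min) * _MIN
    res = simulate(ss.state, params, bath,
                   SimulationConfig(duration_ms=total,
                                    record_every_ms=10_000.0), events)
    i_on = np.searchsorted(res.time_ms, on_at)
    return {
        "timeseries": res,
        "summary": {
            "volume_peak_pL": float(res.volume_pL[:i_on + 1].max()),
            "volume_baseline_pL": float(res.volume_pL[0]),
            "vm_peak_mV": float(res.vm_mV[:i_on + 1].max()),
            "vm_recovered_mV": float(res.vm_mV[-1]),
            "cl_recovered_mM": float(res.cl_mM[-1]),
            "recovered": bool(res.steady),
        },
    }


def fig1d(p_values=None, n_numeric: int = 4):
    """Pump-rate sweep; numerical runs must sit on the solver's curve."""
    ss, params, bath = baseline_steady_state()
    s0 = ss.state
    x_moles = s0.pool.total_concentration * s0.volume
    if p_values is None:
        p_values = np.geomspace(0.02, 1.0, 21)
    sw = sweep("P", p_values, params, bath, x_moles, -0.85, s0.length)
    idx = np.linspace(0, len(p_values) - 1, n_numeric).astype(int)
    max_dvm = 0.0
    for i in idx:
        if sw.states[i] is None:
            continue
        p = params.copy()
        p.pump_rate = float(p_values[i])
        res = simulate(s0, p, bath, _settle_config(120.0))
        max_dvm = max(max_dvm,
                      abs(res.final["vm_mV"] - sw.states[i].vm * 1e3))
    return {
        "sweeps": {"P": sw},
        "summary": {"max_numeric_analytic_vm_gap_mV": float(max_dvm)},
    }


def fig2(n_grid: int = 21):
    """Conductance sweeps: g_K, g_Na, and g_Cl with and without KCC2."""
    ss, params, bath = baseline_steady_state()
    s0 = ss.state
    xm = s0.pool.total_concentration * s0.volume
    sweeps = {
        "g_K": sweep("g_K", np.geomspace(5, 500, n_grid), params, bath,
                     xm, -0.85, s0.length),
        "g_Na": sweep("g_Na", np.geomspace(1, 100, n_grid), params, bath,
                      xm, -0.85, s0.length),
        "g_Cl": sweep("g_Cl", np.geomspace(0.1, 1000, n_grid), params,
                      bath, xm, -0.85, s0.length),
    }
    no_kcc2 = params.copy()
    no_kcc2.g_kcc2 = 0.0
    sweeps["g_Cl_no_kcc2"] = sweep("g_Cl", np.geomspace(0.1, 1000, n_grid),
                                   no_kcc2, bath, xm, -0.85, s0.length)
    gap = sweeps["g_K"].column("ecl_mV") - sweeps["g_K"].column("vm_mV")
    return {
        "sweeps": sweeps,
        "summary": {
            "gK_ecl_vm_gap_first_mV": float(gap[0]),
            "gK_ecl_vm_gap_last_mV": float(gap[-1]),
            "gCl_no_kcc2_max_abs_df_mV": float(
                np.nanmax(np.abs(sweeps["g_Cl_no_kcc2"].column("df_mV")))),
        },
    }


def fig3ab(g_to_uS: float = 370.0, ramp_min: float = 10.0,
           settle_min: float = 60.0, n_grid: int = 25):
    """KCC2 conductance ramp (time series) and steady-state sweep."""
    ss, params, bath = baseline_steady_state()
    s0 = ss.state
    xm = s0.pool.total_concentration * s0.volume
    ev = param_ramp("g_kcc2", g_to_uS, start_ms=1 * _MIN,
                    stop_ms=(1 + ramp_min) * _MIN)
    res = simulate(s0, params, bath,
                   SimulationConfig(
                       duration_ms=(1 + ramp_min + settle_min) * _MIN,
                       record_every_ms=5000.0), [ev])
    sw = sweep("g_KCC2", np.linspace(0.0, 600.0, n_grid), params, bath,
               xm, -0.85, s0.length)
    return {
        "timeseries": res,
        "sweeps": {"g_KCC2": sw},
        "summary": {
            "ecl_start_mV": float(res.ecl_mV[0]),
            "ecl_end_mV": float(res.ecl_mV[-1]),
            "vm_change_mV": float(res.vm_mV[-1] - res.vm_mV[0]),
            "df_change_mV": float(res.df_mV[-1] - res.df_mV[0]),
        },
    }


def fig4a_c_d(x0_mM=(77.5, 154.9, 232.4), inject_rate_mM_s: float = 0.1,
              inject_min: float = 10.0, swap_mM: float = 20.0):
    """Impermeant amount (not charge) manipulations leave E_Cl/E_K/V_m alone.

    (a) different initial pool concentrations at z = -0.85; (c) constant-
    rate injection of mean-charge anions then settle; (d) osmoneutral
    extracellular Cl-/X- swap.
    """
    out_a = {}
    for x0 in x0_mM:
        state, params, bath = make_default_cell(x_mM=x0)
        out_a[x0] = simulate(state, params, bath, _settle_config(60.0))
    finals = list(out_a.values())
    ecl_spread = np.ptp([r.final["ecl_mV"] for r in finals])
    w_by_x0 = np.array([r.final["volume_pL"] for r in finals])

    ss, params, bath = baseline_steady_state()
    ev = inject_impermeant_event(inject_rate_mM_s, start_ms=1 * _MIN,
                                 stop_ms=(1 + inject_min) * _MIN)
    res_c = simulate(ss.state, params, bath, _settle_config(90.0), [ev])
    res_d = simulate(ss.state, params, bath, _settle_config(90.0),
                     [extracellular_swap_event(swap_mM, at_ms=1 * _MIN)])
    return {
        "timeseries": {"a": out_a, "c": res_c, "d": res_d},
        "summary": {
            "a_ecl_spread_mV": float(ecl_spread),
            "a_volume_per_x0_pL": w_by_x0.tolist(),
            "c_ecl_shift_mV": float(res_c.ecl_mV[-1] - res_c.ecl_mV[0]),
            "c_volume_ratio": float(res_c.volume_pL[-1] / res_c.volume_pL[0]),
            "d_ecl_shift_mV": float(res_d.ecl_mV[-1] - res_d.ecl_mV[0]),
            "d_volume_ratio": float(res_d.volume_pL[-1] / res_d.volume_pL[0]),
        },
    }


def fig5a_c(target_z: float = -1.0, ramp_min: float = 10.0,
            inject_valence: float = -1.5, inject_rate_mM_s: float = 0.08,
            inject_min: float = 10.0):
    """Mean-charge manipulations shift E_Cl, E_K and V_m together.

    (a) ramp the pool mean valence at fixed moles; (c) add a more negative
    species, raising moles and lowering the mean charge.
    """
    ss, params, bath = baseline_steady_state()
    ev_a = ramp_mean_charge_event(target_z, start_ms=1 * _MIN,
                                  stop_ms=(1 + ramp_min) * _MIN)
    res_a = simulate(ss.state, params, bath, _settle_config(90.0), [ev_a])
    ev_c = inject_impermeant_event(inject_rate_mM_s, start_ms=1 * _MIN,
                                   stop_ms=(1 + inject_min) * _MIN,
                                   valence=inject_valence)
    res_c = simulate(ss.state, params, bath, _settle_config(90.0), [ev_c])
    return {
        "timeseries": {"a": res_a, "c": res_c},
        "summary": {
            "a_ddf_mV": float(res_a.df_mV[-1] - res_a.df_mV[0]),
            "a_ecl_shift_mV": float(res_a.ecl_mV[-1] - res_a.ecl_mV[0]),
            "a_vm_shift_mV": float(res_a.vm_mV[-1] - res_a.vm_mV[0]),
            "c_final_z": float(res_c.z[-1]),
            "c_ddf_mV": float(res_c.df_mV[-1] - res_c.df_mV[0]),
            "c_ecl_shift_mV": float(res_c.ecl_mV[-1] - res_c.ecl_mV[0]),
            "c_volume_ratio": float(res_c.volume_pL[-1] / res_c.volume_pL[0]),
        },
    }


def fig6a_c(target_z: float = -1.0, ramp_min: float = 10.0,
            inject_rate_mM_s: float = 0.1, inject_min: float = 10.0):
    """Impermeant-driven driving-force shifts vanish when J_p is clamped.

    (a) the mean-charge ramp with the Na+-dependent pump versus a pump
    clamped at its baseline rate; (c) mean-charge injection under the
    membrane-tension volume constraint, again with variable or clamped
    pump.
    """
    ss, params, bath = baseline_steady_state()
    ramp = ramp_mean_charge_event(target_z, start_ms=1 * _MIN,
                                  stop_ms=(1 + ramp_min) * _MIN)
    res_var = simulate(ss.state, params, bath, _settle_config(90.0), [ramp])
    res_fix = simulate(ss.state, params, bath, _settle_config(90.0),
                       [fix_pump_event(at_ms=0.0, jp=ss.jp), ramp])

    tension = params.copy()
    tension.volume_mode = "tension"
    tension.r_a = ss.state.radius
    inj = inject_impermeant_event(inject_rate_mM_s, start_ms=1 * _MIN,
                                  stop_ms=(1 + inject_min) * _MIN)
    res_t_var = simulate(ss.state, tension, bath, _settle_config(90.0), [inj])
    res_t_fix = simulate(ss.state, tension, bath, _settle_config(90.0),
                         [fix_pump_event(at_ms=0.0, jp=ss.jp), inj])
    bath_osm_mM = bath.osmolarity / MM
    gap_mM = (res_t_var.na_mM[-1] + res_t_var.k_mM[-1]
              + res_t_var.cl_mM[-1] + res_t_var.x_mM[-1] - bath_osm_mM)
    return {
        "timeseries": {"a_variable": res_var, "a_fixed": res_fix,
                       "c_variable": res_t_var, "c_fixed": res_t_fix},
        "summary": {
            "a_ddf_variable_mV": float(res_var.df_mV[-1] - res_var.df_mV[0]),
            "a_ddf_fixed_mV": float(res_fix.df_mV[-1] - res_fix.df_mV[0]),
            "c_osmotic_gap_mM": float(gap_mM),
            "c_ddf_variable_mV": float(res_t_var.df_mV[-1]
                                       - res_t_var.df_mV[0]),
            "c_ddf_fixed_mV": float(res_t_fix.df_mV[-1]
                                    - res_t_fix.df_mV[0]),
        },
    }


# ---------------------------------------------------------------------------
# Dendrite experiments
# ---------------------------------------------------------------------------

MANIPULATED_COMPARTMENT = 1  # second from the top end of the dendrite


def local_kcc2_dendrite(g_local_uS: float = 600.0,
                        d_cl: Optional[float] = None,
                        compartment: int = MANIPULATED_COMPARTMENT):
    """Steady driving-force profile after a local KCC2 increase.

    Returns (baseline ChainSteadyState, perturbed ChainSteadyState,
    per-compartment dDF in mV).
    """
    diffusion = DiffusionParams() if d_cl is None else DiffusionParams(d_cl=d_cl)
    chain = make_default_dendrite(diffusion=diffusion)
    base = solve_chain_steady_state(chain)
    pert = base.chain.copy()
    pert.params[compartment].g_kcc2 = g_local_uS * 1e-4
    sol = solve_chain_steady_state(pert, guess=base)
    return base, sol, sol.df_mV - base.df_mV


def local_charge_dendrite(target_z: float = -0.93, valence: float = -1.5,
                          compartment: int = MANIPULATED_COMPARTMENT):
    """Steady dDF profile after lowering one compartment's mean charge.

    A species of the given valence is added to the compartment's pool until
    its mean charge reaches ``target_z`` (the amount follows from the
    weighted-mean rule), then the chain's new fixed point is solved.
    """
    chain = make_default_dendrite()
    base = solve_chain_steady_state(chain)
    pert = base.chain.copy()
    pool = pert.states[compartment].pool
    z0 = pool.mean_charge
    c0 = pool.total_concentration
    if not (valence < target_z < z0 or valence > target_z > z0):
        raise ValueError("target mean charge must lie between the current "
                         "mean and the added species' valence")
    added = c0 * (z0 - target_z) / (target_z - valence)
    pert.states[compartment].pool = pool.with_added(added, valence)
    sol = solve_chain_steady_state(pert, guess=base)
    return base, sol, sol.df_mV - base.df_mV


def fig7b_c(g_local_uS: float = 600.0, d_cl_low: float = 0.2e-7,
            transient_ms: float = 50.0):
    """Local KCC2 increase: widespread vs confined dDF by Cl- diffusion."""
    base, sol, ddf = local_kcc2_dendrite(g_local_uS)
    base_lo, sol_lo, ddf_lo = local_kcc2_dendrite(g_local_uS, d_cl=d_cl_low)
    # short fine-dt segment from the perturbed-parameter baseline state,
    # illustrating the onset of the response
    chain = base.chain.copy()
    chain.params[MANIPULATED_COMPARTMENT].g_kcc2 = g_local_uS * 1e-4
    trans = simulate_chain(chain, SimulationConfig(
        dt_ms=1e-3, duration_ms=transient_ms, record_every_ms=1.0,
        stop_when_steady=False))
    return {
        "chain_timeseries": trans,
        "steady_states": {"baseline": base, "local_kcc2": sol,
                          "baseline_low_dcl": base_lo,
                          "local_kcc2_low_dcl": sol_lo},
        "summary": {
            "ddf_local_mV": float(ddf[MANIPULATED_COMPARTMENT]),
            "ddf_far_mV": float(ddf[-1]),
            "ddf_local_low_dcl_mV": float(ddf_lo[MANIPULATED_COMPARTMENT]),
            "ddf_far_low_dcl_mV": float(ddf_lo[-1]),
        },
    }


def fig8b_c(amount_fraction: float = 0.3, target_z: float = -0.93,
            valence: float = -1.5, transient_ms: float = 50.0,
            inject_rate_mM_s: float = 100.0):
    """Local impermeant additions: volume is local, driving force is not.

    (b) adding mean-charge anions to one compartment: the new fixed point
    has a larger volume there and an unchanged driving force everywhere;
    a short fine-dt segment with a constant-rate injection illustrates the
    transient. (c) adding a more negative species until the compartment's
    mean charge reaches ``target_z``: persistent E_Cl/V_m shifts but a
    negligible driving-force change.
    """
    chain = make_default_dendrite()
    base = solve_chain_steady_state(chain)
    comp = MANIPULATED_COMPARTMENT
    pert = base.chain.copy()
    pool = pert.states[comp].pool
    pert.states[comp].pool = pool.with_added(
        amount_fraction * pool.total_concentration, pool.mean_charge)
    sol_b = solve_chain_steady_state(pert, guess=base)
    ddf_b = sol_b.df_mV - base.df_mV
    w_ratio = (sol_b.chain.states[comp].volume
               / base.chain.states[comp].volume)
    trans = simulate_chain(base.chain.copy(), SimulationConfig(
        dt_ms=1e-3, duration_ms=transient_ms, record_every_ms=1.0,
        stop_when_steady=False),
        [inject_impermeant_event(inject_rate_mM_s, start_ms=0.0,
                                 stop_ms=transient_ms, compartment=comp)])
    _, sol_c, ddf_c = local_charge_dendrite(target_z, valence)
    ecl_shift_c = (sol_c.e_cl[comp] - base.e_cl[comp]) * 1e3
    return {
        "chain_timeseries": trans,
        "steady_states": {"baseline": base, "amount_added": sol_b,
                          "charge_added": sol_c},
        "summary": {
            "b_max_abs_ddf_mV": float(np.max(np.abs(ddf_b))),
            "b_volume_ratio_local": float(w_ratio),
            "c_ddf_local_mV": float(ddf_c[comp]),
            "c_max_abs_ddf_mV": float(np.max(np.abs(ddf_c))),
            "c_ecl_shift_local_mV": float(ecl_shift_c),
        },
    }


EXPERIMENTS: dict[str, Callable] = {
    "fig1b": fig1b,
    "fig1c": fig1c,
    "fig1d": fig1d,
    "fig2": fig2,
    "fig3ab": fig3ab,
    "fig4a_c_d": fig4a_c_d,
    "fig5a_c": fig5a_c,
    "fig6a_c": fig6a_c,
    "fig7b_c": fig7b_c,
    "fig8b_c": fig8b_c,
}


def list_experiments() -> list[str]:
    return sorted(EXPERIMENTS)


def run_experiment(name: str, **overrides):
    """Run a registry experiment; unknown names raise KeyError."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; "
                       f"known: {', '.join(list_experiments())}")
    return EXPERIMENTS[name](**overrides)
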