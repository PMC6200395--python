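"""Forward-Euler time integration of the single-compartment model.

Update order within one step: (1) membrane potential, Nernst potentials,
pump and KCC2 fluxes and the water flux are computed from the pre-step
state; (2) ion concentrations advance by their transmembrane fluxes plus
the dilution term (using the pre-step dw/dt); (3) protocol source terms
(impermeant injection) are applied; (4) the volume advances and is
expressed as a radius change at fixed length; (5) impermeant
concentrations are rescaled by the volume ratio so that impermeant moles
are conserved exactly.

A negative concentration anywhere aborts the run (clamping would silently
violate conservation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import CONSTANTS, MM, PL_PER_L, UM
from .core import (
    BathComposition,
    CompartmentState,
    ImpermeantPool,
    MembraneParams,
)
from .protocols import _PARAM_SCALE, ProtocolEvent

__all__ = [
    "SimulationConfig",
    "IntegrationError",
    "TimeSeriesResult",
    "step",
    "simulate",
]

_PI = math.pi

TRACE_COLUMNS = (
    "time_ms", "na_mM", "k_mM", "cl_mM", "x_mM", "z", "radius_um",
    "volume_pL", "vm_mV", "ena_mV", "ek_mV", "ecl_mV", "df_mV", "jp",
    "jkcc2",
)


class IntegrationError(RuntimeError):
    """Raised when the integration leaves the physical domain."""


@dataclass
class SimulationConfig:
    """Integration settings.

    ``dt_ms`` defaults to 1 ms for the single compartment (the chain model
    uses 1e-3 ms). ``steady_tol`` is the largest |d[ion]/dt| in mM/s still
    accepted as steady; together with the relative volume-rate tolerance it
    must hold for ``steady_window`` consecutive steps. With
    ``stop_when_steady`` the run ends early once steady (never before the
    last protocol event has finished).
    """

    dt_ms: float = 1.0
    duration_ms: float = 3_600_000.0
    record_every_ms: float = 1000.0
    steady_tol: float = 1e-6
    steady_volume_tol: float = 1e-9
    steady_window: int = 1000
    stop_when_steady: bool = True

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.duration_ms < 0:
            raise ValueError("duration_ms must be >= 0")


@dataclass
class TimeSeriesResult:
    """Recorded trajectory of state and derived quantities.

    Arrays are aligned with ``time_ms``; concentrations in mM, potentials
    in mV, volume in pL, fluxes in C/(dm^2 s). ``steady`` reports whether
    the steady-state tolerance was met before the run ended.
    """

    time_ms: np.ndarray
    na_mM: np.ndarray
    k_mM: np.ndarray
    cl_mM: np.ndarray
    x_mM: np.ndarray
    z: np.ndarray
    radius_um: np.ndarray
    volume_pL: np.ndarray
    vm_mV: np.ndarray
    ena_mV: np.ndarray
    ek_mV: np.ndarray
    ecl_mV: np.ndarray
    df_mV: np.ndarray
    jp: np.ndarray
    jkcc2: np.ndarray
    final_state: CompartmentState
    steady: bool
    compartment: int = 0

    def to_frame(self):
        """Trajectory as a pandas DataFrame in the shared CSV dialect."""
        import pandas as pd

        data = {"time_ms": self.time_ms, "compartment": self.compartment}
        for name in TRACE_COLUMNS[1:]:
            data[name] = getattr(self, name)
        return pd.DataFrame(data)

    @property
    def final(self) -> dict:
        """Scalar summary of the end of the run."""
        return {
            "na_mM": self.na_mM[-1], "k_mM": self.k_mM[-1],
            "cl_mM": self.cl_mM[-1], "x_mM": self.x_mM[-1],
            "z": self.z[-1], "radius_um": self.radius_um[-1],
            "volume_pL": self.volume_pL[-1], "vm_mV": self.vm_mV[-1],
            "ena_mV": self.ena_mV[-1], "ek_mV": self.ek_mV[-1],
            "ecl_mV": self.ecl_mV[-1], "df_mV": self.df_mV[-1],
            "jp": self.jp[-1], "jkcc2": self.jkcc2[-1],
            "steady": self.steady,
        }


def _derivs(na, k, cl, xt, xq, r, length,
            g_na, g_k, g_cl, g_kcc2, pump_rate, pump_fixed, fixed_jp,
            c_m, v_w, p_w, k_m, r_a, tension,
            na_o, k_o, cl_o, osm_o, F, RTF, RTP):
    """All instantaneous rates and derived quantities from one state.

    Scalar fast path shared by :func:`step` and :func:`simulate`; the
    public operations in :mod:`pumpleak.core` are the reference
    formulation and are cross-checked against this in the test suite.
    """
    am = 2.0 / r
    w = _PI * r * r * length
    vm = F * (na + k - cl + xq) / (c_m * am)
    ena = RTF * math.log(na_o / na)
    ek = RTF * math.log(k_o / k)
    ecl = -RTF * math.log(cl_o / cl)
    if pump_fixed:
        jp = fixed_jp
    else:
        ratio = na / na_o
        jp = pump_rate * ratio * ratio * ratio
    jk = g_kcc2 * (ek - ecl)
    gap = (na + k + cl + xt) - osm_o
    if tension and r > r_a:
        gap -= 4.0 * _PI * k_m * (1.0 - r_a / r) / RTP
    dw = v_w * p_w * (2.0 * _PI * r * length) * gap
    dil = dw / w
    am_f = am / F
    dna = -am_f * (g_na * (vm - ena) + 3.0 * jp) - dil * na
    dk = -am_f * (g_k * (vm - ek) - 2.0 * jp - jk) - dil * k
    dcl = am_f * (g_cl * (vm - ecl) + jk) - dil * cl
    return dna, dk, dcl, dw, vm, ena, ek, ecl, jp, jk


def step(state: CompartmentState, params: MembraneParams,
         bath: BathComposition, dt_ms: float,
         injections: Sequence[tuple[float, float]] = ()) -> CompartmentState:
    """One forward-Euler update of a compartment; returns the new state.

    ``injections`` holds (rate in mM/s, valence) source terms applied after
    the transmembrane and volume updates within the same step.
    """
    dt = dt_ms / 1000.0
    c = CONSTANTS
    pool = state.pool
    xt = pool.total_concentration
    xq = pool.charge_concentration
    dna, dk, dcl, dw, vm, *_ = _derivs(
        state.na, state.k, state.cl, xt, xq, state.radius, state.length,
        params.g_na, params.g_k, params.g_cl, params.g_kcc2,
        params.pump_rate, params.pump_mode == "fixed", params.fixed_jp,
        params.c_m, params.v_w, params.p_w, params.k_m, params.r_a,
        params.volume_mode == "tension",
        bath.na, bath.k, bath.cl, bath.osmolarity,
        c.F, c.RTF, c.RT_pressure,
    )
    na = state.na + dna * dt
    k = state.k + dk * dt
    cl = state.cl + dcl * dt
    for ion, value in (("Na+", na), ("K+", k), ("Cl-", cl)):
        if value < 0:
            raise IntegrationError(
                f"[{ion}]i went negative during step at dt={dt_ms} ms")
    w_old = state.volume
    w_new = w_old + dw * dt
    if w_new <= 0:
        raise IntegrationError("volume went non-positive during step")
    radius = math.sqrt(w_new / (_PI * state.length))
    new_pool = pool.scaled(w_old / w_new)
    for rate_mM_s, valence in injections:
        new_pool = new_pool.with_added(rate_mM_s * MM * dt, valence)
    return CompartmentState(na=na, k=k, cl=cl, pool=new_pool,
                            radius=radius, length=state.length)


# ---------------------------------------------------------------------------
# Protocol event runtime
# ---------------------------------------------------------------------------

class _Controls:
    """Mutable per-run control values the event runtime writes into."""

    __slots__ = ("g_na", "g_k", "g_cl", "g_kcc2", "pump_rate", "pump_fixed",
                 "fixed_jp", "c_m", "v_w", "p_w", "k_m", "r_a", "tension",
                 "na_o", "k_o", "cl_o", "x_o", "last_jp")

    def __init__(self, params: MembraneParams, bath: BathComposition):
        self.g_na = params.g_na
        self.g_k = params.g_k
        self.g_cl = params.g_cl
        self.g_kcc2 = params.g_kcc2
        self.pump_rate = params.pump_rate
        self.pump_fixed = params.pump_mode == "fixed"
        self.fixed_jp = params.fixed_jp
        self.c_m = params.c_m
        self.v_w = params.v_w
        self.p_w = params.p_w
        self.k_m = params.k_m
        self.r_a = params.r_a
        self.tension = params.volume_mode == "tension"
        self.na_o = bath.na
        self.k_o = bath.k
        self.cl_o = bath.cl
        self.x_o = bath.x
        self.last_jp = 0.0

    @property
    def osm_o(self) -> float:
        return self.na_o + self.k_o + self.cl_o + self.x_o


class _EventRuntime:
    """Applies one ProtocolEvent inside the integration loop."""

    def __init__(self, event: ProtocolEvent):
        self.event = event
        self.started = False
        self.done = False
        self.captured: Optional[float] = None

    def apply(self, t_ms: float, dt_ms: float, ctrl: _Controls,
              concs: list, vals: list, injections: list) -> None:
        ev = self.event
        if self.done or t_ms < ev.start_ms:
            return
        kind = ev.kind
        if not self.started:
            self.started = True
            self._capture(ctrl, concs, vals)
        stop = ev.stop_ms
        if kind == "set_param":
            setattr(ctrl, ev.parameter, ev.value * _PARAM_SCALE[ev.parameter])
            self.done = True
        elif kind == "param_ramp":
            span = max(stop - ev.start_ms, dt_ms)
            frac = min((t_ms - ev.start_ms) / span, 1.0)
            target = ev.target * _PARAM_SCALE[ev.parameter]
            setattr(ctrl, ev.parameter,
                    self.captured + (target - self.captured) * frac)
            if t_ms >= stop:
                setattr(ctrl, ev.parameter, target)
                self.done = True
        elif kind == "pump_ramp":
            duration = (stop - ev.start_ms) / 1000.0
            target = 0.0 if ev.direction == "off" else (
                ev.target if ev.target is not None else self.captured)
            if ev.direction == "on" and ev.target is None:
                # restore the pre-run default captured lazily at start
                target = self.default_target
            if duration <= 0:
                ctrl.pump_rate = target
                self.done = True
            else:
                tau = duration / 5.0
                ctrl.pump_rate = target + (self.captured - target) * math.exp(
                    -((t_ms - ev.start_ms) / 1000.0) / tau)
        elif kind == "inject_impermeant":
            if t_ms < stop:
                valence = ev.valence if ev.valence is not None else self.captured
                injections.append((ev.rate_mM_per_s, valence))
            else:
                self.done = True
        elif kind == "ramp_mean_charge":
            span = max(stop - ev.start_ms, dt_ms)
            frac = min((t_ms - ev.start_ms) / span, 1.0)
            z_now = self.captured + (ev.target_z - self.captured) * frac
            total = sum(concs)
            i = ev.species_index
            other = sum(c * v for j, (c, v) in enumerate(zip(concs, vals))
                        if j != i)
            vals[i] = (z_now * total - other) / concs[i]
            if t_ms >= stop:
                self.done = True
        elif kind == "extracellular_swap":
            delta = ev.delta_mM * MM
            if ctrl.cl_o - delta < 0:
                raise IntegrationError(
                    "extracellular swap would make Cl_o negative")
            ctrl.x_o += delta
            ctrl.cl_o -= delta
            self.done = True
        elif kind == "fix_pump":
            ctrl.pump_fixed = True
            ctrl.fixed_jp = ev.value if ev.value is not None else ctrl.last_jp
            self.done = True
        elif kind == "set_volume_mode":
            ctrl.tension = ev.mode == "tension"
            if ev.value is not None:
                ctrl.r_a = ev.value * UM
            self.done = True

    def _capture(self, ctrl: _Controls, concs: list, vals: list) -> None:
        ev = self.event
        kind = ev.kind
        if kind == "param_ramp":
            self.captured = getattr(ctrl, ev.parameter)
        elif kind == "pump_ramp":
            self.captured = ctrl.pump_rate
        elif kind == "inject_impermeant" and ev.valence is None:
            total = sum(concs)
            self.captured = sum(c * v for c, v in zip(concs, vals)) / total
        elif kind == "ramp_mean_charge":
            total = sum(concs)
            self.captured = sum(c * v for c, v in zip(concs, vals)) / total


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def simulate(initial: CompartmentState, params: MembraneParams,
             bath: BathComposition, config: Optional[SimulationConfig] = None,
             events: Sequence[ProtocolEvent] = ()) -> TimeSeriesResult:
    """Integrate one compartment forward in time.

    Records state and derived traces every ``record_every_ms`` and reports
    whether the steady-state tolerance was reached. Protocol events are
    applied at their scheduled times; the run never stops early before the
    last event has finished.
    """
    cfg = config or SimulationConfig()
    c = CONSTANTS
    F, RTF, RTP = c.F, c.RTF, c.RT_pressure
    dt_ms = cfg.dt_ms
    dt = dt_ms / 1000.0
    n_steps = int(round(cfg.duration_ms / dt_ms))
    stride = max(1, int(round(cfg.record_every_ms / dt_ms)))
    tol = cfg.steady_tol * 1e-3  # mM/s -> mol/L/s
    vtol = cfg.steady_volume_tol

    ctrl = _Controls(params, bath)
    # seed the captured pump rate so a fix_pump at t=0 clamps the true
    # instantaneous J_p rather than zero
    if params.pump_mode == "fixed":
        ctrl.last_jp = params.fixed_jp
    else:
        ratio = initial.na / bath.na
        ctrl.last_jp = params.pump_rate * ratio ** 3
    runtime = [_EventRuntime(ev)
               for ev in sorted(events, key=lambda e: e.start_ms)]
    # a pump ramp 'on' without explicit target restores the pre-run rate
    for rt in runtime:
        rt.default_target = params.pump_rate
    last_event_ms = max((ev.end_ms for ev in events), default=-math.inf)

    na, k, cl = initial.na, initial.k, initial.cl
    concs = list(initial.pool.concentrations)
    vals = list(initial.pool.valences)
    r = initial.radius
    length = initial.length

    records: list[tuple] = []
    steady_count = 0
    steady = False
    injections: list[tuple[float, float]] = []
    t_ms = 0.0

    for i in range(n_steps):
        t_ms = i * dt_ms
        injections.clear()
        for rt in runtime:
            rt.apply(t_ms, dt_ms, ctrl, concs, vals, injections)
        xt = 0.0
        xq = 0.0
        for j in range(len(concs)):
            xt += concs[j]
            xq += concs[j] * vals[j]
        dna, dk, dcl, dw, vm, ena, ek, ecl, jp, jk = _derivs(
            na, k, cl, xt, xq, r, length,
            ctrl.g_na, ctrl.g_k, ctrl.g_cl, ctrl.g_kcc2,
            ctrl.pump_rate, ctrl.pump_fixed, ctrl.fixed_jp,
            ctrl.c_m, ctrl.v_w, ctrl.p_w, ctrl.k_m, ctrl.r_a, ctrl.tension,
            ctrl.na_o, ctrl.k_o, ctrl.cl_o, ctrl.osm_o, F, RTF, RTP)
        ctrl.last_jp = jp
        if i % stride == 0:
            records.append((t_ms, na, k, cl, xt, xq / xt, r, vm, ena, ek,
                            ecl, jp, jk))
        na += dna * dt
        k += dk * dt
        cl += dcl * dt
        if na < 0 or k < 0 or cl < 0:
            ion = "Na+" if na < 0 else ("K+" if k < 0 else "Cl-")
            raise IntegrationError(
                f"[{ion}]i went negative at t = {t_ms + dt_ms:.3f} ms")
        w_old = _PI * r * r * length
        w_new = w_old + dw * dt
        if w_new <= 0:
            raise IntegrationError(
                f"volume went non-positive at t = {t_ms + dt_ms:.3f} ms")
        scale = w_old / w_new
        for j in range(len(concs)):
            concs[j] *= scale
        r = math.sqrt(w_new / (_PI * length))
        for rate_mM_s, valence in injections:
            added = rate_mM_s * MM * dt
            for j in range(len(vals)):
                if abs(vals[j] - valence) <= 1e-12:
                    concs[j] += added
                    break
            else:
                concs.append(added)
                vals.append(valence)
        # steady detection on the rates just used
        if (abs(dna) < tol and abs(dk) < tol and abs(dcl) < tol
                and abs(dw) / w_old < vtol):
            steady_count += 1
        else:
            steady_count = 0
        if (cfg.stop_when_steady and steady_count >= cfg.steady_window
                and t_ms >= last_event_ms):
            steady = True
            t_ms += dt_ms
            break
    else:
        t_ms = n_steps * dt_ms
        steady = steady_count >= cfg.steady_window

    # final record from the end state
    xt = sum(concs)
    xq = sum(cc * zz for cc, zz in zip(concs, vals))
    _, _, _, _, vm, ena, ek, ecl, jp, jk = _derivs(
        na, k, cl, xt, xq, r, length,
        ctrl.g_na, ctrl.g_k, ctrl.g_cl, ctrl.g_kcc2,
        ctrl.pump_rate, ctrl.pump_fixed, ctrl.fixed_jp,
        ctrl.c_m, ctrl.v_w, ctrl.p_w, ctrl.k_m, ctrl.r_a, ctrl.tension,
        ctrl.na_o, ctrl.k_o, ctrl.cl_o, ctrl.osm_o, F, RTF, RTP)
    records.append((t_ms, na, k, cl, xt, xq / xt, r, vm, ena, ek, ecl,
                    jp, jk))

    arr = np.asarray(records, dtype=float).T
    final_state = CompartmentState(
        na=na, k=k, cl=cl, pool=ImpermeantPool(zip(concs, vals)),
        radius=r, length=length)
    return TimeSeriesResult(
        time_ms=arr[0],
        na_mM=arr[1] / MM, k_mM=arr[2] / MM, cl_mM=arr[3] / MM,
        x_mM=arr[4] / MM, z=arr[5],
        radius_um=arr[6] / UM,
        volume_pL=_PI * arr[6] ** 2 * length * PL_PER_L,
        vm_mV=arr[7] * 1e3, ena_mV=arr[8] * 1e3, ek_mV=arr[9] * 1e3,
        ecl_mV=arr[10] * 1e3, df_mV=(arr[7] - arr[10]) * 1e3,
        jp=arr[11], jkcc2=arr[12],
        final_state=final_state, steady=steady)
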