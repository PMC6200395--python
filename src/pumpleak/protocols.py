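"""Timed experimental manipulations applied during integration.

A protocol is a list of :class:`ProtocolEvent` objects. Events express the
in-silico experiments of the model: switching the ATPase off and on again
(ouabain-like ramps), ramping the KCC2 conductance, injecting impermeant
species at a constant rate, slowly changing the mean impermeant charge at
fixed mole number (imitating a charge-carrying transmembrane reaction),
osmoneutral extracellular anion/chloride swaps, clamping the pump rate, and
switching the volume model between osmotic and tension modes.

Payload units follow the laboratory conventions of the configuration
surface: conductances in uS/cm^2, pump rate in C/(dm^2 s), injection rates
in mM/s, bath changes in mM, times in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .constants import MM, UM, US_PER_CM2
from .core import (
    BathComposition,
    CompartmentState,
    DomainError,
    ImpermeantPool,
)

__all__ = [
    "ProtocolEvent",
    "pump_ramp_event",
    "set_param",
    "param_ramp",
    "inject_impermeant_event",
    "ramp_mean_charge_event",
    "extracellular_swap_event",
    "fix_pump_event",
    "set_volume_mode_event",
    "inject_impermeant",
    "with_mean_charge",
    "ramp_mean_charge",
    "extracellular_swap",
    "pump_ramp_value",
]

# Parameter names settable by set_param / param_ramp, with the scale that
# converts the payload unit into the canonical internal unit.
_PARAM_SCALE = {
    "g_na": US_PER_CM2,
    "g_k": US_PER_CM2,
    "g_cl": US_PER_CM2,
    "g_kcc2": US_PER_CM2,
    "pump_rate": 1.0,
    "p_w": 1.0,
    "v_w": 1.0,
    "k_m": 1.0,
}


@dataclass
class ProtocolEvent:
    """One timed manipulation.

    ``kind`` selects the manipulation; ``start_ms``/``stop_ms`` bound its
    activity window (``stop_ms`` may be None for instantaneous events).
    ``compartment`` targets a single compartment of a chain (None = all /
    the single compartment). Remaining fields are kind-specific.
    """

    kind: str
    start_ms: float
    stop_ms: Optional[float] = None
    compartment: Optional[int] = None
    parameter: Optional[str] = None
    value: Optional[float] = None
    target: Optional[float] = None
    rate_mM_per_s: Optional[float] = None
    valence: Optional[float] = None
    target_z: Optional[float] = None
    delta_mM: Optional[float] = None
    direction: Optional[str] = None
    mode: Optional[str] = None
    species_index: int = 0

    def __post_init__(self) -> None:
        known = {
            "pump_ramp", "set_param", "param_ramp", "inject_impermeant",
            "ramp_mean_charge", "extracellular_swap", "fix_pump",
            "set_volume_mode",
        }
        if self.kind not in known:
            raise DomainError(f"unknown protocol event kind {self.kind!r}")
        if self.stop_ms is not None and self.stop_ms < self.start_ms:
            raise DomainError("stop_ms must be >= start_ms")
        if self.kind == "inject_impermeant" and (self.rate_mM_per_s or 0.0) < 0:
            raise DomainError("injection rate must be >= 0")
        if self.kind in ("param_ramp", "set_param") and self.parameter not in _PARAM_SCALE:
            raise DomainError(f"unknown parameter {self.parameter!r}")

    @property
    def end_ms(self) -> float:
        return self.start_ms if self.stop_ms is None else self.stop_ms


# -- constructors -----------------------------------------------------------

def pump_ramp_event(direction: str, start_ms: float,
                    duration_ms: float = 900_000.0,
                    target: Optional[float] = None) -> ProtocolEvent:
    """Exponential ATPase ramp toward zero (``off``) or a target rate (``on``).

    The time constant is duration/5, so the ramp is ~99% complete at
    ``start_ms + duration_ms`` (the default window is 15 min, inside the
    10-20 min range over which ouabain acts and is reversed).
    """
    if direction not in ("off", "on"):
        raise DomainError("pump ramp direction must be 'off' or 'on'")
    return ProtocolEvent(kind="pump_ramp", start_ms=start_ms,
                         stop_ms=start_ms + duration_ms,
                         direction=direction, target=target)


def set_param(parameter: str, value: float, at_ms: float,
              compartment: Optional[int] = None) -> ProtocolEvent:
    return ProtocolEvent(kind="set_param", start_ms=at_ms, parameter=parameter,
                         value=value, compartment=compartment)


def param_ramp(parameter: str, target: float, start_ms: float, stop_ms: float,
               compartment: Optional[int] = None) -> ProtocolEvent:
    """Linear ramp of a membrane parameter from its current value."""
    return ProtocolEvent(kind="param_ramp", start_ms=start_ms, stop_ms=stop_ms,
                         parameter=parameter, target=target,
                         compartment=compartment)


def inject_impermeant_event(rate_mM_per_s: float, start_ms: float,
                            stop_ms: float, valence: Optional[float] = None,
                            compartment: Optional[int] = None) -> ProtocolEvent:
    """Constant-rate impermeant influx; ``valence=None`` means the pool's
    mean charge captured at the start of the injection."""
    return ProtocolEvent(kind="inject_impermeant", start_ms=start_ms,
                         stop_ms=stop_ms, rate_mM_per_s=rate_mM_per_s,
                         valence=valence, compartment=compartment)


def ramp_mean_charge_event(target_z: float, start_ms: float, stop_ms: float,
                           compartment: Optional[int] = None,
                           species_index: int = 0) -> ProtocolEvent:
    """Linearly move the pool mean charge to ``target_z`` at fixed moles by
    continuously adjusting the valence of one designated species."""
    return ProtocolEvent(kind="ramp_mean_charge", start_ms=start_ms,
                         stop_ms=stop_ms, target_z=target_z,
                         compartment=compartment, species_index=species_index)


def extracellular_swap_event(delta_mM: float, at_ms: float) -> ProtocolEvent:
    """Instantaneous osmoneutral, electroneutral bath change: X_o rises by
    ``delta_mM`` while Cl_o falls by the same amount."""
    return ProtocolEvent(kind="extracellular_swap", start_ms=at_ms,
                         delta_mM=delta_mM)


def fix_pump_event(at_ms: float, jp: Optional[float] = None) -> ProtocolEvent:
    """Clamp the effective pump rate (at its instantaneous value if ``jp``
    is None), removing the Na+ dependence of the ATPase."""
    return ProtocolEvent(kind="fix_pump", start_ms=at_ms, value=jp)


def set_volume_mode_event(mode: str, at_ms: float,
                          r_a_um: Optional[float] = None) -> ProtocolEvent:
    if mode not in ("osmotic", "tension"):
        raise DomainError("volume mode must be 'osmotic' or 'tension'")
    return ProtocolEvent(kind="set_volume_mode", start_ms=at_ms, mode=mode,
                         value=r_a_um)


# -- pure state operations (used by the integrators and directly testable) --

def inject_impermeant(state: CompartmentState, rate_mM_per_s: float,
                      valence: float, dt_s: float) -> CompartmentState:
    """Add ``rate*dt`` of an impermeant species to the pool.

    Increases the pool's mole count; the mean charge moves by the
    concentration-weighted-mean rule. Membrane charge bookkeeping flows
    through the charge-difference voltage automatically.
    """
    if rate_mM_per_s < 0:
        raise DomainError("injection rate must be >= 0")
    added = rate_mM_per_s * MM * dt_s
    out = state.copy()
    out.pool = out.pool.with_added(added, valence)
    return out


def with_mean_charge(state: CompartmentState, z: float,
                     species_index: int = 0) -> CompartmentState:
    """Return a state whose pool mean charge is ``z``, moles unchanged.

    The valence of the designated species is adjusted so that the
    concentration-weighted mean over all species equals ``z``.
    """
    pool = state.pool
    total = pool.total_concentration
    if total <= 0:
        raise DomainError("cannot set mean charge of an empty pool")
    c_des = pool.concentrations[species_index]
    if c_des <= 0:
        raise DomainError("designated species has zero concentration")
    other = sum(
        c * v for i, (c, v) in enumerate(zip(pool.concentrations, pool.valences))
        if i != species_index
    )
    new_val = (z * total - other) / c_des
    out = state.copy()
    out.pool.valences[species_index] = new_val
    return out


def ramp_mean_charge(state: CompartmentState, target_z: float,
                     window_s: float, dt_s: float,
                     z_start: Optional[float] = None,
                     elapsed_s: float = 0.0,
                     species_index: int = 0) -> CompartmentState:
    """Advance one step of a linear mean-charge ramp (moles fixed)."""
    z0 = state.pool.mean_charge if z_start is None else z_start
    if window_s <= 0:
        frac = 1.0
    else:
        frac = min((elapsed_s + dt_s) / window_s, 1.0)
    return with_mean_charge(state, z0 + (target_z - z0) * frac, species_index)


def extracellular_swap(bath: BathComposition, delta_X_mM: float) -> BathComposition:
    """Swap extracellular Cl- for impermeant X-, preserving bath osmolarity
    and net charge."""
    delta = delta_X_mM * MM
    if bath.cl - delta < 0:
        raise DomainError("extracellular swap would make Cl_o negative")
    out = bath.copy()
    out.x += delta
    out.cl -= delta
    return out


def pump_ramp_value(p_start: float, p_target: float, t_since_s: float,
                    duration_s: float) -> float:
    """Exponential approach of the pump-rate constant toward a target.

    Time constant duration/5; duration 0 is a step change.
    """
    if t_since_s <= 0:
        return p_start
    if duration_s <= 0:
        return p_target
    tau = duration_s / 5.0
    return p_target + (p_start - p_target) * math.exp(-t_since_s / tau)
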