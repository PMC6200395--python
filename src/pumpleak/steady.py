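"""Direct computation of the model's fixed points, and parameter sweeps.

The steady state solves five simultaneous conditions: zero net flux for
each permeant ion (with dw/dt = 0), osmotic balance between cytosol and
bath (optionally offset by membrane tension), and consistency of the
membrane potential with the net intracellular charge. The impermeant pool
enters through its mole number and mean charge; at the fixed point the
pool concentration fixes the volume, w = X_moles / [X].

Root-finding is performed in (log Na, log K, log Cl, log w, V_m), which
keeps concentrations and volume positive, warm-started from the default
steady state. Agreement with the time-integrated fixed point (the
dots-on-lines property of the numerical runs) is part of the test suite's
contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import root

from .constants import CONSTANTS, MM, PL_PER_L, UM, US_PER_CM2
from .core import (
    BathComposition,
    CompartmentState,
    ImpermeantPool,
    MembraneParams,
    kcc2_flux,
    nernst_potential,
    pump_flux,
)

__all__ = [
    "NoSteadyStateError",
    "SteadyState",
    "SweepResult",
    "solve_steady_state",
    "sweep",
    "SWEEPABLE_PARAMETERS",
]

_PI = math.pi


class NoSteadyStateError(RuntimeError):
    """Raised when no (stable) fixed point can be found.

    Carries the final residual vector for diagnosis. Regimes such as a
    silenced pump genuinely lack a steady state: the volume grows without
    bound.
    """

    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class SteadyState:
    """A fixed point of the single-compartment model.

    Potentials in volts internally; ``summary()``/CSV output convert to the
    laboratory units. ``residuals`` holds the raw per-equation imbalances
    (flux residuals in C/(dm^2 s), osmotic in mol/L, charge in mol/L).
    """

    state: CompartmentState
    vm: float
    e_na: float
    e_k: float
    e_cl: float
    jp: float
    jkcc2: float
    residuals: dict
    converged: bool = True

    @property
    def df(self) -> float:
        """Chloride driving force V_m - E_Cl (volt)."""
        return self.vm - self.e_cl

    @property
    def volume_pL(self) -> float:
        return self.state.volume * PL_PER_L

    def row(self) -> dict:
        """Scalar fields in the shared CSV dialect units."""
        s = self.state
        return {
            "na_mM": s.na / MM, "k_mM": s.k / MM, "cl_mM": s.cl / MM,
            "x_mM": s.pool.total_concentration / MM,
            "z": s.pool.mean_charge,
            "radius_um": s.radius / UM,
            "volume_pL": self.volume_pL,
            "vm_mV": self.vm * 1e3, "ena_mV": self.e_na * 1e3,
            "ek_mV": self.e_k * 1e3, "ecl_mV": self.e_cl * 1e3,
            "df_mV": self.df * 1e3, "jp": self.jp, "jkcc2": self.jkcc2,
            "converged": self.converged,
        }


@dataclass
class SweepResult:
    """Steady states along a parameter grid.

    Failed grid points are flagged (never silently dropped); their entry in
    ``states`` is None.
    """

    parameter: str
    values: np.ndarray
    states: list
    failed: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size > 1 and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
            raise ValueError("sweep grid must be strictly monotone")

    def column(self, name: str) -> np.ndarray:
        """Array of one SteadyState scalar across the grid (NaN if failed)."""
        out = np.full(len(self.states), np.nan)
        for i, st in enumerate(self.states):
            if st is not None:
                out[i] = st.row()[name]
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for v, st, bad in zip(self.values, self.states, self.failed):
            row = {"parameter": self.parameter, "value": v}
            if st is None:
                row["converged"] = False
            else:
                row.update(st.row())
                row["converged"] = bool(row["converged"]) and not bad
            rows.append(row)
        return pd.DataFrame(rows)


def _residuals(u, params, bath, x_moles, z, length, osmotic_offset, c):
    ln_na, ln_k, ln_cl, ln_w, vm = u
    na, k, cl, w = math.exp(ln_na), math.exp(ln_k), math.exp(ln_cl), math.exp(ln_w)
    x = x_moles / w
    r = math.sqrt(w / (_PI * length))
    am = 2.0 / r
    e_na = c.RTF * math.log(bath.na / na)
    e_k = c.RTF * math.log(bath.k / k)
    e_cl = -c.RTF * math.log(bath.cl / cl)
    if params.pump_mode == "fixed":
        jp = params.fixed_jp
    else:
        jp = params.pump_rate * (na / bath.na) ** 3
    jk = params.g_kcc2 * (e_k - e_cl)
    if osmotic_offset is not None:
        gap_target = osmotic_offset
    elif params.volume_mode == "tension":
        hp = 0.0 if r <= params.r_a else 4.0 * _PI * params.k_m * (1.0 - params.r_a / r)
        gap_target = hp / c.RT_pressure
    else:
        gap_target = 0.0
    return np.array([
        (params.g_na * (vm - e_na) + 3.0 * jp) * 1e4,
        (params.g_k * (vm - e_k) - 2.0 * jp - jk) * 1e4,
        (params.g_cl * (vm - e_cl) + jk) * 1e4,
        ((na + k + cl + x) - bath.osmolarity - gap_target) * 1e3,
        (params.c_m * am * vm / c.F - (na + k - cl + z * x)) * 1e6,
    ])


def solve_steady_state(params: MembraneParams, bath: BathComposition,
                       x_moles: float, z: float, length: float,
                       guess: Optional[SteadyState] = None,
                       osmotic_offset: Optional[float] = None) -> SteadyState:
    """Solve for the fixed point given an impermeant pool (moles, mean z).

    ``osmotic_offset`` (mol/L), if given, replaces the osmotic-balance
    condition by a prescribed steady transmembrane osmolarity difference
    Pi_i - Pi_o (used for tension-style sweeps). Raises
    :class:`NoSteadyStateError` on non-convergence, reporting residuals.
    """
    if x_moles <= 0:
        raise ValueError("x_moles must be > 0")
    c = CONSTANTS
    if guess is not None:
        s = guess.state
        u0 = [math.log(s.na), math.log(s.k), math.log(s.cl),
              math.log(s.volume), guess.vm]
    else:
        w0 = x_moles / (155.0 * MM)
        u0 = [math.log(14.0 * MM), math.log(123.0 * MM), math.log(5.2 * MM),
              math.log(w0), -0.072]
    sol = root(_residuals, u0,
               args=(params, bath, x_moles, z, length, osmotic_offset, c),
               method="hybr", options={"xtol": 1e-13, "maxfev": 4000})
    res = _residuals(sol.x, params, bath, x_moles, z, length, osmotic_offset, c)
    # accept by residual; hybr's progress heuristic can stall at round-off
    if np.max(np.abs(res)) > 1e-6:
        raise NoSteadyStateError(
            f"steady-state solver did not converge: {sol.message}; "
            f"scaled residuals {res}", residuals=res)
    ln_na, ln_k, ln_cl, ln_w, vm = sol.x
    na, k, cl, w = map(math.exp, (ln_na, ln_k, ln_cl, ln_w))
    x = x_moles / w
    state = CompartmentState(
        na=na, k=k, cl=cl, pool=ImpermeantPool.single(x, z),
        radius=math.sqrt(w / (_PI * length)), length=length)
    e_na = nernst_potential(na, bath.na, +1)
    e_k = nernst_potential(k, bath.k, +1)
    e_cl = nernst_potential(cl, bath.cl, -1)
    jp = pump_flux(na, bath.na, params.pump_rate, params.pump_mode,
                   params.fixed_jp)
    jk = kcc2_flux(e_k, e_cl, params.g_kcc2)
    residuals = {
        "na_flux": params.g_na * (vm - e_na) + 3.0 * jp,
        "k_flux": params.g_k * (vm - e_k) - 2.0 * jp - jk,
        "cl_flux": params.g_cl * (vm - e_cl) + jk,
        "osmotic": state.osmolarity - bath.osmolarity
        - (0.0 if osmotic_offset is None else osmotic_offset),
        "charge": params.c_m * state.area_per_volume * vm / c.F
        - state.net_charge_concentration,
    }
    return SteadyState(state=state, vm=vm, e_na=e_na, e_k=e_k, e_cl=e_cl,
                       jp=jp, jkcc2=jk, residuals=residuals)


SWEEPABLE_PARAMETERS = ("P", "g_Na", "g_K", "g_Cl", "g_KCC2", "z", "K_o",
                        "fixed_Jp", "osmotic_offset")

# grid units for sweepable parameters: conductances uS/cm^2, P and fixed_Jp
# C/(dm^2 s), z dimensionless, K_o mM, osmotic_offset mM.
_SWEEP_SCALE = {
    "P": 1.0, "g_Na": US_PER_CM2, "g_K": US_PER_CM2, "g_Cl": US_PER_CM2,
    "g_KCC2": US_PER_CM2, "z": 1.0, "K_o": MM, "fixed_Jp": 1.0,
    "osmotic_offset": MM,
}


def _apply_sweep_value(name: str, value: float, params: MembraneParams,
                       bath: BathComposition, z: float):
    """Return (params, bath, z, osmotic_offset) for one canonical value."""
    offset = None
    p = params.copy()
    b = bath.copy()
    if name == "P":
        p.pump_rate = value
    elif name == "g_Na":
        p.g_na = value
    elif name == "g_K":
        p.g_k = value
    elif name == "g_Cl":
        p.g_cl = value
    elif name == "g_KCC2":
        p.g_kcc2 = value
    elif name == "z":
        z = value
    elif name == "K_o":
        # swap against Na+ so bath osmolarity and charge stay fixed
        b.na += b.k - value
        b.k = value
        if b.na < 0:
            raise ValueError("K_o sweep exhausted bath Na+")
    elif name == "fixed_Jp":
        p.pump_mode = "fixed"
        p.fixed_jp = value
    elif name == "osmotic_offset":
        offset = value
    else:
        raise ValueError(f"unknown sweep parameter {name!r}")
    return p, b, z, offset


def sweep(parameter: str, values: Sequence[float], params: MembraneParams,
          bath: BathComposition, x_moles: float, z: float,
          length: float) -> SweepResult:
    """Steady states along a grid, by continuation from the default point.

    The grid (in the laboratory units of ``SWEEPABLE_PARAMETERS``) is
    walked outward from the point nearest the default parameterization,
    warm-starting each solve from its neighbour; per-point failures are
    flagged.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    grid = np.asarray(list(values), dtype=float)
    canon = grid * _SWEEP_SCALE[parameter]
    try:
        anchor = solve_steady_state(params, bath, x_moles, z, length)
    except NoSteadyStateError:
        anchor = None

    states: list = [None] * len(canon)
    failed = np.zeros(len(canon), dtype=bool)
    # default canonical value of the swept parameter, to pick the start
    defaults = {
        "P": params.pump_rate, "g_Na": params.g_na, "g_K": params.g_k,
        "g_Cl": params.g_cl, "g_KCC2": params.g_kcc2, "z": z,
        "K_o": bath.k, "fixed_Jp": params.pump_rate * (14.0 / 145.0) ** 3,
        "osmotic_offset": 0.0,
    }
    start = int(np.argmin(np.abs(canon - defaults[parameter])))

    def solve_at(i: int, guess):
        p, b, zz, offset = _apply_sweep_value(parameter, canon[i], params,
                                              bath, z)
        try:
            states[i] = solve_steady_state(p, b, x_moles, zz, length,
                                           guess=guess,
                                           osmotic_offset=offset)
        except NoSteadyStateError:
            failed[i] = True
        return states[i]

    guess = solve_at(start, anchor)
    prev = guess or anchor
    for i in range(start + 1, len(canon)):
        out = solve_at(i, prev)
        prev = out or prev
    prev = guess or anchor
    for i in range(start - 1, -1, -1):
        out = solve_at(i, prev)
        prev = out or prev
    return SweepResult(parameter=parameter, values=grid, states=states,
                       failed=failed)
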