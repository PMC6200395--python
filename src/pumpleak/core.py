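"""Single-compartment pump-leak biophysics: domain types and membrane physics.

A cylindrical cell of fixed length and variable radius encloses Na+, K+ and
Cl- (membrane permeant, moved by leak conductances, the Na+/K+-ATPase and
the K+-Cl- cotransporter KCC2) together with a pool of impermeant species of
mean charge z. The membrane potential follows the charge-difference
formulation: V_m is the net intracellular charge divided by the membrane
capacitance, so no steady-state assumption (as in Goldman-Hodgkin-Katz) is
required. Cell volume responds to the transmembrane osmotic gradient by an
explicit water flux, optionally opposed by a Hookean membrane-tension
(hydrostatic) pressure.

All quantities here are in the canonical units documented in
:mod:`pumpleak.constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

from .constants import CONSTANTS, F_PER_CM2, MM, PL_PER_L, UM, US_PER_CM2, PhysicalConstants

__all__ = [
    "DomainError",
    "MembraneParams",
    "BathComposition",
    "ImpermeantPool",
    "CompartmentState",
    "nernst_potential",
    "membrane_voltage",
    "osmolarity",
    "pump_flux",
    "kcc2_flux",
    "hydrostatic_pressure",
    "volume_flux",
    "ion_derivatives",
]

_PI = math.pi


class DomainError(ValueError):
    """Raised when a physical quantity leaves its admissible domain."""


@dataclass
class MembraneParams:
    """Membrane parameters of one compartment.

    All conductances are specific conductances in S/dm^2; ``pump_rate`` is
    the ATPase pump-rate constant P in C/(dm^2 s); ``c_m`` is the specific
    capacitance in F/dm^2. ``v_w`` (dm^3/mol) and ``p_w`` (dm/s) control the
    osmotic water flux; ``k_m`` (N/dm) and ``r_a`` (dm) parameterize the
    optional membrane-tension volume constraint.

    ``pump_mode`` is ``"dynamic"`` (cubic dependence on the transmembrane
    Na+ gradient) or ``"fixed"`` (the effective pump rate is clamped at
    ``fixed_jp`` regardless of Na+). ``volume_mode`` is ``"osmotic"`` or
    ``"tension"``.
    """

    g_na: float
    g_k: float
    g_cl: float
    g_kcc2: float
    pump_rate: float
    c_m: float
    v_w: float = 0.018
    p_w: float = 0.0015
    k_m: float = 25.0
    r_a: float = 5e-5
    pump_mode: str = "dynamic"
    fixed_jp: float = 0.0
    volume_mode: str = "osmotic"

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_cl", "g_kcc2", "pump_rate"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.c_m <= 0:
            raise DomainError("c_m must be > 0")
        if self.pump_mode not in ("dynamic", "fixed"):
            raise DomainError(f"unknown pump_mode {self.pump_mode!r}")
        if self.volume_mode not in ("osmotic", "tension"):
            raise DomainError(f"unknown volume_mode {self.volume_mode!r}")
        if self.pump_mode == "fixed" and self.fixed_jp < 0:
            raise DomainError("fixed_jp must be >= 0")

    @classmethod
    def from_lab_units(
        cls,
        g_na_uS_cm2: float = 20.0,
        g_k_uS_cm2: float = 70.0,
        g_cl_uS_cm2: float = 20.0,
        g_kcc2_uS_cm2: float = 20.0,
        pump_rate: float = 0.1,
        cm_F_cm2: float = 2e-6,
        v_w: float = 0.018,
        p_w: float = 0.0015,
        k_m: float = 25.0,
        r_a_um: float = 5.0,
        **kwargs,
    ) -> "MembraneParams":
        """Build from the mixed units conventionally quoted in the field.

        Conductances in uS/cm^2, capacitance in F/cm^2, resting radius in um;
        the pump-rate constant is already in C/(dm^2 s).
        """
        return cls(
            g_na=g_na_uS_cm2 * US_PER_CM2,
            g_k=g_k_uS_cm2 * US_PER_CM2,
            g_cl=g_cl_uS_cm2 * US_PER_CM2,
            g_kcc2=g_kcc2_uS_cm2 * US_PER_CM2,
            pump_rate=pump_rate,
            c_m=cm_F_cm2 * F_PER_CM2,
            v_w=v_w,
            p_w=p_w,
            k_m=k_m,
            r_a=r_a_um * UM,
            **kwargs,
        )

    def copy(self) -> "MembraneParams":
        return replace(self)


@dataclass
class BathComposition:
    """Extracellular (infinite-bath) concentrations in mol/L.

    The bath is never updated by transmembrane flux; extracellular
    impermeant species carry a fixed valence of -1.
    """

    na: float
    k: float
    cl: float
    x: float

    def __post_init__(self) -> None:
        if min(self.na, self.k, self.cl, self.x) < 0:
            raise DomainError("bath concentrations must be >= 0")

    @classmethod
    def from_mM(cls, na_mM: float = 145.0, k_mM: float = 3.5,
                cl_mM: float = 119.0, x_mM: float = 29.5) -> "BathComposition":
        return cls(na=na_mM * MM, k=k_mM * MM, cl=cl_mM * MM, x=x_mM * MM)

    @property
    def osmolarity(self) -> float:
        return self.na + self.k + self.cl + self.x

    @property
    def charge_concentration(self) -> float:
        """Net charge concentration Na+ + K+ - Cl- - X- (mol/L)."""
        return self.na + self.k - self.cl - self.x

    def copy(self) -> "BathComposition":
        return replace(self)


class ImpermeantPool:
    """A heterogeneous pool of membrane-impermeant species.

    Each species is a (concentration, valence) pair; valences are signed
    reals (post-translational modification can make them non-integer). The
    mean charge z is the concentration-weighted mean valence. Under a pure
    volume change the moles of every species are conserved, so
    concentrations rescale by the inverse volume ratio.
    """

    __slots__ = ("concentrations", "valences")

    def __init__(self, species: Iterable[tuple[float, float]]):
        concs: list[float] = []
        vals: list[float] = []
        for c, z in species:
            if c < 0:
                raise DomainError("impermeant concentration must be >= 0")
            concs.append(float(c))
            vals.append(float(z))
        self.concentrations = concs
        self.valences = vals

    @classmethod
    def single(cls, concentration: float, valence: float) -> "ImpermeantPool":
        return cls([(concentration, valence)])

    @property
    def total_concentration(self) -> float:
        return sum(self.concentrations)

    @property
    def charge_concentration(self) -> float:
        """Sum of c_i * z_i over species (mol charge / L)."""
        return sum(c * z for c, z in zip(self.concentrations, self.valences))

    @property
    def mean_charge(self) -> float:
        total = self.total_concentration
        if total <= 0:
            raise DomainError("mean charge undefined for an empty pool")
        return self.charge_concentration / total

    def scaled(self, factor: float) -> "ImpermeantPool":
        """Concentrations multiplied by ``factor`` (volume change w0/w1)."""
        return ImpermeantPool(
            [(c * factor, z) for c, z in zip(self.concentrations, self.valences)]
        )

    def with_added(self, concentration: float, valence: float,
                   tol: float = 1e-12) -> "ImpermeantPool":
        """Add an amount of a species, merging with an existing valence."""
        if concentration < 0:
            raise DomainError("added concentration must be >= 0")
        concs = list(self.concentrations)
        vals = list(self.valences)
        for i, z in enumerate(vals):
            if abs(z - valence) <= tol:
                concs[i] += concentration
                break
        else:
            concs.append(concentration)
            vals.append(valence)
        return ImpermeantPool(zip(concs, vals))

    def copy(self) -> "ImpermeantPool":
        return ImpermeantPool(zip(self.concentrations, self.valences))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sp = ", ".join(
            f"({c:.6g}, {z:+.3g})"
            for c, z in zip(self.concentrations, self.valences)
        )
        return f"ImpermeantPool([{sp}])"


@dataclass
class CompartmentState:
    """Intracellular state of one cylindrical compartment.

    Concentrations in mol/L; geometry in dm. The cylinder length is fixed;
    volume changes are expressed as radius changes. Derived geometry:
    volume w = pi r^2 L, lateral surface area SA = 2 pi r L (no end caps),
    and the surface-to-volume ratio A_m = SA/w = 2/r.
    """

    na: float
    k: float
    cl: float
    pool: ImpermeantPool
    radius: float
    length: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise DomainError("radius and length must be > 0")
        if min(self.na, self.k, self.cl) < 0:
            raise DomainError("ion concentrations must be >= 0")

    @property
    def volume(self) -> float:
        return _PI * self.radius * self.radius * self.length

    @property
    def surface_area(self) -> float:
        return 2.0 * _PI * self.radius * self.length

    @property
    def area_per_volume(self) -> float:
        return 2.0 / self.radius

    @property
    def net_charge_concentration(self) -> float:
        """Na+ + K+ - Cl- + sum_i z_i X_i in mol charge / L."""
        return self.na + self.k - self.cl + self.pool.charge_concentration

    @property
    def osmolarity(self) -> float:
        return self.na + self.k + self.cl + self.pool.total_concentration

    def copy(self) -> "CompartmentState":
        return CompartmentState(
            na=self.na, k=self.k, cl=self.cl,
            pool=self.pool.copy(), radius=self.radius, length=self.length,
        )


# ---------------------------------------------------------------------------
# Membrane physics
# ---------------------------------------------------------------------------

def nernst_potential(c_i: float, c_o: float, valence: float,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Nernst (reversal) potential E = (RT/zF) ln(C_o/C_i), in volt."""
    if c_i <= 0 or c_o <= 0:
        raise DomainError("Nernst potential requires positive concentrations")
    if valence == 0:
        raise DomainError("Nernst potential undefined for valence 0")
    return constants.RTF / valence * math.log(c_o / c_i)


def membrane_voltage(state: CompartmentState, c_m: float,
                     constants: PhysicalConstants = CONSTANTS) -> float:
    """Charge-difference membrane potential (volt).

    V_m = F (Na+K-Cl+zX) / (C_m A_m): the net intracellular charge spread
    over the membrane capacitance. Valid arbitrarily far from steady state.
    """
    return constants.F * state.net_charge_concentration / (c_m * state.area_per_volume)


def osmolarity(obj: CompartmentState | BathComposition) -> float:
    """Total solute concentration (mol/L), osmotic coefficient 1.

    Each impermeant species counts by its concentration irrespective of
    valence.
    """
    return obj.osmolarity


def pump_flux(na_i: float, na_o: float, pump_rate: float,
              pump_mode: str = "dynamic", fixed_jp: float = 0.0) -> float:
    """Na+/K+-ATPase effective pump rate J_p in C/(dm^2 s).

    Dynamic mode is the cubic dependence on the transmembrane Na+ gradient,
    J_p = P (Na_i/Na_o)^3; fixed mode returns the configured constant
    regardless of Na_i.
    """
    if na_i < 0:
        raise DomainError("na_i must be >= 0")
    if na_o <= 0:
        raise DomainError("na_o must be > 0")
    if pump_mode == "fixed":
        return fixed_jp
    ratio = na_i / na_o
    return pump_rate * ratio * ratio * ratio


def kcc2_flux(e_k: float, e_cl: float, g_kcc2: float) -> float:
    """KCC2 cotransport flux J_KCC2 = g_KCC2 (E_K - E_Cl), C/(dm^2 s).

    Zero when E_K = E_Cl; the sign convention matches the ion balance
    equations (positive J_KCC2 moves K+ and Cl- into the cell).
    """
    return g_kcc2 * (e_k - e_cl)


def hydrostatic_pressure(radius: float, r_a: float, k_m: float) -> float:
    """Hookean membrane-tension pressure H_p = 4 pi k_m (1 - r_a/r).

    Zero at or below the resting radius r_a; saturates at 4 pi k_m as the
    radius grows.
    """
    if radius <= 0:
        raise DomainError("radius must be > 0")
    if radius <= r_a:
        return 0.0
    return 4.0 * _PI * k_m * (1.0 - r_a / radius)


def volume_flux(state: CompartmentState, bath: BathComposition,
                params: MembraneParams,
                constants: PhysicalConstants = CONSTANTS) -> float:
    """Rate of volume change dw/dt in dm^3/s.

    Osmotic mode: dw/dt = v_w p_w SA (Pi_i - Pi_o). Tension mode subtracts
    the pressure-equivalent osmolarity H_p/(RT), so a sustained osmotic
    differential can be balanced by membrane tension.
    """
    gap = state.osmolarity - bath.osmolarity
    if params.volume_mode == "tension":
        gap -= hydrostatic_pressure(state.radius, params.r_a, params.k_m) / constants.RT_pressure
    return params.v_w * params.p_w * state.surface_area * gap


def ion_derivatives(state: CompartmentState, params: MembraneParams,
                    bath: BathComposition, j_p: float, j_kcc2: float,
                    dwdt: float,
                    constants: PhysicalConstants = CONSTANTS) -> tuple[float, float, float]:
    """Time derivatives (dNa/dt, dK/dt, dCl/dt) in mol/L per second.

    Each permeant ion combines its leak current (Ohm's law against its
    Nernst potential), active transport (3:2 ATPase stoichiometry; 1:1
    KCC2 stoichiometry on K+ and Cl-) and a dilution term from volume
    change.
    """
    vm = membrane_voltage(state, params.c_m, constants)
    e_na = nernst_potential(state.na, bath.na, +1, constants)
    e_k = nernst_potential(state.k, bath.k, +1, constants)
    e_cl = nernst_potential(state.cl, bath.cl, -1, constants)
    am_f = state.area_per_volume / constants.F
    dil = dwdt / state.volume
    dna = -am_f * (params.g_na * (vm - e_na) + 3.0 * j_p) - dil * state.na
    dk = -am_f * (params.g_k * (vm - e_k) - 2.0 * j_p - j_kcc2) - dil * state.k
    dcl = am_f * (params.g_cl * (vm - e_cl) + j_kcc2) - dil * state.cl
    return dna, dk, dcl
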