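"""Configuration handling, fixtures and CSV output.

Configuration files are YAML mappings whose keys mirror the conventional
parameter table (conductances in uS/cm^2, capacitance in F/cm^2, bath in
mM, geometry in um). Resolution order is built-in defaults <- file <- CLI
overrides; unknown keys are rejected by name. The model is deterministic,
so identical configuration + protocol yields byte-identical CSV output
(numbers are written with 17 significant digits).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .chain import ChainModel, DiffusionParams
from .constants import MM, UM
from .core import (
    BathComposition,
    CompartmentState,
    ImpermeantPool,
    MembraneParams,
)
from .dynamics import SimulationConfig
from .protocols import ProtocolEvent

__all__ = [
    "ConfigError",
    "DEFAULT_CONFIG",
    "DEFAULT_X_MM",
    "load_config",
    "load_protocol",
    "build_single",
    "build_chain",
    "make_default_cell",
    "make_default_dendrite",
    "initial_state",
    "write_timeseries",
    "write_frame",
]

# Default intracellular impermeant concentration: exactly electroneutral
# against the default Na/K/Cl targets at mean charge -0.85.
DEFAULT_X_MM = (14.0 + 122.9 - 5.2) / 0.85


class ConfigError(ValueError):
    """Raised for malformed configuration input, naming the offending key."""


DEFAULT_CONFIG = {
    "g_na_uS_cm2": 20.0,
    "g_k_uS_cm2": 70.0,
    "g_cl_uS_cm2": 20.0,
    "g_kcc2_uS_cm2": 20.0,
    "p_pump": 0.1,
    "cm_F_cm2": 2e-6,
    "vw": 0.018,
    "pw": 0.0015,
    "km": 25.0,
    "bath": {"na_mM": 145.0, "k_mM": 3.5, "cl_mM": 119.0, "x_mM": 29.5},
    "cell": {"diameter_um": 10.0, "length_um": 25.0,
             "na_mM": 14.0, "k_mM": None, "cl_mM": 5.2,
             "x_mM": None, "z": -0.85},
    # dt_ms None means "the mode's default": 1 ms for the single
    # compartment, 1e-3 ms for the chain
    "sim": {"dt_ms": None, "duration_ms": 3_600_000.0,
            "record_every_ms": 1000.0},
    "chain": {"n_compartments": 10, "compartment_length_um": 10.0,
              "initial_radius_um": 0.5, "d_na_dm2_s": 1.33e-7,
              "d_k_dm2_s": 1.96e-7, "d_cl_dm2_s": 2.03e-7,
              "mode": "legacy"},
}


def _merge(base: dict, extra: dict, prefix: str = "") -> dict:
    out = dict(base)
    for key, value in extra.items():
        if key not in base:
            raise ConfigError(f"unknown configuration key {prefix + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(
                    f"configuration key {prefix + key!r} must be a mapping")
            out[key] = _merge(base[key], value, prefix=f"{prefix}{key}.")
        else:
            out[key] = value
    return out


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[dict] = None) -> dict:
    """Resolve a configuration: defaults <- file <- overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must be a mapping")
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def load_protocol(path: str | Path) -> list[ProtocolEvent]:
    """Read a protocol file: a YAML list of event mappings."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    if not isinstance(data, list):
        raise ConfigError("protocol file must be a list of events")
    events = []
    for i, entry in enumerate(data):
        try:
            events.append(ProtocolEvent(**entry))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"protocol event {i}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def initial_state(cl_mM: float = 5.2, na_mM: float = 14.0,
                  k_mM: Optional[float] = None,
                  x_mM: Optional[float] = None, z: float = -0.85,
                  diameter_um: float = 10.0,
                  length_um: float = 25.0) -> CompartmentState:
    """Electroneutral initial state with target concentrations.

    If ``k_mM`` is None, K+ balances the net charge so V_m(0) = 0 exactly
    (the printed steady-state concentrations are rounded to 0.1 mM and
    cannot encode the ~6 uM charge offset behind the resting potential; the
    dynamics settle it). If ``x_mM`` is also None the default pool
    (electroneutral against the default Na/K/Cl at z = -0.85) is used, so
    varying ``cl_mM`` never changes the impermeant mole count.
    """
    if x_mM is None:
        x_mM = DEFAULT_X_MM
    if k_mM is None:
        k_mM = cl_mM - na_mM - z * x_mM
        if k_mM < 0:
            raise ConfigError("electroneutral initialization needs K+ >= 0; "
                              "adjust cl_mM/x_mM")
    return CompartmentState(
        na=na_mM * MM, k=k_mM * MM, cl=cl_mM * MM,
        pool=ImpermeantPool.single(x_mM * MM, z),
        radius=0.5 * diameter_um * UM, length=length_um * UM)


def make_default_cell(cl_mM: float = 5.2, **kwargs):
    """Default single cell: 10 um diameter x 25 um cylinder (~1.96 pL).

    Returns ``(state, params, bath)`` with the default parameterization;
    the state settles to the default steady state under ``simulate``.
    """
    state = initial_state(cl_mM=cl_mM, **kwargs)
    params = MembraneParams.from_lab_units(r_a_um=5.0)
    bath = BathComposition.from_mM()
    return state, params, bath


def make_default_dendrite(n_compartments: int = 10,
                          compartment_length_um: float = 10.0,
                          initial_radius_um: float = 0.5,
                          diffusion: Optional[DiffusionParams] = None,
                          mode: str = "legacy") -> ChainModel:
    """Default virtual dendrite: 10 compartments of 10 um x r=0.5 um."""
    states = [
        initial_state(diameter_um=2.0 * initial_radius_um,
                      length_um=compartment_length_um)
        for _ in range(n_compartments)
    ]
    params = [MembraneParams.from_lab_units(r_a_um=initial_radius_um)
              for _ in range(n_compartments)]
    return ChainModel(states=states, params=params,
                      bath=BathComposition.from_mM(),
                      diffusion=diffusion or DiffusionParams(), mode=mode)


def build_single(cfg: dict):
    """Build (state, params, bath, sim_config) from a resolved config."""
    cell = cfg["cell"]
    state = initial_state(
        cl_mM=cell["cl_mM"], na_mM=cell["na_mM"], k_mM=cell["k_mM"],
        x_mM=cell["x_mM"], z=cell["z"],
        diameter_um=cell["diameter_um"], length_um=cell["length_um"])
    params = MembraneParams.from_lab_units(
        g_na_uS_cm2=cfg["g_na_uS_cm2"], g_k_uS_cm2=cfg["g_k_uS_cm2"],
        g_cl_uS_cm2=cfg["g_cl_uS_cm2"], g_kcc2_uS_cm2=cfg["g_kcc2_uS_cm2"],
        pump_rate=cfg["p_pump"], cm_F_cm2=cfg["cm_F_cm2"],
        v_w=cfg["vw"], p_w=cfg["pw"], k_m=cfg["km"],
        r_a_um=0.5 * cell["diameter_um"])
    bath = BathComposition.from_mM(**cfg["bath"])
    sim_kw = dict(cfg["sim"])
    if sim_kw.get("dt_ms") is None:
        sim_kw["dt_ms"] = 1.0
    sim = SimulationConfig(**sim_kw)
    return state, params, bath, sim


def build_chain(cfg: dict):
    """Build (chain, sim_config) from a resolved config."""
    ch = cfg["chain"]
    diffusion = DiffusionParams(d_na=ch["d_na_dm2_s"], d_k=ch["d_k_dm2_s"],
                                d_cl=ch["d_cl_dm2_s"])
    chain = make_default_dendrite(
        n_compartments=ch["n_compartments"],
        compartment_length_um=ch["compartment_length_um"],
        initial_radius_um=ch["initial_radius_um"],
        diffusion=diffusion, mode=ch["mode"])
    for p in chain.params:
        p.g_na = cfg["g_na_uS_cm2"] * 1e-4
        p.g_k = cfg["g_k_uS_cm2"] * 1e-4
        p.g_cl = cfg["g_cl_uS_cm2"] * 1e-4
        p.g_kcc2 = cfg["g_kcc2_uS_cm2"] * 1e-4
        p.pump_rate = cfg["p_pump"]
    sim_kw = dict(cfg["sim"])
    if sim_kw.get("dt_ms") is None:
        sim_kw["dt_ms"] = 1e-3
    sim = SimulationConfig(**sim_kw)
    return chain, sim


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_frame(frame, path: str | Path) -> None:
    """CSV output at 17 significant digits (byte-reproducible)."""
    frame.to_csv(path, index=False, float_format="%.17g")


def write_timeseries(result, path: str | Path) -> None:
    """Write a (chain or single) time-series result in the shared dialect."""
    write_frame(result.to_frame(), path)
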