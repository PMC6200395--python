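# pumpleak

A biophysical pump-leak model of neuronal chloride and volume homeostasis.

Fast synaptic inhibition depends on the driving force for Cl⁻ across
GABA_A/glycine receptor channels, DF = V_m − E_Cl. Whether that driving
force is set by cation-chloride cotransporters (chiefly KCC2) or by the
cell's impermeant anions has been contested. `pumpleak` implements a
single-compartment pump-leak model of a cylindrical neuron — and a
multi-compartment "virtual dendrite" extension — in which that question can
be answered quantitatively: every ion gradient, the membrane potential and
the cell volume emerge from the same small set of first-principles fluxes,
with no sensors or set points.

## The model

A cylinder of fixed length L and variable radius r (volume w = πr²L,
lateral membrane area SA = 2πrL) encloses Na⁺, K⁺, Cl⁻ and a pool of
impermeant species Xᶻ with concentration-weighted mean valence z. The
extracellular bath is infinite and fixed. The membrane potential follows
the charge-difference formulation (valid away from steady state, unlike
Goldman–Hodgkin–Katz):

    V_m = F ([Na⁺]ᵢ + [K⁺]ᵢ − [Cl⁻]ᵢ + z[Xᶻ]ᵢ) / (C_m · A_m),   A_m = SA/w = 2/r

Active transport is a 3:2 Na⁺/K⁺-ATPase whose effective rate is a cubic
function of the transmembrane Na⁺ gradient,

    J_p = P ([Na⁺]ᵢ/[Na⁺]ₒ)³,

and an electroneutral 1:1 K⁺–Cl⁻ cotransporter driven by the difference of
reversal potentials,

    J_KCC2 = g_KCC2 (E_K − E_Cl),    E_ion = (RT/zF) ln([ion]ₒ/[ion]ᵢ).

Each permeant ion combines its ohmic leak g(V_m − E), the pump/cotransport
stoichiometry, and a dilution term from volume change; water moves down the
osmotic gradient, dw/dt = v_w p_w SA (Πᵢ − Πₒ), optionally opposed by a
Hookean membrane-tension pressure H_p = 4πk_m(1 − r_a/r). The
multi-compartment model couples compartments by the Nernst–Planck equation
(Fickian diffusion plus electrical drift); impermeant anions never cross
compartment boundaries.

The package provides:

- `pumpleak.core` / `pumpleak.dynamics` — the domain types, the membrane
  physics, and a forward-Euler integrator (dt = 1 ms);
- `pumpleak.steady` — a direct fixed-point solver and parameter sweeps
  (the counterpart of integrating to equilibrium, verified to agree with
  it);
- `pumpleak.protocols` — timed manipulations: ATPase off/on ramps,
  conductance ramps, impermeant-anion injections, mean-charge changes,
  osmoneutral bath swaps, pump clamping, tension-mode volume handling;
- `pumpleak.chain` — the 10-compartment virtual dendrite with
  electrodiffusion (forward Euler at dt = 10⁻³ ms plus an implicit
  relaxation and a chain fixed-point solver);
- `pumpleak.experiments` — a registry of canned experiments
  (`fig1b` … `fig8b_c`) runnable from Python or the CLI.

## Worked example

Solve the default cell's steady state (10 µm diameter × 25 µm cylinder,
g_Na/g_K/g_Cl/g_KCC2 = 20/70/20/20 µS/cm², P = 0.1 C/(dm²·s), z = −0.85):

```python
from pumpleak import make_default_cell, solve_steady_state

state, params, bath = make_default_cell()
ss = solve_steady_state(params, bath,
                        x_moles=state.pool.total_concentration * state.volume,
                        z=-0.85, length=state.length)
for key, value in ss.row().items():
    print(f"{key:>12}: {value}")
```

prints

```
       na_mM: 14.001919045893056
        k_mM: 122.8730568223493
       cl_mM: 5.164831207779936
        x_mM: 154.96019292397781
           z: -0.85
   radius_um: 4.9996931948056575
   volume_pL: 1.9632544516503718
       vm_mV: -72.59261426358253
      ena_mV: 62.4745990047178
       ek_mV: -95.10381647496592
      ecl_mV: -83.84821536927424
       df_mV: 11.25560110569171
          jp: 9.004480884553346e-05
       jkcc2: -2.2511202211383365e-05
   converged: True
```

That is the resting state of a mature neuron: ~5 mM intracellular Cl⁻, a
−72.6 mV resting potential, a 2 pL volume, and an 11.3 mV chloride driving
force sustained entirely by KCC2 (set `g_kcc2 = 0` and DF collapses to
zero). Integrating the ODEs from any starting composition
(`pumpleak.simulate`) lands on the same point — the fixed point needs no
sensing machinery.

The same model is available from the shell:

```sh
pumpleak steady-state
pumpleak sweep --parameter g_KCC2 --start 0 --stop 600 --num 25 --out sweep.csv
pumpleak experiment fig7b_c --out out/
pumpleak list-experiments
```

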