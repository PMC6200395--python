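# Methods

## Model

One compartment is a cylinder of fixed length and variable radius holding
Na⁺, K⁺, Cl⁻ and a pool of membrane-impermeant species. The five coupled
mechanisms are: ohmic leak currents for each permeant ion; a Na⁺/K⁺-ATPase
with 3:2 stoichiometry whose effective rate is cubic in the transmembrane
Na⁺ ratio, J_p = P([Na⁺]ᵢ/[Na⁺]ₒ)³; electroneutral 1:1 K⁺–Cl⁻ cotransport,
J_KCC2 = g_KCC2(E_K − E_Cl); transmembrane water flux proportional to the
osmotic gradient; and the charge-difference membrane potential, V_m =
F·(net intracellular charge concentration)/(C_m·A_m). The extracellular
space is an infinite bath: its composition never responds to transmembrane
flux, and its impermeant species carry valence −1.

Assumptions worth stating explicitly:

- **No bicarbonate, no synaptic or voltage-gated conductances.** The model
  addresses chronic chloride homeostasis, not transient GABAergic signalling.
- **Osmotic coefficients are 1** and every impermeant species contributes
  its full concentration to osmolarity regardless of valence.
- **Membrane area is the lateral cylinder surface only** (SA = 2πrL, no end
  caps), so the surface-to-volume ratio is exactly 2/r and both rescale
  consistently as the radius changes at fixed length.
- **Temperature is fixed at 310.15 K**; there is no Q10 scaling anywhere.
- **The impermeant pool is a species list**, each entry a (concentration,
  valence) pair; the mean charge z is the concentration-weighted mean
  valence. This lets an influx of a valence −1.5 species shift the mean
  charge of an existing z = −0.85 pool, with the mean emerging from the
  composition rather than being set directly.

### Membrane tension (volume-constrained mode)

In tension mode the water flux is opposed by a Hookean hydrostatic
pressure, H_p = 4πk_m(1 − r_a/r) for r > r_a and 0 otherwise. H_p/(RT)
converts the pressure to an equivalent osmolarity with RT expressed in
N·dm/mol (R·T·10, since 1 J = 10 N·dm); with the default k_m = 25 N/dm the
term saturates at ≈12 mM, i.e. membrane tension can hold a steady
transmembrane osmotic differential of order 10 mM. k_m is deliberately
stiffer than measured membranes so the consequences of a constrained
volume are visible; it is not a physiological estimate.

## Parameters

Canonical internal units are dm, dm³ (= L), mol/L, V, s, S/dm², F/dm² and
C/(dm²·s); constructors convert from the laboratory units below. One canon
avoids silent factor-of-100 errors between cm²- and dm²-based quantities.

| parameter | default | unit | role |
|---|---|---|---|
| g_Na, g_K, g_Cl | 20, 70, 20 | µS/cm² | leak conductances |
| g_KCC2 | 20 | µS/cm² | KCC2 activity |
| P | 0.1 | C/(dm²·s) | ATPase pump-rate constant |
| C_m | 2×10⁻⁶ | F/cm² | specific capacitance |
| v_w | 0.018 | dm³/mol | partial molar volume of water |
| p_w | 0.0015 | dm/s | osmotic water permeability |
| k_m | 25 | N/dm | membrane spring constant (tension mode) |
| [Na⁺]ₒ, [K⁺]ₒ, [Cl⁻]ₒ, [X⁻]ₒ | 145, 3.5, 119, 29.5 | mM | bath (Πₒ = 297 mM) |
| z | −0.85 | — | mean impermeant valence |
| D_Na, D_K, D_Cl | 1.33, 1.96, 2.03 ×10⁻⁷ | dm²/s | cytoplasmic diffusion |
| cell | 10 µm ⌀ × 25 µm | — | single compartment (≈1.96 pL) |
| dendrite | 10 × (1 µm ⌀ × 10 µm) | — | chain compartments |

A note on the pump constant: with the cubic pump law, P = 0.1 C/(dm²·s)
gives an effective rate J_p ≈ 9×10⁻⁵ C/(dm²·s) at the default steady state
([Na⁺]ᵢ = 14 mM), which is exactly what the Na⁺ flux balance
g_Na(V_m − E_Na) = −3J_p requires there.

## Initialization policy

States are built exactly electroneutral, so V_m(0) = 0. Resting-state
concentrations printed to 0.1 mM cannot encode the ~6 µM net-charge offset
behind a −72.6 mV potential, and the dynamics settle that offset within
milliseconds, so nothing is lost by starting neutral. When the initial
Cl⁻ is varied (the convergence experiment), K⁺ — not the impermeant pool —
absorbs the charge difference: this keeps the impermeant mole count
identical across runs, and since that mole count (with z) fully determines
the steady-state volume, all such runs converge to the same volume as well
as the same concentrations. Varying the initial impermeant concentration
instead (at fixed z) changes the mole count and hence the final volume —
linearly — while leaving every potential unchanged.

## Numerics

**Integration.** Forward Euler, dt = 1 ms for the single compartment.
Update order within a step: all fluxes are evaluated on the pre-step
state; ion concentrations advance including the dilution term (using the
pre-step dw/dt); protocol injection source terms are applied; the volume
advances and becomes a radius change at fixed length; impermeant
concentrations are rescaled by the exact volume ratio, conserving their
moles to round-off. A negative concentration aborts the run naming the ion
and time — clamping would silently violate conservation. Halving dt moves
the settled V_m by well under 10⁻³ mV (tested).

**Steady-state detection.** max|d[ion]/dt| < 10⁻⁶ mM/s and |dw/dt|/w <
10⁻⁹ s⁻¹ sustained for 1000 consecutive steps; configurable. Runs never
stop before the last protocol event has finished.

**Fixed-point solver.** scipy's hybrid Newton (`root`, method `hybr`) on
(log Na, log K, log Cl, log w, V_m) with five conditions: three zero-flux
balances, osmotic balance (Πᵢ = Πₒ, with the tension offset or a
prescribed differential where applicable), and consistency of V_m with the
net charge. Log variables keep concentrations and volume positive.
Acceptance is by residual, not by the optimizer's progress heuristic. A
pump rate of zero has no fixed point (the volume grows without bound) and
raises an explicit no-steady-state error. Sweeps walk their grid outward
from the point nearest the default parameterization, warm-starting each
solve from its neighbour; failed points are flagged, never dropped. The
solver's points are verified against the integrator: for random parameter
draws within ±50% of the defaults, a trajectory started at the solved
point stays on it to < 10⁻² mV and < 10⁻² mM.

**Electrodiffusion.** Fluxes between neighbouring compartments follow the
Nernst–Planck form J = −D[(zF/RT)·C̄·ΔV/Δx + ΔC/Δx] with C̄ the interface
mean and Δx the midpoint distance; each compartment uses its own
charge-difference V_m in the drift term (no cable/axial-resistivity term),
and chain ends are sealed. Two normalizations are provided: a
`legacy` scheme dividing the interface flux by each compartment's own
length (the historical discretization of dendritic electrodiffusion;
exact mole conservation only for identical geometries) and a
`conservative` scheme
with an explicit interface area A = π·min(rᵢ, rᵢ₊₁)² — the cross-section
of the thinner neighbour, since the interface cannot exceed it — and
per-volume normalization, conserving chain-wide moles to round-off for any
geometry. Figure-style runs default to the `legacy` scheme; conservation
tests use the `conservative` one.

**Chain time stepping and steady states.** The explicit chain integrator
uses dt = 10⁻³ ms; the binding stability constraint is the axial
charge-relaxation time (the drift term discharging a compartment's
membrane capacitance through the interface cross-section, ~7 µs for the
default dendrite), which the integrator checks and enforces. Persistent
(steady-state) chain quantities are computed by Newton root-finding on the
same discretized right-hand side the integrator uses — the solution is
therefore a fixed point of the integrator by construction, and the test
suite additionally verifies residence of a short fine-dt Euler segment at
each solved point. When a Newton solve from a distant starting point
stalls, the chain is first relaxed by an implicit (BDF) pseudo-transient
integration of the same ODEs — which carries the chain's own impermeant
pools and parameters — and then polished. Problem sizes throughout
(10 compartments; minutes-to-hours of simulated time for single-compartment
protocols) are the package's working defaults.

## Protocols

Timed events during integration: exponential ATPase off/on ramps (time
constant = duration/5, default window 15 min, consistent with the
10–20 min pharmacology of pump block and its reversal; a zero-duration
ramp is a step); linear parameter ramps; constant-rate impermeant
injection (valence defaulting to the pool mean captured at onset);
mean-charge ramps that adjust one designated species' valence continuously
at fixed moles (imitating a charge-carrying transmembrane reaction);
instantaneous osmoneutral, electroneutral bath swaps (X⁻ for Cl⁻); pump
clamping at the instantaneous J_p; and volume-mode switches. Injection
magnitudes the narrative experiments leave open default to values that
land on the described end states (e.g. a valence −1.5 influx sized to move
one dendritic compartment's mean charge from −0.85 to −0.93) and are
configurable. In the dendrite, "the manipulated compartment" is the second
compartment from one end; the farthest compartment reported against it is
the one at the opposite end of the 100 µm chain.

## What the experiments show (and don't)

All inputs are parameter configurations; there is no external data and no
randomness (the test suite's random parameter draws are seeded). Passing
tests demonstrate the internal consistency and robustness of this model —
convergence to a unique fixed point from arbitrary initial compositions,
exact flux balances at rest, the KCC2-dependence of the chloride driving
force, the inertness of amount-only impermeant manipulations, and the
diffusion-dependence of local driving-force control. They do not validate
the model against biological measurements: real neurons have bicarbonate
fluxes, active NKCC1, nonstationary pump regulation, branched
morphologies, and cytoskeletal contributions to volume that are outside
this model's scope.

## Known limitations

- The KCC2 flux law is a single linear conductance in (E_K − E_Cl);
  saturating kinetic variants are not implemented.
- The ATPase is the cubic approximation; experimentally fitted kinetic
  pump models are not included.
- The charge-difference voltage assumes a well-stirred compartment; there
  is no intra-compartment radial structure.
- The `legacy` electrodiffusion normalization is not mole-conserving
  once adjacent radii diverge; use the conservative mode when that
  matters.
- The tension model is a deliberately stiff Hookean caricature, and the
  no-steady-state diagnosis for a silenced pump is a solver outcome, not a
  bifurcation analysis.
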