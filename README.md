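# nanodyad

Nano-scale electrodiffusion in the cardiomyocyte dyad, simulated with the
Poisson–Nernst–Planck (PNP) equations.

Every heartbeat begins with Ca²⁺ ions entering the ~10 nm cleft (the
*dyad*) between the T-tubule membrane and the sarcoplasmic reticulum, where
they trigger ryanodine receptors (RyRs) to release the main Ca²⁺ store. At
nanometer and nanosecond scales, electrical forces shape ion transport in
ways that spatially averaged or pure reaction–diffusion models cannot
capture: concentrations near the membrane deviate from electroneutrality
over the Debye length (~1 nm), and local charge imbalances relax on
sub-nanosecond time scales. `nanodyad` is for computational
electrophysiologists who want to resolve these effects explicitly and to
quantify when simpler models suffice.

## Model

The package solves the buffered PNP system

```
∇·(ε_r ε₀ ∇φ) = −( ρ₀ + F Σ_k z_k (c_k + Σ_j b_{k,j}) )
∂c_k/∂t = ∇·D_k∇c_k + ∇·( D_k z_k e/(k_B T) c_k ∇φ ) − Σ_j J^B_{k,j}
∂b_{k,j}/∂t = J^B_{k,j} = k_on c_k (B_tot − b) − k_off b
```

for Na⁺, K⁺, Ca²⁺ and Cl⁻ on a rectangular extracellular / membrane /
intracellular domain with two stationary intracellular Ca²⁺ buffers and a
background charge ρ₀ that makes the initial state exactly electroneutral.
Single K⁺, Na⁺ and Ca²⁺ channels (`i = g (v − v₀)` with the Nernst potential
v₀ from mouth-averaged concentrations) and a 3:1 Na⁺/Ca²⁺ exchanger enter as
internal flux boundary conditions on 4 × 4 nm membrane patches.

Numerically, each step splits explicit buffer kinetics from a **fully
coupled implicit** backward-Euler solve of the Poisson and Nernst–Planck
equations (drift mobility frozen at the interim concentrations, channel
fluxes linearized into the system). The coupled treatment removes the
sub-nanosecond stability limit of split schemes and allows microsecond time
steps. Space is discretized with conservative finite volumes on an adaptive
tensor mesh (0.5 nm next to the membrane, doubling away).

Also included: the reduced models used for comparison — pure diffusion,
reaction–diffusion with an imported membrane potential, and one-/two-
compartment ODE dyad models — plus diagnostics (charge-density profiles,
Debye-layer fits, equation-term magnitudes, RyR activation time).

## Worked example

Establish the resting state of the cell: from an electroneutral initial
condition, a single open K⁺ channel charges the membrane until the
transmembrane potential reaches the K⁺ Nernst level, and a Debye layer forms
on both membrane faces.

```python
import math
from nanodyad import preset, run, nernst_potential, mouth_state
from nanodyad.scenarios import units_3d

units = units_3d(250.0, 250.0)                 # reduced transverse domain
for u in units:
    u["schedule"] = [[0.0, math.inf]] if u["id"] == "K" else []
sc = preset("rest3d", "smoke").with_(
    geometry={"Ly": 250.0, "Lz": 250.0},
    units=units,
    solver={"dt": 1e-2, "buffer_substeps": 10},
    duration=3.0,                              # ms
)
result = run(sc)
m = mouth_state(result.state.phi, result.state.conc_dict(),
                result.mesh.unit_faces["K"])
print(f"v       = {m.v:.2f} mV")
print(f"Nernst  = {nernst_potential(1, m.ce['K'], m.ci['K']):.2f} mV")
```

prints

```
v       = -85.07 mV
Nernst  = -85.07 mV
```

i.e. the steady transmembrane potential (about −85 mV here, −86 mV from the
bulk concentrations 5/125 mM) equals the K⁺ Nernst potential evaluated at
the channel-mouth concentrations — the channel flux has self-consistently
vanished. `result.trajectory` holds the recorded time series (`v_K`,
point concentrations, patch-averaged Ca²⁺, species masses), and
`line_profile(result.state, result.mesh, "K")` extracts the Debye-layer
profiles of φ, c_k and ρ across the membrane.

## Command line

```bash
nanodyad list-presets
nanodyad run rest3d --resolution smoke --out results/rest -v
nanodyad run ca_open --set geometry.Li=5 --set solver.dt=2.5e-3 --out results/ca
nanodyad resume results/rest/checkpoint.npz --scenario my_scenario.yaml --out more
nanodyad summarize results/ca/trajectory.csv --series ca_ryr_ca --t-open 0.1
```

Presets cover the canonical scenarios (2D electroneutrality decay and
Debye-layer examples, resting state, Na⁺ upstroke, dyad Ca²⁺ entry with and
without NCX, and the dyad-width/diffusivity activation sweep), each at a
`reference` resolution and a coarsened `smoke` resolution. Runs write a
trajectory CSV, a VTK rectilinear snapshot (`.vtr`), a restartable
checkpoint and a JSON manifest of the fully resolved configuration.

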