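# Methods

## Model

`nanodyad` simulates electrodiffusion in the cardiomyocyte dyad — the
nanometer-scale cytosolic cleft between the T-tubule membrane and the
sarcoplasmic-reticulum (SR) membrane — with the Poisson–Nernst–Planck (PNP)
equations extended by stationary Ca²⁺-binding buffers:

```
∇·(ε_r ε₀ ∇φ) = −ρ,                     ρ = ρ₀ + F Σ_k z_k (c_k + Σ_j b_{k,j})
∂c_k/∂t = ∇·D_k∇c_k + ∇·( D_k z_k e/(k_B T) c_k ∇φ ) − Σ_j J^B_{k,j}
∂b_{k,j}/∂t = J^B_{k,j},                J^B = k_on c (B_tot − b) − k_off b
```

for the species k ∈ {Na⁺, K⁺, Ca²⁺, Cl⁻} (the simple 2D examples use K⁺/Cl⁻
only).  The domain is a rectangular cuboid split along x into extracellular
space Ωe (T-tubule lumen, depth `Le` = 100 nm), membrane Ωm (`Lm` = 5 nm,
ε_r = 2, D = 0) and intracellular dyad Ωi (`Li` = 7 nm by default, bounded on
the right by the closed SR membrane).  The background charge density ρ₀ is
chosen per cell so that the initial state is exactly electroneutral; it
represents immobile charge, including that of the buffer proteins, and is
zero inside the membrane.  Buffer-bound Ca²⁺ carries the valence of free
Ca²⁺ in ρ; all other protein charge sits in ρ₀.

Boundary conditions: homogeneous Neumann for all concentrations everywhere
(the *total* diffusive-plus-drift normal flux vanishes), homogeneous Neumann
for φ except a Dirichlet anchor φ = 0 on the leftmost (extracellular)
boundary.  The 2D perturbation example instead fixes φ = 0 and c = 100 mM on
all four sides.

### Membrane units

Channels and the Na⁺/Ca²⁺ exchanger (NCX) occupy `wc` × `wc` = 4 × 4 nm
membrane patches and enter as internal flux boundary conditions on the mouth
faces between the membrane and the adjacent cell layers.  A flux density J
(mM·nm/ms) is positive from intracellular to extracellular.

* **Channels** follow the ohmic single-channel model `i = g (v − v₀)` with
  `v = φ̄_i − φ̄_e` and the Nernst potential
  `v₀ = k_B T/(z e) · ln(c̄_e/c̄_i)` evaluated from area-weighted averages
  over the first non-membrane cell layer at each mouth.  The flux density is
  `J = g (v − v₀) / (z F wc²)`.  Conductances: g_K = 5 pS, g_Na = 20 pS,
  g_Ca = 8 pS.
* **NCX** uses an established allosterically regulated current-density
  formulation (in A/F) whose numerator vanishes at the reversal potential
  `3 v_Na − 2 v_Ca`; the single-exchanger current is `i = (C_m/δ_NCX) I_NCX`
  and the 3:1 stoichiometry gives `J_Na = 3 i/(F wc²)`,
  `J_Ca = − i/(F wc²)`.  At rest the exchanger extrudes Ca²⁺ and imports
  Na⁺; during the upstroke it reverses.

Gating is deterministic and instantaneous: a unit is open iff the current
time lies in one of its schedule intervals.

### Units

Internal units are nm / ms / mM / mV.  With ε₀ expressed in fF/m
(8854), `ε_r ε₀ ∇²φ` evaluated in mV/nm² is directly in C/m³, matching
`F Σ z c` with F in C/mol and c in mM (1 mM = 1 mol/m³), so the charge
density needs no unit conversion anywhere.  Conductances in zS times mV give
currents in yA, and `ymol/(nm²·s) = mM·nm/ms` holds identically.
Conversions to SI happen only at input parsing and reporting.

## Numerics

Each time step is a first-order operator splitting:

1. **Buffering step** — forward Euler on the binding kinetics, producing
   interim concentrations c̃ and updated bound concentrations.  Free + bound
   Ca is conserved exactly per cell.  Near an open Ca²⁺ channel the local
   binding rate `k_on·c` can exceed 1/Δt at the larger desk-scale time
   steps, so the step optionally subdivides into m identical forward-Euler
   substeps (`buffer_substeps`, default 1; the scaled 3D scenarios use 10).
   A bound concentration leaving [0, B_tot] raises an error advising a
   smaller Δt.
2. **Coupled implicit step** — backward Euler on the Poisson and
   Nernst–Planck equations *simultaneously*, linearized by freezing the
   drift mobility at c̃.  Unknowns are φ at every cell and c_k at every
   non-membrane cell.  Channel fluxes enter implicitly: the Nernst logarithm
   is expanded to first order about c̃,
   `ln(c_e/c_i) ≈ ln(c̃_e/c̃_i) + c_e/c̃_e − c_i/c̃_i`,
   making J affine in the current-step unknowns and exactly zero at
   `v = v₀(c̃)`, `c = c̃`.  (Care is needed with the mouth subscripts here:
   mixing the two mouths in one expansion term — an easy slip — yields a
   flux that does not vanish at equilibrium; the expansion above is the
   consistent one and is verified by the equilibrium test.)
   NCX fluxes are explicit: previous-step potential, interim concentrations.

The fully coupled implicit treatment is what permits time steps of order
1 µs where a split potential/transport scheme requires sub-ns steps.

### Spatial discretization

Conservative two-point-flux finite volumes on a tensor-product mesh; unknowns
at cell centers.  Face diffusivities are harmonic means of the adjacent cell
values — exactly zero into the membrane, so the membrane is impermeable by
construction and mass conservation is exact (interior face fluxes cancel
pairwise).  The face drift mobility uses the arithmetic mean of the adjacent
interim concentrations.  Face permittivities are harmonic means (ε_r = 80
bulk, 2 membrane).  Dirichlet boundaries use half-cell transmissibilities.

### Mesh

Along x the spacing is `fine_dx` (default 0.5 nm; 0.25 nm for dyads narrower
than 5 nm) in the cells adjacent to both membrane faces and to the SR
boundary, doubling per interval away from them, capped at `max_spacing`
(64 nm at reference resolution, 512 nm in the coarsened "smoke" variants).
Transversally the spacing is `fine_dyz` (2 nm reference, 4 nm smoke) over
each unit patch, doubling away.  Gaps between doubling ladders are filled by
a uniform block sized so that neighbouring intervals never differ by more
than a factor two; where that is impossible (degenerate short segments) the
segment falls back to a uniform grid no coarser than the fine spacing.
Mouth face sets always tile the wc² patch exactly, independent of
refinement.  Mesh generation is deterministic and mirror-symmetric.

### Linear solver

The coupled matrix (N_φ + K·N_c unknowns, ~5 nonzero blocks per cell) is
solved with SuperLU.  Small systems (≤ 4000 unknowns) are factorized
directly every step.  Larger systems exploit that the matrix changes slowly
(only drift coefficients and channel linearizations move between steps): one
LU factorization is frozen and reused as a GMRES preconditioner with the
previous solution as initial guess, refactoring when gating changes or
convergence degrades (> 30 iterations or residual above tolerance).  In the
3D scenarios this converges in 2–4 iterations per step.  Every step verifies
the true relative residual against the configured tolerance (default 1e-8;
the direct path achieves ~1e-14).  Unknowns are ordered by field block
rather than interleaved per cell; SuperLU's fill-reducing column permutation
makes the input ordering immaterial.

Concentrations are never clipped: a step producing a concentration below
−`neg_conc_tol` raises a diagnostic recommending a smaller time step.

## Reduced comparison models

* **Pure diffusion** — backward Euler on `∂c/∂t = ∇·D∇c` only; species
  decouple, no potential, no membrane fluxes, no buffering.  The matrix is
  static and factorized once.
* **Reaction–diffusion** — buffering + diffusion + membrane fluxes, with
  mouth potentials imported from a matched PNP run (`PotentialTrace`,
  piecewise-linear in time; channel fluxes use the trace at the new time
  level, the explicit NCX at the previous one, mirroring the PNP
  discretization).  With drift disabled and units closed this coincides with
  the full model field-for-field, which is tested.
* **Compartment ODE models** — reconstructions (the original compartment
  equations are not part of the main formulation): well-mixed compartments
  with mass-action buffering and linear diffusive exchange
  `Φ = k (c_neighbor − c_self)` in amount units.  The single-compartment
  variant is a dyad box (volume `Li × A_d`, A_d = 30 × 30 nm² — the
  RyR-apposed patch area) exchanging with a large cytosol compartment with a
  calibrated, diffusivity-independent coefficient `k_dl`; its activation
  time is therefore insensitive to D_Ca by construction.  The two-compartment
  variant splits the dyad at Li/2 into channel-side and RyR-side halves with
  a Fickian exchange `θ · D_Ca · A_d/(Li/2)` plus lateral leaks to the
  cytosol across the patch perimeter, all scaled by the single calibrated
  factor θ, so activation is monotone in both D_Ca and Li.  Calibration is a
  bracketed scalar root-find (log-space Brent) matching the reference
  activation time at D_Ca = 2×10⁵ nm²/ms, Li = 7 nm.  Integration uses the
  same operator splitting as the PDE models (explicit buffering, implicit
  exchange with the channel flux linearized about the post-buffering
  concentration).

## Diagnostics

* **Transmembrane potential** v = φ̄_i − φ̄_e per unit, from the mouth
  averages.
* **Equation-term magnitudes** B_d (diffusion), B_e (drift), B_b (buffering)
  are evaluated with the same discrete stencils as the solver, so
  `B_d + B_e − B_b = Δc/Δt` holds to solver rounding at every cell away
  from unit mouths.
* **RyR activation time** — delay from Ca²⁺-channel opening until the
  area-averaged free [Ca²⁺] on the 30 × 30 nm SR-boundary patch directly
  across from the channel first exceeds 0.5 µM, linearly interpolated
  between samples.  The patch average is overlap-area-weighted over the
  SR-adjacent intracellular cell layer ("not activated" is reported as a
  sentinel when the threshold is never crossed).
* **Line profiles** of φ, c_k and ρ along x at a chosen (y, z), used for the
  Debye-layer analyses; concentrations are masked inside the membrane.

## Scenario presets and problem sizes

Each preset carries a `reference` resolution (original time steps and mesh
grading: Δt = 0.1 ns for the 2D examples, 10 µs for the resting state, 1 µs
for upstroke/dyad scenarios, 1 ns for the activation sweep) and a `smoke`
resolution for desk-scale work (transverse fine spacing 4 nm, doubling cap
512 nm, Δt = 50 µs resting / 2.5 µs upstroke / 5 µs dyad scenarios, 10
buffering substeps).  The test suite and worked examples use the smoke
resolutions with these problem sizes:

* resting state: full 1 × 1 µm² membrane, ~8.5k cells, 3–5 ms simulated
  (the charging time constant is ~0.7 ms); a reduced 250 × 250 nm domain for
  the Nernst-equilibrium check;
* upstroke and dyad Ca²⁺ scenarios: full membrane area preserved (it sets
  the depolarization speed through the capacitance-to-conductance ratio),
  0.5–1 ms simulated; the steep Ca²⁺ entry transient is sampled at
  Δt = 2.5 µs;
* activation-time sweep: 100 × 100 nm transverse box, Δt = 5 ns, with the
  Ca²⁺ channel opened at t = 5 µs from the electroneutral state (identical
  protocol for the full and reaction–diffusion models, so their comparison
  is like-for-like);
* the 2D examples: 50 × 50 nm box (the original domain size is not
  specified); the perturbation example uses a Gaussian K⁺ elevation of
  amplitude 10 mM and width σ = 5 nm at the center (shape and amplitude are
  likewise unspecified; the decay-to-electroneutrality time constant is
  amplitude-independent in the linear regime).

Values measured on the smoke meshes sit within tens of percent of the
reference figures: the steep sub-microsecond Ca²⁺ transient after channel
opening is the most resolution-sensitive quantity (its peak grows from
~0.5 mM at Δt = 5 µs to ~0.85 mM at Δt = 2.5 µs on the coarse transverse
mesh, approaching the ~0.7 mM obtained at Δt = 1 µs on the reference mesh).

## What the scenarios do and do not emulate

The scenarios reproduce idealized study conditions: a rectangular dyad, one
channel of each type plus one NCX, deterministic gating, stationary buffers,
and a closed SR membrane without RyR release fluxes.  Passing tests
demonstrate correct electrodiffusion physics (electroneutrality relaxation,
Debye-layer structure, Nernst equilibria, upstroke dynamics, flux-driven
Ca²⁺ transport) under these conditions; they do not validate against
irregular dyad reconstructions, channel clustering, stochastic gating,
mobile buffers, or post-RyR-activation dynamics, all of which are out of
scope.  The continuum description itself is an averaged view: dyadic ion
counts are of order one, so concentrations should be read as expected values
over time.

## Known limitations

* The steric-effect PNP extension and the channel-as-membrane-pore
  representation are not implemented (the latter is acknowledged as an
  alternative formulation; this package uses flux boundary conditions for
  all units).
* First-order splitting and linearization limit temporal accuracy to
  O(Δt); the sharp post-opening Ca²⁺ transient needs Δt ≲ 1 µs and ~2 nm
  transverse resolution for quantitative peak values.
* Adaptive time stepping is not provided; the negative-concentration guard
  and buffer-range check surface step-size problems instead.
* The frozen-LU/GMRES strategy assumes the coupled matrix drifts slowly; a
  scenario with rapidly varying interim concentrations will trigger
  frequent refactorizations (correct but slower).
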