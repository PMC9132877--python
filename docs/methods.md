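# Methods

## Model overview

The package simulates the contraction of a rectangular dermal wound
Ω_w ⊂ Ω under cellular traction. Two mechanical formalisms share one
agent-based biology layer and can be swapped behind a common interface
(`mechanics.backend ∈ {phenom, morpho}`):

* **Phenomenological.** Quasi-static balance −∇·σ = f_t + f_p for the
  displacement with homogeneous Dirichlet data ("the tissue does not move
  far away"). σ carries an isotropic elastic part written exactly as the 2D
  restriction of the 3D law, E_s/(1+ν)·{ε + tr(ε)[ν/(1−2ν)] I} — no
  plane-stress conversion is performed — and an η-weighted Kelvin–Voigt
  viscous part μ₁ε̇ + μ₂(∇·u̇)I. Permanence is modelled by plastic point
  forces of constant magnitude Q per unit edge length on all three edges of
  any element whose interior has ever contained a myofibroblast centre;
  activation is binary, per (element, edge) pair, and irreversible, so an
  edge shared by two marked elements carries two opposing loads. No inertia.
* **Morphoelastic.** Momentum balance for the velocity including the
  inertial terms ρ[Dv/Dt + v(∇·v)] — kept verbatim, including the
  non-conservative v(∇·v) term — coupled to the effective-strain evolution
  Dε/Dt + ε skw(L) − skw(L)ε + [tr(ε)−1] sym(L) = −αε. The strain starts at
  zero (consistent with zero initial displacement; no other initial state
  is defined). Displacement is accumulated as u += Δt·v (rectangle rule,
  consistent with backward Euler).

## Discretization

P1 Lagrange elements on a crossed-diagonal structured triangulation of the
rectangle; the wound edges are required to lie on grid lines so the wound
boundary is an exact polyline and the nodal wound indicator is exact.
Cellular and plastic Dirac loads use the immersed-boundary point-load
discretization (nodal loads = P1 basis values at the load point), which
conserves the applied force to machine precision; points on inter-element
edges are assigned to the lowest-indexed containing triangle so runs are
bit-reproducible. All linear systems are solved by direct sparse LU, with
the constant operators factorized once per run.

Time integration is backward Euler throughout. The morphoelastic step is a
Picard fixed-point loop (default tolerance 1e-8 in max-norm, 50 iterations):
the velocity solve lags the strain and the quadratic inertial terms, the
strain solve then uses the new velocity with implicit advection and
relaxation and the ε–L products lagged. The strain components are nodal P1
fields; their production term ∫φ·{ε skw(L) − skw(L)ε + [tr(ε)−1] sym(L)} is
assembled in Galerkin form with the untouched elementwise-constant velocity
gradient (one-point quadrature, element averages of ε). An earlier variant
that first projected L to nodes by lumped averaging left rough strain modes
almost decoupled from the momentum equation, which then relaxed far more
slowly than the viscoelastic time scale; the Galerkin assembly keeps strain
production adjoint to the elastic momentum coupling and removes that
artifact. Because ε is an independent unknown (3 nodal components versus 2
for displacement), a small strain residue incompatible with any
displacement field can survive force release; it scales with the strain
magnitude squared and is the numerical reason the recovered area ratio ends
"slightly above 1" rather than exactly 1 in the α = 0 scenario.

Cytokine transport uses the conservative weak convection form
−∫c v·∇φ (the substrate velocity vanishes on the boundary), consistent mass,
implicit decay, and a Robin boundary mass matrix D·κ_c·∮φφ. Negative nodal
concentrations produced near sharp fronts are clipped to zero and the
removed mass is logged on the field. The fibrin/collagen tensor transport
uses the same convection operator but a lumped mass matrix for the time
derivative and reaction: with zero velocity, tPA degradation is then exactly
pointwise, so the indicator-valued initial fibrin tensor decays without
spurious smearing across the wound edge. Collagen point sources are scaled
by the inverse lumped mass so the deposited integrated density equals the
secretion rate times Δt independent of mesh resolution. Tensors are
projected onto the PSD cone (eigenvalue clip at −1e-12) after every step.

The FEM layer is verified by a manufactured divergence-free velocity field
on four nested meshes: the observed L2 convergence order of the velocity
solve is ≈ 1.9–2.0 (theoretical 2), asserted ≥ 1.8 in the test suite.

## Scar observables

The wound area is tracked Lagrangianly: 96 material points seeded on the
wound rectangle boundary are advected each step by the backend's
displacement increment interpolated at their current position (phenom: Δu;
morpho: Δt·v); the area follows from the shoelace formula and r(t) = A/A(0)
is exactly 1 at t = 0. t_min is the earliest time of maximal contraction
(ties to the earliest sample; always > 0). t_end is the first time after
t_min at which the per-step area change drops below 1 % of the maximal
contraction per unit time, evaluated on the stored cadence; an oscillating
series that never qualifies is flagged unconverged. The collagen ratio ρ̂_c
integrates tr(Ω^c) over the current polygon (centroid-fan, edge-midpoint
quadrature) against the healthy-skin level 1/α_ρ. The Monte Carlo error
estimators are σ̂/√n and σ̂/(|μ̂|√n); the relative error is flagged
undefined for zero mean.

ρ^k := tr(Ω^k) is used as the bundle density: it is the unique
rotation-invariant scalar consistent with the isotropic initial tensors
(trace of I/(2α_ρ) = 1/α_ρ), which makes the density saturations in the
chemotaxis weight and in collagen secretion exact at t = 0. The angular
fiber-density representation behind Ω^k is never discretized; the tensor
components are the state variables.

## Cell layer

Cells are points with radius R; the traction discretization is the
circumscribing square of side 2R with one inward load of magnitude P·2R per
side midpoint (P is force per unit length, so the Table-scale arithmetic
P_f·2R = 2.08·5 = 10.4 is exact). A cell's four loads cancel identically,
making each cell a zero-net-force multipole. Macrophages exert no traction.

Migration is Euler–Maruyama: chemotaxis drift μ_c·∇c/(‖∇c‖+γ) (PDGF for
macrophages, TGF-β for (myo)fibroblasts, the latter steered by the matrix
[1−α_ρρ^c]I + α_ρρ^c·Ω̂^c with Ω̂^c the unit-trace collagen tensor —
isotropic fallback when the trace vanishes), passive convection with the
substrate velocity, an optional cell–cell interaction drift (a pluggable
callback, default zero; the upstream interaction law is not specified
here), and a Wiener increment σ_rw·dW. The chemotaxis weight is
μ_c = s·(1 − α_ρ(ρ^f+ρ^c)/2), floored at zero. Centres reflect at the
domain boundary inset by R so the whole traction square stays inside. The
active-displacement direction r_N = (dx − v dt)/‖dx − v dt‖ (undefined and
retained from the previous step for purely convective steps) orients
collagen deposition.

Events are exponential clocks sampled per step with probability
1 − e^(−rate·Δt), in a fixed order for reproducibility: macrophage influx
(Poisson with intensity λ_immune·|wound edge|·Δt, uniform positions on the
wound boundary), fibroblast→myofibroblast differentiation at rate
λ_diff·c_TGF, fibroblast division at rate λ_d·W/(W+W_half) with W the local
elastic strain energy density (the saturation prevents unbounded rates; the
functional form of strain-energy-coupled division is otherwise free),
myofibroblast/macrophage apoptosis at rate λ_a, then migration. Daughters
are placed at distance 2R in a uniform random direction, resampled if
outside the inset domain.

## Scenarios and parameters

Two unit presets fix the study conditions:

* `sensitivity_preset` (cm–g–day): domain 0.2 × 0.2 cm, wound 0.04 × 0.04
  cm, Δt = 0.02 day, ρ = 1.02 g/cm³, μ₁ = μ₂ = 100 g/(cm·day), P = 200,
  E_s = 31 [20–200] g/(cm·day²), η = 1 [0.6–3], α = 0.2 [0–1] /day,
  ν = 0.48 [0.118–0.495]. Cells: a fixed, centred 3 × 3 grid of identical
  force carriers strictly inside the wound (the source setting states
  neither count nor placement; all conclusions drawn from this scenario are
  qualitative/monotone and do not depend on the layout), radius
  R = 2.5e-4 cm — the same physical 2.5 μm cell radius the micro-scale
  preset specifies. Traction is active on [0, 5) day ("released at all
  times from t = 5"), and the default mesh is 20 × 20 grid cells with
  default t_final = 40 day; the run loop stops early once t_end is
  detected. P is interpreted as force per unit length (consistent with the
  P·2R load arithmetic), since the printed unit is not a force unit.
* `comparison_preset` (μm–kg–h): domain 120 × 80 μm, wound 40 × 30 μm,
  Δt = 0.1 h, E_s = 100, ν = 0.48, η = 10, μ₁ = 16.89, μ₂ = 11.26,
  R = 2.5 μm, P_f = 2.08, P_m = 10.4, Q = 33, α = 0.01/h. The ECM density
  is the cm–g–day value converted (1.02e-15 kg/μm³ at unit thickness), so
  inertia is negligible at this scale. The full stochastic biology runs on
  top (default 30 seeded fibroblasts in the healthy skin, default horizon
  20 h).

Parameters with no stated values are configuration defaults chosen once on
physical grounds and documented here: cytokine diffusion 30–60 μm²/h
(diffusion-dominated and oscillation-free on the default meshes), Robin
leakage κ_c = 0.02/μm, linear decays 0.05–0.1/h, macrophage TGF-β secretion
10/h per cell; migration speed s = 5 μm/h (a realistic biased fibroblast
speed), gradient regularizer γ = 1e-6 (small against typical gradient
magnitudes, so chemotaxis is direction- rather than magnitude-limited —
chemoattraction of cells into the damaged region is a stated feature of the
model), random-walk amplitude σ_rw = 0.3 μm/√h, α_ρ = 1 (nondimensional
densities), fibrin degradation δ_ρ = 0.5 per concentration per h; event
rates default to the Monte Carlo input means λ_d = 2, λ_a = 10,
λ_immune = 0.04 per μm per h, and λ_diff = 2/h per unit TGF-β with
W_half = 1.

## Two-backend comparison

To compare the formalisms on identical inputs, the stochastic biology is
run once (driven by the morphoelastic backend), recording the assembled
traction load vector and the myofibroblast element occupancy at every step;
the phenomenological backend then replays that recorded history. Both
curves answer only for the mechanical formalism. In non-permanent mode
(Q = 0, α = 0) the relative-area curves agree to a few 1e-4 on the default
scenario; the acceptance bound is 0.05.

## Monte Carlo study

Inputs: E_s ~ LogNormal(log 50, 0.1), λ_d ~ Uniform(1.5, 2.5),
λ_a ~ Normal(10, 0.1), λ_immune ~ LogNormal(log 0.04, 1e-5). Per-sample
seeds derive deterministically from (base seed, index). Each sample runs
the full stochastic model and reports twelve outputs (equilibrium and
minimal-area times and areas, collagen-ratio crossing times/areas at 0.5
and 0.8, early-checkpoint readouts); summaries attach mean, SD, Monte Carlo
error and relative error, pairwise Pearson correlations with p-values, and
a Shapiro–Wilk normality check of the final area. Failed samples are
logged and excluded with a reported count. The desk-scale default is tens
of samples on the micro-scale scenario; the full-scale summary statistics
depend on upstream parameter values that are not available here, so only
the error-propagation arithmetic (checked exactly against printed reference
rows) and the sampling machinery are asserted.

## Problem sizes used by the default test runs

Sensitivity runs use the 20 × 20 mesh (441 nodes) and stop at the detected
t_end (typically 300–700 steps); the comparison runs the 24 × 16 micro-mesh
(425 nodes) for 200 steps; the convergence study uses nested meshes from
8 × 8 to 64 × 64. These sizes resolve the wound with 4–8 elements per edge
and keep every documented qualitative property stable under refinement.

## Known limitations

* The effective strain is a nodal field with more degrees of freedom than
  any displacement field; post-release strain residues (quadratic in strain
  magnitude) slow the terminal decay and leave r(t_end) within a fraction
  of a percent of, not exactly at, 1.
* No stabilization is applied to the transport operators; the default
  regimes are diffusion/viscosity-dominated, and sharp-front undershoots in
  the cytokine solver are clipped (and logged) rather than prevented.
* The fiber tensors do not feed back into the stress law (the constitutive
  model is isotropic); collagen anisotropy only steers cell migration.
* Cells are fixed squares (no shape change, four boundary segments); finer
  boundary discretizations are out of scope.
* Synthetic scenarios emulate the stated study conditions, not a particular
  patient's skin: passing tests demonstrate internal consistency and the
  documented qualitative behaviours, not clinical predictive accuracy.
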