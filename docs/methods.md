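# Methods

## Model

Two pedestrians move on a convex rectangular domain Ω ⊂ ℝ² over a time
horizon [0, T].  Pedestrian p ∈ {1, 2} is an Itô diffusion with reflecting
barriers at the walls,

    dX⁽ᵖ⁾ = b⁽ᵖ⁾(t) dt + σ dB⁽ᵖ⁾,     b⁽ᵖ⁾(t) = v⁽ᵖ⁾ + u⁽ᵖ⁾(t),

where v⁽ᵖ⁾ is a constant base velocity pointing from the departure point
D⁽ᵖ⁾ toward the arrival point A⁽ᵖ⁾ (by default v = (A − D)/T), u⁽ᵖ⁾(t) is
the pedestrian's open-loop avoidance strategy, and σ dB models motion
variability.  The position density f⁽ᵖ⁾(x, t) then satisfies the
Fokker–Planck (convection–diffusion) equation

    ∂ₜf − (σ²/2) Δf + ∇·(b f) = 0,    F·n = 0 on ∂Ω,

with flux F_j = (σ²/2) ∂_j f − b_j f, started from an isotropic Gaussian
f₀ ∝ exp(−|x − D|²/w) truncated to Ω and normalized (w = 0.5 by default,
i.e. positional standard deviation 0.5 length units per axis).

Each pedestrian prices a strategy by

    J_p = α ∫ |x − A⁽ᵖ⁾|² f⁽ᵖ⁾(x, T) dx            (terminal cost)
        + (ν/2) ‖u⁽ᵖ⁾‖²_{H¹(0,T)}                   (control effort)
        + ρ ∫₀ᵀ ∫ f⁽¹⁾ f⁽²⁾ dx dt                    (collision term W).

W is a small-radius surrogate for the probability that the two pedestrians
come within an overcrowding radius r of each other: with independent
positions, Prob{|X⁽²⁾ − X⁽¹⁾| < r} ≈ r² ∫ f⁽¹⁾f⁽²⁾ dx in 2-D (up to the
unit-ball area π, absorbed into the strength C of ρ = C·r²).  Because the
game is separable — J_p = G_p(u⁽ᵖ⁾) + W(u⁽¹⁾, u⁽²⁾) — any minimizer of the
composite functional Ĵ = G₁ + G₂ + W is a Nash equilibrium: no player can
lower its own cost by deviating unilaterally.  The package therefore
minimizes Ĵ jointly over both strategies and verifies the equilibrium
property a posteriori by random unilateral perturbation probes
(`verify_nash`).

Controls are admissible when componentwise bounded in [u_a, u_b] and
pinned to zero at t = 0 and t = T (strategies switch on and off inside the
horizon); they live on the M+1 time nodes.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| α | terminal-cost weight | 100 | strongly rewards arriving at A |
| ν | control-cost weight (H¹) | 1 | bounded, slowly varying strategies |
| ρ | collision strength | 0.01 / 150–200 | "no game" baseline vs avoidance regime |
| σ | dispersion (length/√time) | 0.05·min side of Ω | a few percent of the arena per √time; keeps the density a coherent blob |
| w | initial-density width | 0.5 | ≈0.5 length-unit positional uncertainty |
| u_a, u_b | control bounds | ∓5 (∓40 for the T = 1 arena) | inactive unless the horizon is short |
| N, M | cells per axis, time steps | 50, 50 | benchmark resolution |

σ is deliberately a free configuration parameter: the benchmark
specifications fix the geometry and cost weights but not the dispersion.

## Discretization

Cell-centered uniform tensor grid; all spatial integrals are midpoint
sums, all time integrals trapezoidal.  The transport solver uses
dimensional (Lie) splitting per time step: for each axis, an explicit
sub-cycled finite-volume advection sweep followed by an implicit
central-difference diffusion solve (one symmetric tridiagonal system per
axis per step, factored once per solve).

Because the drift is spatially constant, advection is a pure translation.
A monotone *linear* scheme (upwind or exponentially fitted/Chang–Cooper
fluxes) is at most first-order accurate for it (the Godunov order
barrier) and at the benchmark resolutions — cell Péclet numbers
2|b|h/σ² of order 10 — would add artificial dispersion several times the
physical σ²/2.  That inflation is not cosmetic: it inflates the terminal
variance, which the α-weighted quadratic terminal cost can then "pay" to
squeeze against the reflecting walls, distorting the equilibria, and it
breaks the Monte Carlo cross-validation.  The advection sweep therefore
uses a second-order face correction in smooth van Albada form,

    F_{i+1/2} = g_i + (1 − a)·e²d/(e² + d²),    e = g_i − g_{i−1},
                                                 d = g_{i+1} − g_i,

with Courant number a ≤ 1 enforced by sub-cycling (the sub-step count is
fixed from the control *bounds*, so the discrete map does not change with
the control).  The correction is applied without clipping at extrema; it
is bounded by min(|e|/2, |d|), positively homogeneous of degree one, and —
unlike a clipped TVD limiter — continuously differentiable in the cell
values, which keeps the reduced cost C¹ in the controls.  Mass is
conserved exactly (flux form, zero-flux wall faces); nonnegativity holds
at the local roundoff scale on the smooth densities evolved here and is
enforced at run time (the solver raises if any cell drops below −10⁻¹²).
Advection evaluates the drift at the left time node t_k, matching the
Euler–Maruyama convention of the Monte Carlo module, so the discrete mean
dynamics of the two representations coincide up to scheme error.

Observed self-convergence: first order in Δt (implicit Euler plus
splitting), about second order in h for resolved profiles.

## Discrete adjoint and gradient

Gradients are discretize-then-optimize: the backward sweep applies the
exact transposes of the linearized forward sub-steps (the diffusion solves
are symmetric and self-transposed; the advection Jacobians are formed from
the analytic derivatives of the face correction), and contracts, per time
node and control component, the derivative of each sub-step with respect
to the drift.  The resulting finite-dimensional gradient of Ĵ matches
central finite differences to ~10⁻⁸ relative error — the package's core
correctness test.  In continuous language the gradient is the classical

    ∇_{u_k} Ĵ = ν u_k − ν u_k″ − ∫ (∂p/∂x_k) f dx,

with p the adjoint state (terminal condition −α|x − A|², source ρ f of the
other player); the stored adjoint field reproduces that interpretation
while the coupling term is kept in its exact discrete form.

The L² gradient is lifted to H¹ by solving −w″ + w = g with zero endpoint
values (second-order tridiagonal solve), giving smooth, endpoint-vanishing
updates.

## Optimization

Projected gradient descent on Ĵ over both controls jointly, from u = 0:
H¹-smoothed gradient, componentwise projection onto the box with pinned
endpoints, monotone Armijo backtracking (slope 10⁻⁴, shrink 0.5), with a
Barzilai–Borwein spectral scaling of the first trial step — plain steepest
descent crawls on the ill-conditioned tail.  Iteration stops when the H¹
norm of the projected gradient falls below 10⁻⁵·(1 + |Ĵ|), or when
accepted steps stop making relative progress (10⁻⁹ over five iterations).

Two structural obstacles require a stall-escape mechanism.  First,
symmetric head-on crossings are stationary points of W (the overlap is
maximal at zero relative shift), so the avoidance direction has zero
gradient on the symmetric manifold.  Second, the upwind switch of the
advection sweep leaves derivative kinks where a drift component vanishes,
and descent can jam there.  After each stall the iterate is nudged by a
small deterministic admissible perturbation (1% of the bound width,
counter-based generator, opposite signs for the two players) and descent
resumes; the best iterate over at most three segments is returned.  At
ρ = 0 the solver's accuracy guarantee follows from the strong H¹ convexity
of the control cost: ‖u − u*‖_{H¹} ≤ ‖projected gradient‖_{H¹}/ν.

`solve_best_response` reuses the same machinery to minimize a single
player's cost with the opponent frozen; it provides the independent
single-player solves used by the separability check and a best-response
cross-check of the joint route.

## Monte Carlo cross-validation

`simulate_ensemble` integrates the SDE by Euler–Maruyama with the drift at
the left time node and coordinate-wise folding reflection at the walls
(fold into the box, repeated until interior — valid for arbitrary step
sizes).  Initial positions are rejection-sampled from the truncated
initial Gaussian; randomness comes from a counter-based Philox generator
keyed by the seed, so ensembles are bit-exactly reproducible.
`compare_to_fp` checks the ensemble mean against the grid mean at every
time node (3-standard-error criterion, n = 10⁴ by default) and reports the
histogram-vs-density total-variation distance per node.

## What the scenarios emulate — and what they do not

The four shipped scenarios reproduce the geometry of controlled human
avoidance experiments: two walkers with prescribed start and goal points
whose straight-line paths cross (at 135°, at right angles in an open
arena, and in a narrow corridor).  The model is a *static, open-loop* game
with complete information: strategies are entire trajectories chosen in
advance.  Real walkers with continuous visual contact play a dynamic game
and re-plan online; agreement is therefore expected for the blind/
simultaneous setting and only qualitative where early visual information
is available.  Constant base drifts, isotropic position uncertainty and a
constant σ are further idealizations.  Passing tests certify the
mathematical machinery on these idealized conditions, not predictive power
for arbitrary crowd data.

## Findings and known limitations

* **Wall attraction of the terminal cost.**  With reflecting walls, the
  quadratic terminal cost rewards compressing the density against a wall
  (variance reduction can outweigh a mean offset at α = 100).  Converged
  equilibria therefore drive toward walls more than the idealized
  straight-line picture suggests; the effect grows with the density's
  spread relative to the wall distance.
* **Corridor benchmark meeting time.**  In the narrow-corridor scenario
  the initial and terminal Gaussians sit one standard deviation from the
  walls; truncation shifts the initial mean ~0.14 length units inward and
  the equilibrium compensates by moving faster, advancing the mean-path
  crossing by about two time nodes relative to the drift-only prediction
  (2.3 vs 2.5; the drift-only solver itself crosses at 2.4).
* **No avoidance at the shortest horizon.**  In the T = 1 arena the H¹
  cost of any meaningful separation (the ‖u′‖² term scales as T⁻³) exceeds
  the collision term W ≈ 1.6 by an order of magnitude, so the ρ = 200
  equilibrium still crosses; this persists for σ ∈ [0.3, 1] and when
  descent is seeded from a strongly avoiding strategy.  Avoidance under
  high interaction strength is reproduced in the three longer-horizon
  scenarios.
* The composite-minimization route finds *one* equilibrium; symmetric
  scenarios admit mirror-image equilibria, and the perturbation restarts
  select one deterministically.
* The optimizer certifies equilibria through `verify_nash` probes, not
  through vanishing gradients: residual kink rattling leaves a projected-
  gradient floor that the stall criterion, not the norm criterion, usually
  terminates.

## Problem sizes

Benchmark solves use the 50×50 spatial grid with 50 time steps that the
scenarios prescribe; gradient–finite-difference comparisons use 8×8 cells
with 8 steps where central differences are affordable; Monte Carlo
cross-checks use 10⁴ particles (10⁵ for the free-space variance test).
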