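# Methods

## Model overview

`tumorperf` simulates steady fluid exchange between a tumor-induced
capillary network and the interstitium of a 2-D tissue domain.  The
domain is a 2 mm square discretized on a 100×100 cell-centered grid
(h = 20 µm).  A solid tumor is a disc of radius 0.2 mm centered on the
midpoint of the right edge (the no-flux boundary mirrors it into a full
disc).  The parent vessel is a chain of 28 µm segments along the left
edge, with the inlet (3325 Pa, 25 mmHg) at one end and the outlet
(1330 Pa, 10 mmHg) at the other; capillaries are lattice edges of
length h with initial diameter 12 µm.

All internal state is SI.  Tissue transport coefficients are stored per
region:

| quantity | normal | tumor | unit (as tabulated) |
|---|---|---|---|
| L_p (vessel wall) | 0.36e-7 | 2.80e-7 | cm/(mmHg s) |
| K (interstitium) | 8.53e-9 | 4.13e-8 | cm²/(mmHg s) |
| S/V | 70 | 200 | 1/cm |
| π_B | 20 | 20 | mmHg |
| π_i | 10 | 15 | mmHg |
| σ | 0.91 | 0.82 | – |

Lymphatic drainage is set to zero everywhere.

## Angiogenesis generator

Endothelial tip cells execute a biased random walk on the grid.  The
five movement probabilities come from the explicit 5-point
discretization of a tip-density equation with random motility
(D = 3.5e-4), saturating chemotaxis (χ₀ = 0.38, saturation 0.6) up the
tumor-angiogenic-factor (TAF) gradient, and haptotaxis (ρ = 0.34) up
the fibronectin gradient; negative coefficients are clamped at zero and
the five values renormalized.  Walker time step 0.02 (dimensionless),
up to 4000 steps.

Initial profiles (the dimensionless fields are free modelling choices;
nothing in the underlying data fixes them):

* TAF: `c = exp(−d²/0.36)` with d the nondimensional distance to the
  nearest tumor cell, clamped to 1 inside the tumor.  The decay scale is
  matched to the 0.9-unit parent-to-tumor distance so the chemotactic
  pull peaks mid-corridor.
* Fibronectin: `f = 0.3 exp(−x²/0.45)`, concentrated at the parent
  vessel.  The level is deliberately below the conventional 0.75: the
  haptotactic drift toward the parent must modulate migration without
  reversing it, otherwise no sprout can cross the domain.  Tips deposit
  fibronectin (production 0.05, degradation 0.1 per unit time) capped at
  the parent level 0.3, and consume TAF (uptake 0.1) at their current
  cell.

Branching: a tip that has advanced and has not branched for 60 steps
splits with probability {0, 0.2, 0.3, 0.4, 1.0} for local TAF in
(<0.3, <0.5, <0.7, <0.8, ≥0.8), into a random free neighbor cell.
Anastomosis: a tip stepping onto any occupied cell (other than its
immediately previous one) links a junction segment and retires; tips
younger than 60 steps treat occupied cells as obstacles instead.  The
maturity gate matters: without it, closely spaced sprouts annihilate
each other near the parent vessel and the 10-sprout networks
degenerate, whereas the final structures should be (and with the gate
are) nearly independent of the sprout count.  Tips may invade and
vascularize the tumor; the walk ends when all tips have fused or the
step budget is exhausted.

The raw network is pruned topologically before any flow solve: segments
at non-boundary nodes of degree < 2 are removed iteratively (dead ends
cannot carry steady flow), then components unreachable from the inlet
are dropped.  A second, flow-based rule (`prune_by_flow`) removes
segments below 1% of the network's peak flow and is used for
visualization and post-processing, not inside the solves.

## Intravascular flow

Segment flow is Poiseuille, `Q_b = π D⁴ ΔP/(128 µ_app L)`.  Apparent
viscosity follows the empirical in-vitro law: `µ_app = µ_plasma ·
µ_rel(D, H)` with `µ_rel = 1 + (µ₄₅ − 1) · [(1−H)^C − 1]/[(1−0.45)^C − 1]`,
`µ₄₅(D) = 3.2 − 2.44 e^(−0.06 D^0.645) + 220 e^(−1.3 D)` (D in µm), and
the usual shape exponent C(D).  µ_plasma = 1.2e-3 Pa s.  The parent
vessel uses a fixed bulk value of 3.1e-3 Pa s rather than the small-tube
fit (whose calibration range does not extend to a 28 µm arteriole at
H = 0.45); with ΔP = 1950 Pa along the 2 mm parent this gives the
reference flow Q_ref ≈ 4.87e-3 mm³/s used by the metabolic stimulus.

Transvascular exchange follows Starling's law with segment-averaged
pressures, `Q_t = L_p π D L [(P̄_b − P̄_i) − σ(π_B − π_i)]`, with wall
coefficients chosen by the tissue region containing the segment
midpoint.  Nodal mass conservation (each segment's leak charged half to
each endpoint) closes a linear system in the nodal pressures, solved
either by a direct sparse factorization (default) or by matrix SOR
(ω = 1.5); both agree to solver precision and the SOR route is
cross-checked against a dense solve in the tests.  Wall shear is
`τ_w = 32 µ_app |Q_b| / (π D³)`.

## Hematocrit phase separation

The parent vessel carries discharge hematocrit 0.45.  Because flow runs
from higher to lower nodal pressure, the flow graph is acyclic and one
junction sweep in descending-pressure order propagates hematocrit
exactly.  At a diverging junction the split is biased toward the faster
branch: `H_i/H_slowest = 1 + ζ (U_i/U_slowest − 1)` with ζ = 0.5,
rescaled so red-cell flux is conserved; a branch whose velocity ratio to
the fastest exceeds U_cr = 2.5 receives no red cells at all.  H is
clamped at 0.95 with the excess flux pushed onto sibling branches.
Junctions with outflow but no vascular inflow (stagnant pockets fed by
transvascular reabsorption) receive plasma, H = 0.  Because the
critical-ratio cutoff makes the junction rule bistable, the outer
coupling loop under-relaxes hematocrit updates by 0.5.

## Structural adaptation

Each capillary segment takes Euler steps
`ΔD = D Δt (S_wss + S_p + S_m − k_s)` with Δt = 0.1 s, under-relaxed by
0.5, clamped to [4, 24] µm; parent segments never remodel.  The stimuli
are `S_wss = log₁₀(τ_w + τ_ref)`, `S_p = −k_p log₁₀ τ_e(P̄_b)`, and
`S_m = k_m log₁₀(Q_ref/(Q_b H) + 1)` with τ_ref = 0.103, k_p = 0.1,
k_m = 0.07, k_s = 0.35.  τ_e is the sigmoidal shear set point implied by
intravascular pressure, `100 − 86 exp(−5000 (log₁₀ log₁₀ P)^5.4)` in
dyn/cm² with P in mmHg, floored at 14 dyn/cm² (1.4 Pa) below 10 mmHg.

Stresses inside the logarithms are expressed in dyn/cm², the unit in
which this stimulus family and τ_ref were calibrated.  This is a
deliberate and load-bearing choice: in pascals the shear equilibrium
implied by k_s = 0.35 (~1.6 Pa) exceeds any wall shear achievable in a
capillary bed tapping a single parent vessel (observed median
~0.03 Pa), and every vessel then collapses uniformly to the 4 µm floor.
In dyn/cm² adaptation is heterogeneous — high-flow trunks fatten toward
the 24 µm bound, stagnant side branches shrink to 4 µm — which is the
qualitatively expected remodeling.  A stagnant segment's metabolic term
is capped at `Q_b H = 1e-6 Q_ref` to bound the logarithm.

## Interstitial solver

Steady continuity with the Starling source,
`−∇·(K ∇P_i) = Φ_B(P_i)`, is discretized on the cell-centered 5-point
stencil with harmonic face averaging of K across the tumor boundary.
The left edge carries Dirichlet P_i = 0 (gauge; the value is a config
option), the other edges are no-flux.  The source is linear in P_i, so
its coefficient folds into the stencil diagonal and the whole system is
linear: the default backend factorizes the operator once (it is
constant across coupling iterations) and reuses the LU factors; the
classical red-black SOR sweep (ω = 1.94) is provided and agrees with
the direct route to below 1e-6.  The solver is verified against the 1-D
closed form `P = P_e [1 − cosh((L−x)/λ)/cosh(L/λ)]`,
`λ = √(K/(L_p S/V))`, to 0.015% in max norm, and a 100→200 grid
refinement changes the baseline maximum by under 2%.

## The three approaches

* **Approach 1 (no network).**  The blood source indicator is 1 in
  every cell with a constant, uniform intravascular pressure equal to
  its initialization value 1330 Pa (the outlet pressure).  A single
  interstitial solve gives a ~570 Pa maximum at the tumor center.
  Restricting sources to the tumor, or raising the uniform P_b to the
  2660 Pa network average, are config options — both produce far higher
  maxima (≈1770 Pa at P_b = 2660) because without whole-domain sources
  the normal tissue cannot act as the near-equilibrium sink that keeps
  the far field low.
* **Approach 2 (rigid network).**  Fixed D, H = 0.45, viscosity from
  the in-vitro law.  The nodal and interstitial solves alternate,
  exchanging per-segment interstitial pressures and per-cell mean
  nodal pressures, until both relative errors (max-norm change over
  max-norm value) fall below 1e-6; the coupling through the wall is
  weak, so 3–5 outer iterations suffice.
* **Approach 3 (adaptive network).**  Each outer iteration runs: nodal
  flow solve → hematocrit phase separation (damped 0.5) → viscosity
  update → one adaptation Euler step (damped 0.5) → interstitial solve
  → convergence test on P_b, P_i (1e-6) and D, H (1e-4), up to 500
  iterations.  Some realizations never meet the structural tolerance
  because a few segments cycle indefinitely around the hematocrit
  cutoff or a diameter clamp while every pressure field is static; an
  oscillation guard detects this (pressure trace flat to 0.1% over 30
  iterations with no improvement in the structural error) and ends the
  run, flagging it `oscillating`.

Ensemble drivers run ≥10 angiogenesis seeds per configuration and
report the median and IQR of the maximum interstitial pressure; the
rigid and adaptive solves share each seed's network (a paired design).

## Numerical and design notes

* The nodal system is strictly diagonally dominant (leak conductances
  are ~1e-7 of Poiseuille conductances), so both SOR and LU are safe;
  an isolated subnetwork would make it singular, which topological
  pruning prevents by construction.
* Boundary (inlet/outlet) nodes absorb their half-share of adjacent
  segments' transvascular leak, making the global balance
  inlet = outlet + ΣQ_t close to machine precision.
* Per-cell blood pressure is the unweighted mean of the endpoint
  pressures of all segments touching the cell; the source indicator
  marks both endpoint cells of every segment.
* Problem sizes: default runs use the full 100×100 grid; a rigid
  coupled solve takes ~1 s and an adaptive one 5–30 s on one CPU, so a
  full 10-seed, two-sprout-count ensemble study completes in minutes.

## What the generator does and does not emulate

The synthetic networks reproduce the qualitative morphology of
tumor-induced angiogenesis — sprouts crossing the domain, branching
that intensifies near the tumor (brush border), anastomotic loops, and
tumor invasion — with final structure largely independent of the
initial sprout count.  They do not emulate: endothelial proliferation
kinetics, vessel regression biology, curved vessel geometry (segments
are lattice edges), 3-D effects, or calibrated vessel densities from
real tumors.  Consequently, quantities that depend on absolute
perfusion density (notably how closely the tumor interstitium
approaches its Starling equilibrium pressure) carry the generator's
density as a modelling assumption, and passing tests demonstrate
internal consistency of the coupled solver, not agreement with any
particular experimental vasculature.

## Known limitations

* Structural adaptation redistributes flow (bimodal diameters, more
  uniform perfusion) but leaves the per-cell blood pressure map near
  the tumor — and hence the interstitial pressure field — nearly
  unchanged: the interstitial source depends only on where vessels are
  and at what pressure, not on how much blood they carry.  Claims that
  adaptation per se raises peak IFP by ~1.5× are not reproduced by this
  implementation; here the rigid and adaptive peaks nearly coincide,
  and both sit well above the no-network baseline (ratio > 2).
* The hematocrit cutoff rule is discontinuous; a small number of
  junctions can cycle between states indefinitely (handled by the
  oscillation guard, and without effect on the pressure fields).
* With a well-vascularized tumor the peak IFP saturates near the tumor
  Starling equilibrium `P_b − σ(π_B − π_i)`; its value therefore tracks
  the nodal pressure of whichever trunks supply the tumor plexus, which
  varies across angiogenesis seeds by several hundred Pa.
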