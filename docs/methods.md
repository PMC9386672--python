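# Methods

## The model and its assumptions

`sexcoevo` analyses a deterministic two-sex SIS host–pathogen system. Hosts
are classified by sex (f, m) and disease status (S, I). Births arise from a
harmonic-mean mating function b·(females)(males)/N with a one-to-one birth
sex ratio; newborns of infected mothers are themselves infected with
probability v (vertical transmission). All hosts die at per-capita rate μN
(density-dependent regulation); infected hosts additionally die at the
sex-specific virulence rate α_i and recover — with no acquired immunity —
at the sex-specific rate γ_i. Horizontal transmission is mass-action,
S_i β(α_j) I_j, where the transmissibility of a strain depends only on the
virulence it expresses in its current host's sex, not on the recipient.

Assumptions worth keeping in mind: recovery confers no immunity (SIS, not
SIR); a single resident pathogen strain circulates; hosts are diploid and a
rare mutant allele appears only in heterozygotes, hence the factor ½ on the
two mutant birth channels; no age structure or behavioural sex differences —
the only asymmetries available are v (an intrinsically female trait) and the
cost coefficients c_f, c_m.

## Trade-offs and cost modes

The pathogen trades transmission against host survival through the
saturating form β(α) = β_max α/(α + d); d sets the virulence at which half
the maximal transmissibility is reached. The host pays for recovery in
fertility: b(γ_f, γ_m) = b_max e^{−c_f γ_f²} e^{−c_m γ_m²}, with the cost of
either mate depressing the pair's birth rate.

`cost_mode` switches how that cost is levied:

* **fixed** (default): the exponential factors always apply — a maintenance
  cost, innate-like immunity.
* **variable**: the factor e^{−c_i γ_i²} weights only *infected* parents in
  the mating pool, with b_max as the leading coefficient — an activation
  cost, adaptive-like immunity. This is one of several defensible readings
  of "cost only while infected"; it is the minimal one that preserves the
  structure of the resident equations, and it is isolated in
  `model_core._birth_pieces` (and the matching branch of
  `invasion.mutant_host_system`) so an alternative form can be swapped in
  one place.

## Numerical procedure

**Equilibrium.** The resident system is integrated (LSODA, rtol 1e-10,
atol 1e-12) from the disease-free state seeded with 1% infected in each sex,
in horizon chunks of 250 time units until the scaled RHS norm falls below
1e-10, then polished with a Newton root-find (MINPACK hybr). Pure
root-finding from arbitrary seeds is rejected deliberately: the extinct and
disease-free equilibria attract Newton steps, and the analysis needs the
*asymptotically stable* endemic state. Stability is certified by the
eigenvalues of a forward finite-difference Jacobian (step
max(1e-6, 1e-6·|y_j|)); the perturbation-return property test cross-checks
the certificate dynamically. Endemicity requires Ī_i > 1e-6·N̄ in both
sexes — anything smaller is treated as extinction and snapped to the
disease-free closed form N̄ = b/(2μ). Inside the evolutionary loop the
previous equilibrium warm-starts a direct Newton solve; the integrate-first
path is the fallback whenever the polished state is of a different kind
(endemic vs disease-free) or uncertified.

**Invasion fitness.** Each mutant linear system is split into a
non-negative birth part F and a removal-dominated transition part T, and
W = ρ(F(−T)⁻¹). For the pathogen, "births" are new infections (horizontal
and vertical); for the host they are the reproduction terms. The split is
the canonical next-generation one, and the threshold property — sign(W − 1)
equals the sign of the dominant eigenvalue of F + T — is not assumed but
verified against the eigenvalue oracle on 200 randomized scenarios, which is
split-independent.

**Selection gradients.** Central finite differences of W in each mutant
trait at the resident value, step 1e-4·max(1, |trait|), one-sided at the
γ, α ≥ 0 boundary. The resident equilibrium is *not* re-solved when the
mutant trait is perturbed: the mutant is rare and its environment fixed.
Halving the step changes components at second order (verified empirically).

**Trait iteration.** All four traits move simultaneously from the same
equilibrium, each by a signed step following its gradient sign. Per-trait
steps start at 0.01, halve on a gradient sign reversal, floor at 1e-6, and
regrow by a factor 1.3 (capped at the initial step) while the sign
persists. The regrowth matters: without it a transient reversal early in
the path can collapse a step to the floor while that trait still has far to
travel, stalling the walk. Iteration stops when all four |gradients| fall
below 1e-6 (on the W scale — well above finite-difference noise at the
chosen step, fine enough to pin traits to ~1e-4); convergence is certified
post hoc by re-evaluating the gradients at the outcome. Traits are clamped
at zero.

**Initialization.** The default initial traits are γ_f = γ_m = 0.5,
α_f = α_m = 2.0. The virulence value is chosen inside the pathogen-viable
window of the baseline parameter sets: at b_max = 2, β_max = 1.1, d = 4,
μ = 0.1 and γ = 0.5 the endemic equilibrium exists roughly for
α ∈ (1.6, 3.9) — below it transmission is too weak, above it infections
clear too fast for β to compensate. Outcome independence from the start
point is tested separately with three dispersed initial conditions.

**ESS verification.** W is evaluated on an 11×11 lattice of mutant trait
pairs in a box of half-width 0.1 around the outcome (clipped at zero),
separately for the pathogen's (α̃_f, α̃_m) and the host's (γ̂_f, γ̂_m); the
outcome is an ESS for a party if W ≤ 1 + 1e-7 everywhere (the slack absorbs
solver noise at the neutral point, where W = 1 only to machine precision).

**Sweeps.** `sweep_phase_plane` solves the co-evolution on a (v, Δc) grid,
warm-starting each cell from its row neighbour and falling back to a cold
start on failure. Costs are parameterized by midpoint: c_f = c_0 − Δc/2,
c_m = c_0 + Δc/2, so Δc > 0 means costlier male immunity. The default desk-
scale grid is 7 values of v in [0, 0.9] by 7 values of Δc in ±1.6·c_0 —
coarse enough to run in seconds, fine enough to resolve the three-region
topology. Region labels use the tie tolerance 1e-4 on trait differences
(above solver accuracy, far below visible region structure).

## Case metrics

Medical records measure outcomes per infection, not per unit time. With the
model's constant exit hazards — recovery γ_i*, disease death α_i*, natural
death μN̄ — an infection ends in disease death with probability
χ_i = α_i*/(γ_i* + α_i* + μN̄) and in recovery with probability
η_i = γ_i*/(γ_i* + α_i* + μN̄); the remainder is natural death while
infected. These competing-risk forms are the unique probabilities
consistent with the model's exponential waiting times; they live behind
`outcomes.case_metrics` alone so they can be replaced if a different
convention is preferred. Reclassifying sweeps by (Δη, Δχ) instead of
(Δγ, Δα) grows the female-defended/male-virulent region — faster female
recovery lowers female case mortality even where raw virulence is higher in
females — which is why that region reaches the v = 0 axis on the case-metric
basis.

## What the scenario generator does and does not emulate

`scenarios.paper_scenarios` pins the four named benchmark parameter sets
(baseline c_0 = 0.01 with b_max = 2, β_max = 1.1;
phase-plane and case-metric sets at c_0 = 0.1; the cost-mode comparison at
c_0 = 0.5 with b_max = 3.5, β_max = 3.1; all with d = 4, μ = 0.1).
`scenarios.random_scenario` draws parameters uniformly (log-uniformly for μ
and c_0, which span an order of magnitude) on ranges that contain all four
named sets, for the property suites. Everything is purely model-based:
passing tests certify the mathematics and numerics of the model, not any
fit to empirical epidemiological data — no real-data features (reporting
noise, age structure, seasonality, strain diversity) are represented.

## Numerical choices and degenerate inputs

Empty population (N = 0) is absorbing and returns zero derivatives so
integrators never divide by zero. Non-endemic equilibria raise on invasion
analysis (fitness is undefined without a resident). Equilibrium failures
and pathogen extinction mid-run are reported as flagged, non-converged
outcomes, never silently. All randomness is seed-explicit.

## Limitations

* Agreement with the deposited outputs of the original analysis is at the
  sign/region/monotonicity level; step sizes and tolerances of the original
  routine are unpublished, so bit-level agreement is not claimed.
* No evolutionary branching detection: if the singular point is not
  convergence stable the walk reports non-convergence rather than analysing
  dimorphism.
* No limit-cycle analysis: a resident system that fails to settle is
  reported as no-convergence.
* The variable-cost birth function and the case-metric formulas are
  package-level definitions (documented above), each isolated behind a
  single function for replacement.
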