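# Methods

## The mechanistic model

`scarnet` simulates post-burn scar contraction with a one-dimensional
morphoelastic continuum model of the dermis. Six coupled fields live on a
deforming material domain:

* four constituents — signaling molecules `c`, fibroblasts `N`,
  myofibroblasts `M` and collagen `ρ` — each obeying a balance of the form

      ż + (z v)′ = −J_z′ + R_z ,

  where `(zv)′` is passive convection with the tissue, `J_z` a
  non-convective flux and `R_z` the chemical response;
* the displacement velocity `v`, from the momentum balance
  `ρ_t (v̇ + 2 v v′) = σ′ + f` with viscoelastic stress
  `σ = μ v′ + E √ρ · ε` and a traction body force
  `f = ∂/∂x [ ξ M ρ / (R² + ρ²) ]` exerted by myofibroblasts pulling on
  collagen;
* the effective (elastic) strain `ε`, evolving morphoelastically,
  `ε̇ + v ε′ + (ε − 1) v′ = −G` with `G = ζ c M ε`: wherever
  myofibroblasts and signaling coincide with elastic strain, that strain
  is converted into permanent (plastic) deformation at rate `ζ` — this is
  what makes a contracture permanent after the cells have gone.

Constitutive closures (all isolated in `model_core`, so they can be
swapped without touching the solver):

* `J_c = −D_c c′` (Fickian); `J_{N,M} = −D_F (N+M) z′ + χ_F z c′`
  (cell-density-dependent random walk plus chemotaxis); collagen does not
  migrate.
* `R_c = k_c c/(a_c^II + c) · (N + η^II M) − δ_c g(·) c` with the generic
  protease activity `g = (N + η^II M) ρ / (1 + a_c^III c)`. The
  linearization of this balance around the homeostatic state is what
  produces the admissibility condition below.
* Logistic-type proliferation with chemical enhancement, signaling-driven
  differentiation `k_F c N` from fibroblasts to myofibroblasts, and
  linear apoptosis for both cell types. The proliferation exponent `q`
  and the baseline collagen secretion rate `k_ρ` are not free: they are
  pinned by requiring the homeostatic state
  (c=0, N=N̄, M=0, ρ=ρ̄, v=0, ε=0) to be an exact fixed point,
  `k_ρ = δ_ρ ρ̄²` and `q = ln(δ_N / (r_F (1 − κ_F N̄))) / ln N̄`.

**Stability admissibility.** The homeostatic equilibrium is linearly
stable against signaling perturbations iff

    k_c < δ_c · ρ̄ · a_c^II    (strict),

and every sampled parameter set must satisfy it (draws are rejected
otherwise). The boundary case is excluded.

## Discretization

Linear (P1) finite elements on a half domain `[0, 10]` cm (202 nodes by
default), symmetry at `x = 0` (v = 0, zero species flux) and far-field
dermal conditions at `x = 10` (v = 0, c = 0, N = N̄, M = 0). The wound
occupies `[0, L)` with a sigmoidal initial transition (steepness 40 /cm,
i.e. a front a few millimetres wide — smooth enough to avoid Gibbs
artifacts on linear elements). Initially the wound carries elevated
signaling `c_w` and 20 % of the homeostatic fibroblast and collagen
densities; myofibroblasts appear only through differentiation.

Time integration is backward Euler (one-day steps over 365 days) on all
six fields monolithically. Each step runs Picard iterations: nonlinear
coefficients are frozen at the current iterate, the resulting
block-tridiagonal system (6×6 nodal blocks, interleaved ordering) is
solved directly, and the loop ends when the combined relative update norm
drops below 1e-4 (at most 50 iterations, else the step fails loudly).
Reaction sources enter at the iterate with a nonnegative implicit damping
on each species' own decay terms; because the lagged terms are evaluated
at the converged iterate, the fixed point of the Picard loop is exactly
the fully implicit backward-Euler state — the splitting changes the
iteration count, never the answer.

The mesh is updated-Lagrangian: nodes are material points advected with
`v` each step, so material derivatives are plain nodal differences and
the only convective remnant is the dilution term `z v′` (lumped). Mesh
tangling is fatal. Species are clipped at zero after each converged step;
the clipped mass is tracked and the run aborts if it exceeds 1e-3 of a
species' initial content. Mass matrices are lumped (helps positivity;
the diffusion subproblem remains second-order accurate in space, which
the test suite verifies on nested meshes).

The **RSA** (relative surface area — in 1D, relative wound length) tracks
the material point initially at `x = L`: RSA(t) = edge(t)/L, recorded
once per day; entry `k` of the course is the state after `k+1` days.
A `SimulationResult` also records the wound-edge trajectory and the
Picard iteration counts.

Two implementations of the same scheme exist: a NumPy reference
(`fem_solver`) and a compiled kernel (`_kernels`, numba) with a
hand-rolled block-Thomas solver. They implement identical discretizations
and are cross-checked in the tests (RSA agreement to ~1e-14); `simulate`
dispatches to the kernel by default.

## Parameter values and the synthetic corpus

The 25 varied parameters (wound length `L` plus 24 kinetic/mechanical
constants; see `scarnet/data/default_ranges.yaml`) are drawn uniformly
and independently, with rejection under the stability condition; the
remaining constants are fixed. Nominal values are physiologically
plausible magnitudes for human dermis from the 1D morphoelastic modeling
literature (e.g. D_c = 2.9e-3 cm²/day, N̄ = 1e4 cells/cm³,
ρ̄ = 0.1 g/cm³, δ_c ρ̄ a_c^II = 5e-13 against k_c = 4e-13). Most ranges
span ±20 % around the nominal; `L` spans 1–4 cm and `k_c` is widened to
[2e-13, 8e-13] so the stability filter genuinely rejects (≈ half of all
draws), keeping the filter code on a hot path rather than a dead one.
The traction magnitude `ξ` and plasticity rate `ζ` were calibrated once
so that the nominal wound reproduces the clinically reported contraction
regime — peak contraction near 45 % of the wound area around day 5–6
weeks with roughly 8 % permanent loss — and were then frozen; across the
sampled ranges the corpus spans minimum RSAs of roughly 0.2–0.87 and
last RSAs of 0.55–1.0.

Corpus rows are reproducible in isolation: row `i` of a corpus with
master seed `s` uses the counter-based stream `SeedSequence(s, (i, a))`
(attempt `a` increments only if the solver fails and the row is
redrawn). Failure rates above 5 % abort generation.

Inputs are Min-Max scaled to [0, 1] with parameters fitted on the
training split only; targets stay unscaled — they already live in (0, 1]
and the network's sigmoid output matches that range directly. The 20 %
test set is held out before the tenfold cross-validation partition of
the remaining 80 %.

## The surrogate and its training protocol

Architecture 25 → 100 → 100 → 365 (two ReLU hidden layers, sigmoid
output; 49,565 trainable parameters), Glorot-uniform initialization from
a seed. Training minimizes the MSE with Adamax (initial learning rate
0.015, multiplied by 0.99 each epoch, batches of 64). Early stopping
monitors the validation MSE where a validation split exists (training
MSE otherwise): changes smaller than 1e-5 count as no improvement, 30
such epochs stop training, and the best-observed weights are restored.
A hard cap of 2000 epochs guards automation; in practice training stops
after a few hundred. The learning-rate range test sweeps [1e-4, 1] per
optimizer (eight NumPy-implemented optimizers: SGD, RMSprop, Adam,
Adamax, Nadam, Adagrad, Adadelta, Ftrl), records the moving-average
smoothed final loss, and flags divergent cells instead of raising.

Since no deep-learning framework is a dependency, the network, its
backpropagation and the optimizers are implemented in NumPy inside the
package; they are small (≈ 50k parameters) and train in seconds on a
single CPU.

## Metrics

R² is pooled over all (sample, day) pairs; it can be negative and is
undefined for constant targets. aRRMSE averages, over the 365 days, the
per-day RMSE normalized by that day's deviation from its mean (the
column-mean predictor scores exactly 1; < 0.1 is conventionally
"excellent"). aRelErr is the flat mean of |e|/|y|. Cross-validation
scores aggregate as mean ± sample standard deviation (ddof = 1). The
characteristics table reports R² and MAE for the minimum RSA (peak
contraction) and last RSA (permanent contraction), alongside the
min/max/range/average of their target distributions.

## Monte-Carlo uncertainty

A patient scenario assigns each varied parameter a point value or a
uniform range; draws are filtered by the same stability condition (using
the fixed parameters attached to the scenario), predicted in one batch,
and summarized as 5/25/50/75/95 % daily quantile curves, min/last-RSA
distributions, and P(1 − min RSA > threshold) — the probability that
peak contraction exceeds a clinical threshold (default 40 %). Draw-level
predictions are retained (capped at 20k) so every summary can be
recounted exactly. Mapping patient age or wound location onto parameter
distributions is deliberately out of scope: the engine accepts explicit
distributions, and an age-mapping layer would sit in front of
`PatientScenario`.

## What the synthetic data does and does not show

The corpus is generated by the package's own solver, so surrogate
accuracy statements are statements about reproducing *this model*, not
about predicting clinical outcomes; independence of parameters, uniform
marginals, and the specific closure choices are all idealizations. Tests
passing here show the pipeline is internally consistent (solver verified
against analytic/ODE oracles, surrogate faithful to the solver); they do
not validate the biology.

## Problem sizes and numerical choices in the shipped checks

The test suite and the acceptance script run at desk scale, chosen as
the package's own verification conditions: 2,000 simulations on a
101-node mesh for the fidelity check (test R² > 0.9, aRRMSE < 0.3 — a
weak stand-in for full-corpus accuracy, which uses 18,000 fine-mesh
runs), 10⁴ draws for the stability-rate check, and refined time steps
(dt = 0.01–0.05 days) for the oracle equivalence tests so that the
backward-Euler time error does not mask the comparison; the integrator's
first-order convergence is quantified separately. Picard tolerance 1e-4
on a combined relative-update norm with per-field floors (c_w, N̄, ρ̄,
1e-3 cm/day, 1e-3 strain) keeps the test insensitive to fields that are
identically zero.

## Known limitations

One spatial dimension (no wound shape or depth); infinitesimal strain;
no contact, no growth of the surrounding skin; uniform independent
parameter sampling rather than patient-calibrated joint distributions;
the closure constants are literature-magnitude placeholders, not a
published supplementary table; and the surrogate's fixed 365-output head
cannot predict beyond one year or at finer-than-daily resolution.
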