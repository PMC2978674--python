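# Methods

## The model

`fspswitch` analyses transient stochastic switching in the excitable
ComK/ComS module that gates competence in *Bacillus subtilis*.  The
reduced model tracks molecule counts `x = (K, S)` of ComK and ComS and
four reaction channels (system size Ω, molecules per nM):

| channel | stoichiometry | propensity |
|---|---|---|
| ComK production | (+1, 0) | `Ω·ak + Ω·bk·K^n / ((Ω·k0)^n + K^n)` |
| ComK degradation | (−1, 0) | `δk·K / (1 + K/(Ω·Γk) + S/(Ω·Γs))` |
| ComS production | (0, +1) | `Ω·bs / (1 + (K/(Ω·k1))^p)` |
| ComS degradation | (0, −1) | `δs·S / (1 + K/(Ω·Γk) + S/(Ω·Γs))` |

The shared degradation denominator encodes competition of ComK and ComS
for the MecA–ClpP–ClpC protease; the Hill terms encode ComK
auto-activation (order `n`) and ComK-mediated ComS repression (order
`p`).  The chemical master equation `dp/dt = A p` governs the probability
of each count state; the deterministic rate equations are the macroscopic
limit `dc/dt = Σ_r ν_r w_r(Ω c)/Ω` and are Ω-invariant by construction.

Nominal parameters (the `ParameterSet` defaults, per-second/nM units):
`ak = 0.0028`, `bk = 0.049`, `bs = 0.057` nM/s; `k0 = 100`, `k1 = 110`,
`Γk = 500`, `Γs = 50` nM; `δk = δs = 0.0014` 1/s; `n = 2`, `p = 5`;
`Ω = 1` (counts numerically equal nM — no cell volume is fixed by the
rate set, so Ω is an explicit, configurable dial).  All analysis time is
in seconds; the 40-hour study horizon is 144,000 s.  Optional first-order
dilution channels exist but default to zero, since the saturable
degradation constants above are the only decay rates the parameterisation
fixes.

**Deterministic structure (computed, not assumed).**  With the nominal
rates the planar system has a single stable fixed point, the vegetative
state, at `(K, S) ≈ (15.91, 226.13)` nM.  Excitability is of the
fast–slow type: freezing ComS at its vegetative value leaves a bistable
fast ComK subsystem with roots near 16 (stable), 45 (unstable threshold)
and 160 nM (upper branch).  A fluctuation that lifts ComK past the
separatrix triggers a slow excursion — ComK rises toward the upper
branch while ComS is repressed and decays, which re-arms ComK
degradation and returns the cell to the vegetative state.  Deterministic
excursions peak near 160–185 nM ComK; stochastic 40-h paths at Ω = 1
show maxima up to ≈120 molecules.

**Regions.**  "Competent" is defined as `ComK ≥ 65·Ω` molecules: above
the ≈45 nM excitation threshold with margin, about four times the
vegetative level, and inside the empirical gap between ordinary
fluctuation maxima (≤58) and excursion maxima (≥66) observed in seeded
40-h ensembles.  With this region the 40-h entry probability is 0.357
and the resulting elasticity table reproduces the qualitative structure
expected of the circuit (see below).  "Returned" means `ComK ≤ 25·Ω`
(the vegetative basin).  Both thresholds are configurable and every
output echoes the region actually used; region predicates may be
arbitrary (rectangles are just the convenient shorthand), and rectangle
and predicate forms of the same set produce identical operators.

**Full model.**  A five-species variant (ComK, ComS, MecA, MecA:ComK,
MecA:ComS) with mass-action binding/unbinding and complex-mediated
degradation is provided for structural studies.  Its binding constants
are not fixed by the parameterisation above and must be supplied in
configuration; unsupplied catalytic/dissociation rates are derived from
the consistency rule that quasi-steady-state elimination reproduce the
reduced model (`(ku + kcat)/kb = Γ`, `kcat·MecA_total/Γ = δ`).  Total
MecA is conserved by every channel.  The variant is exercised by tests
(conservation, QSS agreement with the reduced rate equations, SSA mean
agreement under fast binding) but is marked experimental.

## Finite state projection

The lattice is truncated to a box (default `K ≤ 1200`, `S ≤ 600` at
Ω = 1 — generous for all default analyses; entry problems are further
capped by the absorbing competence region at `K = 65`).  Enumeration is
lexicographic with the first species fastest, fixed forever, so state
indexing is bit-reproducible.  Designated regions are aggregated into
absorbing sink states; transitions out of the box that belong to no named
region feed an `overflow` sink.  Diagonals are set to minus the column's
off-diagonal sum, so columns sum to zero exactly by construction (and are
asserted to within 1e−12); sinks receive and never emit.  The overflow
mass at time t is the FSP certificate: the reported hitting probability
can be wrong by at most ε(t).

`expand_until_certified` grows the box by a fixed multiplicative step
(default 1.5 per species) until ε(T) meets a target (default 1e−3) or a
cap is reached, in which case it raises with the best certificate
achieved.  The growth sequence is deterministic.

**Transient solver.**  `solve_transient` uses uniformization: with
λ = max total exit rate, `B = I + A/λ` is a stochastic matrix and
`e^{At} p = Σ_k Poisson(λt; k) B^k p`.  All series terms are nonnegative,
so the solve is cancellation-free, conserves probability to the truncated
Poisson tail, and needs no step-size control.  The series is cut where
the Poisson tail drops below the solve tolerance (default 1e−10, divided
across grid segments); a hard cap on series length guards against
pathological λ·t.  Negative floating-point dust cannot arise in the
plain solve; reported sink masses are nevertheless clamped at zero while
raw values are kept for diagnostics.  The solver is validated against a
dense `expm` reference (an independent code path, capped at 2,000 states)
to ≤1e−8 on every fixture.

## Sensitivities

For a parameter θ the derivative of the absorbed mass solves the block
system `d/dt [p; s] = [[A, 0], [∂A/∂θ, A]] [p; s]` with `s(0) = 0`
(method 1).  `∂A/∂θ` is assembled analytically from the propensity
templates — derivative edges live only where the propensity itself can
fire, so its sparsity pattern is contained in A's — and verified against
central differences of the propensities (relative step 1e−6, tolerance
1e−6) at build time.  The block system is integrated by the same
uniformization scheme; with several parameters the forward propagation of
`p` is shared, so a five-parameter table costs little more than one
augmented solve.  Method 2 is a central difference of the FSP hitting
probability at relative step h (default 1e−2), both perturbed solves on
the identical state space, initial vector and grid.  The two methods
agree to ≤5% relative on the competence model (≈2% at the 40-h horizon,
dominated by the finite-difference truncation at the large elasticities
of the ComS rates) and to ≈1e−4 on closed-form toys.

Results carry three scalings side by side — raw `∂P/∂θ`, semi-normalized
`θ0·∂P/∂θ`, and elasticity `(θ0/P)·∂P/∂θ` — with the convention recorded
in the output metadata; the two normalized forms differ by the global
factor 1/P, so sign patterns and cancellation ratios are identical under
either.  On the nominal circuit over 40 h the elasticities are
approximately +5.1 (ak), +6.5 (bk), +41.1 (bs), −10.7 (δk), −41.1 (δs):
expression rates promote entry, degradation rates oppose it, the ComS
pair (bs, δs) cancels to ≈0.01% and the ComK triple (ak + bk vs δk) to
≈8% of its gross magnitude — each protein plays a dual role, driving the
cell into competence through synthesis and back out through degradation.

## Return time

The return problem inverts the entry problem: the vegetative region
`{ComK ≤ 25·Ω}` becomes an absorbing `return` sink (a returned trajectory
cannot re-enter competence, by construction), competent states are
transient, and the initial distribution is uniform over the competence
region.  The start set is a *bounded* rectangle (threshold up to the
recommended entry box), fixed independently of the truncation box: a
start region tied to the box would make the target quantity drift as the
box grows, whereas with the bounded rectangle the expectation is
box-converged (the three estimators agree to <0.001% across nested
boxes).

Three estimators are computed and cross-checked:

* Riemann sum `Σ_i t_i* [g1(t_i) − g1(t_{i−1})]` over a uniform partition
  (default Δt = 60 s), midpoint `t_i*` by default ("right" available);
  divided by the returned mass, i.e. conditional on return within T_max;
* tail integral `∫_0^{T_max} (1 − g1) dt` (trapezoidal), with the tail
  beyond the horizon bounded by `(1 − g1(T_max))·T_tail`;
* the exact absorbing-chain expectation from one sparse solve of
  `Qᵀτ = −1` (preceded by a reachability scan that rejects chains with
  sink-less transient states) — the exactness anchor.

Every reported expectation states the unreturned mass and the FSP error;
when their sum is below 1e−3 the value reads as an unconditional mean
first-passage time, otherwise as an expectation over returns within the
horizon.  Gillespie sampling of the same first-passage time (uniform
start over the same rectangle, censored runs reported separately, mean
over uncensored returns) provides the external statistical check.

## Stochastic simulation

The simulator is the classic direct method: exponential waiting time at
the total propensity, channel chosen proportionally to its propensity —
two uniform draws per event.  Randomness is pinned to numpy's PCG64;
ensembles derive one child seed per run via
`SeedSequence(master_seed).spawn(n)` (a counter-based split), so any
single run is reproducible in isolation.  Monte-Carlo hitting estimates
carry the distribution-free two-sided Chernoff–Hoeffding half-width
`ε = sqrt(ln(2/δ)/(2n))`; no tau-leaping or hybrid acceleration is
attempted.

## The scaled test circuit

`scaled_competence_fixture(scale)` sets `Ω = scale`, shrinking all counts,
regions and boxes by the scale factor while leaving the deterministic
dynamics in concentration units untouched.  A sign-change scan of the
fast ComK subsystem at frozen vegetative ComS must find its three
branches, guaranteeing the excitable character survives the rescaling.
At scale 0.1 the entry problem has 366 transient states and the return
problem 13,468, so the full pipeline (certified solve, both sensitivity
methods, three return-time estimators, 10,000-run SSA cross-checks) runs
in seconds.  What the scaled circuit emulates is the *mechanism* —
excitable escape, dual-role sensitivities, hours-long return times; what
it does not emulate is the noise magnitude of the real cell: at Ω = 0.1
relative fluctuations are √10 larger, so entry probabilities are higher
(0.18 in 2 h vs 0.36 in 40 h at full scale) and all quantitative values
are fixture-specific.  Passing tests on the fixture therefore validate
the numerics, not biological magnitudes; full-scale magnitudes come from
the Ω = 1 runs in the test suite and `scripts/acceptance.py`.

## Problem sizes and numerical defaults

Default tolerances: solver 1e−10 (1e−12 in oracle comparisons),
certification target ε ≤ 1e−3, generator column-sum assertion 1e−12,
probability-conservation check 1e−9.  The test suite runs the entry
problem at full scale (39,065 states, 10-h horizon for the sensitivity
table) and every other analysis on the scaled or toy fixtures; the
acceptance script runs the full 40-h entry and sensitivity problems
(39,065 states), the scaled return problem (13,468 states, Δt = 60 s,
T_max = 40 h), and a full-scale return problem on a 361×701 box
(234,835 states, Δt = 600 s).  These sizes were chosen so each analysis
is box- and grid-converged to well inside the cross-checks' tolerances
while the whole suite stays interactive.

## Known limitations

* The competence and return thresholds are modelling choices (the rate
  set fixes no canonical boundary); all conclusions are reported relative
  to the echoed region definitions.
* The full five-species model ships without default binding constants and
  is validated structurally, not calibrated.
* Elasticities at small P inherit the relative error of P; for very rare
  events (e.g. thresholds far above the excursion range) both sensitivity
  methods degrade together as P approaches solver precision.
* The Riemann/integral return-time estimators are grid-quantized; the
  linear solve is exact but counts absorption into *any* sink, so it is
  only quoted when overflow mass is negligible.
* No steady-state (infinite-horizon) solver, no tau-leaping, no
  most-likely-path analysis.
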