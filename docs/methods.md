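# Methods

## Model and reduction

The package treats autonomous deterministic networks `dx/dt = R(x)` with
smooth closed-form rate laws, partitioned into a subnetwork `x^s` and a bulk
`x^b`.  One structural assumption is made: for every subnetwork state the
bulk has a unique steady state `x^b*(x^s)` solving `R^b(x^s, x^b*) = 0`.
This is the natural condition for coarse graining to be possible at all —
the subnetwork must be able to generate all fixed points itself; it is the
dynamical analogue of assuming the eliminated degrees of freedom equilibrate
to a unique conditional distribution.

The reduced equation is the QSS drift `v(x^s) = R^s(x^s, x^b*(x^s))` plus a
memory correction.  The memory function is derived by linearizing the bulk
dynamics in the deviation `x^b − x^b*(x^s)` around the moving QSS, which
yields the closed form documented in the README, with the transport of the
perturbation expressed through a time-ordered matrix exponential `E(τ)` of
the generator `l` along the QSS flow.  The expansion is first order in the
bulk deviation; quadratic corrections are out of scope.

Two consequences of the structure of the prefactor `c` (which carries a
factor of the drift) shape everything downstream:

- the memory vanishes identically at every fixed point of the reduced
  dynamics, so the QSS, ZMn and ZMs systems share their fixed points with
  the full system (restricted to subnetwork coordinates);
- near a fixed point the memory linearizes to a convolution with the kernel
  `K(τ) = f⁰ᵀ e^{lᵀτ} G`, `G = J⁻¹ (∂R^b/∂x^s) Dv`, which reproduces the
  dynamics of the full linearized system exactly.  This is verified
  numerically (impulse-response agreement to ~1e-10 on the two-node switch)
  and the ZMs augmented Jacobian `[[Dv, f⁰ᵀ], [G, lᵀ]]` is algebraically
  conjugate to the full Jacobian via `ε = δx^b + J⁻¹(∂R^b/∂x^s) δx^s`.

### Orientation of the propagator

The index placement in the generator `l` and the ordering of the
time-ordered exponential are not fixed by notation alone; they are fixed
here by derivation and certified by tests.  Writing the bulk deviation from
QSS as `ε`, the exact bulk-linear dynamics give `dε/dt = lᵀ ε + c`, which
forces the auxiliary ODE of the self-consistent variant to be
`dm/dt = c + lᵀ m` and the propagator to satisfy `dE/dτ = E·l(φ_v(x^s, τ))`
(new generator entering on the right).  Both candidate orientations are
numerically distinguishable on a non-symmetric two-species bulk; the
`linear_bulk_demo` fixture exercises exactly this and the self-consistent
trajectory matches the full subnetwork trajectory to ~1e-10 in sup-norm,
which fails by many orders of magnitude under the transposed convention.

## Numerical evaluation

**Bulk QSS.**  If the bulk rates are affine in the bulk species (detected
symbolically), `x^b* = −D(x^s)⁻¹ g(x^s)` is obtained by a single linear
solve and uniqueness is automatic.  Otherwise a damped Newton iteration with
the analytic bulk Jacobian is used, warm-started along trajectories;
without a warm start a deterministic multi-start (cached solution, origin,
and 8 Halton points in a box sized by production/degradation balance)
screens for violations of the uniqueness assumption and raises an error if
distinct roots are found.  Residual tolerance 1e-10 (max-norm).

**Derivatives.**  Rate expressions are parsed with sympy and differentiated
symbolically (the default); central finite differences with step
`max(1e-6, 1e-6·|x_j|)` serve as fallback and as the cross-check used
throughout the test-suite.  Silent derivative errors are the dominant
failure mode of memory methods, so every ingredient formula is additionally
pinned by a closed-form scalar-case oracle on the two-node switch.

**Propagator and memory.**  `E(τ)` is computed by solving the joint ODE
`y′ = v(y)`, `E′ = E l(y)` with LSODA at rtol 1e-10/atol 1e-12 and dense
output; for scalar bulks it is validated against adaptive quadrature of
`∫ l dτ`, and at fixed points against the matrix exponential.  The
closed-form memory is validated against the transport PDE it must satisfy
(`∂_τ f = l f + v·∇f`, method-of-lines residual < 1e-4 with fine-step
central differences).

**ZMn integrator.**  The projected equation with the explicit history
integral is discretized on a fixed grid with trapezoidal weights and
advanced by Heun's predictor–corrector; each history node carries its
transported point and propagator, advanced jointly by one vectorized RK4
step per outer step, so cost is linear in history length per step.  Nodes
whose propagator norm falls below 1e-12 are pruned.  Default history length
2000 nodes for the integration window; accuracy is O(h²) and self-
convergence is Richardson-tested.  No discretization for this equation is
prescribed by theory; all choices here are certified by self-convergence
and by agreement with the auxiliary-ODE variant near fixed points.

**ZMs integrator.**  The self-consistent variant integrates the augmented
system `(x^s, m)` with LSODA (default rtol 1e-8); the auxiliary-ODE route is
validated against direct nested quadrature of the double-integral form
(product-of-exponentials propagator, midpoint sampling, trapezoidal history;
agreement < 1e-6).  ZMs is the default variant for analysis tooling — it is
cheaper (dimension `n_sub + n_bulk`), exact for bulk-linear rates, and
shares its linearization with ZMn.

**Channels.**  The decomposition expands the two derivative factors inside
`c` (outgoing edge: subnetwork species → bulk species) and `f⁰` (incoming
edge: bulk species → subnetwork species); the canonical granularity is the
quadruple (source, out-bulk, in-bulk, target), with sender→receiver pairs
available as an aggregated view.  Channels whose defining derivative is
identically zero are dropped symbolically.  Additivity is exact (checked to
1e-10 at random states).  Channel-resolved self-consistent integration
carries one auxiliary m-vector per outgoing edge; ablation keeps a subset of
quadruples and reproduces the QSS system when the subset is empty.  The
importance metric is the time-integral of the absolute channel contribution
to `dx^s/dt` along a trajectory, normalized to sum 1 — a reconstruction, as
no canonical metric is fixed by theory; integrated-signed and max-abs
variants are provided.

## Fixtures and what they do (and do not) represent

Fixture defaults are the study conditions for the test-suite:

- `bistable2` (a=6, n=3): reproduces the printed fixed points
  (6.000, 0.028)/(0.028, 6.000), saddle (1.460, 1.460).
- `multistable_or` N=3 (a=4, n=2): tetrastable; basin analysis on the
  (x₁, x₂) subnetwork with x₃ eliminated.
- `repressilator` (a, n scanned over [1,10]×[2.6,5]): the scan ranges are a
  package choice bracketing the full system's analytic Hopf curve
  `n xⁿ/(1+xⁿ) = 2`, `x(1+xⁿ) = a`.
- `linear_bulk_demo`: one subnetwork species, two-species non-symmetric
  Hurwitz bulk entering all rates linearly; the exactness/orientation
  certificate.
- `neural_tube4`: an illustrative four-factor cross-repression circuit with
  a morphogen signal p activating both subnetwork factors, asymmetric
  weights chosen so that (i) the circuit is tristable at intermediate
  signal (both-low/Irx-Pax-high, Olig-high, Nkx-high) and (ii) Olig responds
  before Nkx where both are induced.  The parametrization is *not* a
  published fit (that parametrization is not publicly printed); every
  conclusion drawn on this fixture is qualitative — fate-map topology,
  reduction fidelity, dominant-channel structure — and the fixture is
  user-replaceable by any YAML config.

Hill terms in all fixtures are written `(x²)^{n/2} = |x|ⁿ`.  On the
nonnegative orthant — where all fixture trajectories of the *full* systems
remain — this is the standard Hill form; the even extension keeps rate laws
defined and smooth when a *reduced* trajectory's oscillation trough grazes
slightly below zero, which otherwise is undefined for fractional n.

What the fixtures do not emulate: stochasticity, spatial coupling, explicit
delays, non-smooth rate laws — the method assumes smooth deterministic
dynamics throughout, and passing tests say nothing about those regimes.

## Analysis conventions

- **Fixed points**: deterministic Halton multi-start into `scipy`'s hybrid
  root finder, duplicate merging at 1e-6, classification by Jacobian
  eigenvalues with |Re λ| < 1e-8 flagged "marginal" rather than silently
  classified (Hopf scans sit exactly at marginality).
- **Basins**: each grid node is integrated in chunks (carrying the
  variant's internal state, including the memory vector) until within 1e-3
  of a catalogued attractor or t_max = 500; unresolved nodes are reported
  as −1, never silently labeled.  Bisection refinement (20 steps) locates
  separatrix crossings between oppositely labeled points.
- **Oscillation classification**: after discarding the first 30% of the
  window, a trajectory is *sustained* when the oscillation envelope
  (max−min) over the final half-window — which must contain ≥ 5 periods —
  matches the preceding half-window within 1%.  The envelope form is robust
  to the anharmonic and period-doubled limit cycles the reduced systems
  produce at strong repression, where per-period peak ratios are
  ill-behaved.  Quantitative period/amplitude agreement of sustained
  reduced-system oscillations is explicitly not claimed.
- **Hopf scans**: classification at each grid point from a fixed
  off-attractor start (symmetric point scaled by (1.3, 0.7); full system's
  bulk at QSS), with horizon t_end = 160.  For the full system an
  eigenvalue criterion at the symmetric fixed point provides the exact
  boundary; grid points with |Re λ| below 2/(0.35·t_end) — two e-foldings
  of the leading mode over a classification half-window — are flagged
  marginal, since no finite-horizon simulation can resolve them.  The test
  grid is 13×9; runtime scales linearly in grid size.
- **Determinism**: no analysis draws random numbers; repeated runs are
  bit-reproducible.  CLI `--seed` is accepted for uniformity only.

## Known limitations

- Near a saddle, escape-time sensitivity amplifies the method's intrinsic
  error without bound: for the two-node switch the sup-norm error of the
  reduced transients (fraction of the inter-attractor gap) is ~1–5% for
  starts a moderate distance from the saddle but grows arbitrarily as the
  start approaches it, for ZMn more than for ZMs.  This is a property of
  the truncated memory expansion, not of the integrators (both are
  convergence-tested).
- The ZMn integrator's fixed history grid makes long integrations
  quadratic in time overall; ZMs is the intended tool for trajectory-scale
  work and for all phase-space analyses.
- Uniqueness of the bulk QSS is verified heuristically (multi-start), not
  proven; models violating it raise an error where detected.
- Channel importance has no canonical definition; rankings are stable
  across the provided metrics on the fixtures but are reported as
  qualitative.
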