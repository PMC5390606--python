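# Methods

## Model overview

`cyclenet` couples two models of the cell cycle control network:

1. a **random walk with restart** on a directed gene-interaction graph,
   whose per-step visiting probabilities of five hub regulators
   (CCNB1, TP53, CCND1, CDKN1B, CDH1) serve as state samples; and
2. a **five-variable ODE system**, linear apart from a single bilinear
   term r24·x1·x3 in the TP53 equation, calibrated to those samples and
   simulated with classical fixed-step fourth-order Runge–Kutta (RK4).

The walk is a structural restart process, not a PageRank-style damped
walk: restart happens only through the explicit S node (every gene has
an edge to and from S) and exit through the T node (every gene points to
T, whose single out-edge returns to S).  No teleportation weights exist.

## Graph construction

- Table cells act row-on-column: `X` at (i, j) means gene *i* regulates
  gene *j* and contributes edge i → j.
- **Binding is treated as symmetric**: `Y` (and the `Y` part of `X/Y`)
  contributes both i → j and j → i by default.  Interaction tables of
  this kind are frequently not code-symmetric (a pair can be `Y` in one
  triangle and `X/Y` in the other), so every cell is processed
  independently and duplicate contributions collapse to a single edge —
  the uniform-probability walk cannot distinguish multi-edges anyway.
  `binding_bidirectional=False` restores strict row → column reading.
- **Diagonal non-empty cells become self-loops** by default
  (`include_self_loops=False` drops them).  A self-loop only adds a
  length-1 cycle and slightly redistributes out-edge probability; the
  ergodicity argument is unaffected.
- Node order is fixed as S, genes in table order, T, so the start vector
  (0, 1/n, …, 1/n, 0) and all matrices/vectors align positionally.

Ergodicity holds for *every* interaction table by construction:
gene → T → S → gene is a 3-cycle and any gene-gene edge closes a
4-cycle, so the cycle-length gcd is 1; S makes the graph strongly
connected.  `validate_network` verifies both (BFS level-difference
period algorithm), and the test suite cross-checks them against
brute-force reachability and exhaustive cycle enumeration on randomized
tables.

## Random walk and stationary distribution

Row u of the transition matrix M holds 1/outdeg(u) on each
out-neighbour.  The stationary distribution (PM = P) is computed two
independent ways:

- `eigen` (default): the eigenvector of Mᵀ whose eigenvalue lies within
  1e-8 of 1 (scipy dense eigensolver), negative components below 1e-12
  in magnitude clipped as floating-point noise, then normalized;
- `power`: iteration from the uniform vector until the L1 change drops
  below `tol` (default 1e-12, `max_iter` 100000).

Both are cheap at n = 16; each serves as the oracle for the other in the
tests (agreement within 1e-10 on the packaged network).  Failure to
converge (power) or the absence of a near-1 eigenvalue (eigen) signals a
non-ergodic input and raises rather than returning a spurious vector.

## Sampling and time scale

One walk step is mapped to one ODE time unit; the walk's integer step
index is the sample time.  The default calibration trajectory is 60
steps (61 samples) from the uniform-over-genes start — long enough that
the chain has converged well within the window.  Neither the step count
nor a physical time scale is a claim about biology; both are parameters.

## Static stage (gradient matching)

Derivative samples are estimated by finite differences of accuracy
order 4 (configurable 2/4/6): central stencils in the interior, with the
(order+1)-point window sliding to one-sided stencils of the same order
at the boundaries.  Stencil weights are obtained by solving the exact
Vandermonde moment system, so the stencil is exact on polynomials up to
degree = order (the tests verify exactness on cubics and the ~16×
error drop under step halving).

Because the right-hand side is linear in the coefficients, each of the
five equations is then an independent ordinary least-squares problem:
regressors are the sampled states appearing in that equation (plus the
x1·x3 product column for TP53), the response is the derivative sample.
The solve uses an SVD route (numpy `lstsq`) with a relative rank
tolerance of 1e-10; a rank-deficient regressor matrix (e.g. samples
taken entirely at a steady state) raises an error suggesting a longer or
richer sampling window rather than returning an arbitrary minimum-norm
solution.  An optional ridge penalty (default 0 — plain OLS) is exposed
for ill-conditioned user data.  Per-coefficient standard errors from the
per-equation OLS are reported as diagnostics.

## Dynamic adaptation

The static estimate is refined by minimizing

J(p) = w_tr · Σ_{k ∈ first half} ‖x_sim(t_k; p) − x_k‖² + w_ss · ‖x_sim(t_end; p) − x_N‖²

with defaults w_tr = 1, w_ss = 10: the first term tracks the transient,
the second anchors the steady state.  The optimizer is a damped
Gauss–Newton (Levenberg–Marquardt) loop: forward-difference Jacobian in
the 19 parameters, damping factor starting at 1e-3, multiplied by 10 on
a rejected trial step and divided by 10 on acceptance, so the objective
is non-increasing along accepted steps (`objective_history` records it).
Simulation inside the objective runs RK4 from the first sample at
`sim_step` (default 0.01).  `max_iter` defaults to 50; exhaustion
returns the best point found with `converged=False`.

Two numerical guards make the refinement robust:

- **State clamping.**  Trial parameter sets can be dynamically unstable;
  inside the objective the RK4 state saturates at ±1e6 instead of
  overflowing, keeping J finite and the step-rejection logic meaningful.
  Simulation outside the calibration loop does not clamp — a divergent
  system raises with the blow-up time.
- **Stable restart.**  On short or nearly stationary sample windows the
  static stage can return an unstable system (this happens for the
  packaged 14-gene network, whose walk mixes in a few steps, leaving
  mostly-plateau samples).  When the static estimate's trajectory leaves
  a generous data-scaled box over the sample window, `CellCycleODE.fit`
  restarts the dynamic stage from a neutral stable point — unit
  self-decay (r11 = r22 = r32 = r43 = r54 = −1) with no coupling — from
  which the trajectory objective is informative.  On the packaged
  network this drives J from ~0.5 to ~1e-7 in 50 iterations and the
  simulated steady states match the walk's stationary probabilities to
  ~1e-5.

## Synthetic-data generators

`random_table(n_genes, edge_density, seed)` draws interaction codes
independently per cell (regulation with density/2, binding and both with
density/4 each); it exercises the *structural* guarantees — any such
table must yield an ergodic augmented graph.  It does not emulate the
degree distribution or code correlations of curated interaction tables,
so passing tests show the construction and walk machinery is correct for
arbitrary tables, not that real networks look like these.

`random_stable_params(seed)` draws self-decay coefficients uniform in
[−2, −1] and small nonnegative cross terms (r24 in [0, 0.5], others in
[0, 0.6]), giving a diagonally dominant negative linear part; ≥95% of
draws relax to a steady state from x0 = 1.  These sets probe parameter
recovery across the stable regime, not biological plausibility.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| walk steps | 60 | well past chain convergence; one step = one time unit |
| RK4 step h | 0.01 | global error ≪ coefficient tolerance on O(1) rates |
| finite-difference order | 4 | lowest conventionally "higher-order" stencil; matches smooth walk trajectories |
| transient/steady weights | 1 / 10 | the single steady-state term needs weight to balance ~30 transient terms |
| Gauss–Newton damping | 1e-3, ×10/÷10 | standard Levenberg–Marquardt schedule |
| power-iteration tol | 1e-12 (L1) | near machine precision at n = 16 |
| rank tolerance | 1e-10 relative | separates plateau collinearity from genuine rank |

## Known limitations

- The five-gene projection of the 16-state walk is not autonomous, so no
  ODE of this form reproduces the samples exactly; the calibration finds
  the best compromise under J, and the static and dynamic estimates can
  differ substantially on such data (the round-trip tests, where the
  data *are* generated by the model, recover coefficients to 1e-7).
- Fixed-step RK4 only; stiff or rapidly growing systems should use a
  smaller h (divergence raises with the blow-up time).
- No identifiability analysis or parameter confidence intervals beyond
  the static-stage OLS standard errors; the dynamic objective's Hessian
  is not interrogated.
- Problem sizes throughout (16-node graph, 61-sample windows, ≤50
  refinement iterations) are the pipeline's defaults and what the test
  suite exercises; all scale linearly if raised.
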