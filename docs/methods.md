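# Methods

This note records the models, the algebra, the objective, the
optimisation protocol, and the numerical choices behind `defit`, at the
level of detail a user needs to interpret (and distrust appropriately)
its results.

## Problem setting

A small biochemical network is written as an autonomous ODE system
`x' = f(x; k)` with rational right-hand sides, known initial conditions,
and unknown kinetic parameters `k`.  Only one state variable is
measurable; its time course is sampled on a uniform grid.  The task is
to recover `k` from that single curve.  With most states unmeasured the
standard relative-error objective is nearly flat along large parameter
manifolds, and stochastic optimisers return widely scattered estimates.
The remedy implemented here augments the objective with algebraic
consequences of the model itself — the eliminated (input–output)
equations — which vanish on the data exactly when the parameters are
right.

## Benchmark models

Three models ship with the package (`defit/configs/*.yaml`).

**model1 — binding/dissociation (mass action).**
`A + B <-> AB` with association rate `k_p` and dissociation rate `k_m`:

    x_A'  = -k_p x_A x_B + k_m x_AB
    x_B'  = -k_p x_A x_B + k_m x_AB
    x_AB' =  k_p x_A x_B - k_m x_AB

Reference conditions: `x_A(0)=10, x_B(0)=20, x_AB(0)=0`,
`k_p=0.05, k_m=0.5`; the complex `x_AB` is observed.

**model2 — linear activation cascade.**
A pool `P` feeds three intermediates that each activate the observed
species `x_1` linearly; `x_1` is cleared through two channels:

    P'   = -(k_p2 + k_p3 + k_p4) P
    x_i' =  k_pi P - k_i1 x_i            (i = 2, 3, 4)
    x_1' =  k_21 x_2 + k_31 x_3 + k_41 x_4 - (k_e1 + k_e2) x_1

Reference conditions: `x_1(0)=10, x_2(0)=130, x_3(0)=80, x_4(0)=170`,
`k_21=5, k_31=7, k_41=11, k_p2=3, k_p3=4, k_p4=10, k_e1=5, k_e2=3`.
`P(0) = 100.0` is a package convention (the benchmark literature leaves
it unstated); all synthetic data and acceptance experiments use it.
Note two structural facts that shape everything downstream: `k_e1` and
`k_e2` enter only through their sum (they are not separately
identifiable), and the three branches are exchangeable as *pairs*
`(k_pi, k_i1)` except for the distinct initial conditions — the printed
ICs are the only thing that makes "which branch is which" answerable.

**boulier_example — two-compartment exchange with saturable clearance.**
The classic differential-elimination demonstration model:

    x_1' = -k_12 x_1 + k_21 x_2 - V_e x_1 / (k_e + x_1)
    x_2' =  k_12 x_1 - k_21 x_2

with `x_1` observed.  Its reference parameter values and bounds are
package conventions; the model is an elimination benchmark, not a
recovery benchmark.

**Sampling grid.** All reference curves use `t = 0.01, 0.02, ..., 1.00`
(T = 100 points).  `t = 0` is excluded from the objective because the
observed `x_AB(0) = 0` would put a zero in the relative-error
denominator.

**Noise model.** Noisy data are `X_e(t) = X(t) + c·Rn` with `Rn`
standard normal generated by an explicit Box–Muller transform from a
seeded uniform stream; the benchmark noise scale is `c = 0.666`.  A
multiplicative variant `X·(1 + c·Rn)` is available behind
`NoiseSpec(mode="multiplicative")`.  Additive noise at this scale is
severe at early times where the Model 1 signal is near zero; see
"Limitations".

## Differential elimination

`eliminate()` rewrites a model into an equivalent system in the observed
variable `y`, its derivatives `y__d1 ... y__dk`, the parameters, and —
one per equation — a residual unmeasured state.  The strategy, adequate
for the bundled ≤5-state rational models (general Rosenfeld–Gröbner
machinery over differential ideals is deliberately out of scope):

1. **Conservation-law reduction.**  Linear combinations `c·x` with
   `d(c·x)/dt ≡ 0` are found from the symbolic null space of the
   right-hand sides.  With initial conditions of unmeasured states
   treated as known (the default; they are printed for the benchmarks),
   each law removes one unmeasured state algebraically.  For model1
   both `x_A` and `x_B` are removable; the equivalent system emits one
   member for the top-ranked removed state (`x_A`) and inlines the
   lower-ranked resolution (`x_B = 20 - x_AB`) as a substitution, which
   yields the canonical two-member system (one state member, one
   input–output member).
2. **Prolongation.**  The observed variable's Lie-derivative chain
   `L^k y` (repeated substitution of the right-hand sides) provides
   equations `y__dk = L^k y` for `k = 1..m`, `m` the number of
   remaining unmeasured states.  These are linear in the unmeasured
   states for the bundled models and are solved exactly (Cramer);
   `sympy.solve` is the fallback for nonlinear cases.  Each solved
   state contributes one member, linear in its leader.
3. **Input–output member.**  For linear homogeneous reduced systems
   (model2) the minimal data-only equation is the characteristic ODE
   `p(d/dt) y = 0`, with `p` the characteristic polynomial of the
   system matrix; otherwise it is obtained by substituting the state
   resolutions into the next prolongation and clearing denominators.

Equations are normalised by clearing denominators, expanding, stripping
rational content, and fixing the sign of the leading term; tests compare
equations "up to a nonzero constant factor".  The member counts are 2
(model1), 5 (model2: four state members plus the order-5 input–output
member), and 2 (boulier_example, input–output order 2).

Systems serialise to a deterministic text form
(`defit/fixtures/*.txt`); fixtures ship for model1 and boulier_example
and are asserted byte-identical to a fresh derivation in the test
suite.  model2's system expands to ~100 KB of text and is instead
derived on demand (~30 s of symbolic work, cached per process).

**Soundness oracle.**  Every member, evaluated along an exactly
integrated trajectory with exact Lie-derivative inputs at the
generating parameters, vanishes.  Because model2's input–output member
has monomials of magnitude ~1e11 on the reference data, "vanishes" is
asserted on cancellation-aware relative residuals
(`|residual| / Σ|monomials|`, floored at 1), which is the only
meaningful statement at double precision; model1's and
boulier_example's members also vanish in raw absolute terms.

## Data-side derivatives

Evaluating constraints on measured data requires derivative estimates
of the observed series (`estimate_derivatives`):

- `central_difference` (default): iterated second-order stencils
  (`numpy.gradient`, one-sided second-order at the boundary).  An
  `accuracy` setting switches to direct Fornberg-weight stencils of
  higher accuracy order; noiseless benchmark curves use accuracy 8,
  which on the T = 100 grid reduces the order-4 estimate error from
  ~2e-3 to ~5e-5 relative (reference data are integrated at rtol
  1e-12).  Pushing accuracy further buys little: the one-sided
  high-order boundary stencils amplify the integrator's output error by
  `h^-k`, and that noise floor takes over.
- `smoothing_spline`: cubic smoothing spline with GCV-selected
  smoothing (`scipy.interpolate.make_smoothing_spline`), the default
  once the data carry noise; orders above three re-smooth the last
  derivative series before differentiating again.

Orders above 4 are supported but warn: on sampled data the order-5
estimate needed by model2's input–output member is dominated by
truncation/noise error, so constraint evaluation defaults to
`max_order = 4`, which skips that member (with a warning) and relies on
the four state members.  The member still counts toward the system
size L.

## The objective

For candidate parameters `k`:

- **Error term.**  `E = Σ_t |x^c_t - x^m_t| / max(|x^m_t|, ε)` over the
  observed variables (ε = 1e-12 guards zero denominators; with the
  benchmark grids no denominator is zero).  `E/T` — the mean relative
  error per time point — is the success criterion: 0.01 for model1,
  0.001 for model2.
- **Constraint term.**  `C_DE = Σ_l Σ_t |C_{l,t}|` over the equivalent
  system's members.  Each member is evaluated with the observed series
  and its estimated derivatives from the *data* and the residual
  unmeasured state from the *candidate simulation* — the only
  self-consistent split: simulating everything makes the constraints
  identically zero, while resolving each leader from its own member's
  resolution expression does the same.  Two representation choices
  matter numerically:
  - Members that pin a prolongation-solved state are evaluated through
    their prolongation combination `y__dk - L^k y` (an exact linear
    combination of the system's members).  The solved triangular form
    carries elimination determinants that vanish on parameter
    coincidence hyperplanes (e.g. `k_21 = k_31`), which litters the
    search space with spurious walls and near-null valleys; the
    prolongation form is wall-free.
  - The input–output member is made monic in its highest derivative, so
    no parameter-dependent overall factor can fake a small residual.
- **Blend.**  `OF = (1 - α)·E + α·C_DE`, with α the constraint weight:
  0.1 (model1), 0.9999999 (model2), 0.995 (model1 with noise).

**Constraint normalisation.**  Three options:

- `raw_sum` (model1 default): unit weights, mirroring the absolute-value
  structure of E.
- `per_equation_scaled`: each member's contribution is divided by its
  residual range over a fixed reference sample of in-bounds parameter
  draws — appropriate when members differ by orders of magnitude, as
  model2's do (its order-k members scale like the k-th derivative).
- `pareto_balanced` (model2 default): per-equation scaling plus one
  global factor chosen so that `α·C_DE` and `(1-α)·E` are comparable at
  *near-optimal* fits, obtained from a handful of short seeded
  error-only optimisations at evaluator construction.  Rationale: the
  published weights were calibrated against a particular (unpublished)
  unit system for `C_DE` via Pareto trade-off between E and C; with a
  different unit system the same α encodes a different trade-off, so
  the units are calibrated back to the α.  The advisory
  `pareto_alpha_scan` utility exposes the same trade-off directly
  (median E vs median C over a small α grid, knee by maximum
  perpendicular distance to the endpoints' chord).

## Optimisation protocol

Three minimisers, all driven through a batched objective evaluator:

- **GA**: real-coded; tournament selection (size 2), BLX-0.5 crossover
  (probability 0.9), Gaussian mutation (probability 0.1, scale 5% of
  the bound range), elitism 1, population 50 (campaigns for model2 use
  100).  Out-of-bounds genes are clipped.
- **PSO**: global-best swarm of 30; inertia 0.729, cognitive = social =
  1.49445; reflecting bounds.
- **Powell**: scipy's bounded direction-set minimiser, from random
  starts in campaigns (the local baseline; on the constrained
  objective it exhibits exactly the trapping behaviour that motivates
  the evolutionary methods).

A trial runs in phases of at most `restart_generations` (default 250)
generations inside the overall generation budget (2000).  A phase that
meets the `E/T` threshold stops the trial, which reports the crossing
candidate as-is — the protocol's stopping rule, and the regime of the
binding model, whose trials cross within tens of generations.  A phase
that exhausts its cap without crossing (the regime of the constrained
cascade fit, where no phase crosses) is instead *polished* — its best
point refined by a bounded Nelder–Mead descent of the same objective
(budget `min(polish_maxfev, 300·n_params)` evaluations) — and the
search restarts from a fresh population; the trial finally reports the
best refined solution across phases (by objective value), after
`polish_rounds` fresh-simplex refinement rounds, and its `E/T` —
recomputed with the adaptive reference integrator — decides success.

The polish step is what turns "the phase ended somewhere in a basin"
into "the basin's actual minimiser", and the restart + best-of
selection is what lets the constraint term choose *between* basins: for
model2 the near-perfect fits form several families (branch relabellings
made inequivalent only by the initial conditions), whose refined
objective values differ by factors of 5–50, with the generating
parameters' family lowest.

**Campaigns.**  A campaign runs independently seeded trials
(`SeedSequence` spawning), records one `TrialResult` per trial
(estimates, final `E/T` and `C_DE`, success flag, generations used,
seed), and summarises per-parameter histograms over successful trials
with the declared bin widths (0.01 for `k_p`, 0.1 for `k_m`, 1.0 for
all model2 parameters; bins centered on integer multiples of the
width).  `results.csv` / `summary.json` / histogram and scatter plots
are written by `Campaign.save` and the CLI.

**Inner-loop integration.**  Reference curves and final trial
diagnostics use `solve_ivp` (LSODA, rtol 1e-8 or tighter; synthetic
reference data are generated at rtol 1e-12).  The optimiser inner loop
uses a fixed-step classic Runge–Kutta propagator vectorised over the
whole population (2 substeps per sampling interval by default; the
benchmark campaigns use 1, where the fastest admissible mode still has
λh ≲ 1.7 and the error at relevant candidates is ~1e-5 relative —
far below the success thresholds).  For linear models the RK4 step is
applied as a per-candidate matrix power, which is exact for the scheme
and an order of magnitude faster.  Diverged candidates receive a large
finite penalty (1e15) and never abort a trial.

## Problem sizes used

Desk-scale defaults reproduce the benchmark qualitatively at reduced
cost: campaigns default to 20 trials (the original protocol's 200 is
available via `--full`/`trials=200`), the generation cap stays at 2000
(population 50, or 100 for the cascade model), and noisy-data campaigns
in the test suite cap generations at 250 (noisy trials cannot meet the
error threshold — see below — so they would otherwise always consume
the full budget).

## What the synthetic generator does and does not emulate

The generator reproduces the benchmark study design: exact model
structure, known initial conditions, a single observed variable on a
uniform dense grid, and optional additive Gaussian noise.  Real
time-course data differ in ways that matter for the constraint term:
irregular and sparse sampling degrades the derivative estimates that
the constraints consume; model misspecification makes the eliminated
equations inexact even at the "right" parameters; and measurement noise
is rarely additive-homoscedastic.  Passing tests therefore demonstrate
correct implementation of the method and its behaviour under the
benchmark conditions, not performance on laboratory data.

## Numerical choices and degenerate inputs

- Box–Muller draws uniforms on (0, 1] so the logarithm is finite;
  `c = 0` returns the input unchanged, bit for bit.
- Histogram bins are centered on multiples of the width (the bin at 5.0
  covers [4.5, 5.5)); ties take the smallest center.
- Equation residual evaluation guards division and overflow with numpy
  error states and maps non-finite results to the penalty value.
- `eliminate` raises a budget error (naming the blocking state) if
  expressions exceed a size budget or a state cannot be resolved;
  single-observed-variable models only.
- The balance factor of `pareto_balanced` degrades gracefully: if the
  probe optimisations all fail it falls back to 1.0.

## Known limitations

- **Near-equivalent families of the cascade model.**  model2's single
  observed curve barely distinguishes some branch relabellings: e.g.
  transfer rates (6.49, 4.90, 10.85) with refit production rates
  reproduce the reference `x_1` to a mean relative error of ~2e-6 per
  point — three orders of magnitude below the success threshold.  The
  constraint penalty does rank the generating family below these rivals
  at full convergence, but the margin is a factor of a few and a
  bounded-budget trial does not always realise it; campaign histograms
  reliably recover `k_21` and `k_41`, while the modal `k_31` bin can
  land on a rival family's value.  This is an identifiability property
  of the model under these observation conditions, not an optimiser
  artefact; it is the package's primary caveat.
- With additive noise at the benchmark scale (`c = 0.666`) the mean
  relative error of even the *generating* parameters against a noisy
  Model 1 reference is far above the 0.01 success threshold (the early
  curve is near zero, so the relative noise is huge); noisy campaigns
  therefore report essentially no "successes" and are analysed through
  the distribution of best-found estimates, whose median is pulled
  toward the true values by the constraint term.  Because failed trials
  are refined to convergence, repeated trials on one noisy dataset
  yield essentially one estimate (the deterministic optimum of that
  dataset's objective): spread should be assessed across noise
  realisations, not across trials.
- `k_e1`/`k_e2` of model2 are reported as estimated but only their sum
  is identifiable; campaign histograms of either alone are ridge
  projections.
- model2's order-5 input–output member is excluded from data-side
  constraint evaluation by default (derivative order above the cap);
  its information is partially redundant with the four state members.
- The elimination module targets small explicit rational systems; it is
  not a general differential-algebra package.
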