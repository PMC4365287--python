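# Methods

## Model and assumptions

The package treats a hermaphroditic population as a multiset of scalar traits
evolving by a Markov jump process: pairwise mating produces one offspring per
mating with trait drawn from a kernel `K(x, y, dz)`; individuals die naturally
at rate `D(x)` or through pairwise competition at rate `(I(x)/N) Σⱼ U(x, xⱼ)`.
Standing assumptions, enforced where cheap and sampled otherwise: the
preference `a(x, y)` is symmetric and bounded away from zero and infinity on
the trait space, `p, D, I, U` are nonnegative and bounded, `K(x, y, ·)` is a
probability measure supported in the trait space, symmetric in the parents,
with mean `(x + y)/2`.  Traits are one-dimensional throughout: the Wasserstein
machinery and all solvers assume `d = 1`.

The deterministic (mean-field) flow is solved in two representations: grid
densities (uniform cells, midpoint values, half-open cell convention, density
piecewise constant so the CDF is piecewise linear and mass bookkeeping is
exact) and atomic measures (weighted point masses).  The Wasserstein distance
between probability measures is computed as the exact integral of the
absolute CDF difference over the union of atom positions and cell edges —
piecewise-linear segments integrated in closed form, no sampling — so the
metric is deterministic and symmetric to machine precision.

## Mating models and their conventions

* `semi_random`: rate `p(xᵢ)p(xⱼ)/Σₗ p(xₗ)` with selfing; without selfing the
  two "chooser" roles are averaged with the focal individual removed from its
  own denominator (read literally from the rate formula), and the diagonal is
  zero.  Only the selfing variant has row sums exactly `p(xᵢ)`; notably, both
  variants have **total** birth rate exactly `Σᵢ p(xᵢ)`, which the simulator
  exploits.
* `assortative_female`: preference normalized over the focal row; unit row
  sums; the one intentionally asymmetric variant (two-sex reading, first
  argument is the female).  The selfing flag does not alter it.
* `assortative_symmetric`: the mean of the two female-referenced rates.  The
  non-selfing form drops both the focal and the partner term from each
  denominator and therefore needs `n ≥ 3`.
* `assortative_normalized` / `general_cumulative`: symmetric rates
  `(cᵢ + cⱼ)ā(xᵢ, xⱼ)` with `ā = a` or `ā = a·p·p`; the coefficients solve the
  dense linear system with diagonal `ā_ii + Σₗ ā_il` (unique positive solution
  by diagonal dominance; residual checked against 1e-8).  The measure form is
  a Fredholm equation of the second kind discretized by Nyström on the atoms
  or grid cells; for atomic measures with equal weights it reproduces the
  discrete coefficients times `n`.  These variants are provided as *rates
  only*: the stability theory in this package makes no claim for them, because
  the normalization couples the rate to the state.  The normalized-flow solver
  will run them, and the tests assert only mass and positivity there.

## The birth operator 𝒫 and its numerical routes

`apply_P` evaluates `(𝒫μ)(A) = ∬ K(x, y, A) μ(dx) μ(dy)` by the route the
representation and kernel admit:

* **atomic × quadrature images** (midpoint, interpolation, any kernel with a
  noise quadrature rule): each parent pair contributes deterministic
  Gauss-rule images of the offspring law, so the operator stays deterministic
  with exact mean (the rules integrate polynomials of degree ≥ 3 exactly).
  Solvers re-bin the result with mean-conserving cloud-in-cell weights, which
  keeps the conserved mean exact and inflates the second moment by at most
  `Δ²/6` per unit of re-binned mass — orders of magnitude below the variance
  scales the tests resolve.
* **grid × additive kernel**: `𝒫u = h * law((X₁+X₂)/2)`.  Cell masses are
  convolved by FFT on a half-width lattice (the pairwise midpoints of a
  uniform grid live on the half grid), the noise is applied as a lattice
  convolution with its mass renormalized to one, and the result is deposited
  back with cloud-in-cell weights.  Mean error is at the level of float
  round-off; mass lost past the grid edge is made visible by the boundary
  warning and compensated by renormalization.
* **grid × multiplicative kernel**: with `S = X + Y` (FFT convolution of cell
  masses), `𝒫u(z) = Σₖ w(sₖ) h(z/sₖ)/sₖ`, evaluated chunked over `z`.
* **grid × generic density kernel**: a dense `G³` tensor contraction,
  guarded at `G ≤ 192` cells.
* **atomic × density kernel onto a grid** (`out_grid=`): the exact mixture
  density `Σᵢⱼ wᵢwⱼ k(xᵢ, xⱼ, z)` sampled at the target midpoints — used for
  the empirical contraction checks, where quadrature discretization of the
  noise could contaminate a strict-inequality assertion.

## Time stepping

The normalized flow `μ' = 𝒫μ − μ` is advanced by the positivity-preserving
mixture step `μ ← (1 − w)μ + w𝒫μ` with `w = dt` (default) or the exact
Duhamel weight `w = 1 − e^{−dt}` (option `duhamel=True`, matching the mild
integral form of the equation).  Mass stays exactly one; `dt ≤ 1` is enforced
because larger steps lose positivity.  The first-order bias of the default
step shifts fitted exponential rates by about `dt/4` relative — at the
default `dt = 0.01` that is 0.25%, well inside the 2% band used for the
variance-decay checks.

The full density equation uses explicit Euler with midpoint quadrature.  A
CFL-style guard rejects `dt · max(death rate) > 0.5`; negative undershoots
below 1e-12 are clipped, anything larger errors.  Mass error against the
logistic closed form is first order in `dt` (verified by a dt-halving test);
the default `dt = 0.001` holds it near 1e-6 at horizon 10 because the
carrying capacity is a fixed point of the Euler map as well.

The simulator is the standard SSA: exponential waiting time at the total
rate, event chosen proportionally.  Birth-pair sampling uses closed-form
marginals for semi-random mating (O(n) per event) and the dense rate matrix
otherwise (O(n²), intended for small populations).  One root seed drives
everything; replicate streams are spawned from a `SeedSequence`, so runs are
reproducible bit for bit.  Competition includes the self term `j = i` (the
product-measure reading of the generator); `exclude_self_competition=True`
switches to `n − 1` interactions per head, since the model statement leaves
this open.

## Stationary laws

The additive stationary series is handled two ways.  The **density** is built
spectrally: the convolution product `f = h₀ * h₁*² * h₂*⁴ * …` has
characteristic function `∏ₙ φ(ω/2ⁿ)^{2ⁿ}`, which is evaluated on the FFT
frequency lattice (closed-form φ for the built-in noise shapes, quadrature
against the density for table noise) and inverted on a ≥ 2× zero-padded grid.
Evaluating φ analytically rather than transforming a sampled `hₙ` matters:
beyond level ~15 the factor `hₙ(x) = 2ⁿh(2ⁿx)` is narrower than any
reasonable cell.  The **sampler** draws level `n` as the block mean of `2ⁿ`
noise draws; levels whose brute-force cost exceeds the draw budget (2·10⁸
draws) use the noise's exact aggregate law where one exists (Gaussian block
means are Gaussian), and error with a depth hint otherwise.  Truncation at
depth `m` leaves residual variance `Var(Z)·2^{1−m}`, reported alongside
results.

Stationary profiles are located by iterating `μ ← 𝒫μ` rather than by time
stepping: both share the same fixed points, and the iteration inherits the
strict contraction of the operator on equal-mean classes.  Atomic starts
under additive or multiplicative kernels are first deposited on a grid (those
kernels smooth instantly and have exact FFT routes); midpoint/interpolation
kernels iterate atomically with cloud-in-cell re-binning.  Convergence is
declared when successive iterates are within `tol` in Wasserstein distance;
non-convergence returns a flag, never silently.  No convergence *rate* is
asserted anywhere — the underlying contraction is strict but unquantified —
so iteration budgets are engineering defaults, reported not asserted.

The stability certificates are numerical, not proofs: `check_condition_i`
maximizes the CDF-derivative integral over sampled parent triples from a
caller-given box (adaptive quadrature with kernel-declared breakpoints, error
estimate checked against 1e-4), and `contraction_constants` returns the
closed-form `(α, C, L)` pairs — additive: `(2, 𝔼Z² + q²/2, ½)`;
multiplicative: `(2, 2q²𝔼Z², 2𝔼Z²)` — raising when `L ≥ 1`.  The
first-absolute-moment bound constants declared per family (additive:
`(𝔼|Z|, ½, ½)`; multiplicative and interpolation: `(0, 1, 1)`) are derived
from the sampling forms, and the test suite checks them by Monte Carlo.

## Synthetic inputs and what the tests show

There is no external data; every input is generated.  The packaged scenarios
pin the study conditions: Gaussian noise σ = 1 on a `[−10, 10]` grid
(additive model), uniform noise on `[0, 1]` with mean trait `q = 1` on
`[0, 15]` (Tjon–Wu), uniform `Z` on `[−1, 1]` from 64 equally spaced founders
on `[0, 1]` (interpolation/trait collapse), constant rates `p = 2, D = 1,
I = U = 1` (logistic mass, carrying capacity 1), and the ladder
`N ∈ {50, 200, 800}` with 6 replicates at `T = 3` for the mean-field probe
(`p = 1, D = 0.5, I = U = 1`, Gaussian σ = 0.5 kernel — a persistent regime
with O(N) individuals, sized so the suite stays in minutes on one CPU).
Passing tests certify the *mathematical* behavior of the model under these
idealized conditions — exact rate identities, conserved means, contraction,
convergence to the constructed laws.  They say nothing about fit to any real
population: real trait data are noisy, multidimensional, age- and
space-structured, and violate the constant-rate assumptions used wherever
closed forms exist.

## Numerical choices and degenerate inputs

Probability-mass tolerance for the Wasserstein precondition is 1e-8 (float
drift from long solver runs).  Grids over unbounded trait spaces must be
bounded by the caller; boundary cells carrying more than 1e-6 of the mass log
a warning so truncation is never silent.  Empty populations are absorbing;
zero-mass measures cannot be rescaled or normalized (errors, not NaNs).
Atomic compression bins to cell midpoints (exact mass, mean within half a
cell per unit mass) or, for all solver-internal use, with linear
(cloud-in-cell) weights (exact mass and mean).  Linear solves are dense
direct solves with one residual check — the systems are small and diagonally
dominant.  Finite-difference CDF derivatives use a central difference with
step `1e-4·(1 + |x|)` when no closed form is available.

## Known limitations

One-dimensional traits only.  The dense-matrix mating paths make the
simulator O(n²) per event for assortative variants.  The normalized
assortative flow is solvable but has no stability theory here.  Additive
kernels are restricted to the unbounded trait space — on a bounded interval
the perturbed offspring could leave it, violating the kernel support
contract.  The stability certificates are sampled over finite boxes and
cannot certify the conditions over an unbounded trait space.
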