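# hermesim

Individual-based and mean-field models of **phenotypic evolution in
hermaphroditic populations** — populations in which every individual carries
both reproductive systems, so any individual can mate with any other (and
possibly with itself).

The package is aimed at theoretical ecologists and applied probabilists who
want to simulate, solve and analyze trait-structured sexual-reproduction
models: it implements the stochastic jump process, its deterministic limit
equation, and the analytical machinery (Wasserstein metric, birth-operator
fixed points, stability certificates) needed to study the long-time trait
profile.

## The model

A population is a finite multiset of traits `x₁, …, xₙ ⊂ F ⊆ ℝ`.  Three kinds
of events occur at exponential rates:

* **mating / birth** — a pair `(xᵢ, xⱼ)` mates at rate `m(xᵢ, xⱼ; x)` and adds
  one offspring with trait drawn from a kernel `K(xᵢ, xⱼ, dz)` satisfying
  `∫ z K(x, y, dz) = (x + y)/2` (the expected offspring trait is the parental
  mean) and `K(x, y, ·) = K(y, x, ·)`.  Mating models include semi-random
  (partner choice ∝ a capability `p(x)`, row sums `p(xᵢ)`), female-referenced
  and symmetrized assortative mating with a preference `a(x, y)`, and a
  row-normalized symmetric variant `m = (cᵢ + cⱼ) a(xᵢ, xⱼ)` whose
  coefficients solve a diagonally dominant linear system (discrete) or a
  Fredholm equation of the second kind (measure form).
* **natural death** — individual `xᵢ` dies at rate `D(xᵢ)`.
* **competition** — `xᵢ` dies at rate `(I(xᵢ)/N) Σⱼ U(xᵢ, xⱼ)` with a
  symmetric competition kernel `U`; `N` is the mean-field scaling.

As `N → ∞` the rescaled empirical measure `ν_t/N` converges to a
deterministic measure-valued flow

```
d/dt μ_t = ∬ m(x, y; μ_t) K(x, y, ·) μ_t(dx) μ_t(dy) − (D + I ∫U dμ_t) μ_t .
```

With constant rates the total mass follows a logistic ODE with carrying
capacity `M̄ = (p − D)/(I U)`, and on the attractor the normalized profile
obeys `μ' = 𝒫μ − μ` with the birth operator
`(𝒫μ)(A) = ∬ K(x, y, A) μ(dx) μ(dy)`.  The mean trait is conserved, and under
two checkable conditions (a CDF-derivative integral below one, and a
second-moment contraction `∫|x|ᵅ 𝒫μ ≤ C + L ∫|x|ᵅ μ` with `L < 1`) the
profile converges in the 1-D Wasserstein metric
`d(μ, ν) = ∫ |Φ_μ − Φ_ν| dx` to the unique fixed point of `𝒫` with the same
mean.  Two kernels admit explicit stationary laws:

* **additive** `z = (x+y)/2 + Z`: the stationary deviation is
  `Y = Z₀₁ + (Z₁₁+Z₁₂)/2 + (Z₂₁+…+Z₂₄)/4 + …` with density
  `f = h₀ * h₁*² * h₂*⁴ * …` (`hₙ(x) = 2ⁿh(2ⁿx)`) and `𝔼Y² = 2𝔼Z²`; Gaussian
  noise gives a Gaussian limit with standard deviation `√2·σ`.
* **multiplicative (Tjon–Wu)** `z = (x+y)Z`, `Z ∈ [0,1]`, `𝔼Z = ½`: the
  normalized flow is the Tjon–Wu form of the Boltzmann energy equation and the
  equilibrium with mean `q` is exponential, `(1/q)e^{−z/q}`.

## Worked example

```python
import numpy as np, math
import hermesim as hs

noise = hs.normal_noise(1.0)
f = hs.density_additive_stationary(noise, -10, 10, 4096, depth=20)
print(hs.moment(f, 2))            # 2.00000405237114  (E Y^2 = 2 E Z^2 = 2)

kernel = hs.make_additive(noise)
start = hs.AtomicMeasure([-1.0, 1.0], [0.5, 0.5])
mu, iters, gaps, ok = hs.fixed_point(start, kernel, tol=1e-4)
target = hs.GridDensity.from_function(
    lambda z: np.exp(-z**2/4) / math.sqrt(4*math.pi), -10, 10, 2048,
    normalize=True)
print(iters, hs.wasserstein(mu, target))   # 12 1.92e-05
```

The first number is the second moment of the stationary trait deviation built
by the spectral convolution series — twice the noise variance, as the theory
predicts.  The fixed-point iteration of the birth operator reaches the same
law (Normal with variance 2) from a two-point start in 12 iterations, to
2·10⁻⁵ in Wasserstein distance.

The `examples/` directory holds one narrative script per capability
(mating-rate identities, stochastic simulation, mean-field convergence,
stationary laws, stability certificates, trait collapse); each prints the
numbers it computes and what they mean.  A thin CLI mirrors the library:

```sh
hermesim scenarios                                     # packaged setups
hermesim solve-macro --config run.json --out prefix    # mean-field densities
hermesim simulate-ibm --config run.json --out prefix   # stochastic paths
```

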