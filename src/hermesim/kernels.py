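"""Offspring-trait kernels K(x, y, dz) and their stability diagnostics.

Every kernel satisfies the structural contracts of the model: K(x, y, .) is a
probability measure supported in the trait space, symmetric in the parents,
with mean equal to the parental midpoint (x + y) / 2.  Three concrete families
are provided:

* additive     z = (x+y)/2 + Z          with Z a zero-mean noise with density h
               (only on an unbounded trait space, where the perturbed offspring
               cannot leave F);
* multiplicative (Tjon--Wu)  z = (x+y) Z  with Z in [0,1] and E Z = 1/2,
               on F = [0, inf);
* interpolation  z = (x+y)/2 + Z |x-y|/2 with Z in [-1,1], E Z = 0, so the
               offspring lies between the parents; the degenerate case Z == 0
               is the deterministic midpoint kernel.

Numerical checkers are included for the two sufficient conditions of the
asymptotic-stability theorem for the normalized flow: a sampled sup over
parent triples of the integral

    int | dK/dx(a, y, z) - dK/dx(b, y, z) | dz  < 1        (condition i)

and the alpha-moment contraction  int |x|^a P mu <= C + L int |x|^a mu with
L < 1 (condition ii), for which the additive and multiplicative families have
closed-form constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, stats

from .measures import HALF_LINE, REAL_LINE, TraitSpace


@dataclass
class NoiseSpec:
    """A scalar noise law Z: density, CDF, sampler and moment metadata.

    ``aggregate_sampler(nterms, size, rng)``, when provided, draws the block
    mean  (Z_1 + ... + Z_nterms) / nterms  exactly (e.g. Gaussian); it lets
    deep levels of the additive stationary series be sampled without 2^n
    individual draws.
    """

    name: str
    density: Callable
    cdf: Callable
    sampler: Callable                      # sampler(rng, size) -> draws
    mean: float
    second_moment: float
    support: Tuple[float, float]
    cf: Optional[Callable] = None          # characteristic function, optional
    abs_moment: Optional[float] = None
    aggregate_sampler: Optional[Callable] = None
    quad_nodes: Optional[Callable] = None  # quad_nodes(n) -> (nodes, weights)

    def __post_init__(self) -> None:
        total, _ = integrate.quad(self.density, *self.support, limit=200)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"noise density integrates to {total}, not 1")
        if self.abs_moment is None:
            self.abs_moment, _ = integrate.quad(
                lambda z: abs(z) * self.density(z), *self.support, limit=200)

    @property
    def variance(self) -> float:
        return self.second_moment - self.mean ** 2

    def scaled_first_moment(self, alpha: float) -> float:
        """Quadrature of  int h(z/alpha) z / alpha^2 dz  over z >= 0, which by
        substitution equals the first moment int x h(x) dx of the noise."""
        lo, hi = self.support
        val, _ = integrate.quad(lambda z: self.density(z / alpha) * z / alpha ** 2,
                                alpha * lo, alpha * hi,
                                points=[alpha * lo, alpha * hi], limit=200)
        return val


def normal_noise(sigma: float = 1.0) -> NoiseSpec:
    s = float(sigma)
    dist = stats.norm(0.0, s)
    return NoiseSpec(
        name=f"normal(sigma={s})",
        density=dist.pdf, cdf=dist.cdf,
        sampler=lambda rng, size=None: rng.normal(0.0, s, size),
        mean=0.0, second_moment=s ** 2,
        support=(-np.inf, np.inf),
        cf=lambda w: np.exp(-0.5 * s ** 2 * np.asarray(w) ** 2),
        abs_moment=s * math.sqrt(2.0 / math.pi),
        aggregate_sampler=lambda rng, nterms, size=None:
            rng.normal(0.0, s / math.sqrt(nterms), size),
        quad_nodes=lambda n: _hermite_nodes(n, s),
    )


def _hermite_nodes(n: int, sigma: float) -> Tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x * sigma, w / w.sum()


def _legendre_nodes(n: int, lo: float, hi: float) -> Tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (hi + lo) + 0.5 * (hi - lo) * x, w / w.sum()


def uniform01_noise() -> NoiseSpec:
    """Z ~ Uniform(0, 1): the classical Tjon--Wu noise (E Z = 1/2)."""
    dist = stats.uniform(0.0, 1.0)
    return NoiseSpec(
        name="uniform01",
        density=lambda z: dist.pdf(z), cdf=lambda z: dist.cdf(z),
        sampler=lambda rng, size=None: rng.uniform(0.0, 1.0, size),
        mean=0.5, second_moment=1.0 / 3.0,
        support=(0.0, 1.0),
        cf=lambda w: _sinc_cf(np.asarray(w) / 2.0) * np.exp(0.5j * np.asarray(w)),
        quad_nodes=lambda n: _legendre_nodes(n, 0.0, 1.0),
    )


def uniform_sym_noise(halfwidth: float = 1.0) -> NoiseSpec:
    """Z ~ Uniform(-halfwidth, halfwidth), zero mean."""
    hw = float(halfwidth)
    dist = stats.uniform(-hw, 2 * hw)
    return NoiseSpec(
        name=f"uniform_sym(halfwidth={hw})",
        density=lambda z: dist.pdf(z), cdf=lambda z: dist.cdf(z),
        sampler=lambda rng, size=None: rng.uniform(-hw, hw, size),
        mean=0.0, second_moment=hw ** 2 / 3.0,
        support=(-hw, hw),
        cf=lambda w: _sinc_cf(np.asarray(w) * hw),
        quad_nodes=lambda n: _legendre_nodes(n, -hw, hw),
    )


def _sinc_cf(u: np.ndarray) -> np.ndarray:
    # sin(u)/u with the removable singularity filled in
    return np.sinc(np.asarray(u) / np.pi)


def _piecewise_linear_moment(v: np.ndarray, d: np.ndarray, k: int) -> float:
    """Exact k-th raw moment of a piecewise-linear density on nodes v."""
    x0, x1 = v[:-1], v[1:]
    h = x1 - x0
    b = (d[1:] - d[:-1]) / h
    a = d[:-1] - b * x0
    part = (a * (x1 ** (k + 1) - x0 ** (k + 1)) / (k + 1)
            + b * (x1 ** (k + 2) - x0 ** (k + 2)) / (k + 2))
    return float(part.sum())


def table_noise(values: Sequence[float], densities: Sequence[float]) -> NoiseSpec:
    """Noise from a two-column table (value, density), read as piecewise
    linear between the tabulated points and renormalized."""
    v = np.asarray(values, dtype=float)
    d = np.maximum(np.asarray(densities, dtype=float), 0.0)
    if v.size < 2 or np.any(np.diff(v) <= 0):
        raise ValueError("table noise needs strictly increasing values")
    total = np.trapezoid(d, v)
    if total <= 0:
        raise ValueError("table noise has zero mass")
    d = d / total
    dens = lambda z: np.interp(np.asarray(z, dtype=float), v, d, left=0.0, right=0.0)
    # CDF on the table grid, linear inside panels of the linear density
    cdf_grid = np.concatenate([[0.0], np.cumsum(0.5 * (d[1:] + d[:-1]) * np.diff(v))])
    cdf_grid /= cdf_grid[-1]
    mean = _piecewise_linear_moment(v, d, 1)
    m2 = _piecewise_linear_moment(v, d, 2)

    def sampler(rng, size=None):
        u = rng.uniform(0.0, 1.0, size)
        return np.interp(u, cdf_grid, v)

    return NoiseSpec(
        name="table", density=dens,
        cdf=lambda z: np.interp(np.asarray(z, dtype=float), v, cdf_grid,
                                left=0.0, right=1.0),
        sampler=sampler, mean=float(mean), second_moment=float(m2),
        support=(float(v[0]), float(v[-1])),
    )


# ---------------------------------------------------------------------------

@dataclass
class OffspringKernel:
    """The offspring-trait transition law K(x, y, dz).

    ``sample(x, y, rng, size)`` draws offspring traits; ``density``/``cdf``
    evaluate k(x, y, z) and its CDF when a density exists; ``dcdf_dx`` is the
    partial derivative of the CDF in the first parent (closed form where
    available, else a central difference); ``atomic_images(x, y, order)``
    returns a deterministic quadrature discretization (locations, probs) of
    K(x, y, .), used by the deterministic measure solvers.
    """

    family: str
    space: TraitSpace
    sample: Callable
    noise: Optional[NoiseSpec] = None
    density: Optional[Callable] = None
    cdf: Optional[Callable] = None
    dcdf_dx_closed: Optional[Callable] = None
    moment_bound: Tuple[float, float, float] = (0.0, 1.0, 1.0)
    fd_step: float = 1e-4
    # z-values where dK/dx(x, y, .) may jump, as a function of (x, y)
    dcdf_breaks: Optional[Callable] = None

    def dcdf_dx(self, x, y, z):
        if self.dcdf_dx_closed is not None:
            return self.dcdf_dx_closed(x, y, z)
        if self.cdf is None:
            raise ValueError("kernel has no CDF; cannot differentiate")
        h = self.fd_step * (1.0 + abs(float(np.max(np.abs(np.asarray(x)))))) \
            if np.ndim(x) else self.fd_step * (1.0 + abs(x))
        return (np.asarray(self.cdf(np.asarray(x) + h, y, z))
                - np.asarray(self.cdf(np.asarray(x) - h, y, z))) / (2.0 * h)

    def atomic_images(self, x, y, order: int = 12):
        """Deterministic (locations, probabilities) discretization of
        K(x, y, .) with exact mean; moments exact to the quadrature order."""
        if self.family == "midpoint":
            return np.array([(x + y) / 2.0]), np.array([1.0])
        if self.noise is None or self.noise.quad_nodes is None:
            raise ValueError(f"{self.family} kernel has no quadrature rule")
        z, w = self.noise.quad_nodes(order)
        if self.family == "additive":
            return (x + y) / 2.0 + z, w
        if self.family == "interpolation":
            return (x + y) / 2.0 + z * abs(x - y) / 2.0, w
        if self.family == "multiplicative":
            return (x + y) * z, w
        raise ValueError(f"no atomic images for family {self.family!r}")


def make_additive(noise: NoiseSpec, space: TraitSpace = REAL_LINE) -> OffspringKernel:
    """Additive-noise kernel k(x, y, z) = h(z - (x+y)/2) on F = R."""
    if abs(noise.mean) > 1e-9:
        raise ValueError(f"additive kernel needs zero-mean noise, got {noise.mean}")
    if space.bounded or np.isfinite(space.lower) or np.isfinite(space.upper):
        raise ValueError("additive kernels are only offered on the whole real "
                         "line: on a bounded F the perturbed offspring can "
                         "leave the trait space")
    h, H = noise.density, noise.cdf

    def sample(x, y, rng, size=None):
        return (np.asarray(x) + np.asarray(y)) / 2.0 + noise.sampler(rng, size)

    return OffspringKernel(
        family="additive", space=space, sample=sample, noise=noise,
        density=lambda x, y, z: h(np.asarray(z) - (np.asarray(x) + np.asarray(y)) / 2.0),
        cdf=lambda x, y, z: H(np.asarray(z) - (np.asarray(x) + np.asarray(y)) / 2.0),
        dcdf_dx_closed=lambda x, y, z: -0.5 * h(
            np.asarray(z) - (np.asarray(x) + np.asarray(y)) / 2.0),
        moment_bound=(noise.abs_moment, 0.5, 0.5),
    )


def make_multiplicative(noise: NoiseSpec) -> OffspringKernel:
    """Tjon--Wu kernel k(x, y, z) = h(z/(x+y)) / (x+y) on F = [0, inf)."""
    lo, hi = noise.support
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise ValueError("multiplicative noise must take values in [0, 1]")
    if abs(noise.mean - 0.5) > 1e-6:
        raise ValueError(f"multiplicative noise needs mean 1/2 (parental-mean "
                         f"offspring identity), got {noise.mean}")
    h, H = noise.density, noise.cdf

    def density(x, y, z):
        s = np.asarray(x, dtype=float) + np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, h(np.divide(z, s, out=np.zeros_like(z + s),
                                              where=s > 0)) / np.where(s > 0, s, 1.0),
                           0.0)
        return np.where((z >= 0) & (z <= s), out, 0.0)

    def cdf(x, y, z):
        s = np.asarray(x, dtype=float) + np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inner = H(np.divide(z, s, out=np.zeros_like(z + s), where=s > 0))
        return np.where(s > 0, inner, (z >= 0).astype(float))

    def dcdf(x, y, z):
        s = np.asarray(x, dtype=float) + np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0,
                           -h(np.divide(z, s, out=np.zeros_like(z + s), where=s > 0))
                           * z / np.where(s > 0, s * s, 1.0), 0.0)
        return out

    def sample(x, y, rng, size=None):
        return (np.asarray(x) + np.asarray(y)) * noise.sampler(rng, size)

    return OffspringKernel(
        family="multiplicative", space=HALF_LINE, sample=sample, noise=noise,
        density=density, cdf=cdf, dcdf_dx_closed=dcdf,
        moment_bound=(0.0, 1.0, 1.0),
        dcdf_breaks=lambda x, y: [0.0, (x + y) * noise.support[0],
                                  (x + y) * noise.support[1]],
    )


def make_interpolation(noise: NoiseSpec) -> OffspringKernel:
    """Between-parents kernel z = (x+y)/2 + Z |x-y|/2 with Z in [-1, 1]."""
    lo, hi = noise.support
    if lo < -1.0 - 1e-12 or hi > 1.0 + 1e-12:
        raise ValueError("interpolation noise must take values in [-1, 1]")
    if abs(noise.mean) > 1e-9:
        raise ValueError("interpolation noise must have zero mean")
    if noise.second_moment >= 1.0 - 1e-12:
        raise ValueError("interpolation noise must not be concentrated on "
                         "|Z| = 1 (variance must be < 1)")
    h, H = noise.density, noise.cdf

    def density(x, y, z):
        half = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float)) / 2.0
        mid = (np.asarray(x) + np.asarray(y)) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(half > 0,
                           h(np.divide(np.asarray(z) - mid, half,
                                       out=np.zeros_like(np.asarray(z) + half),
                                       where=half > 0)) / np.where(half > 0, half, 1.0),
                           np.nan)  # x == y: K is a Dirac, no density
        return out

    def cdf(x, y, z):
        half = np.abs(np.asarray(x, dtype=float) - np.asarray(y, dtype=float)) / 2.0
        mid = (np.asarray(x) + np.asarray(y)) / 2.0
        z = np.asarray(z, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inner = H(np.divide(z - mid, half, out=np.zeros_like(z + half),
                                where=half > 0))
        return np.where(half > 0, inner, (z >= mid).astype(float))

    def sample(x, y, rng, size=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x + y) / 2.0 + noise.sampler(rng, size) * np.abs(x - y) / 2.0

    return OffspringKernel(
        family="interpolation", space=REAL_LINE, sample=sample, noise=noise,
        density=density, cdf=cdf, moment_bound=(0.0, 1.0, 1.0),
    )


def make_midpoint(space: TraitSpace = REAL_LINE) -> OffspringKernel:
    """Deterministic kernel: the offspring trait is exactly the parental mean."""

    def sample(x, y, rng=None, size=None):
        mid = (np.asarray(x, dtype=float) + np.asarray(y, dtype=float)) / 2.0
        if size is None or mid.ndim > 0:
            return mid
        return np.full(size, float(mid))

    def cdf(x, y, z):
        mid = (np.asarray(x, dtype=float) + np.asarray(y, dtype=float)) / 2.0
        return (np.asarray(z) >= mid).astype(float)

    return OffspringKernel(family="midpoint", space=space, sample=sample,
                           cdf=cdf, moment_bound=(0.0, 0.5, 0.5))


# --- numerical checkers for the stability conditions -----------------------

def check_condition_i(kernel: OffspringKernel,
                      triples: Optional[np.ndarray] = None,
                      box: Tuple[float, float] = (-3.0, 3.0),
                      ntriples: int = 64,
                      zrange: Optional[Tuple[float, float]] = None,
                      seed: int = 0) -> Tuple[float, bool]:
    """Sampled certificate for the CDF-derivative condition (i).

    Returns ``(max_integral, holds)`` where ``max_integral`` is the largest
    value over the sampled parent triples (a, b, y) of

        int | dK/dx(a, y, z) - dK/dx(b, y, z) | dz

    and ``holds`` is True when that maximum is < 1.  This is a sampled check
    over a finite box, not a proof: the condition quantifies over all triples.
    Each integral is evaluated by adaptive quadrature with the kernel's
    declared discontinuity points as breakpoints; a quadrature error estimate
    above 1e-4 raises.
    """
    rng = np.random.default_rng(seed)
    lo, hi = box
    lo = max(lo, kernel.space.lower)
    hi = min(hi, kernel.space.upper)
    if triples is None:
        triples = rng.uniform(lo, hi, size=(ntriples, 3))
    triples = np.asarray(triples, dtype=float)
    if zrange is None:
        # z range generous enough to hold K(x, y, .) for parents in the box
        zlo = max(kernel.space.lower, 2.0 * lo - (hi - lo) - 10.0)
        zhi = min(kernel.space.upper, 2.0 * hi + (hi - lo) + 10.0)
    else:
        zlo, zhi = zrange

    worst = 0.0
    for a, b, y in triples:
        breaks = []
        if kernel.dcdf_breaks is not None:
            breaks = sorted({float(np.clip(p, zlo, zhi))
                             for p in (*kernel.dcdf_breaks(a, y),
                                       *kernel.dcdf_breaks(b, y))})
        val, err = integrate.quad(
            lambda z: abs(float(kernel.dcdf_dx(a, y, z))
                          - float(kernel.dcdf_dx(b, y, z))),
            zlo, zhi, points=breaks or None, limit=400)
        if err > 1e-4 * max(1.0, val):
            raise RuntimeError(
                f"condition (i) quadrature not converged for triple "
                f"({a}, {b}, {y}): value {val}, error estimate {err}")
        worst = max(worst, val)
    return worst, worst < 1.0


def contraction_constants(kernel: OffspringKernel, q: float
                          ) -> Tuple[float, float, float]:
    """Closed-form (alpha, C, L) for the second-moment contraction of the
    birth operator around mean q: additive -> (2, E Z^2 + q^2/2, 1/2);
    multiplicative -> (2, 2 q^2 E Z^2, 2 E Z^2).  Raises if L >= 1."""
    if kernel.family == "additive":
        ez2 = kernel.noise.second_moment
        alpha, C, L = 2.0, ez2 + 0.5 * q * q, 0.5
    elif kernel.family == "multiplicative":
        ez2 = kernel.noise.second_moment
        alpha, C, L = 2.0, 2.0 * q * q * ez2, 2.0 * ez2
    else:
        raise ValueError(f"no closed-form contraction constants for "
                         f"{kernel.family!r}; supply (alpha, C, L) manually")
    if L >= 1.0:
        raise ValueError(f"moment contraction fails: L = {L} >= 1")
    return alpha, C, L


def empirical_kernel_mean(kernel: OffspringKernel, x: float, y: float,
                          n: int, seed: int = 0) -> float:
    """Monte-Carlo mean of n offspring draws from K(x, y, .)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.asarray(kernel.sample(x, y, rng, n), dtype=float)
    if draws.ndim == 0:
        return float(draws)
    return float(draws.mean())
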