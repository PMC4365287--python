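"""Stationary trait distributions and convergence diagnostics.

For the additive-noise model the stationary law around mean q is the law of
q + Y with

    Y = Z_01 + (Z_11 + Z_12)/2 + (Z_21 + ... + Z_24)/4 + ...,

an infinite series of block means of i.i.d. copies of the noise; its density
is the infinite convolution f = h_0 * h_1^{*2} * h_2^{*4} * ... with
h_n(x) = 2^n h(2^n x), and E Y^2 = 2 E Z^2.  Both a sampler and a spectral
density builder (characteristic-function product on the FFT lattice) are
provided, truncated at a configurable depth with residual variance
Var(Z) / 2^depth.

For the multiplicative (Tjon--Wu) model with uniform noise the equilibrium
is the exponential law with the conserved mean q; it is exposed in closed
form and cross-checked against the fixed point of the birth operator.

``fixed_point`` iterates the birth operator P to its unique fixed point in
the equal-mean class (the mean is conserved by every iterate), and
``variance_decay_fit`` extracts the exponential variance-decay rate
(1 - Var(Z)) / 2 of the between-parents (interpolation) model from a solver
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .kernels import NoiseSpec, OffspringKernel
from .macroscopic import MacroTrajectory, apply_P
from .mating import MatingModel
from .measures import (AtomicMeasure, GridDensity, MeasureLike,
                       atomic_to_grid, compress, moment, rescale_to_mass,
                       wasserstein)

#: total independent noise draws allowed per call of the brute-force sampler
DRAW_BUDGET = 200_000_000


@dataclass
class SeriesSpec:
    """Truncation and sampling control for the additive stationary series."""

    depth: int = 30
    nsamples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def residual_variance(self, noise: NoiseSpec) -> float:
        """Variance of the dropped tail of the series: levels 0..depth-1 are
        kept, so the remainder is sum_{n >= depth} Var(Z)/2^n
        = Var(Z) * 2^(1-depth)."""
        return noise.variance * 2.0 ** (1 - self.depth)


def sample_additive_stationary(noise: NoiseSpec, spec: SeriesSpec) -> np.ndarray:
    """i.i.d. draws of the depth-truncated stationary deviation Y.

    Level n contributes the block mean of 2^n fresh noise draws scaled by
    2^-n, i.e. (Z_1 + ... + Z_{2^n}) / 2^n.  Levels whose brute-force cost
    would exceed the draw budget use the noise's exact aggregate sampler
    (available for Gaussian noise, where the block mean is again Gaussian);
    without one, the call errors with a budget hint.
    """
    rng = np.random.default_rng(spec.seed)
    out = np.zeros(spec.nsamples)
    for level in range(spec.depth):
        nterms = 2 ** level
        cost = nterms * spec.nsamples
        if cost <= DRAW_BUDGET:
            draws = noise.sampler(rng, (spec.nsamples, nterms)) if nterms > 1 \
                else noise.sampler(rng, spec.nsamples)
            contrib = draws.mean(axis=1) if nterms > 1 else draws
        elif noise.aggregate_sampler is not None:
            contrib = noise.aggregate_sampler(rng, nterms, spec.nsamples)
        else:
            raise ValueError(
                f"level {level} needs {cost:.3g} draws, over the budget "
                f"{DRAW_BUDGET:.3g}; lower the depth to "
                f"<= {int(math.log2(max(DRAW_BUDGET // spec.nsamples, 1))) + 1} "
                f"or supply noise with an aggregate sampler")
        out += contrib
    return out


def density_additive_stationary(noise: NoiseSpec, lower: float, upper: float,
                                ncells: int, depth: int = 20) -> GridDensity:
    """Spectral construction of the truncated stationary density.

    The convolution product f = h_0 * h_1^{*2} * ... is evaluated through its
    characteristic function: on the FFT frequency lattice each factor
    contributes phi(omega / 2^n)^(2^n), with phi the noise characteristic
    function (closed form for the built-in shapes, quadrature against the
    density for table noise).  The result is inverted on a zero-padded grid
    (>= 2x the requested span, wrap-around suppressed), clipped at zero and
    normalized to unit mass.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    dx = (upper - lower) / ncells
    npad = 1 << int(np.ceil(np.log2(2 * ncells)))
    omega = 2.0 * np.pi * np.fft.rfftfreq(npad, d=dx)
    phi = noise.cf if noise.cf is not None else _quadrature_cf(noise)
    F = np.ones(omega.size, dtype=complex)
    for n in range(depth):
        F *= np.asarray(phi(omega / 2.0 ** n), dtype=complex) ** (2 ** n)
    # values on the periodic lattice x_j = j*dx (j = 0..npad-1), x wraps at L/2
    # (conjugate so that irfft's +i convention inverts the +i CF convention)
    vals = np.fft.irfft(np.conj(F), npad) / dx
    xs = np.arange(npad) * dx
    half = npad // 2
    xs[half:] -= npad * dx              # map the top half to negative x
    mids = lower + (np.arange(ncells) + 0.5) * dx
    # nearest lattice point for each requested midpoint
    order = np.argsort(xs)
    vals_sorted = vals[order]
    xs_sorted = xs[order]
    out = np.interp(mids, xs_sorted, vals_sorted)
    out = np.maximum(out, 0.0)
    mass_out = out.sum() * dx
    if mass_out < 1.0 - 1e-8:
        tail = 1.0 - mass_out
        if tail > 1e-4:
            raise ValueError(
                f"grid [{lower}, {upper}] leaves {tail:.3g} of the stationary "
                f"mass outside; widen the grid")
    g = GridDensity(lower, upper, out)
    return rescale_to_mass(g, 1.0)


def _quadrature_cf(noise: NoiseSpec, npts: int = 4096):
    lo, hi = noise.support
    if not (np.isfinite(lo) and np.isfinite(hi)):
        sd = math.sqrt(max(noise.variance, 1e-300))
        lo, hi = noise.mean - 10 * sd, noise.mean + 10 * sd
    xs = np.linspace(lo, hi, npts)
    dens = np.asarray(noise.density(xs), dtype=float)
    dens = dens / np.trapezoid(dens, xs)

    def phi(w):
        w = np.atleast_1d(np.asarray(w, dtype=float))
        out = np.empty(w.shape, dtype=complex)
        chunk = 256
        for s in range(0, w.size, chunk):
            blk = w[s:s + chunk]
            out[s:s + chunk] = np.trapezoid(
                dens * np.exp(1j * np.outer(blk, xs)), xs, axis=1)
        return out

    return phi


def fixed_point(mu0: MeasureLike, kernel: OffspringKernel,
                mating: Optional[MatingModel] = None,
                tol: float = 1e-3, max_iter: int = 200, order: int = 12,
                compress_box: Optional[Tuple[float, float]] = None,
                compress_cells: int = 1024
                ) -> Tuple[MeasureLike, int, np.ndarray, bool]:
    """Iterate mu <- P mu to the stationary trait law.

    Returns (mu_star, iterations, gap_series, converged); the gap series is
    d(mu_k, mu_{k+1}) and is expected to be (weakly) decreasing under the
    strict-contraction conditions.  Non-convergence within max_iter returns
    the last iterate with converged=False, never silently.  Atomic iterates
    are re-binned (mean-conserving) onto ``compress_cells`` cells of a box
    wide enough to hold the stationary law, inferred from the kernel family
    when not given.
    """
    if abs(moment(mu0, 0) - 1.0) > 1e-8:
        raise ValueError("mu0 must be a probability measure")
    mu = mu0
    atomic = isinstance(mu0, AtomicMeasure)
    if atomic and compress_box is None:
        lo = float(mu0.locations.min())
        hi = float(mu0.locations.max())
        if kernel.family == "additive":
            spread = 10.0 * math.sqrt(2.0 * kernel.noise.second_moment)
            compress_box = (lo - spread, hi + spread)
        elif kernel.family == "multiplicative":
            compress_box = (0.0, max(hi, 15.0 * mu0.mean, 1.0))
        else:
            compress_box = (lo, hi)
    if atomic and kernel.family in ("additive", "multiplicative"):
        # these kernels have exact FFT grid routes; a grid representation is
        # both faster and more accurate than quadrature images of the noise
        mu = rescale_to_mass(atomic_to_grid(mu0, compress_box[0],
                                            compress_box[1], compress_cells),
                             1.0)
        atomic = False
    gaps = []
    for it in range(1, max_iter + 1):
        nxt = apply_P(mu, kernel, mating, normalize=True, order=order)
        if atomic:
            # quadrature images can overshoot the box with negligible weight;
            # clamp them to the boundary before re-binning
            clipped = AtomicMeasure(
                np.clip(nxt.locations, compress_box[0], compress_box[1]),
                nxt.weights, nxt.space)
            nxt = rescale_to_mass(
                compress(clipped, compress_box[0], compress_box[1],
                         compress_cells, linear=True), 1.0)
        gap = wasserstein(mu, nxt)
        gaps.append(gap)
        mu = nxt
        if gap < tol:
            return mu, it, np.array(gaps), True
    return mu, max_iter, np.array(gaps), False


def variance_decay_fit(trajectory: MacroTrajectory,
                       drop_initial: float = 0.1,
                       var_floor: float = 1e-10) -> float:
    """Exponential decay rate of the trait variance along a trajectory.

    Least-squares slope of log variance against time (sign flipped), after
    dropping the initial ``drop_initial`` fraction of the time points
    (discretization transient) and any points with variance below the floor.
    """
    t = np.asarray(trajectory.times, dtype=float)
    v = np.asarray(trajectory.variance, dtype=float)
    if t.size < 3:
        raise ValueError("trajectory too short for a decay fit")
    start = int(math.floor(drop_initial * t.size))
    t, v = t[start:], v[start:]
    keep = v > var_floor
    t, v = t[keep], v[keep]
    if t.size < 2:
        raise ValueError("no usable window: variance below floor everywhere")
    slope, _ = np.polyfit(t, np.log(v), 1)
    return float(-slope)


def tjon_wu_equilibrium(q: float, lower: float, upper: float,
                        ncells: int) -> GridDensity:
    """Exponential equilibrium (1/q) exp(-z/q) of the Tjon--Wu model with
    uniform noise, normalized on the grid.  (Verified in the test suite as a
    fixed point of the birth operator.)"""
    if q <= 0:
        raise ValueError("q must be positive")
    if lower < 0:
        raise ValueError("the Tjon--Wu model lives on [0, inf)")
    from .measures import HALF_LINE
    g = GridDensity.from_function(lambda z: np.exp(-z / q) / q, lower, upper,
                                  ncells, space=HALF_LINE)
    return rescale_to_mass(g, 1.0)
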