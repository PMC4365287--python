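"""Deterministic mean-field solvers.

In the infinite-population limit the trait distribution mu_t solves a
nonlinear integro-differential equation: a bilinear birth term (mating rate
times offspring kernel) minus trait-dependent natural and competitive death.
With constant demographic rates the total mass follows a logistic ODE with
carrying capacity Mbar = (p - D) / (I U), and after rescaling mass and time
the dynamics on the attractor reduces to the normalized evolution equation

    mu_t' = P mu_t - mu_t,      (P mu)(A) = int int K(x, y, A) mu(dx) mu(dy),

whose fixed points are the stationary trait profiles.  This module provides

* the logistic mass solution and the extinction/persistence classifier,
* ``apply_P``: the one-step birth operator on atomic measures and grid
  densities (exact quadrature images, FFT convolution for additive kernels,
  a scaled-convolution transform for multiplicative kernels, and a dense
  tensor contraction for general kernels with a density),
* ``solve_normalized``: positivity-preserving mixture stepping of the
  normalized equation (plain Euler weights or exact Duhamel weights),
* ``solve_density``: explicit Euler for the full density equation on a grid,
* ``attractor_rescale``: the mass/time rescaling that maps constant-rate
  solutions of the full equation onto the normalized flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal

from .kernels import OffspringKernel
from .mating import MatingModel, solve_fredholm_c
from .measures import (AtomicMeasure, GridDensity, MeasureLike, compress,
                       moment, rescale_to_mass, variance)

MAX_TENSOR_CELLS = 192          # guard for the dense G^3 birth contraction


def _scalar(v) -> bool:
    return np.isscalar(v) or isinstance(v, (int, float))


def _eval(f, x):
    if callable(f):
        return np.asarray(f(np.asarray(x, dtype=float)), dtype=float)
    return np.full(np.asarray(x).shape, float(f))


@dataclass
class MacroParams:
    """Demography plus mating and offspring kernel for the mean-field model.

    p, D, I, U may be constants (required for the carrying-capacity analysis)
    or vectorized trait functions (density solver).
    """

    p: object = 1.0
    D: object = 0.0
    I: object = 0.0
    U: object = 0.0
    mating: MatingModel = field(default_factory=MatingModel)
    kernel: Optional[OffspringKernel] = None

    @property
    def constant_mode(self) -> bool:
        return all(_scalar(v) for v in (self.p, self.D, self.I, self.U))

    def effective_p(self) -> float:
        """Constant per-capita birth rate: p for semi-random mating, 1 for the
        unit-row-sum assortative variants."""
        if self.mating.variant == "semi_random":
            if not _scalar(self.p):
                raise ValueError("constant-rate analysis needs constant p")
            return float(self.p)
        return 1.0


@dataclass
class MacroTrajectory:
    """Snapshots of a deterministic measure-valued solution."""

    times: np.ndarray
    measures: List[MeasureLike]
    meta: dict = field(default_factory=dict)

    @property
    def mass(self) -> np.ndarray:
        return np.array([moment(m, 0) for m in self.measures])

    @property
    def mean(self) -> np.ndarray:
        return np.array([moment(m, 1) / max(moment(m, 0), 1e-300)
                         for m in self.measures])

    @property
    def variance(self) -> np.ndarray:
        return np.array([variance(m) for m in self.measures])


# --- total mass -------------------------------------------------------------

def mass_solution(M0: float, params: MacroParams, t) -> np.ndarray:
    """Closed-form solution of M' = p M - (D + I U M) M with constant rates.

    Logistic toward Mbar = (p - D)/(I U) when I U > 0; exponential when
    I U = 0; decay to zero when p <= D.
    """
    if M0 <= 0:
        raise ValueError("M0 must be positive")
    if not params.constant_mode:
        raise ValueError("mass_solution requires constant p, D, I, U")
    t = np.asarray(t, dtype=float)
    r = params.effective_p() - float(params.D)
    beta = float(params.I) * float(params.U)
    if beta == 0.0:
        return M0 * np.exp(r * t)
    if r == 0.0:
        return M0 / (1.0 + beta * M0 * t)
    # stable forms on both sides of r = 0
    if r > 0:
        return r / (beta + (r / M0 - beta) * np.exp(-r * t))
    ert = np.exp(r * t)
    return r * M0 * ert / (r + beta * M0 * (ert - 1.0))


def carrying_capacity(params: MacroParams) -> float:
    r = params.effective_p() - float(params.D)
    beta = float(params.I) * float(params.U)
    if beta <= 0:
        raise ValueError("carrying capacity needs I U > 0")
    return r / beta


def classify_persistence(p_range, D_range, mating_variant: str = "semi_random") -> str:
    """Extinction/persistence from the rate bounds: extinct when
    inf D >= sup p, persistent when sup D < inf p (p := 1 for the
    assortative variants); otherwise undetermined."""
    d_lo, d_hi = map(float, D_range)
    if mating_variant == "semi_random":
        p_lo, p_hi = map(float, p_range)
    else:
        p_lo = p_hi = 1.0
    if d_lo >= p_hi:
        return "extinct"
    if d_hi < p_lo:
        return "persistent"
    return "undetermined"


# --- the birth operator P ---------------------------------------------------

def _pair_weights(locs: np.ndarray, w: np.ndarray,
                  mating: Optional[MatingModel]) -> Optional[np.ndarray]:
    """Pairwise factor psi(x_i, x_j; mu) for the normalized assortative flow;
    None means unit weights (random mating)."""
    if mating is None or mating.variant == "semi_random":
        return None
    A = mating.a_at(locs[:, None], locs[None, :])
    if mating.variant in ("assortative_female", "assortative_symmetric"):
        g = A @ w
        if mating.variant == "assortative_female":
            return A / g[:, None]
        return 0.5 * A * (1.0 / g[:, None] + 1.0 / g[None, :])
    if mating.variant in ("assortative_normalized", "general_cumulative"):
        mu = AtomicMeasure(locs, w)
        coeffs = solve_fredholm_c(mu, mating)
        c = coeffs.values
        psi = (c[:, None] + c[None, :]) * A
        if mating.variant == "general_cumulative":
            p = mating.p_at(locs)
            psi = psi * np.outer(p, p)
        return psi
    raise ValueError(f"unknown mating variant {mating.variant!r}")


def _atomic_P(mu: AtomicMeasure, kernel: OffspringKernel,
              mating: Optional[MatingModel], order: int) -> AtomicMeasure:
    locs, w = mu.locations, mu.weights
    psi = _pair_weights(locs, w, mating)
    X = locs[:, None] + np.zeros_like(locs)[None, :]
    Y = np.zeros_like(locs)[:, None] + locs[None, :]
    WW = np.outer(w, w)
    if psi is not None:
        WW = WW * psi
    if kernel.family == "midpoint":
        img = (X + Y) / 2.0
        return AtomicMeasure(img.ravel(), WW.ravel(), mu.space)
    if kernel.noise is None or kernel.noise.quad_nodes is None:
        raise ValueError(f"kernel family {kernel.family!r} has no quadrature "
                         f"rule; use a grid density representation")
    z, q = kernel.noise.quad_nodes(order)
    if kernel.family == "additive":
        img = ((X + Y) / 2.0)[..., None] + z
    elif kernel.family == "interpolation":
        img = ((X + Y) / 2.0)[..., None] + z * (np.abs(X - Y) / 2.0)[..., None]
    elif kernel.family == "multiplicative":
        img = (X + Y)[..., None] * z
    else:
        raise ValueError(f"no atomic images for family {kernel.family!r}")
    wts = WW[..., None] * q
    return AtomicMeasure(img.ravel(), wts.ravel(), mu.space)


def _grid_P_additive(u: GridDensity, kernel: OffspringKernel) -> GridDensity:
    """P u for an additive kernel: the density of (X + Y)/2 + Z via FFT
    convolution of cell masses on a half-width lattice, deposited back with
    mean-conserving linear weights."""
    dx = u.cellwidth
    delta = dx / 2.0
    w = u.values * dx                      # cell masses
    w2 = signal.fftconvolve(w, w)          # masses of X+Y at index k = i+j
    # midpoints (m_i + m_j)/2 sit at  lo + (k+1) * delta
    noise = kernel.noise
    lo_s, hi_s = noise.support
    if not np.isfinite(lo_s):
        sd = math.sqrt(max(noise.variance, 1e-300))
        lo_s, hi_s = -9.0 * sd, 9.0 * sd
    nlo = int(np.floor(lo_s / delta)) - 1
    nhi = int(np.ceil(hi_s / delta)) + 1
    zoff = np.arange(nlo, nhi + 1) * delta
    q = np.asarray(noise.density(zoff), dtype=float) * delta
    s = q.sum()
    if s > 0:
        q = q / s                          # exact unit kernel mass on the lattice
    p = signal.fftconvolve(w2, q)          # masses at lo + (k + 1 + n) * delta
    pos = u.lower + (np.arange(p.size) + 1 + nlo) * delta
    return _deposit(pos, p, u)


def _grid_P_multiplicative(u: GridDensity, kernel: OffspringKernel,
                           chunk: int = 256) -> GridDensity:
    """P u for a multiplicative kernel: density of (X + Y) Z, computed as
    sum_k w2_k h(z / s_k) / s_k over the lattice masses w2 of S = X + Y."""
    dx = u.cellwidth
    w = u.values * dx
    w2 = signal.fftconvolve(w, w)
    s = 2.0 * u.lower + (np.arange(w2.size) + 1.0) * dx
    keep = (s > 0) & (w2 > 0)
    s, w2 = s[keep], w2[keep]
    h = kernel.noise.density
    z = u.midpoints
    out = np.empty_like(z)
    coeff = w2 / s
    for start in range(0, z.size, chunk):
        blk = z[start:start + chunk]
        out[start:start + chunk] = (np.asarray(h(blk[:, None] / s[None, :]),
                                               dtype=float) @ coeff)
    return GridDensity(u.lower, u.upper, np.maximum(out, 0.0), u.space)


def _grid_P_tensor(u: GridDensity, kernel: OffspringKernel,
                   mating: Optional[MatingModel]) -> GridDensity:
    if u.ncells > MAX_TENSOR_CELLS:
        raise ValueError(
            f"dense birth contraction limited to {MAX_TENSOR_CELLS} cells "
            f"(got {u.ncells}); use an additive/multiplicative kernel fast "
            f"path or a coarser grid")
    if kernel.density is None:
        raise ValueError("grid route needs a kernel density")
    mids = u.midpoints
    dx = u.cellwidth
    W = np.outer(u.values, u.values) * dx * dx
    psi = _pair_weights(mids, u.values * dx, mating)
    if psi is not None:
        W = W * psi
    K = np.asarray(kernel.density(mids[None, :, None], mids[None, None, :],
                                  mids[:, None, None]), dtype=float)
    K = np.nan_to_num(K, nan=0.0)
    vals = np.einsum("zij,ij->z", K, W)
    return GridDensity(u.lower, u.upper, np.maximum(vals, 0.0), u.space)


def _deposit(pos: np.ndarray, masses: np.ndarray, like: GridDensity) -> GridDensity:
    """Mean-conserving (cloud-in-cell) deposit of point masses on the grid of
    ``like``; mass falling outside is dropped (the boundary warning of the
    grid container makes the truncation visible)."""
    dx = like.cellwidth
    acc = np.zeros(like.ncells)
    fi = (pos - like.lower) / dx - 0.5
    inside = (fi > -1.0) & (fi < like.ncells)
    fi, m = fi[inside], masses[inside]
    i0 = np.floor(fi).astype(int)
    frac = fi - i0
    lo_ok = (i0 >= 0) & (i0 < like.ncells)
    hi_ok = (i0 + 1 >= 0) & (i0 + 1 < like.ncells)
    np.add.at(acc, i0[lo_ok], (m * (1.0 - frac))[lo_ok])
    np.add.at(acc, (i0 + 1)[hi_ok], (m * frac)[hi_ok])
    return GridDensity(like.lower, like.upper, np.maximum(acc, 0.0) / dx,
                       like.space)


def apply_P(mu: MeasureLike, kernel: OffspringKernel,
            mating: Optional[MatingModel] = None,
            normalize: bool = True, order: int = 12,
            out_grid: Optional[GridDensity] = None) -> MeasureLike:
    """One application of the birth operator (P mu)(A) = iint K(x,y,A) mu mu.

    For random (semi-random) mating this is the plain product-measure push
    through the kernel; an assortative MatingModel inserts the normalized
    pair weight psi(x, y; mu).  mu must be a probability measure; the output
    is renormalized to unit mass (compensating grid truncation) unless
    ``normalize=False``.
    """
    m = moment(mu, 0)
    if abs(m - 1.0) > 1e-6:
        raise ValueError(f"apply_P expects a probability measure, mass={m}")
    if isinstance(mu, AtomicMeasure):
        if out_grid is not None:
            if kernel.density is None:
                raise ValueError("atomic-to-grid route needs a kernel density")
            mids = out_grid.midpoints
            psi = _pair_weights(mu.locations, mu.weights, mating)
            WW = np.outer(mu.weights, mu.weights)
            if psi is not None:
                WW = WW * psi
            K = np.asarray(kernel.density(mu.locations[None, :, None],
                                          mu.locations[None, None, :],
                                          mids[:, None, None]), dtype=float)
            vals = np.einsum("zij,ij->z", np.nan_to_num(K, nan=0.0), WW)
            res = GridDensity(out_grid.lower, out_grid.upper,
                              np.maximum(vals, 0.0), mu.space)
        else:
            res = _atomic_P(mu, kernel, mating, order)
    elif isinstance(mu, GridDensity):
        if kernel.family == "additive" and (mating is None or
                                            mating.variant == "semi_random"):
            res = _grid_P_additive(mu, kernel)
        elif kernel.family == "multiplicative" and (mating is None or
                                                    mating.variant == "semi_random"):
            res = _grid_P_multiplicative(mu, kernel)
        else:
            res = _grid_P_tensor(mu, kernel, mating)
    else:
        raise TypeError(f"unsupported measure type {type(mu)!r}")
    if normalize:
        res = rescale_to_mass(res, 1.0)
    return res


# --- normalized evolution mu' = P mu - mu -----------------------------------

def solve_normalized(mu0: MeasureLike, kernel: OffspringKernel,
                     mating: Optional[MatingModel] = None,
                     T: float = 1.0, dt: float = 0.01,
                     snapshot_times: Optional[Sequence[float]] = None,
                     duhamel: bool = False, order: int = 12,
                     compress_cells: int = 512) -> MacroTrajectory:
    """Positivity-preserving mixture stepping of mu' = P mu - mu.

    Each step replaces mu by (1 - w) mu + w P mu with w = dt (plain Euler) or
    w = 1 - exp(-dt) (the exact Duhamel weight of the mild form).  Mass stays
    exactly one; the first moment is conserved up to quadrature/compression
    error.  Atomic states are re-binned onto ``compress_cells`` mean-conserving
    cells after every step to keep the atom count bounded.
    """
    if not 0.0 < dt <= 1.0:
        raise ValueError("need 0 < dt <= 1 (mixture step loses positivity "
                         "beyond dt = 1)")
    if abs(moment(mu0, 0) - 1.0) > 1e-8:
        raise ValueError("mu0 must be a probability measure")
    nsteps = int(round(T / dt))
    times = [0.0]
    mu = mu0
    if isinstance(mu0, AtomicMeasure):
        span = mu0.locations.max() - mu0.locations.min() if mu0.locations.size else 1.0
        pad = 0.5 * max(span, 1e-6)
        box = (mu0.locations.min() - pad, mu0.locations.max() + pad)
    snaps = [mu]
    w_mix = (1.0 - math.exp(-dt)) if duhamel else dt
    want = None if snapshot_times is None else list(snapshot_times)
    for k in range(1, nsteps + 1):
        pm = apply_P(mu, kernel, mating, normalize=True, order=order)
        if isinstance(mu, AtomicMeasure):
            merged = AtomicMeasure(
                np.concatenate([mu.locations, pm.locations]),
                np.concatenate([mu.weights * (1.0 - w_mix), pm.weights * w_mix]),
                mu.space)
            mu = compress(merged, box[0], box[1], compress_cells, linear=True)
        else:
            mu = GridDensity(mu.lower, mu.upper,
                             (1.0 - w_mix) * mu.values + w_mix * pm.values,
                             mu.space)
        t = k * dt
        if want is None or any(abs(t - s) < 0.5 * dt for s in want):
            times.append(t)
            snaps.append(mu)
    return MacroTrajectory(np.array(times), snaps,
                           meta={"dt": dt, "duhamel": duhamel, "T": T})


# --- full density equation on a grid ----------------------------------------

def solve_density(u0: GridDensity, params: MacroParams,
                  T: float = 1.0, dt: float = 0.001,
                  snapshot_every: Optional[float] = None) -> MacroTrajectory:
    """Explicit Euler for the full mean-field density equation.

    Birth uses the exact FFT route when the kernel is additive or
    multiplicative and mating is semi-random (with trait-dependent p folded
    into the convolved masses); otherwise a dense tensor contraction with the
    kernel density (grid limited to MAX_TENSOR_CELLS cells).
    """
    kernel = params.kernel
    if kernel is None:
        raise ValueError("MacroParams.kernel is required")
    mids = u0.midpoints
    D = _eval(params.D, mids)
    Iv = _eval(params.I, mids)
    dx = u0.cellwidth
    U_const = _scalar(params.U)
    if not U_const:
        Umat = np.asarray(params.U(mids[:, None], mids[None, :]), dtype=float)
    mating = params.mating
    semi = mating.variant == "semi_random"
    fast = semi and kernel.family in ("additive", "multiplicative")
    if not fast and kernel.density is None:
        raise ValueError("density solver needs a kernel density")

    u = u0.values.copy()
    times = [0.0]
    snaps = [GridDensity(u0.lower, u0.upper, u.copy(), u0.space)]
    nsteps = int(round(T / dt))
    every = max(1, int(round((snapshot_every or max(T / 50.0, dt)) / dt)))
    pvals = _eval(mating.p, mids) if semi else None

    for k in range(1, nsteps + 1):
        M = u.sum() * dx
        if M <= 0:
            u = np.zeros_like(u)
            times.append(k * dt)
            snaps.append(GridDensity(u0.lower, u0.upper, u.copy(), u0.space))
            break
        # birth
        if semi:
            denom = float(pvals @ u) * dx
            ut = pvals * u
            if fast:
                g = GridDensity(u0.lower, u0.upper, ut, u0.space)
                mass_t = ut.sum() * dx
                gp = rescale_to_mass(g, 1.0) if mass_t > 0 else g
                if kernel.family == "additive":
                    praw = _grid_P_additive(gp, kernel).values
                else:
                    praw = _grid_P_multiplicative(gp, kernel).values
                birth = praw * (mass_t ** 2 / denom)
            else:
                g = GridDensity(u0.lower, u0.upper, ut, u0.space)
                K = _kernel_tensor(kernel, mids)
                birth = np.einsum("zij,i,j->z", K, ut, ut) * dx * dx / denom
        else:
            psi = _pair_weights(mids, u * dx, mating)
            K = _kernel_tensor(kernel, mids)
            W = np.outer(u, u) * dx * dx * psi
            birth = np.einsum("zij,ij->z", K, W)
        # death
        comp = Iv * (float(params.U) * M if U_const else (Umat @ u) * dx)
        death_rate = D + comp
        if dt * death_rate.max(initial=0.0) > 0.5:
            raise ValueError(
                f"dt = {dt} too large for max death rate "
                f"{death_rate.max():.3g} (CFL-style guard dt * rate <= 0.5)")
        u = u + dt * (birth - death_rate * u)
        if u.min(initial=0.0) < 0:
            if u.min() < -1e-12:
                raise ValueError(f"negative undershoot {u.min():.3g}; reduce dt")
            u = np.maximum(u, 0.0)
        if k % every == 0 or k == nsteps:
            times.append(k * dt)
            snaps.append(GridDensity(u0.lower, u0.upper, u.copy(), u0.space))
    return MacroTrajectory(np.array(times), snaps, meta={"dt": dt, "T": T})


_TENSOR_CACHE: dict = {}


def _kernel_tensor(kernel: OffspringKernel, mids: np.ndarray) -> np.ndarray:
    if mids.size > MAX_TENSOR_CELLS:
        raise ValueError(
            f"dense birth contraction limited to {MAX_TENSOR_CELLS} cells "
            f"(got {mids.size})")
    key = (id(kernel), mids.size, float(mids[0]), float(mids[-1]))
    if key not in _TENSOR_CACHE:
        K = np.asarray(kernel.density(mids[None, :, None], mids[None, None, :],
                                      mids[:, None, None]), dtype=float)
        _TENSOR_CACHE[key] = np.nan_to_num(K, nan=0.0)
        if len(_TENSOR_CACHE) > 8:
            _TENSOR_CACHE.pop(next(iter(_TENSOR_CACHE)))
    return _TENSOR_CACHE[key]


def attractor_rescale(trajectory: MacroTrajectory, params: MacroParams
                      ) -> MacroTrajectory:
    """Normalize every snapshot to a probability measure and rescale the clock
    by the constant per-capita birth rate, mapping constant-rate solutions of
    the full equation onto the normalized flow."""
    if not params.constant_mode:
        raise ValueError("attractor rescaling needs constant rates")
    p = params.effective_p()
    measures = []
    for m in trajectory.measures:
        if moment(m, 0) <= 0:
            raise ValueError("extinct trajectory cannot be normalized")
        measures.append(rescale_to_mass(m, 1.0))
    return MacroTrajectory(trajectory.times * p, measures,
                           meta={**trajectory.meta, "rescaled": True})
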