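"""Mating-rate models for hermaphroditic populations.

Five variants are implemented, each in a discrete (finite population) and an
infinitesimal (measure) form:

* ``semi_random`` -- partner choice proportional to a trait-dependent mating
  capability p(x); with self-fertilization the row sums equal p(x_i), without
  it the rate is symmetrized over the two "chooser" roles and the diagonal is
  zero.
* ``assortative_female`` -- the classical two-sex preference model: the rate is
  the preference a(x_i, x_j) normalized over the partners of the focal (female)
  individual, so every row sums to one; generally asymmetric.
* ``assortative_symmetric`` -- the hermaphroditic symmetrization: the mean of
  the two female-reference rates.
* ``assortative_normalized`` -- a symmetric rate (c_i + c_j) a(x_i, x_j) with
  coefficients chosen so that every row sums to one; the coefficients solve a
  diagonally dominant linear system (discrete) or a Fredholm integral equation
  of the second kind (measure form).
* ``general_cumulative`` -- the same construction applied to the cumulative
  preference a(x, y) p(x) p(y), with row sums p(x_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .measures import GridDensity, MeasureLike, TraitSpace, grid_to_atoms

VARIANTS = ("semi_random", "assortative_female", "assortative_symmetric",
            "assortative_normalized", "general_cumulative")

RESIDUAL_TOL = 1e-8


def _eval1(f, x):
    out = f(np.asarray(x, dtype=float)) if callable(f) else f
    return np.asarray(out, dtype=float) + np.zeros_like(np.asarray(x, dtype=float))


def _eval2(f, x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = f(x, y) if callable(f) else f
    return np.asarray(out, dtype=float) + np.zeros(np.broadcast(x, y).shape)


@dataclass
class MatingModel:
    """Tagged mating-rate specification.

    p and a may be constants or vectorized callables; p is the mating
    capability (semi-random / cumulative variants), a the symmetric preference
    function (assortative variants).
    """

    variant: str = "semi_random"
    p: object = 1.0
    a: object = 1.0
    selfing: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    def p_at(self, x):
        return _eval1(self.p, x)

    def a_at(self, x, y):
        return _eval2(self.a, x, y)

    def validate(self, space: TraitSpace, nsamples: int = 64,
                 seed: int = 0) -> None:
        """Sampled check of the standing bounds: 0 < a on F, p bounded and
        positive, a symmetric."""
        rng = np.random.default_rng(seed)
        lo = space.lower if np.isfinite(space.lower) else -10.0
        hi = space.upper if np.isfinite(space.upper) else 10.0
        xs = rng.uniform(lo, hi, nsamples)
        ys = rng.uniform(lo, hi, nsamples)
        pv = self.p_at(xs)
        if np.any(pv <= 0) or not np.all(np.isfinite(pv)):
            raise ValueError("p(x) must be positive and finite on the trait space")
        av = self.a_at(xs, ys)
        if np.any(av <= 0) or not np.all(np.isfinite(av)):
            raise ValueError("a(x,y) must be positive and finite on the trait space")
        if np.max(np.abs(av - self.a_at(ys, xs))) > 1e-10 * max(1.0, np.max(np.abs(av))):
            raise ValueError("preference function a(x,y) must be symmetric")


# built-in preference shapes ------------------------------------------------

def gaussian_pref(scale: float = 1.0) -> Callable:
    """a(x, y) = exp(-(x-y)^2 / scale^2)."""
    s2 = float(scale) ** 2
    return lambda x, y: np.exp(-((np.asarray(x) - np.asarray(y)) ** 2) / s2)


def triangular_pref(scale: float = 1.0, eps: float = 1e-3) -> Callable:
    """a(x, y) = max(0, 1 - |x-y| / scale) + eps (eps keeps a > 0)."""
    s = float(scale)
    return lambda x, y: np.maximum(0.0, 1.0 - np.abs(np.asarray(x) - np.asarray(y)) / s) + eps


@dataclass
class NormalizationCoeffs:
    """Normalization coefficients c for the row-sum-one symmetric rate.

    ``values`` are the coefficients at the nodes (atoms or grid midpoints),
    ``nodes`` the corresponding trait values, ``residual`` the max-norm defect
    of the defining linear / Fredholm system.
    """

    values: np.ndarray
    nodes: np.ndarray
    residual: float

    def __call__(self, x):
        """Piecewise-linear interpolation of c between the nodes."""
        order = np.argsort(self.nodes)
        return np.interp(np.asarray(x, dtype=float),
                         self.nodes[order], self.values[order])


# discrete rates ------------------------------------------------------------

def rate_matrix(traits: Sequence[float], model: MatingModel) -> np.ndarray:
    """Full n x n matrix of pairwise mating rates m(x_i, x_j; x)."""
    x = np.asarray(traits, dtype=float)
    n = x.size
    if n == 0:
        return np.zeros((0, 0))
    if model.variant == "semi_random":
        p = _eval1(model.p, x)
        S = p.sum()
        if model.selfing:
            return np.outer(p, p) / S
        if n < 2:
            raise ValueError("a non-selfing population of size 1 has no partner")
        g = 1.0 / (S - p)  # 1 / sum_{l != i} p_l
        M = 0.5 * np.outer(p, p) * (g[:, None] + g[None, :])
        np.fill_diagonal(M, 0.0)
        return M
    A = _eval2(model.a, x[:, None], x[None, :])
    if model.variant == "assortative_female":
        return A / A.sum(axis=1, keepdims=True)
    if model.variant == "assortative_symmetric":
        if model.selfing:
            R = A.sum(axis=1)
            M = 0.5 * A * (1.0 / R[:, None] + 1.0 / R[None, :])
            return M
        if n < 3:
            raise ValueError("the non-selfing symmetric assortative rate drops "
                             "two terms from each denominator and needs n >= 3")
        # drop the l=i and l=j terms from both denominators; zero diagonal
        R = A.sum(axis=1)
        diag = np.diag(A)
        # denominator of the x_i-referenced term for the pair (i, j)
        D1 = R[:, None] - diag[:, None] - A
        D2 = D1.T
        with np.errstate(divide="ignore"):
            M = 0.5 * A * (1.0 / D1 + 1.0 / D2)
        np.fill_diagonal(M, 0.0)
        return M
    if model.variant == "assortative_normalized":
        coeffs = solve_normalization(x, model.a)
        c = coeffs.values
        return (c[:, None] + c[None, :]) * A
    if model.variant == "general_cumulative":
        p = _eval1(model.p, x)
        Abar = A * np.outer(p, p)
        coeffs = solve_normalization(x, lambda u, v: _eval2(model.a, u, v)
                                     * _eval1(model.p, u) * _eval1(model.p, v),
                                     row_target=p)
        c = coeffs.values
        return (c[:, None] + c[None, :]) * Abar
    raise ValueError(f"unknown variant {model.variant!r}")


def discrete_rate(i: int, j: int, traits: Sequence[float],
                  model: MatingModel) -> float:
    """Pairwise mating rate m(x_i, x_j; x) for 0-based indices i, j."""
    n = len(traits)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"indices ({i}, {j}) out of range for n={n}")
    return float(rate_matrix(traits, model)[i, j])


def rate_row_sum(i: int, traits: Sequence[float], model: MatingModel) -> float:
    """Total mating rate of individual i: sum_j m(x_i, x_j; x)."""
    n = len(traits)
    if not 0 <= i < n:
        raise IndexError(f"index {i} out of range for n={n}")
    return float(rate_matrix(traits, model)[i].sum())


def solve_normalization(traits: Sequence[float], a,
                        row_target=None) -> NormalizationCoeffs:
    """Coefficients c_1..c_n with sum_j (c_i + c_j) a(x_i, x_j) = target_i.

    The system  sum_j b_ij c_j = target_i  with b_ij = a_ij (i != j) and
    b_ii = a_ii + sum_l a_il has positive entries and a dominant diagonal, so
    it has a unique positive solution (dense direct solve).  The default
    target is 1 (unit row sums).
    """
    x = np.asarray(traits, dtype=float)
    n = x.size
    if n < 1:
        raise ValueError("need at least one individual")
    A = _eval2(a, x[:, None], x[None, :])
    if np.any(A <= 0):
        raise ValueError("preference must be positive on all pairs")
    B = A.copy()
    np.fill_diagonal(B, np.diag(A) + A.sum(axis=1))
    rhs = np.ones(n) if row_target is None else np.asarray(row_target, dtype=float)
    try:
        c = np.linalg.solve(B, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by positivity
        raise RuntimeError(
            f"normalization solve failed (cond ~ {np.linalg.cond(B):.3g})") from exc
    residual = float(np.max(np.abs(B @ c - rhs)))
    if residual > RESIDUAL_TOL:
        raise RuntimeError(
            f"normalization residual {residual:.3g} exceeds {RESIDUAL_TOL} "
            f"(cond ~ {np.linalg.cond(B):.3g})")
    if np.any(c <= 0):
        raise RuntimeError("normalization solution not positive; "
                           "check the preference function")
    return NormalizationCoeffs(values=c, nodes=x, residual=residual)


# infinitesimal (measure-form) rates ----------------------------------------

def _measure_nodes(mu: MeasureLike) -> tuple:
    if isinstance(mu, GridDensity):
        mu = grid_to_atoms(mu)
    return mu.locations, mu.weights


def integrate_against(mu: MeasureLike, fn: Callable) -> float:
    x, w = _measure_nodes(mu)
    return float(_eval1(fn, x) @ w)


def infinitesimal_rate(x, y, mu: MeasureLike, model: MatingModel,
                       coeffs: Optional[NormalizationCoeffs] = None) -> float:
    """Measure-form mating rate m(x, y; mu)."""
    locs, w = _measure_nodes(mu)
    mass = w.sum()
    if mass <= 0:
        raise ValueError("mating rate undefined for a zero-mass measure")
    if model.variant == "semi_random":
        denom = float(_eval1(model.p, locs) @ w)
        return float(_eval1(model.p, x) * _eval1(model.p, y) / denom)
    if model.variant == "assortative_female":
        denom = float(_eval2(model.a, x, locs) @ w)
        return float(_eval2(model.a, x, y) / denom)
    if model.variant == "assortative_symmetric":
        dx = float(_eval2(model.a, x, locs) @ w)
        dy = float(_eval2(model.a, y, locs) @ w)
        axy = float(_eval2(model.a, x, y))
        return 0.5 * axy / dx + 0.5 * axy / dy
    if model.variant in ("assortative_normalized", "general_cumulative"):
        if coeffs is None:
            raise ValueError(f"variant {model.variant!r} needs NormalizationCoeffs "
                             f"(see solve_fredholm_c)")
        m = (coeffs(x) + coeffs(y)) * float(_eval2(model.a, x, y))
        if model.variant == "general_cumulative":
            m *= float(_eval1(model.p, x) * _eval1(model.p, y))
        return float(m)
    raise ValueError(f"unknown variant {model.variant!r}")


def solve_fredholm_c(mu: MeasureLike, model: MatingModel) -> NormalizationCoeffs:
    """Nystrom solution of the normalization Fredholm equation

        c(x) int a(x,y) p(y) mu(dy) + int c(y) a(x,y) p(y) mu(dy) = 1

    on the atoms of mu (grid densities are collapsed to midpoint masses).
    For the plain assortative_normalized variant p = 1.
    """
    locs, w = _measure_nodes(mu)
    n = locs.size
    if n < 1:
        raise ValueError("measure has no support")
    use_p = model.variant == "general_cumulative"
    p = _eval1(model.p, locs) if use_p else np.ones(n)
    A = _eval2(model.a, locs[:, None], locs[None, :])
    W = A * (p * w)[None, :]               # W_ij = a_ij p_j w_j
    M = W + np.diag(W.sum(axis=1))
    rhs = np.ones(n)
    c = np.linalg.solve(M, rhs)
    residual = float(np.max(np.abs(M @ c - rhs)))
    if residual > RESIDUAL_TOL:
        raise RuntimeError(
            f"Fredholm residual {residual:.3g} exceeds {RESIDUAL_TOL} "
            f"(cond ~ {np.linalg.cond(M):.3g})")
    return NormalizationCoeffs(values=c, nodes=locs, residual=residual)
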