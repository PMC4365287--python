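"""Finite measures on a one-dimensional trait space.

Populations and their deterministic limits are represented either as finite
collections of weighted atoms (:class:`AtomicMeasure`) or as nonnegative
densities on a uniform grid (:class:`GridDensity`).  Both expose cumulative
distribution functions, raw moments and exact mass bookkeeping, and the
one-dimensional Wasserstein (Kantorovich--Rubinstein) distance between two
probability measures is computed as the L1 norm of the difference of their
CDFs,

    d(mu, nu) = integral over F of |Phi_mu(x) - Phi_nu(x)| dx,

evaluated exactly on the union of atom positions and cell edges (the CDF
difference is piecewise linear there, so no sampling is involved).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

#: tolerance on |mass - 1| below which a measure is accepted as a probability
#: measure by :func:`wasserstein` (float drift from the solvers).
PROBABILITY_MASS_TOL = 1e-8

#: boundary cells of a grid carrying more relative mass than this trigger a
#: truncation warning (visible grid truncation of an unbounded trait space).
BOUNDARY_MASS_WARN = 1e-6


@dataclass(frozen=True)
class TraitSpace:
    """Closed convex trait interval F, possibly unbounded on either side."""

    lower: float = -math.inf
    upper: float = math.inf
    dimension: int = 1

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper}]")
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.lower) & (x <= self.upper)

    @property
    def bounded(self) -> bool:
        return math.isfinite(self.lower) and math.isfinite(self.upper)


REAL_LINE = TraitSpace(-math.inf, math.inf)
HALF_LINE = TraitSpace(0.0, math.inf)


@dataclass
class AtomicMeasure:
    """Finite positive measure given as weighted atoms on a trait space."""

    locations: np.ndarray
    weights: np.ndarray
    space: TraitSpace = REAL_LINE

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.locations.shape != self.weights.shape:
            raise ValueError("locations and weights must have the same length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.all(self.space.contains(self.locations)):
            raise ValueError("atom locations must lie in the trait space")

    @property
    def mass(self) -> float:
        return float(self.weights.sum())

    @property
    def mean(self) -> float:
        m = self.mass
        if m == 0:
            raise ValueError("empty measure has no mean")
        return float(self.locations @ self.weights / m)

    def sorted(self) -> "AtomicMeasure":
        order = np.argsort(self.locations, kind="stable")
        return AtomicMeasure(self.locations[order], self.weights[order], self.space)

    @staticmethod
    def from_traits(traits: Sequence[float], space: TraitSpace = REAL_LINE,
                    weight: float = 1.0) -> "AtomicMeasure":
        """Empirical measure sum of weight * delta_{x_i} over a trait multiset."""
        traits = np.asarray(traits, dtype=float)
        return AtomicMeasure(traits, np.full(traits.shape, weight), space)


@dataclass
class GridDensity:
    """Nonnegative density sampled at midpoints of a uniform 1-D grid.

    Cells are half open, [lower + i*dx, lower + (i+1)*dx), and the density is
    read as piecewise constant on the cells, so mass = sum(values) * dx holds
    exactly and the CDF is piecewise linear.
    """

    lower: float
    upper: float
    values: np.ndarray
    space: TraitSpace = REAL_LINE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")
        if self.values.size < 1:
            raise ValueError("grid needs at least one cell")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")
        if self.lower < self.space.lower - 1e-12 or self.upper > self.space.upper + 1e-12:
            raise ValueError("grid must lie inside the trait space")
        self._warn_boundary_mass()

    def _warn_boundary_mass(self) -> None:
        m = self.mass
        if m <= 0 or self.values.size < 3:
            return
        # only a truncation concern where the trait space extends past the grid
        edge = 0.0
        if self.lower > self.space.lower + 1e-12:
            edge += self.values[0] * self.cellwidth
        if self.upper < self.space.upper - 1e-12:
            edge += self.values[-1] * self.cellwidth
        if edge > BOUNDARY_MASS_WARN * m:
            logger.warning(
                "grid [%g, %g] carries %.3g of its mass in the boundary cells; "
                "consider a wider grid", self.lower, self.upper, edge / m)

    @property
    def ncells(self) -> int:
        return self.values.size

    @property
    def cellwidth(self) -> float:
        return (self.upper - self.lower) / self.values.size

    @property
    def midpoints(self) -> np.ndarray:
        dx = self.cellwidth
        return self.lower + (np.arange(self.values.size) + 0.5) * dx

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.values.size + 1)

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.cellwidth)

    @property
    def mean(self) -> float:
        m = self.mass
        if m == 0:
            raise ValueError("empty measure has no mean")
        return float((self.midpoints @ self.values) * self.cellwidth / m)

    @staticmethod
    def from_function(fn, lower: float, upper: float, ncells: int,
                      space: TraitSpace = REAL_LINE, normalize: bool = False
                      ) -> "GridDensity":
        dx = (upper - lower) / ncells
        mids = lower + (np.arange(ncells) + 0.5) * dx
        vals = np.maximum(np.asarray(fn(mids), dtype=float), 0.0)
        g = GridDensity(lower, upper, vals, space)
        if normalize:
            g = rescale_to_mass(g, 1.0)
        return g


MeasureLike = Union[AtomicMeasure, GridDensity]


def cdf_eval(mu: MeasureLike, z) -> np.ndarray:
    """Right-continuous CDF of a finite measure, evaluated at z (scalar or array)."""
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    if isinstance(mu, AtomicMeasure):
        if mu.locations.size == 0:
            out = np.zeros_like(z)
        else:
            srt = mu.sorted()
            cum = np.concatenate([[0.0], np.cumsum(srt.weights)])
            idx = np.searchsorted(srt.locations, z, side="right")
            out = cum[idx]
    elif isinstance(mu, GridDensity):
        cum = np.concatenate([[0.0], np.cumsum(mu.values) * mu.cellwidth])
        dx = mu.cellwidth
        pos = np.clip((z - mu.lower) / dx, 0.0, mu.ncells)
        i = np.minimum(pos.astype(int), mu.ncells - 1)
        frac = pos - i
        out = cum[i] + frac * mu.values[i] * dx
        out[z < mu.lower] = 0.0
        out[z >= mu.upper] = cum[-1]
    else:
        raise TypeError(f"unsupported measure type {type(mu)!r}")
    return float(out[0]) if scalar else out


def moment(mu: MeasureLike, order: int, absolute: bool = False) -> float:
    """Unnormalized raw moment  integral of z^order (or |z|^order) d mu."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if isinstance(mu, AtomicMeasure):
        x, w = mu.locations, mu.weights
        dx = 1.0
    elif isinstance(mu, GridDensity):
        x, w = mu.midpoints, mu.values
        dx = mu.cellwidth
    else:
        raise TypeError(f"unsupported measure type {type(mu)!r}")
    if order == 0:
        return float(w.sum() * dx)
    zk = np.abs(x) ** order if absolute else x ** float(order)
    return float((zk @ w) * dx)


def variance(mu: MeasureLike) -> float:
    """Variance of the normalized measure."""
    m = moment(mu, 0)
    if m <= 0:
        raise ValueError("variance of an empty measure is undefined")
    m1 = moment(mu, 1) / m
    return moment(mu, 2) / m - m1 * m1


def rescale_to_mass(mu: MeasureLike, target_mass: float) -> MeasureLike:
    """Scale the weights/values so the total mass equals target_mass."""
    if target_mass <= 0:
        raise ValueError("target mass must be positive")
    m = moment(mu, 0)
    if m <= 0:
        raise ValueError("cannot rescale a zero-mass (extinct) measure")
    c = target_mass / m
    if isinstance(mu, AtomicMeasure):
        return AtomicMeasure(mu.locations.copy(), mu.weights * c, mu.space)
    return GridDensity(mu.lower, mu.upper, mu.values * c, mu.space)


def _breakpoints(mu: MeasureLike) -> np.ndarray:
    if isinstance(mu, AtomicMeasure):
        return np.unique(mu.locations)
    return mu.edges


def _segment_endpoint_cdfs(mu: MeasureLike, pts: np.ndarray) -> tuple:
    """CDF values just right of every segment start and just left of every
    segment end, for segments delimited by pts (which contain every breakpoint
    of mu).  Atomic CDFs are constant on open segments; grid CDFs are linear
    and continuous."""
    if isinstance(mu, AtomicMeasure):
        left = cdf_eval(mu, pts[:-1])
        return left, left
    return cdf_eval(mu, pts[:-1]), cdf_eval(mu, pts[1:])


def wasserstein(mu: MeasureLike, nu: MeasureLike) -> float:
    """1-D Wasserstein distance between two probability measures.

    Computed as the exact integral of |Phi_mu - Phi_nu| over the union of the
    breakpoints of both CDFs; between breakpoints the difference is linear.
    """
    m_mu, m_nu = moment(mu, 0), moment(nu, 0)
    if abs(m_mu - 1.0) > PROBABILITY_MASS_TOL or abs(m_nu - 1.0) > PROBABILITY_MASS_TOL:
        raise ValueError(
            f"wasserstein requires probability measures; masses are "
            f"{m_mu!r} and {m_nu!r}")
    pts = np.union1d(_breakpoints(mu), _breakpoints(nu))
    if pts.size < 2:
        return 0.0
    a0, a1 = _segment_endpoint_cdfs(mu, pts)
    b0, b1 = _segment_endpoint_cdfs(nu, pts)
    f0, f1 = a0 - b0, a1 - b1
    length = np.diff(pts)
    same = f0 * f1 >= 0.0
    seg = np.empty_like(length)
    seg[same] = 0.5 * (np.abs(f0[same]) + np.abs(f1[same])) * length[same]
    cross = ~same
    r = f0[cross] / (f0[cross] - f1[cross])
    seg[cross] = 0.5 * (np.abs(f0[cross]) * r
                        + np.abs(f1[cross]) * (1.0 - r)) * length[cross]
    return float(seg.sum())


def compress(mu: AtomicMeasure, lower: float, upper: float, ncells: int,
             linear: bool = False) -> AtomicMeasure:
    """Bin atoms onto a uniform grid of cell midpoints, conserving total mass.

    With ``linear=True`` each atom's weight is split between the two nearest
    midpoints (cloud-in-cell), which additionally conserves the first moment
    exactly; the default sums weights per half-open cell, which keeps the
    first moment within half a cellwidth per unit mass.
    """
    if ncells < 1:
        raise ValueError("ncells must be positive")
    x, w = mu.locations, mu.weights
    outside = (x < lower) | (x > upper)
    if np.any(outside):
        raise ValueError(f"atoms outside [{lower}, {upper}]: {x[outside][:10]}")
    dx = (upper - lower) / ncells
    mids = lower + (np.arange(ncells) + 0.5) * dx
    acc = np.zeros(ncells)
    if linear:
        pos = (x - lower) / dx - 0.5  # fractional midpoint index
        i0 = np.clip(np.floor(pos).astype(int), 0, ncells - 1)
        i1 = np.clip(i0 + 1, 0, ncells - 1)
        frac = np.clip(pos - i0, 0.0, 1.0)
        # atoms beyond the outermost midpoints keep all mass on that midpoint
        frac[pos < 0] = 0.0
        frac[pos > ncells - 1] = 1.0
        np.add.at(acc, i0, w * (1.0 - frac))
        np.add.at(acc, i1, w * frac)
    else:
        idx = np.minimum(((x - lower) / dx).astype(int), ncells - 1)
        np.add.at(acc, idx, w)
    keep = acc > 0
    return AtomicMeasure(mids[keep], acc[keep], mu.space)


def atomic_to_grid(mu: AtomicMeasure, lower: float, upper: float,
                   ncells: int) -> GridDensity:
    """Cloud-in-cell deposit of an atomic measure as a grid density
    (mass and mean conserving up to the edge cells)."""
    binned = compress(mu, lower, upper, ncells, linear=True)
    dx = (upper - lower) / ncells
    vals = np.zeros(ncells)
    idx = np.rint((binned.locations - lower) / dx - 0.5).astype(int)
    vals[idx] = binned.weights / dx
    return GridDensity(lower, upper, vals, mu.space)


def grid_to_atoms(g: GridDensity) -> AtomicMeasure:
    """Midpoint point-mass representation of a grid density."""
    return AtomicMeasure(g.midpoints, g.values * g.cellwidth, g.space)


# --------------------------------------------------------------------------
# TSV serialization: `location\tweight` (atomic) or `z\tdensity` (grid) with a
# `# mass=<float> mean=<float>` header; floats written with repr so a
# write-then-read round trip is bit exact.

def write_measure(mu: MeasureLike, path) -> None:
    with open(path, "w") as fh:
        mass = moment(mu, 0)
        mean = moment(mu, 1) / mass if mass > 0 else math.nan
        fh.write(f"# mass={mass!r} mean={mean!r}\n")
        if isinstance(mu, AtomicMeasure):
            fh.write("location\tweight\n")
            for x, w in zip(mu.locations, mu.weights):
                fh.write(f"{float(x)!r}\t{float(w)!r}\n")
        else:
            fh.write(f"# grid lower={float(mu.lower)!r} upper={float(mu.upper)!r} "
                     f"ncells={mu.ncells}\n")
            fh.write("z\tdensity\n")
            for x, v in zip(mu.midpoints, mu.values):
                fh.write(f"{float(x)!r}\t{float(v)!r}\n")


def read_measure(path, space: TraitSpace = REAL_LINE) -> MeasureLike:
    grid_meta = None
    rows = []
    kind = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# grid "):
                parts = dict(tok.split("=") for tok in line[7:].split())
                grid_meta = (float(parts["lower"]), float(parts["upper"]),
                             int(parts["ncells"]))
            elif line.startswith("#"):
                continue
            elif line.startswith(("location", "z\t")):
                kind = "atomic" if line.startswith("location") else "grid"
            elif line:
                a, b = line.split("\t")
                rows.append((float(a), float(b)))
    if kind is None:
        raise ValueError(f"{path}: not a measure TSV")
    xs = np.array([r[0] for r in rows])
    ys = np.array([r[1] for r in rows])
    if kind == "atomic":
        return AtomicMeasure(xs, ys, space)
    lower, upper, ncells = grid_meta
    vals = np.zeros(ncells)
    dx = (upper - lower) / ncells
    idx = np.rint((xs - lower) / dx - 0.5).astype(int)
    vals[idx] = ys
    return GridDensity(lower, upper, vals, space)
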