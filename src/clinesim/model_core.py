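"""Model constants and the pure functions of the simulation model.

The simulated organism is diploid with ``n_loci`` unlinked bi-allelic
loci of equal additive effect ``alpha``; the phenotype is the allele-dose
sum, so with 64 loci and ``alpha = 1`` it ranges over 0–128.  Individuals
live on a cylinder (y wraps, x does not) and experience:

* logistic density regulation within a circle of radius
  ``density_radius`` holding at most ``K`` individuals,
* stabilizing selection of strength ``1/(2*V_S)`` toward the local
  optimum ``U(x)``,
* Gaussian dispersal (offspring movement of standard deviation ``D``)
  plus mate-search movement within the mating distance ``MD``.

The expected offspring number of a female with phenotype ``z`` at
position ``x`` and local density ``N`` is

    W_F = max(0, 2 + r_F*(1 - N/K) - s*(U(x) - z)**2),       s = 1/(2*V_S)

so that dispersing a distance ``sigma`` along a gradient of steepness
``b`` (an expected optimum shift of ``b*sigma``) costs exactly the
dispersal load ``b**2 sigma**2 / (2 V_S)`` in expected offspring.  The
mean growth rate of a local population with trait mean ``z_bar`` and
phenotypic variance ``V_P`` is

    r(N) = r_m*(1 - N/K) - (z_bar - U)**2/(2*V_S) - V_P/(2*V_S),  r_m = r_F/2

where the last term is the standing load contributed by variance around
a matched optimum.  Mate-search movement contributes to gene flow like a
dispersal step, so the total dispersal scale is
``TD = sqrt(D**2 + SM**2/2)`` with ``SM = MD/sqrt(2)``, and its
one-dimensional (along-gradient) projection is ``sigma = TD/sqrt(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .gradients import GradientSpec, optimum_at
from . import _kernels

__all__ = [
    "SimParams",
    "DispersalScales",
    "dispersal_scales",
    "d_from_td",
    "phenotype",
    "expected_offspring",
    "mean_growth_rate",
    "dispersal_load",
    "local_density",
    "density_counts",
    "cylinder_distance",
    "FEMALE",
    "MALE",
]

FEMALE = 0
MALE = 1


class DispersalScales(NamedTuple):
    """Derived dispersal scales: mate-search SM, total TD, 1-D sigma."""

    sm: float
    td: float
    sigma: float


def dispersal_scales(d: float, md: float) -> DispersalScales:
    """Dispersal algebra: ``SM = MD/sqrt2``, ``TD = sqrt(D^2 + SM^2/2)``,
    ``sigma = TD/sqrt2``."""
    if d < 0:
        raise ValueError("offspring dispersal D must be non-negative")
    if md <= 0:
        raise ValueError("mating distance MD must be positive")
    sm = md / math.sqrt(2.0)
    td = math.sqrt(d * d + 0.5 * sm * sm)
    return DispersalScales(sm=sm, td=td, sigma=td / math.sqrt(2.0))


def d_from_td(td: float, md: float) -> float:
    """Offspring dispersal ``D`` that yields a target total dispersal ``TD``.

    Raises if ``TD**2 < SM**2/2``: mate-search movement alone already
    exceeds the requested total, so no non-negative ``D`` can reach it.
    """
    sm = md / math.sqrt(2.0)
    d2 = td * td - 0.5 * sm * sm
    if -1e-9 * max(td * td, 1.0) < d2 < 0.0:  # clamp floating round-off at the floor
        d2 = 0.0
    if d2 < 0:
        raise ValueError(
            f"target TD={td} unreachable with MD={md}: TD must be at least {math.sqrt(0.5) * sm:.4f}"
        )
    return math.sqrt(d2)


@dataclass(frozen=True)
class SimParams:
    """Demographic and genetic constants of a run.

    ``r_m = r_f/2`` and ``s = 1/(2*v_s)`` are derived, never set.  Either
    ``d`` (offspring dispersal s.d.) or ``td`` (target total dispersal)
    may be given; ``td`` is converted through :func:`d_from_td`.
    """

    r_f: float = 1.6
    k: float = 25.0
    v_s: float = 4.0
    mu: float = 1.0e-4
    n_loci: int = 64
    alpha: float = 1.0
    md: float = 150.0
    d: float | None = None
    td: float | None = None
    density_radius: float = 50.0
    habitat_x: float = 32000.0
    habitat_y: float = 1000.0
    include_focal: bool = True
    x_boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.d is None and self.td is None:
            object.__setattr__(self, "td", 500.0)
        if self.d is None:
            object.__setattr__(self, "d", d_from_td(self.td, self.md))
        else:
            if self.td is not None and not math.isclose(
                self.td, dispersal_scales(self.d, self.md).td, rel_tol=1e-9
            ):
                raise ValueError("give either d or td, not inconsistent values of both")
            object.__setattr__(self, "td", dispersal_scales(self.d, self.md).td)
        for name in ("r_f", "k", "v_s", "alpha", "md", "density_radius", "habitat_x", "habitat_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mutation rate mu must lie in [0, 1]")
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.d < 0:
            raise ValueError("dispersal D must be non-negative")
        if self.x_boundary not in ("reflect", "absorb"):
            raise ValueError("x_boundary must be 'reflect' or 'absorb'")

    # -- derived quantities -------------------------------------------------
    @property
    def r_m(self) -> float:
        """Maximum rate of increase, ``r_F/2``."""
        return 0.5 * self.r_f

    @property
    def s(self) -> float:
        """Selection curvature, ``1/(2*V_S)``."""
        return 1.0 / (2.0 * self.v_s)

    @property
    def scales(self) -> DispersalScales:
        return dispersal_scales(self.d, self.md)

    @property
    def sm(self) -> float:
        return self.scales.sm

    @property
    def sigma(self) -> float:
        """One-dimensional projection of total dispersal, ``TD/sqrt2``."""
        return self.scales.sigma

    @property
    def z_max(self) -> float:
        """Largest attainable phenotype, ``2*alpha*n_loci``."""
        return 2.0 * self.alpha * self.n_loci

    def with_td(self, td: float) -> "SimParams":
        return replace(self, d=None, td=td)


def phenotype(genome: np.ndarray, alpha: float = 1.0):
    """Additive phenotype ``z = alpha * (sum of allele doses)``.

    ``genome`` has shape ``(..., n_loci, 2)`` with entries in {0, 1};
    leading axes are preserved (a stack of genomes gives a vector of z).
    """
    g = np.asarray(genome)
    return alpha * g.sum(axis=(-1, -2))


def expected_offspring(z, x, n_local, params: SimParams, spec: GradientSpec):
    """Poisson mean offspring number ``W_F`` (truncated at zero).

    ``W_F = max(0, 2 + r_F*(1 - N/K) - s*(U(x) - z)**2)`` with
    ``s = 1/(2*V_S)``: a replacement-level baseline of two offspring,
    logistic density regulation, and quadratic stabilizing selection
    toward the local optimum.  The selection term is calibrated so the
    per-generation fitness cost of dispersing a distance ``sigma`` along
    a gradient of steepness ``b`` is ``b^2 sigma^2/(2 V_S)``.  On
    nonlinear gradients the linear optimum ``b*x`` generalizes to
    ``U(x)``; fitness is otherwise unchanged.  Truncation applies to the
    mean, before Poisson sampling.
    """
    u = optimum_at(x, spec)
    w = 2.0 + params.r_f * (1.0 - np.asarray(n_local) / params.k) - params.s * (u - np.asarray(z)) ** 2
    return np.maximum(0.0, w)


def mean_growth_rate(z_bar, v_p, u, n, params: SimParams):
    """Population mean growth rate.

    ``r = r_m*(1 - N/K) - (z_bar - U)^2/(2 V_S) - V_P/(2 V_S)``; the last
    two terms are the maladaptation load and the standing load.
    """
    v_p = np.asarray(v_p, dtype=float)
    if np.any(v_p < 0):
        raise ValueError("phenotypic variance V_P must be non-negative")
    two_vs = 2.0 * params.v_s
    return params.r_m * (1.0 - np.asarray(n) / params.k) - (np.asarray(z_bar) - u) ** 2 / two_vs - v_p / two_vs


def dispersal_load(b: float, sigma: float, v_s: float) -> float:
    """Fitness decrement from dispersing a distance ``sigma`` along a
    gradient of steepness ``b``: ``b^2 sigma^2 / (2 V_S)``."""
    return b * b * sigma * sigma / (2.0 * v_s)


def cylinder_distance(p, q, habitat_y: float) -> np.ndarray:
    """Distance on the cylinder: y uses the minimum image, x does not wrap."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    dx = p[:, 0, None] - q[None, :, 0]
    dy = np.abs(p[:, 1, None] - q[None, :, 1])
    dy = np.minimum(dy, habitat_y - dy)
    return np.sqrt(dx * dx + dy * dy)


def local_density(
    positions,
    focal,
    radius: float = 50.0,
    include_focal: bool = True,
    habitat_y: float = 1000.0,
) -> int:
    """Number of individuals within ``radius`` of a focal individual.

    ``focal`` is either an integer index into ``positions`` (the focal
    individual is then counted iff ``include_focal``) or an arbitrary
    (x, y) point, in which case all individuals within the circle are
    counted.  Distances are cylinder distances (y wraps).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if isinstance(focal, (int, np.integer)):
        centre = pos[int(focal)]
        dist = cylinder_distance(centre, pos, habitat_y)[0]
        n = int(np.count_nonzero(dist <= radius))
        return n if include_focal else n - 1
    centre = np.asarray(focal, dtype=float)
    dist = cylinder_distance(centre, pos, habitat_y)[0]
    return int(np.count_nonzero(dist <= radius))


def density_counts(
    x: np.ndarray,
    y: np.ndarray,
    habitat_x: float,
    habitat_y: float,
    radius: float = 50.0,
    include_focal: bool = True,
) -> np.ndarray:
    """Local density of every individual at once (exact circle counts).

    Uses a uniform-grid neighborhood search; results are identical to an
    all-pairs count with the cylinder metric.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.size == 0:
        return np.zeros(0, dtype=np.int64)
    ncx, ncy, cwx, cwy = _kernels.grid_layout(habitat_x, habitat_y, radius)
    order, starts = _kernels.build_grid(x, y, ncx, ncy, cwx, cwy)
    self_member = np.ones(x.size, dtype=np.bool_)
    return _kernels.count_within(
        x, y, self_member, x, y, order, starts,
        ncx, ncy, cwx, cwy, float(radius), float(habitat_y), bool(include_focal),
    )
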