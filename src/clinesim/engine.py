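"""Discrete-generation life cycle and full simulation runs.

One generation consists of, for every female in the current population:
mate choice among the males within the mating distance (weighted by each
male's expected-offspring fitness at its own position and local
density), a Poisson number of offspring with mean equal to the female's
own expected-offspring fitness, Mendelian transmission with symmetric
mutation on the transmitted gametes, and Gaussian dispersal of the
offspring from the mother's position.  Generations are non-overlapping:
the next generation consists only of the offspring.

Positions are continuous.  The habitat is a cylinder: y wraps, while the
x boundary either reflects (default) or absorbs.  A run is fully
reproducible from its configuration and seed; all randomness flows from
one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .gradients import GradientSpec
from .model_core import FEMALE, MALE, SimParams, density_counts, expected_offspring, phenotype

if TYPE_CHECKING:  # pragma: no cover
    from .cli_io import RunConfig

__all__ = [
    "Individual",
    "Population",
    "RunHistory",
    "choose_mate",
    "make_offspring",
    "disperse",
    "step",
    "run",
]


@dataclass
class Individual:
    """A single diploid individual with a continuous 2-D position."""

    x: float
    y: float
    sex: int
    genome: np.ndarray  # (n_loci, 2) allele matrix of 0/1


@dataclass
class Population:
    """A generation-indexed collection of individuals (struct-of-arrays)."""

    generation: int
    x: np.ndarray
    y: np.ndarray
    sex: np.ndarray
    genomes: np.ndarray  # (n, n_loci, 2) uint8

    @classmethod
    def empty(cls, generation: int, n_loci: int) -> "Population":
        return cls(
            generation=generation,
            x=np.zeros(0),
            y=np.zeros(0),
            sex=np.zeros(0, dtype=np.uint8),
            genomes=np.zeros((0, n_loci, 2), dtype=np.uint8),
        )

    @property
    def size(self) -> int:
        return int(self.x.size)

    def phenotypes(self, alpha: float = 1.0) -> np.ndarray:
        return phenotype(self.genomes, alpha)

    def individual(self, i: int) -> Individual:
        return Individual(float(self.x[i]), float(self.y[i]), int(self.sex[i]), self.genomes[i].copy())


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def choose_mate(
    female: int,
    pop: Population,
    params: SimParams,
    spec: GradientSpec,
    rng: np.random.Generator,
) -> Optional[int]:
    """Pick a mate for one female; returns a population index or ``None``.

    Candidates are the males within the mating distance MD (cylinder
    metric); each is chosen with probability proportional to its
    expected-offspring fitness evaluated at its own phenotype, position
    and local density.  ``None`` when no male is in range or every
    candidate has zero fitness — the female then leaves no offspring.
    """
    dens = density_counts(
        pop.x, pop.y, params.habitat_x, params.habitat_y,
        params.density_radius, params.include_focal,
    )
    w = expected_offspring(pop.phenotypes(params.alpha), pop.x, dens, params, spec)
    dx = pop.x - pop.x[female]
    dy = np.abs(pop.y - pop.y[female])
    dy = np.minimum(dy, params.habitat_y - dy)
    in_range = (dx * dx + dy * dy <= params.md**2) & (pop.sex == MALE)
    cand = np.flatnonzero(in_range)
    if cand.size == 0:
        return None
    weights = w[cand]
    total = weights.sum()
    if total <= 0:
        return None
    return int(rng.choice(cand, p=weights / total))


def make_offspring(
    mother: Individual,
    father: Individual,
    params: SimParams,
    rng: np.random.Generator,
) -> Individual:
    """Mendelian transmission with symmetric mutation at rate ``mu``.

    At each unlinked locus one uniformly random allele copy is drawn
    from each parent; each transmitted allele flips with probability
    ``mu`` (mutation acts on gametes only).  Sex is Bernoulli(1/2) and
    the offspring starts at the mother's position, before dispersal.
    """
    loci = np.arange(params.n_loci)
    egg = mother.genome[loci, rng.integers(0, 2, params.n_loci)]
    sperm = father.genome[loci, rng.integers(0, 2, params.n_loci)]
    genome = np.stack((egg, sperm), axis=1).astype(np.uint8)
    if params.mu > 0:
        flips = rng.random((params.n_loci, 2)) < params.mu
        genome = genome ^ flips
    return Individual(
        x=mother.x, y=mother.y, sex=int(rng.integers(0, 2)), genome=genome.astype(np.uint8)
    )


def _fold_reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Reflect positions into [0, length] (triangular fold)."""
    x = np.mod(x, 2.0 * length)
    return np.where(x > length, 2.0 * length - x, x)


def _disperse_positions(x, y, params: SimParams, rng: np.random.Generator):
    """Displace positions by a signed N(0, D) distance in a uniform direction."""
    n = x.size
    r = rng.normal(0.0, params.d, n) if params.d > 0 else np.zeros(n)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    nx = x + r * np.cos(theta)
    ny = np.mod(y + r * np.sin(theta), params.habitat_y)
    if params.x_boundary == "reflect":
        nx = _fold_reflect(nx, params.habitat_x)
        keep = None
    else:  # absorb: individuals leaving the x extent are lost
        keep = (nx >= 0.0) & (nx <= params.habitat_x)
    return nx, ny, keep


def disperse(offspring: Individual, params: SimParams, rng: np.random.Generator) -> Individual:
    """Dispersal of a single offspring (y wraps; x per boundary policy).

    Under the absorbing policy an individual that leaves the habitat is
    returned with position ``nan`` to mark the loss.
    """
    nx, ny, keep = _disperse_positions(
        np.array([offspring.x]), np.array([offspring.y]), params, rng
    )
    if keep is not None and not keep[0]:
        return Individual(math.nan, math.nan, offspring.sex, offspring.genome)
    return Individual(float(nx[0]), float(ny[0]), offspring.sex, offspring.genome)


def _gametes(genomes: np.ndarray, parent_idx: np.ndarray, mu: float, rng: np.random.Generator):
    n = parent_idx.size
    n_loci = genomes.shape[1]
    bits = rng.integers(0, 2, size=(n, n_loci))
    g = genomes[parent_idx[:, None], np.arange(n_loci)[None, :], bits]
    if mu > 0:
        flips = rng.random((n, n_loci)) < mu
        g = g ^ flips
    return g.astype(np.uint8)


# ---------------------------------------------------------------------------
# one generation
# ---------------------------------------------------------------------------

def step(
    pop: Population,
    params: SimParams,
    spec: GradientSpec,
    rng: np.random.Generator,
) -> Population:
    """Advance the population one (non-overlapping) generation.

    Densities are evaluated once per individual from the parental
    generation; mate choice, Poisson reproduction, gamete transmission
    and offspring dispersal then follow.  All parents die.
    """
    gen = pop.generation + 1
    if pop.size == 0:
        return Population.empty(gen, params.n_loci)

    z = pop.phenotypes(params.alpha)
    dens = density_counts(
        pop.x, pop.y, params.habitat_x, params.habitat_y,
        params.density_radius, params.include_focal,
    )
    w = expected_offspring(z, pop.x, dens, params, spec)

    f_idx = np.flatnonzero(pop.sex == FEMALE)
    m_idx = np.flatnonzero(pop.sex == MALE)
    if f_idx.size == 0 or m_idx.size == 0:
        return Population.empty(gen, params.n_loci)

    u = rng.random(f_idx.size)
    mx = np.ascontiguousarray(pop.x[m_idx])
    my = np.ascontiguousarray(pop.y[m_idx])
    ncx, ncy, cwx, cwy = _kernels.grid_layout(params.habitat_x, params.habitat_y, params.md)
    order, starts = _kernels.build_grid(mx, my, ncx, ncy, cwx, cwy)
    mates_local = _kernels.pick_mates(
        np.ascontiguousarray(pop.x[f_idx]), np.ascontiguousarray(pop.y[f_idx]),
        mx, my, np.ascontiguousarray(w[m_idx]),
        order, starts, ncx, ncy, cwx, cwy,
        float(params.md), float(params.habitat_y), u,
    )
    mated = mates_local >= 0
    mothers = f_idx[mated]
    fathers = m_idx[mates_local[mated]]

    counts = rng.poisson(w[mothers])
    mothers = np.repeat(mothers, counts)
    fathers = np.repeat(fathers, counts)
    n_off = mothers.size
    if n_off == 0:
        return Population.empty(gen, params.n_loci)

    egg = _gametes(pop.genomes, mothers, params.mu, rng)
    sperm = _gametes(pop.genomes, fathers, params.mu, rng)
    genomes = np.stack((egg, sperm), axis=2)
    sex = rng.integers(0, 2, n_off).astype(np.uint8)
    nx, ny, keep = _disperse_positions(pop.x[mothers], pop.y[mothers], params, rng)
    if keep is not None:
        nx, ny, sex, genomes = nx[keep], ny[keep], sex[keep], genomes[keep]
    return Population(generation=gen, x=nx, y=ny, sex=sex, genomes=genomes)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

@dataclass
class RunHistory:
    """Per-generation summaries and snapshots of a completed run."""

    config: "RunConfig"
    seed: int
    generation: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    size: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    occupied_frac: np.ndarray = field(default_factory=lambda: np.zeros(0))
    x_lo: np.ndarray = field(default_factory=lambda: np.zeros(0))
    x_hi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    z_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    z_var: np.ndarray = field(default_factory=lambda: np.zeros(0))
    snapshots: dict[int, Population] = field(default_factory=dict)
    stopped: str = "completed"

    @property
    def final_generation(self) -> int:
        return int(self.generation[-1])

    @property
    def final_size(self) -> int:
        return int(self.size[-1])

    @property
    def final_population(self) -> Population:
        return self.snapshots[max(self.snapshots)]

    @property
    def min_occupied_frac(self) -> float:
        return float(self.occupied_frac.min())

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "size": self.size,
                "occupied_frac": self.occupied_frac,
                "x_lo": self.x_lo,
                "x_hi": self.x_hi,
                "z_mean": self.z_mean,
                "z_var": self.z_var,
            }
        )


def occupancy_min_count(params: SimParams, frac: float, slice_width: float = 100.0) -> int:
    """Minimum slice count for a slice to register as occupied.

    ``frac`` is a fraction of the count a slice holds at carrying
    capacity; single dispersing stragglers (which are strongly
    maladapted and leave no offspring) then do not register as range
    occupancy.  ``frac = 0`` recovers the literal >=1-individual rule.
    """
    at_k = params.k * slice_width * params.habitat_y / (math.pi * params.density_radius**2)
    return max(1, int(math.ceil(frac * at_k)))


def _adapted_escape(
    pop: Population,
    params: SimParams,
    spec: GradientSpec,
    window: tuple[float, float],
    min_count: int,
    slice_width: float = 100.0,
) -> bool:
    """Has the population spread past the window on both sides with
    phenotypic clines formed?  (Robustly occupied slices beyond each
    window edge whose trait means sit at least 8*alpha beyond the
    central optimum — transient maladapted dispersal tails cannot
    satisfy the trait condition.)"""
    from .gradients import optimum_at

    n_slices = max(1, int(round(params.habitat_x / slice_width)))
    idx = np.minimum((pop.x / slice_width).astype(int), n_slices - 1)
    counts = np.bincount(idx, minlength=n_slices)
    occ = counts >= min_count
    if not occ.any():
        return False
    z = pop.phenotypes(params.alpha)
    zmean = np.full(n_slices, np.nan)
    zmean[occ] = np.bincount(idx, weights=z, minlength=n_slices)[occ] / counts[occ]
    mids = (np.arange(n_slices) + 0.5) * slice_width
    u_c = float(optimum_at(0.5 * params.habitat_x, spec))
    span = 8.0 * params.alpha
    left = occ & (mids < window[0])
    right = occ & (mids > window[1])
    if not (left.any() and right.any()):
        return False
    return bool(np.nanmin(zmean[left]) <= u_c - span) and bool(
        np.nanmax(zmean[right]) >= u_c + span
    )


def _occupancy(pop: Population, habitat_x: float, min_count: int = 1, slice_width: float = 100.0):
    """(fraction of occupied slices, x-range of occupied slices)."""
    if pop.size == 0:
        return 0.0, math.nan, math.nan
    n_slices = max(1, int(round(habitat_x / slice_width)))
    idx = np.minimum((pop.x / slice_width).astype(int), n_slices - 1)
    occ = np.bincount(idx, minlength=n_slices) >= min_count
    if not occ.any():
        return 0.0, math.nan, math.nan
    where = np.flatnonzero(occ)
    return float(occ.mean()), float(where[0] * slice_width), float((where[-1] + 1) * slice_width)


def run(config: "RunConfig") -> RunHistory:
    """Run a full simulation from its configuration; see
    :class:`clinesim.cli_io.RunConfig` for the knobs.

    Records total size, occupied-slice fraction, occupied x-range and the
    mean/variance of the phenotype every generation, stores population
    snapshots at the configured cadence (the initial and final states are
    always kept) and stops early on extinction or on any configured
    early-stop condition (range collapse / spread beyond the
    classification window).
    """
    from .initializers import colonizing_start, perfect_start  # local import: no cycle

    config.validate()
    params, spec = config.params, config.gradient
    rng = np.random.default_rng(config.seed)
    if config.init_mode == "colonizing":
        pop = colonizing_start(params, spec, rng, n=config.n_colonizers)
    else:
        pop = perfect_start(params, spec, rng, cline_width_factor=config.cline_width_factor)

    hist = RunHistory(config=config, seed=config.seed)
    gens, sizes, occs, xlos, xhis, zms, zvs = [], [], [], [], [], [], []
    win = config.escape_window
    min_count = occupancy_min_count(params, config.occupancy_min_frac)

    def record(p: Population) -> float:
        occ, xlo, xhi = _occupancy(p, params.habitat_x, min_count)
        gens.append(p.generation)
        sizes.append(p.size)
        occs.append(occ)
        xlos.append(xlo)
        xhis.append(xhi)
        if p.size:
            z = p.phenotypes(params.alpha)
            zms.append(float(z.mean()))
            zvs.append(float(z.var()))
        else:
            zms.append(math.nan)
            zvs.append(math.nan)
        return occ

    record(pop)
    hist.snapshots[0] = pop
    for g in range(1, config.generations + 1):
        pop = step(pop, params, spec, rng)
        occ = record(pop)
        if config.snapshot_every and g % config.snapshot_every == 0:
            hist.snapshots[g] = pop
        if pop.size == 0:
            hist.stopped = "extinct"
            break
        if config.collapse_below is not None and occ < config.collapse_below:
            hist.stopped = "collapsed"
            break
        if (
            win is not None
            and xlos[-1] < win[0]
            and xhis[-1] > win[1]
            and _adapted_escape(pop, params, spec, win, min_count)
        ):
            hist.stopped = "escaped"
            break

    hist.snapshots[pop.generation] = pop
    hist.generation = np.asarray(gens, dtype=int)
    hist.size = np.asarray(sizes, dtype=int)
    hist.occupied_frac = np.asarray(occs)
    hist.x_lo = np.asarray(xlos)
    hist.x_hi = np.asarray(xhis)
    hist.z_mean = np.asarray(zms)
    hist.z_var = np.asarray(zvs)
    return hist
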