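"""Starting conditions: central colonization and whole-range perfect adaptation.

The colonizing start seeds 500 individuals into the central 500-unit
strip of the habitat with phenotypes scattered tightly around the
central optimum.  The perfect start fills the whole habitat at carrying
capacity with genotypes arranged in a staircase of allele-frequency
clines, so the slice-mean phenotype tracks the optimum everywhere from
generation zero.

The cline staircase is parameterized in optimum units rather than in
space: locus ``i`` (of 64) switches from 0 to 1 around the threshold
``u_i = alpha*(2*i + 1)``, following a logistic profile of width
``b*w_c`` in phenotype units, where ``w_c = sigma*sqrt(2*V_S)/alpha`` is
the dispersal/selection cline length-scale.  Because thresholds live in
optimum units, the construction adapts to any gradient shape: cline
spacing in space is ``2*alpha/b`` on linear limbs, clines compress where
a sigmoid gradient steepens, and no cline sits inside a flat portion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import Population
from .gradients import GradientSpec, optimum_at
from .model_core import SimParams

__all__ = ["ClineLayout", "colonizing_start", "perfect_start", "genomes_for_phenotypes"]


@dataclass(frozen=True)
class ClineLayout:
    """Per-locus thresholds (in optimum units) and the cline width scale.

    ``thresholds`` is strictly increasing with spacing ``2*alpha``;
    ``width_u = b*w_c`` is the logistic width in phenotype units (zero
    width degenerates to step clines, used when ``b = 0``).
    """

    thresholds: np.ndarray
    width_u: float

    @classmethod
    def default(
        cls, params: SimParams, spec: GradientSpec, cline_width_factor: float = 1.0
    ) -> "ClineLayout":
        thr = params.alpha * (2.0 * np.arange(params.n_loci) + 1.0)
        w_c = params.sigma * math.sqrt(2.0 * params.v_s) / params.alpha
        return cls(thresholds=thr, width_u=spec.b * w_c * cline_width_factor)

    @property
    def spacing(self) -> float:
        """Threshold spacing in optimum units (2*alpha)."""
        return float(self.thresholds[1] - self.thresholds[0]) if self.thresholds.size > 1 else 0.0

    def centre_positions(self, spec: GradientSpec) -> np.ndarray:
        """Spatial cline centres: the x where the optimum crosses each
        threshold (nan when the crossing lies outside the habitat)."""
        out = np.full(self.thresholds.size, np.nan)
        for i, u in enumerate(self.thresholds):
            if spec.kind == "linear":
                x = u / spec.b if spec.b > 0 else math.nan
            elif spec.kind == "sigmoid":
                x = spec.centre_x + np.cbrt((u - spec.sigmoid_offset) * spec.sigmoid_scale / spec.sigmoid_coef)
            else:
                uc = spec.b * spec.centre_x
                if spec.b == 0:
                    x = math.nan
                elif u >= uc:
                    x = spec.centre_x + 0.5 * spec.w + (u - uc) / spec.b
                else:
                    x = spec.centre_x - 0.5 * spec.w - (uc - u) / spec.b
            if not math.isnan(x) and 0.0 <= x <= spec.x_max:
                out[i] = x
        return out

    def allele_freq(self, u) -> np.ndarray:
        """Expected 1-allele frequency at optimum value(s) ``u``;
        shape ``(n_points, n_loci)``."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        delta = u[:, None] - self.thresholds[None, :]
        if self.width_u <= 0:
            return (delta > 0).astype(float)
        return 1.0 / (1.0 + np.exp(np.clip(-4.0 * delta / self.width_u, -60.0, 60.0)))

    def expected_mean(self, u) -> np.ndarray:
        """Expected phenotypic mean at optimum value(s) ``u`` (tracks u)."""
        return 2.0 * self.allele_freq(u).sum(axis=1)


def genomes_for_phenotypes(z: np.ndarray, n_loci: int) -> np.ndarray:
    """Genomes realizing integer allele-dose targets ``z`` (in units of
    alpha) by filling loci in a fixed ladder order: locus ``i`` carries
    dose 2 when ``z >= 2*(i+1)``, dose 1 when ``z = 2*i + 1``, else 0.

    Filling in a shared order keeps the founders' per-locus allele
    frequencies step-like (near fixation or loss except at the two or
    three ladder-boundary loci), as in a locally adapted source
    population, so the genic variance matches the constructed
    phenotypic variance.  Placing 1-alleles uniformly at random among
    the ``2*n_loci`` slots would instead hide a genic variance of
    ``2*n_loci*p*(1-p)`` (an order of magnitude larger) behind negative
    linkage disequilibrium that recombination releases within a couple
    of generations.
    """
    z = np.asarray(z)
    k = np.rint(z).astype(int)
    if np.any(k < 0) or np.any(k > 2 * n_loci):
        raise ValueError("target phenotypes outside the attainable range")
    dose = np.clip(k[:, None] - 2 * np.arange(n_loci)[None, :], 0, 2)
    g = np.zeros((z.size, n_loci, 2), dtype=np.uint8)
    g[:, :, 0] = dose >= 1
    g[:, :, 1] = dose == 2
    return g


def colonizing_start(
    params: SimParams,
    spec: GradientSpec,
    rng: np.random.Generator,
    n: int = 500,
) -> Population:
    """Central colonization: ``n`` individuals uniform on the central
    500 x habitat_y strip, integer phenotypes uniform on
    ``[z_opt - 2*alpha, z_opt + 2*alpha]`` where ``z_opt`` is the central
    optimum, genotypes built by the ladder-order fill of
    :func:`genomes_for_phenotypes`, sexes Bernoulli(1/2).

    With the defaults (500 individuals on 500 x 1,000 units) the initial
    expected local density in a radius-50 circle is
    ``500/(500*1000) * pi * 50**2 = 7.85``.
    """
    centre = 0.5 * params.habitat_x
    z_opt = float(optimum_at(centre, spec))
    lo = z_opt - 2.0 * params.alpha
    hi = z_opt + 2.0 * params.alpha
    if lo < 0 or hi > params.z_max:
        raise ValueError(
            f"central optimum {z_opt} puts the colonizing phenotype range "
            f"[{lo}, {hi}] outside the attainable [0, {params.z_max}]"
        )
    x = rng.uniform(centre - 250.0, centre + 250.0, n)
    y = rng.uniform(0.0, params.habitat_y, n)
    choices = np.arange(math.ceil(lo / params.alpha), math.floor(hi / params.alpha) + 1)
    z = rng.choice(choices, n)
    genomes = genomes_for_phenotypes(z, params.n_loci)
    sex = rng.integers(0, 2, n).astype(np.uint8)
    return Population(generation=0, x=x, y=y, sex=sex, genomes=genomes)


def perfect_start(
    params: SimParams,
    spec: GradientSpec,
    rng: np.random.Generator,
    cline_width_factor: float = 1.0,
) -> Population:
    """Perfect adaptation: density at carrying capacity throughout the
    range (uniform positions) and genotypes drawn from the staggered
    cline layout so the slice-mean phenotype matches the optimum.

    The total count is ``K/(pi*r^2)`` individuals per unit area times the
    habitat area.  Each allele is an independent Bernoulli draw from the
    layout's frequency at the individual's position.
    """
    area = params.habitat_x * params.habitat_y
    dens = params.k / (math.pi * params.density_radius**2)
    n = int(round(dens * area))
    x = rng.uniform(0.0, params.habitat_x, n)
    y = rng.uniform(0.0, params.habitat_y, n)
    layout = ClineLayout.default(params, spec, cline_width_factor)
    p = layout.allele_freq(optimum_at(x, spec))
    genomes = (rng.random((n, params.n_loci, 2)) < p[:, :, None]).astype(np.uint8)
    sex = rng.integers(0, 2, n).astype(np.uint8)
    return Population(generation=0, x=x, y=y, sex=sex, genomes=genomes)
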