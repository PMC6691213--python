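"""Life-cycle operations: mate choice, inheritance, dispersal, stepping."""

import math

import numpy as np
import pytest

from clinesim import engine
from clinesim.cli_io import RunConfig
from clinesim.engine import (
    Individual,
    Population,
    choose_mate,
    disperse,
    make_offspring,
    run,
    step,
)
from clinesim.gradients import GradientSpec
from clinesim.model_core import FEMALE, MALE, SimParams

FLAT = GradientSpec(kind="linear", b=0.0, centre_x=1000.0)


def _pop(x, y, sex, z, n_loci=64, generation=0):
    """Population with ladder-filled genomes realizing phenotypes z."""
    from clinesim.initializers import genomes_for_phenotypes

    return Population(
        generation=generation,
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        sex=np.asarray(sex, dtype=np.uint8),
        genomes=genomes_for_phenotypes(np.asarray(z), n_loci),
    )


# ---------------------------------------------------------------------------
# mate choice
# ---------------------------------------------------------------------------

def test_choose_mate_none_without_males():
    p = SimParams(habitat_x=2000.0, habitat_y=300.0)
    spec = GradientSpec(kind="linear", b=0.0, centre_x=1000.0)
    rng = np.random.default_rng(0)
    # lone female
    pop = _pop([500.0], [100.0], [FEMALE], [0])
    assert choose_mate(0, pop, p, spec, rng) is None
    # male beyond the mating distance
    pop = _pop([500.0, 700.0], [100.0, 100.0], [FEMALE, MALE], [0, 0])
    assert choose_mate(0, pop, p, spec, rng) is None
    # male just inside
    pop = _pop([500.0, 640.0], [100.0, 100.0], [FEMALE, MALE], [0, 0])
    assert choose_mate(0, pop, p, spec, rng) == 1


def test_choose_mate_fitness_proportional():
    """Two candidates are chosen in proportion to their expected-offspring
    fitness at their own position and phenotype."""
    p = SimParams(k=1e9, habitat_x=2000.0, habitat_y=300.0)
    spec = GradientSpec(kind="linear", b=0.0, centre_x=1000.0)
    # male 1 matched (z=0 -> W=3.6); male 2 off by 3 (W=3.6-0.125*9=2.475)
    pop = _pop([500.0, 450.0, 550.0], [100.0] * 3, [FEMALE, MALE, MALE], [0, 0, 3])
    expected = 3.6 / (3.6 + 2.475)
    rng = np.random.default_rng(42)
    draws = np.array([choose_mate(0, pop, p, spec, rng) for _ in range(4000)])
    freq = (draws == 1).mean()
    assert freq == pytest.approx(expected, abs=0.03)  # ~4 binomial SD


def test_choose_mate_zero_weight_candidates():
    p = SimParams(k=1e9, habitat_x=2000.0, habitat_y=300.0)
    spec = GradientSpec(kind="linear", b=0.0, centre_x=1000.0)
    # the only candidate male has W = 0 (mismatch beyond the viability cut)
    pop = _pop([500.0, 520.0], [100.0, 100.0], [FEMALE, MALE], [0, 8])
    assert choose_mate(0, pop, p, spec, np.random.default_rng(0)) is None


# ---------------------------------------------------------------------------
# inheritance
# ---------------------------------------------------------------------------

def test_make_offspring_mendelian():
    p = SimParams(mu=0.0, habitat_x=2000.0, habitat_y=300.0)
    rng = np.random.default_rng(1)
    z0 = np.zeros((64, 2), dtype=np.uint8)
    mother = Individual(100.0, 50.0, FEMALE, z0.copy())
    father = Individual(120.0, 50.0, MALE, z0.copy())
    kid = make_offspring(mother, father, p, rng)
    assert kid.genome.sum() == 0 and (kid.x, kid.y) == (100.0, 50.0)

    # heterozygous locus transmits allele 1 with frequency 1/2
    het = z0.copy()
    het[0, 0] = 1
    mother = Individual(100.0, 50.0, FEMALE, het)
    trans = [make_offspring(mother, father, p, rng).genome[0].sum() for _ in range(3000)]
    assert np.mean(trans) == pytest.approx(0.5, abs=0.035)


def test_mutation_symmetry_at_half():
    """mu = 1/2 erases all parental information: transmitted alleles are
    uniform regardless of the parent genotype."""
    p = SimParams(mu=0.5, habitat_x=2000.0, habitat_y=300.0)
    rng = np.random.default_rng(2)
    z0 = np.zeros((64, 2), dtype=np.uint8)
    mother = Individual(0.0, 0.0, FEMALE, z0.copy())
    father = Individual(0.0, 0.0, MALE, np.ones((64, 2), dtype=np.uint8))
    doses = np.array([make_offspring(mother, father, p, rng).genome.mean() for _ in range(400)])
    assert doses.mean() == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------

def test_disperse_identity_at_zero_d():
    p = SimParams(d=0.0, habitat_x=2000.0, habitat_y=300.0)
    rng = np.random.default_rng(3)
    ind = Individual(123.0, 45.0, MALE, np.zeros((64, 2), dtype=np.uint8))
    out = disperse(ind, p, rng)
    assert (out.x, out.y) == (123.0, 45.0)


def test_disperse_marginal_axis_scale_and_wrap():
    """Signed N(0, D) distances in uniform directions give per-axis
    displacement SD D/sqrt(2); y always lands inside [0, habitat_y)."""
    p = SimParams(d=200.0, habitat_x=1e7, habitat_y=300.0)
    rng = np.random.default_rng(4)
    n = 100_000
    x0 = np.full(n, 5e6)
    y0 = np.full(n, 150.0)
    nx, ny, keep = engine._disperse_positions(x0, y0, p, rng)
    assert keep is None
    assert np.std(nx - x0) == pytest.approx(200.0 / math.sqrt(2), rel=0.02)
    assert np.all((ny >= 0.0) & (ny < 300.0))


def test_reflecting_boundary_folds_into_habitat():
    p = SimParams(d=500.0, habitat_x=1000.0, habitat_y=300.0)
    rng = np.random.default_rng(5)
    nx, ny, _ = engine._disperse_positions(np.full(5000, 10.0), np.full(5000, 0.0), p, rng)
    assert np.all((nx >= 0.0) & (nx <= 1000.0))


def test_absorbing_boundary_drops_leavers():
    p = SimParams(d=500.0, habitat_x=1000.0, habitat_y=300.0, x_boundary="absorb")
    rng = np.random.default_rng(6)
    nx, ny, keep = engine._disperse_positions(np.full(5000, 10.0), np.full(5000, 0.0), p, rng)
    assert keep is not None and 0 < keep.sum() < 5000
    assert np.all((nx[keep] >= 0.0) & (nx[keep] <= 1000.0))


# ---------------------------------------------------------------------------
# one generation and whole runs
# ---------------------------------------------------------------------------

def test_step_empty_and_mateless():
    p = SimParams(habitat_x=2000.0, habitat_y=300.0)
    spec = GradientSpec(kind="linear", b=0.0, centre_x=1000.0)
    rng = np.random.default_rng(7)
    empty = Population.empty(0, p.n_loci)
    assert step(empty, p, spec, rng).size == 0
    # a single female with no males leaves no offspring
    lone = _pop([500.0], [100.0], [FEMALE], [0])
    assert step(lone, p, spec, rng).size == 0


def test_offspring_counts_match_poisson_moments():
    """At fixed (z, x, N) the per-female offspring number has Poisson
    mean ~= variance ~= W_F."""
    p = SimParams(k=1e9, mu=0.0, d=1.0, habitat_x=2000.0, habitat_y=300.0)
    spec = GradientSpec(kind="linear", b=0.0, centre_x=1000.0)
    pair = _pop([500.0, 510.0], [100.0, 100.0], [FEMALE, MALE], [0, 0])
    w = 3.6  # matched optimum, N negligible relative to K
    rng = np.random.default_rng(8)
    counts = np.array([step(pair, p, spec, rng).size for _ in range(600)])
    assert counts.mean() == pytest.approx(w, rel=0.1)
    assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.25)


def _tiny_config(seed=0, generations=20):
    hx = 3000.0
    return RunConfig(
        params=SimParams(k=10.0, td=300.0, habitat_x=hx, habitat_y=500.0),
        gradient=GradientSpec(kind="linear", b=0.004, centre_x=hx / 2),
        init_mode="colonizing",
        n_colonizers=120,
        generations=generations,
        seed=seed,
    )


def test_run_zero_generations_and_metadata():
    hist = run(_tiny_config(generations=0))
    assert hist.final_generation == 0
    assert hist.final_size == 120
    assert 0 in hist.snapshots


def test_run_determinism():
    """Identical (config, seed) gives bit-identical trajectories."""
    h1 = run(_tiny_config(seed=11))
    h2 = run(_tiny_config(seed=11))
    np.testing.assert_array_equal(h1.size, h2.size)
    p1, p2 = h1.final_population, h2.final_population
    np.testing.assert_array_equal(p1.x, p2.x)
    np.testing.assert_array_equal(p1.genomes, p2.genomes)
    h3 = run(_tiny_config(seed=12))
    assert not np.array_equal(h1.size, h3.size)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_flat_world_stability(seed):
    """With b = 0 and a perfect start at carrying capacity, 200
    generations change total size by less than ~25% and keep the trait
    mean within one unit of the (flat) optimum, with variance at
    mutation-drift levels."""
    hx = 1500.0
    cfg = RunConfig(
        params=SimParams(k=15.0, td=300.0, habitat_x=hx),
        gradient=GradientSpec(kind="linear", b=0.0, centre_x=hx / 2),
        init_mode="perfect",
        generations=200,
        seed=seed,
    )
    hist = run(cfg)
    n0 = hist.size[0]
    assert abs(hist.final_size - n0) / n0 < 0.25
    assert abs(hist.z_mean[-1]) < 1.0
    assert hist.z_var[-1] < 1.0
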