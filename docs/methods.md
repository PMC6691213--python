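# Methods

## The model

`clinesim` simulates a sexual, diploid population living on a long, thin
habitat — a cylinder of extent `habitat_x x habitat_y` (default
32,000 x 1,000 spatial units) whose short axis wraps. A single
quantitative trait `z` is controlled by `n_loci = 64` unlinked
bi-allelic loci of equal additive effect `alpha = 1`, so `z` is the
allele-dose sum and ranges over 0–128. There is no environmental
variance. A spatially varying optimum `U(x)` imposes stabilizing
selection; density dependence is logistic within a circle of radius 50
holding at most `K` individuals.

Generations are discrete and non-overlapping:

1. **Density.** Every individual's local density `N` is the exact count
   of individuals within radius 50 (cylinder metric), computed from the
   parental generation. The focal individual is counted or not by a
   per-run flag (`include_focal`); excluding it matches the convention
   used for drift-threshold comparisons, retaining it matches earlier
   colonization studies. The difference is a constant offset of one.
2. **Mate choice.** Each female samples one male from those within the
   mating distance `MD = 150`, with probability proportional to the
   male's expected-offspring fitness at *his* phenotype, position and
   local density. No male in range, or all candidate weights zero,
   means no offspring for that female. Males experience selection only
   through this fitness-weighted mating success.
3. **Reproduction.** The female's offspring number is Poisson with mean

       W = max(0, 2 + r_F (1 - N/K) - s (U(x) - z)^2),   s = 1/(2 V_S)

   with `r_F = 1.6` and `V_S = 4` (`s = 0.125`). Truncation applies to
   the mean before sampling. The calibration of the selection term is
   chosen so that dispersing a distance `sigma` along a gradient of
   steepness `b` costs exactly `b^2 sigma^2/(2 V_S)` in expected
   offspring — the form under which increasing dispersal at constant
   gradient is equivalent to steepening the gradient at constant
   dispersal. (The source literature for this model family states the
   female fitness function, the phenotype growth rate and the dispersal
   load with mutually inconsistent selection coefficients — they differ
   by factors of two; we fix the calibration by the dispersal-load
   identity, which is also the only choice that reproduces the reported
   two-fold central-density contrast between interrupted and linear
   gradients, and we treat the remaining factor-of-two mismatch of the
   printed growth-rate equation as an approximation inherited from the
   continuum theory.)
4. **Inheritance.** Each offspring receives one uniformly chosen allele
   copy per locus from each parent; transmitted alleles mutate
   symmetrically with probability `mu = 1e-4`. Sex is Bernoulli(1/2).
5. **Dispersal.** Offspring start at the mother's position and move a
   signed `Normal(0, D)` distance in a uniformly random direction
   (per-axis displacement s.d. `D/sqrt(2)`). The y coordinate wraps;
   the x boundary reflects by default (`absorb` drops emigrants).
   Mate search adds gene flow like a dispersal step, giving the total
   dispersal scale `TD = sqrt(D^2 + SM^2/2)`, `SM = MD/sqrt(2)`, with
   one-dimensional projection `sigma = TD/sqrt(2)`. Configurations may
   specify either `D` or the target `TD`.

The population mean growth rate
`r = r_m (1 - N/K) - (z_bar - U)^2/(2 V_S) - V_P/(2 V_S)` (with
`r_m = r_F/2`) is provided as a diagnostic; its last term is the
standing load that dispersal along a gradient inflates.

## Gradient shapes

* **linear** — `U = b x`, default `b = 0.004`.
* **sigmoid** — `U = 64 + 1.56 (x - centre)^3 / 1e11`: slope zero at the
  centre, growing quadratically outward; spans 0.1–127.9 over the full
  habitat.
* **flat_linear** — slope `b` interrupted by a central flat portion of
  width `w`; the profile is continuous, so the outer limbs are shifted
  inward by `b w/2` and the total optimum span shrinks by `b w`.
  `w = 0` is bit-identical to linear. Slope queries exactly on a flat
  edge return the outward value `b`.

## Starting conditions

* **Colonizing start** — 500 individuals uniform on the central
  500 x `habitat_y` strip (initial local density 7.85), integer
  phenotypes uniform on `z_opt ± 2 alpha` around the central optimum.
  Genotypes realize each target dose by filling loci in a fixed ladder
  order, so founders are polymorphic only at the two or three
  ladder-boundary loci and the genic variance equals the constructed
  phenotypic variance (~2). Scattering the 1-alleles uniformly across
  the 128 slots would instead hide a genic variance of ~14 behind
  negative linkage disequilibrium that recombination releases within a
  couple of generations — an explosive and unintended head start for
  adaptation.
* **Perfect start** — density `K` per circle everywhere (uniform
  positions, `K/(pi 50^2)` per unit area) with genotypes drawn from a
  staircase of allele-frequency clines: locus `i` turns on around the
  optimum value `u_i = alpha (2 i + 1)` following a logistic profile of
  width `b w_c` in phenotype units, `w_c = sigma sqrt(2 V_S)/alpha`
  (configurable factor). Because thresholds live in optimum units the
  construction adapts to any gradient shape — spatial spacing
  `2 alpha / b = 500` units on linear limbs, compressed clines where a
  sigmoid steepens, no clines inside a flat portion, step clines in the
  `b = 0` limit. The published recipe for this construction is
  unpublished; ours is a documented stand-in whose contract is that the
  slice-mean phenotype tracks `U(x)` (verified to within ±2 in tests).

## Statistics

* **Slice statistics** — per 100-unit half-open slice: count, mean
  radius-50 density of members, trait mean, trait variance `V_P`
  (equal to the realized genetic variance; population variance,
  `ddof = 0`), per-locus allele frequencies. Empty slices are kept as
  NaN rows, never zero-filled.
* **Cline width** — inverse maximum absolute slope of a locus's
  frequency-vs-x profile, slope estimated by centred differences after
  a 3-slice moving average; profiles that never cross 0.5 return a
  no-cline marker (NaN). The estimator floor for an ideal step is
  about three slices.
* **Critical gradient** — scanning outward from the centre, the margin
  is the first slice where growth at zero density fails given the local
  phenotypes: `s E[(U - z)^2] >= r_F` (mismatch threshold 12.8 at
  defaults). The crossing is linearly interpolated between slice
  midpoints and the local optimum slope there is reported per side;
  sides where the condition never fails inside the occupied range are
  habitat-limited (`None`).
* **Drift threshold** — `0.15 N sigma s`, with a flag comparing a
  supplied effective gradient `B` against it. The literature does not
  pin down `B`'s formula or whether `N` is a neighborhood size or the
  radius-50 count; we default to the radius-50 count with the focal
  individual excluded and expose the scaling as arguments.

## Outcome classification

Colonizing runs at the classification generation: `extinct`;
`full_spread` (occupancy at or above 95% of slices, or past the window
on both sides); `one_side_spread` (past the window on exactly one
side); `slow_spread` (clines formed but occupancy confined to the
window); `no_spread` (confined, no cline). The window is
7,000 < x < 25,000 at full scale, rescaled proportionally for smaller
habitats. A cline "has formed" on a side when occupied-slice trait
means reach at least `8 alpha` beyond the central optimum (four
substitutions). Perfect-start runs: `persist_full` (occupancy >= 90%)
versus `collapsed`. A slice counts as occupied when it holds at least
`occupancy_min_frac` (default 5%) of its at-carrying-capacity count;
this is indistinguishable from a literal one-individual rule at full
scale but essential on scaled habitats, whose window sits only a few
dispersal standard deviations from the centre and would otherwise be
"occupied" by single-generation tails of maladapted dispersers that
leave no offspring.

## Desk-scale protocol and problem sizes

The published campaigns (32,000-unit habitat, 3,000–10,000 generations,
large parameter grids) are cluster-scale. The package's desk-scale
protocol shrinks `habitat_x` four-fold to 8,000 (centre 4,000, window
1,750–6,250) and leaves every per-unit parameter untouched (`b`, `V_S`,
`mu`, `alpha`, `MD`, density radius), so all local dynamics are
preserved; a perfect start then holds ~25,000 individuals at `K = 25`.
Persistence sweeps run 500 generations (the published collapses are
reported as typically complete within 500), confinement sweeps classify
at generation 1,500, with an early stop once spread past the window is
*adapted* (robustly occupied slices beyond both window edges whose
trait means lie at least `8 alpha` beyond the central optimum).
Scaled sigmoid presets divide the cubic's scale constant by 16, which
compresses the slope field four-fold spatially while preserving slope
values, so the critical-gradient margin keeps its slope and scales its
position. Replicate seeds derive deterministically from a base seed
via `SeedSequence(base, cell, replicate)`.

## What reproduces and what does not

With these choices the simulator reproduces: the analytic initial
conditions (density 7.85, phenotype range 0–128, central sigmoid
optimum 64); persistence of perfect-start linear-gradient populations
at moderate dispersal with load-depressed equilibrium densities;
critical-gradient margins on the steepening gradient whose reach
shrinks as dispersal grows; the variance inflation and density
depression at flat-centre edges; and the roughly two-fold excess of
central density on an interrupted gradient over the linear gradient at
the same `TD = 850`, `K = 25` (measured ratio ~1.9).

Two published phenomena do not reproduce under any self-consistent
reading of the printed model, and the corresponding checks are left
failing rather than weakened. First, perfect-start populations do not
collapse rapidly at `TD >= 1200`: at `K = 25` and `K = 50` they settle
into a stable equilibrium at reduced density (verified to 1,500
generations at desk scale and 500 at full scale). Second, small flat
centres do not confine colonizing populations: founder polymorphism at
the ladder-boundary loci plus mutational input nucleates clines on the
linear limbs within ~50 generations, before the centre-to-edge density
contrast that drives swamping can establish; widths up to 3,000 units
(8.5 sigma) were probed at both published parameter combinations. Both
discrepancies plausibly trace to unpublished details of the original
implementation (the original authors themselves report genetic
variances above their analytical expectations without a mechanism).

## Known limitations

* The phenotype is purely genetic; plasticity and environmental
  variance are out of scope.
* Density counts use raw circle membership with no correction for
  circles truncated at the x-ends; headline dynamics occur far from the
  ends, but the ends equilibrate a few percent denser.
* The synthetic campaigns emulate the study conditions, not real data:
  equal allelic effects, free recombination, constant `K` in space and
  time. Passing tests demonstrate internal consistency of the model
  implementation, not fidelity to any natural population.
* The cline-width estimator is resolution-limited below ~3 slices and
  undefined for profiles that never cross 0.5.
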