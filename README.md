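# clinesim

Individual-based simulation of local adaptation and species' range
margins along **linear**, **steepening (sigmoid)** and **interrupted
(flat-linear)** ecological gradients.

## The scientific problem

Why does adaptation stop at ecological margins? On a uniform gradient,
gene flow along the gradient inflates genetic variance; the resulting
*standing load* `V_P / 2V_S` depresses growth and density, and genetic
drift in the thinned population can then overwhelm selection — or, on
most of parameter space, nothing stops adaptation at all and the
population spreads without limit. Real gradients, however, steepen away
from patch centres or are interrupted by regions where the optimum does
not change, and those nonlinearities reshape where (and whether) a
margin forms. `clinesim` is a forward-in-time simulator for exploring
exactly this: a diploid population with a 64-locus additive trait `z`
(range 0–128, `alpha = 1`) under stabilizing selection toward a
spatially varying optimum `U(x)`, with logistic density regulation in a
radius-50 circle (capacity `K`), fitness-weighted mate choice within
`MD = 150`, symmetric mutation at `mu = 1e-4`, and Gaussian dispersal
on a 32,000 x 1,000 cylinder.

Each female leaves a Poisson number of offspring with mean

```
W = max(0, 2 + r_F (1 - N/K) - s (U(x) - z)^2),   s = 1/(2 V_S)
```

(`r_F = 1.6`, `V_S = 4`), and the total gene-flow scale combines
offspring and mate-search movement: `TD = sqrt(D^2 + SM^2/2)` with
`SM = MD/sqrt(2)` and one-dimensional projection `sigma = TD/sqrt(2)`.
See `docs/methods.md` for the full model description and the design
decisions.

Intended users: population geneticists and evolutionary ecologists who
want a transparent, fast, reproducible reimplementation of this model
family for exploring range-margin formation, cline dynamics and
swamping at patch edges.

## Worked example

Colonization of an interrupted gradient (flat centre of width 2,000 at
`K = 25`, `TD = 850`) on the desk-scale habitat, followed by slice
statistics at the final generation:

```python
import numpy as np
from clinesim import (GradientSpec, RunConfig, SimParams, classify,
                      run, slice_stats)

hx = 8000.0
cfg = RunConfig(
    params=SimParams(k=25.0, td=850.0, habitat_x=hx),
    gradient=GradientSpec(kind="flat_linear", b=0.004, w=2000.0, centre_x=hx / 2),
    init_mode="colonizing",
    generations=500,
    seed=5,
)
hist = run(cfg)
df = slice_stats(hist.final_population, cfg.params, cfg.gradient)
centre = (df.x_mid >= 3700) & (df.x_mid <= 4300) & (df.n > 0)
limb = (df.x_mid >= 1000) & (df.x_mid <= 2000) & (df.n > 0)
print("outcome:", classify(hist).value, "| final size:", hist.final_size)
print("central slices: density %.1f  V_P %.2f" %
      (df.density[centre].mean(), df.z_var[centre].mean()))
print("limb slices:    density %.1f  V_P %.2f" %
      (df.density[limb].mean(), df.z_var[limb].mean()))
```

which prints

```
outcome: full_spread | final size: 14694
central slices: density 21.4  V_P 1.15
limb slices:    density 12.4  V_P 10.24
```

The flat centre sits near carrying capacity with almost no genetic
variance (gene flow across a flat optimum creates no standing load),
while the sloped limbs carry the clinal variance (`V_P ~ 9`) whose load
depresses density to roughly half of `K` — the density contrast that
makes interrupted gradients behave so differently from uniform ones.

The same machinery is scriptable from the shell:

```bash
clinesim preset-list
clinesim simulate --preset interrupted-colonizing-scaled --seed 1 --out runs/demo
clinesim analyze runs/demo/snapshot_gen750.tsv --config runs/demo/config.yaml
```

(`simulate` writes a per-generation summary CSV, population snapshots,
slice tables and a run-metadata JSON; `sweep` runs a parameter grid with
deterministic replicate seeds and a resumable tidy results table.)

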