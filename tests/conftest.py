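"""Shared fixtures.

The heavy simulation campaigns (the dispersal sweep on the linear
gradient, the flat-centre confinement sweeps, the density-doubling and
variance-trough runs) are session-scoped so several acceptance and
property tests can share one set of runs.  All of them use the package's
desk-scale protocol: habitat 8,000 x 1,000 (per-unit parameters
untouched), with the classification window rescaled proportionally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clinesim import engine
from clinesim.cli_io import RunConfig, SweepSpec, child_seed, run_sweep
from clinesim.gradients import GradientSpec
from clinesim.model_core import SimParams
from clinesim.outcomes import classification_window, classify

DESK_X = 8000.0
BASE_SEED = 20240915


def desk_config(
    kind: str = "linear",
    k: float = 25.0,
    td: float = 500.0,
    w: float = 0.0,
    init_mode: str = "perfect",
    generations: int = 500,
    include_focal: bool = True,
    seed: int = 0,
    **kw,
) -> RunConfig:
    return RunConfig(
        params=SimParams(k=k, td=td, habitat_x=DESK_X, include_focal=include_focal),
        gradient=GradientSpec(kind=kind, b=0.004, w=w, centre_x=DESK_X / 2),
        init_mode=init_mode,
        generations=generations,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def linear_td_sweep() -> pd.DataFrame:
    """Perfect-start persistence/collapse sweep on the linear gradient:
    TD in {900..1300} x 3 seeds, 500 generations, K=25."""
    rows = []
    for td in (900.0, 1000.0, 1100.0, 1200.0, 1300.0):
        for rep in range(3):
            cfg = desk_config(
                td=td,
                init_mode="perfect",
                include_focal=False,
                generations=500,
                seed=child_seed(BASE_SEED, int(td), rep),
                collapse_below=0.5,
            )
            hist = engine.run(cfg)
            rows.append(
                {
                    "td": td,
                    "replicate": rep,
                    "final_occ": hist.occupied_frac[-1],
                    "min_occ": hist.min_occupied_frac,
                    "extinct": hist.final_size == 0,
                    "persist": hist.final_size > 0 and hist.occupied_frac[-1] >= 0.9,
                    "collapse": hist.final_size == 0 or hist.min_occupied_frac < 0.5,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def flat_confinement_runs() -> dict:
    """Colonizing runs on the interrupted gradient.

    part_a: w=100 at TD=850, K=25 (3 seeds); part_b: w sweep
    {500..3000} at TD=500, K=7 (3 seeds).  Labels come from the outcome
    classifier at the scaled classification generation (1,500), with the
    adapted-spread early stop as a pure run-time economy.
    """
    win = classification_window(DESK_X)

    def campaign(k, td, widths, tag):
        rows = []
        for i, w in enumerate(widths):
            for rep in range(3):
                cfg = desk_config(
                    kind="flat_linear",
                    k=k,
                    td=td,
                    w=w,
                    init_mode="colonizing",
                    generations=1500,
                    seed=child_seed(BASE_SEED + 1, 100 * i + ord(tag), rep),
                    escape_window=win,
                )
                hist = engine.run(cfg)
                rows.append({"w": w, "replicate": rep, "label": classify(hist).value})
        return pd.DataFrame(rows)

    return {
        "part_a": campaign(25.0, 850.0, [100.0], "a"),
        "part_b": campaign(7.0, 500.0, [500.0, 1000.0, 1500.0, 2000.0, 3000.0], "b"),
    }


@pytest.fixture(scope="session")
def central_density_runs() -> pd.DataFrame:
    """Central slice density of flat-centre (w=2000) vs linear colonizing
    runs at TD=850, K=25, measured at generation 500 (3 seeds each)."""
    from clinesim.stats import slice_stats

    rows = []
    for kind, w in (("flat_linear", 2000.0), ("linear", 0.0)):
        for rep in range(3):
            cfg = desk_config(
                kind=kind,
                td=850.0,
                w=w,
                init_mode="colonizing",
                generations=500,
                seed=child_seed(BASE_SEED + 2, int(w), rep),
            )
            hist = engine.run(cfg)
            df = slice_stats(hist.final_population, cfg.params, cfg.gradient)
            m = (df["x_mid"] >= 3700) & (df["x_mid"] <= 4300) & (df["n"] > 0)
            rows.append({"kind": kind, "replicate": rep, "central_density": df["density"][m].mean()})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def trough_runs() -> list[dict]:
    """Perfect-start flat-centre runs (w=2000, K=25, TD=850) summarised as
    centre vs flat-edge slice variance and density (3 seeds)."""
    from clinesim.stats import slice_stats

    out = []
    for rep in range(3):
        cfg = desk_config(
            kind="flat_linear",
            td=850.0,
            w=2000.0,
            init_mode="perfect",
            include_focal=False,
            generations=400,
            seed=child_seed(BASE_SEED + 3, 0, rep),
        )
        hist = engine.run(cfg)
        df = slice_stats(hist.final_population, cfg.params, cfg.gradient)
        mids = df["x_mid"].to_numpy()

        def band(lo, hi):
            m = (mids >= lo) & (mids <= hi) & (df["n"] > 0)
            return float(df["z_var"][m].mean()), float(df["density"][m].mean())

        centre_v, centre_d = band(3700, 4300)
        lv, ld = band(2700, 3200)
        rv, rd = band(4800, 5300)
        out.append(
            {
                "centre_var": centre_v,
                "centre_dens": centre_d,
                "edge_var": 0.5 * (lv + rv),
                "edge_dens": 0.5 * (ld + rd),
            }
        )
    return out
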