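"""Classification of a completed run into the range-dynamics taxonomy.

Colonizing runs are labelled by how far the population spread and
whether phenotypic clines formed:

``full_spread``
    occupancy reaches at least 95% of the habitat x extent (or the
    population has pushed past the classification window on both sides);
``slow_spread``
    cline(s) formed but occupancy is still confined to the central
    window (7,000 < x < 25,000 on the full-scale habitat, rescaled
    proportionally for smaller habitats) at the classification
    generation;
``one_side_spread``
    occupancy beyond the window on exactly one side;
``no_spread``
    confined to the window with no phenotypic cline on either side;
``extinct``
    final size zero.

A slice counts as occupied when it holds at least a small configurable
fraction (``occupancy_min_frac`` of its at-carrying-capacity count,
default 5%) so that single dispersing stragglers — strongly maladapted
individuals that leave no offspring — do not register as range
occupancy.  On the full-scale habitat this is indistinguishable from a
literal one-individual rule; on scaled habitats, whose classification
window is only a few dispersal standard deviations from the centre, it
is what keeps the taxonomy meaningful.

A cline "has formed" on a side when the occupied-slice trait means on
that side extend at least ``8*alpha`` (four locus substitutions) beyond
the central optimum.  Perfect-adaptation runs are labelled
``persist_full`` (occupancy still at least 90%) or ``collapsed`` (the
occupied range is no longer full; extinction is reported as
``extinct``).  All thresholds are configurable.
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np

from .engine import RunHistory
from .gradients import GradientSpec, optimum_at
from .model_core import SimParams

__all__ = ["OutcomeLabel", "classify", "classification_window", "FULL_SCALE_WINDOW"]

#: classification window printed for the full 32,000-unit habitat
FULL_SCALE_WINDOW = (7000.0, 25000.0)
FULL_SCALE_X = 32000.0


class OutcomeLabel(str, Enum):
    full_spread = "full_spread"
    slow_spread = "slow_spread"
    one_side_spread = "one_side_spread"
    no_spread = "no_spread"
    extinct = "extinct"
    persist_full = "persist_full"
    collapsed = "collapsed"


def classification_window(habitat_x: float) -> tuple[float, float]:
    """The no-spread window, rescaled proportionally to the habitat."""
    f = habitat_x / FULL_SCALE_X
    return (FULL_SCALE_WINDOW[0] * f, FULL_SCALE_WINDOW[1] * f)


def classify(
    history: RunHistory,
    params: SimParams | None = None,
    spec: GradientSpec | None = None,
    *,
    slice_width: float = 100.0,
    cline_span: float | None = None,
    full_spread_frac: float = 0.95,
    persist_frac: float = 0.90,
    at_generation: int | None = None,
) -> OutcomeLabel:
    """Classify the fate of a run from its final (or a stored) snapshot.

    ``at_generation`` selects a stored snapshot; by default the last one
    is used.  Raises when the requested generation was not recorded or
    the history is shorter than it.  Classification is deterministic
    given a history.
    """
    config = history.config
    params = params or config.params
    spec = spec or config.gradient
    if at_generation is None:
        pop = history.final_population
    else:
        if at_generation not in history.snapshots:
            raise ValueError(
                f"no snapshot at generation {at_generation}; run recorded up to "
                f"generation {history.final_generation}"
            )
        pop = history.snapshots[at_generation]

    if pop.size == 0:
        return OutcomeLabel.extinct

    from .engine import occupancy_min_count

    min_count = occupancy_min_count(params, config.occupancy_min_frac, slice_width)
    n_slices = int(round(params.habitat_x / slice_width))
    idx = np.minimum((pop.x / slice_width).astype(int), n_slices - 1)
    counts = np.bincount(idx, minlength=n_slices)
    occ = counts >= min_count
    occ_frac = occ.mean()
    if not occ.any():  # only scattered stragglers left: the range is gone
        return OutcomeLabel.collapsed if config.init_mode == "perfect" else OutcomeLabel.no_spread

    if config.init_mode == "perfect":
        return OutcomeLabel.persist_full if occ_frac >= persist_frac else OutcomeLabel.collapsed

    win_lo, win_hi = classification_window(params.habitat_x)
    mids = (np.arange(n_slices) + 0.5) * slice_width
    beyond_left = bool(np.any(occ & (mids < win_lo)))
    beyond_right = bool(np.any(occ & (mids > win_hi)))

    if occ_frac >= full_spread_frac or (beyond_left and beyond_right):
        return OutcomeLabel.full_spread

    # cline formation: occupied-slice trait means span >= cline_span
    # beyond the central optimum on a given side
    span = 8.0 * params.alpha if cline_span is None else cline_span
    z = pop.phenotypes(params.alpha)
    zsum = np.bincount(idx, weights=z, minlength=n_slices)
    zmean = np.full(n_slices, np.nan)
    zmean[occ] = zsum[occ] / counts[occ]
    u_centre = float(optimum_at(0.5 * params.habitat_x, spec))
    centre_i = int(0.5 * params.habitat_x / slice_width)
    right_means = zmean[centre_i:][occ[centre_i:]]
    left_means = zmean[:centre_i][occ[:centre_i]]
    cline_right = right_means.size > 0 and bool(np.nanmax(right_means) >= u_centre + span)
    cline_left = left_means.size > 0 and bool(np.nanmin(left_means) <= u_centre - span)

    if beyond_left != beyond_right:  # exactly one side
        return OutcomeLabel.one_side_spread
    if cline_left or cline_right:
        return OutcomeLabel.slow_spread
    return OutcomeLabel.no_spread
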