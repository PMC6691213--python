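"""Spatial-slice summaries, cline widths, the critical-gradient estimator
and the drift-threshold comparison.

All spatial statistics are computed on half-open 100-unit slices of the
x axis, matching the resolution at which trait means, variances, local
densities and allele frequencies are summarized.  Because the phenotype
here is purely genetic, the within-slice phenotypic variance ``V_P``
equals the (realized) genetic variance.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .engine import Population
from .gradients import GradientSpec, local_slope, optimum_at
from .model_core import SimParams, density_counts

__all__ = [
    "slice_stats",
    "cline_width",
    "critical_gradient",
    "MarginEstimate",
    "PBThreshold",
    "pb_threshold",
]


def slice_stats(
    pop: Population,
    params: SimParams,
    spec: GradientSpec | None = None,
    slice_width: float = 100.0,
) -> pd.DataFrame:
    """Per-slice density, trait mean, variance ``V_P`` and allele
    frequencies.

    Individuals are binned into half-open slices ``[k*w, (k+1)*w)``.
    ``density`` is the mean, over slice members, of the exact radius-50
    local-density count (the run's focal-inclusion convention applies).
    Empty slices are kept as rows with ``n = 0`` and NaN statistics so
    the slice grid stays regular; they are never zero-filled.

    Returns a DataFrame with columns ``x_mid, n, density, z_mean, z_var``
    and one ``p_<locus>`` column per locus.
    """
    n_slices = int(round(params.habitat_x / slice_width))
    if not math.isclose(n_slices * slice_width, params.habitat_x):
        raise ValueError("slice_width must divide habitat_x")
    mids = (np.arange(n_slices) + 0.5) * slice_width
    cols = {
        "x_mid": mids,
        "n": np.zeros(n_slices, dtype=int),
        "density": np.full(n_slices, np.nan),
        "z_mean": np.full(n_slices, np.nan),
        "z_var": np.full(n_slices, np.nan),
    }
    freqs = np.full((n_slices, params.n_loci), np.nan)
    if pop.size:
        idx = np.minimum((pop.x / slice_width).astype(int), n_slices - 1)
        z = pop.phenotypes(params.alpha)
        dens = density_counts(
            pop.x, pop.y, params.habitat_x, params.habitat_y,
            params.density_radius, params.include_focal,
        )
        counts = np.bincount(idx, minlength=n_slices)
        occ = counts > 0
        cols["n"] = counts
        with np.errstate(invalid="ignore"):
            sums = np.bincount(idx, weights=z, minlength=n_slices)
            sq = np.bincount(idx, weights=z * z, minlength=n_slices)
            dsum = np.bincount(idx, weights=dens.astype(float), minlength=n_slices)
            mean = np.where(occ, sums / np.maximum(counts, 1), np.nan)
            cols["z_mean"] = np.where(occ, mean, np.nan)
            cols["z_var"] = np.where(occ, sq / np.maximum(counts, 1) - mean**2, np.nan)
            cols["density"] = np.where(occ, dsum / np.maximum(counts, 1), np.nan)
        dose = pop.genomes.sum(axis=2) / 2.0  # (n, n_loci) in [0, 1]
        for ell in range(params.n_loci):
            fsum = np.bincount(idx, weights=dose[:, ell], minlength=n_slices)
            freqs[occ, ell] = fsum[occ] / counts[occ]
        cols["z_var"] = np.maximum(cols["z_var"], 0.0)  # clamp fp round-off
    df = pd.DataFrame(cols)
    for ell in range(params.n_loci):
        df[f"p_{ell}"] = freqs[:, ell]
    return df


def cline_width(freq_profile: np.ndarray, slice_width: float = 100.0) -> float:
    """Cline width of one locus from its per-slice frequency profile.

    Width is the inverse of the maximum absolute slope of the profile,
    with the slope estimated by centred differences after a 3-slice
    moving average.  A profile that never crosses 0.5 carries no cline
    and returns NaN; an ideal step resolves to the smoothing-limited
    floor of about three slices.
    """
    f = np.asarray(freq_profile, dtype=float)
    f = f[~np.isnan(f)]
    if f.size < 3:
        return math.nan
    if not (np.any(f < 0.5) and np.any(f > 0.5)):
        return math.nan  # monotone-flat: no cline
    smooth = np.convolve(f, np.ones(3) / 3.0, mode="valid")
    if smooth.size < 3:
        return math.nan
    slopes = (smooth[2:] - smooth[:-2]) / (2.0 * slice_width)
    peak = np.max(np.abs(slopes))
    if peak <= 0:
        return math.nan
    return float(1.0 / peak)


class MarginEstimate(NamedTuple):
    """Range margin on one side: position and local optimum slope.

    ``x_margin`` is ``None`` when the zero-growth condition never fails
    inside the occupied range (habitat-limited, no margin detected).
    """

    x_margin: Optional[float]
    slope: Optional[float]


def _scan_side(mids, msq, occ, order, threshold, spec):
    """Walk slices outward; return interpolated margin when the
    density-free growth condition first fails."""
    prev_mid = None
    prev_val = None
    for i in order:
        if not occ[i]:
            break  # occupied range ends before the condition fails
        val = msq[i]
        if val >= threshold:
            if prev_mid is None:
                x_m = mids[i]
            else:  # linear interpolation to the level crossing
                t = (threshold - prev_val) / (val - prev_val)
                x_m = prev_mid + t * (mids[i] - prev_mid)
            x_m = float(np.clip(x_m, 0.0, spec.x_max))
            return MarginEstimate(x_m, float(local_slope(x_m, spec)))
        prev_mid, prev_val = mids[i], val
    return MarginEstimate(None, None)


def critical_gradient(
    pop: Population,
    params: SimParams,
    spec: GradientSpec,
    slice_width: float = 100.0,
) -> dict[str, MarginEstimate]:
    """Range margins where the intrinsic rate of increase reaches zero.

    Scanning outward from the habitat centre, the margin is the first
    slice where growth at zero density fails given the local phenotype
    distribution: mean offspring ``2 + r_F - s*E[(U - z)^2]`` drops
    to replacement, i.e. ``s * E[(U - z)^2] >= r_F``.  The crossing
    is linearly interpolated between adjacent slice midpoints and the
    optimum slope there is reported.  Returns ``{"left": ..., "right":
    ...}``; a side is habitat-limited (``None``) when the condition
    never fails inside the occupied range.
    """
    if pop.size == 0:
        raise ValueError("cannot locate margins of an extinct population")
    n_slices = int(round(params.habitat_x / slice_width))
    mids = (np.arange(n_slices) + 0.5) * slice_width
    idx = np.minimum((pop.x / slice_width).astype(int), n_slices - 1)
    z = pop.phenotypes(params.alpha)
    mis = (optimum_at(pop.x, spec) - z) ** 2
    counts = np.bincount(idx, minlength=n_slices)
    occ = counts > 0
    msq = np.full(n_slices, np.nan)
    msq[occ] = np.bincount(idx, weights=mis, minlength=n_slices)[occ] / counts[occ]
    threshold = params.r_f / params.s
    centre_i = int(0.5 * params.habitat_x / slice_width)
    right = _scan_side(mids, msq, occ, range(centre_i, n_slices), threshold, spec)
    left = _scan_side(mids, msq, occ, range(centre_i - 1, -1, -1), threshold, spec)
    return {"left": left, "right": right}


class PBThreshold(NamedTuple):
    """Drift threshold ``0.15*N*sigma*s`` and, when an effective gradient
    ``B`` was supplied, whether it exceeds the threshold (predicting
    failure of adaptation)."""

    threshold: float
    exceeds: Optional[bool]


def pb_threshold(
    n: float,
    sigma: float,
    s: float,
    b_effective: float | None = None,
    factor: float = 0.15,
) -> PBThreshold:
    """Drift threshold for the effective environmental gradient.

    Adaptation is predicted to fail when the effective gradient ``B``
    exceeds ``factor*N*sigma*s`` (default factor 0.15), where ``N`` is
    the local population size, ``sigma`` the one-dimensional dispersal
    distance and ``s`` the selection per locus.  By default ``N`` is the
    radius-50 count with the focal individual excluded; a convenient
    effective gradient is ``local slope x sigma`` (the optimum shift per
    dispersal distance) — both conventions are scaling hooks, not fixed
    by the threshold itself.
    """
    if min(n, sigma, s) < 0:
        raise ValueError("pb_threshold arguments must be non-negative")
    thr = factor * n * sigma * s
    return PBThreshold(thr, None if b_effective is None else bool(b_effective > thr))
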