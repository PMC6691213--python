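"""Spatial profiles of the phenotypic optimum.

The habitat is a long, thin cylinder; the optimum trait value ``U(x)``
changes only along the long (x) axis.  Three shapes are supported:

``linear``
    ``U(x) = b*x`` — a uniform gradient of steepness ``b``.
``sigmoid``
    ``U(x) = offset + coef*(x - centre_x)**3 / scale`` — a steepening
    gradient whose slope is zero at the centre and grows quadratically
    with distance from it.  With the default constants (offset 64,
    coefficient 1.56, scale 1e11, centre 16,000) the optimum stays inside
    the attainable phenotypic range 0–128 over a 32,000-unit habitat.
``flat_linear``
    a uniform gradient of steepness ``b`` interrupted by a central flat
    portion of width ``w``: the slope is exactly zero on
    ``[centre_x - w/2, centre_x + w/2]`` and exactly ``b`` outside.  The
    profile is kept continuous, so the two sloped limbs are shifted
    inward and the total optimum span is reduced by ``b*w`` relative to
    the pure linear gradient.  With ``w = 0`` the profile is identical to
    ``linear``.

Only the slope of the optimum may jump (at the edges of the flat
portion); the optimum itself is continuous for every kind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GradientSpec", "optimum_at", "local_slope", "KINDS"]

KINDS = ("linear", "sigmoid", "flat_linear")

#: default constants of the steepening (cubic) optimum
SIGMOID_OFFSET = 64.0
SIGMOID_COEF = 1.56
SIGMOID_SCALE = 1.0e11


@dataclass(frozen=True)
class GradientSpec:
    """Shape of the optimum profile along the x axis.

    Parameters
    ----------
    kind : {"linear", "sigmoid", "flat_linear"}
    b : float
        Optimum change per spatial unit on the sloped portions
        (phenotype units per habitat unit).
    w : float
        Width of the central flat portion (``flat_linear`` only).
    centre_x : float
        Habitat centre; the flat portion and the sigmoid inflection sit
        here.
    x_max : float, optional
        Upper end of the habitat; queries outside ``[0, x_max]`` raise.
        Defaults to ``2 * centre_x``.
    sigmoid_offset, sigmoid_coef, sigmoid_scale : float
        Constants of the cubic optimum.  Scaled-habitat presets divide
        ``sigmoid_scale`` to compress the slope field spatially while
        preserving the slope values.
    """

    kind: str = "linear"
    b: float = 0.004
    w: float = 0.0
    centre_x: float = 16000.0
    x_max: float | None = None
    sigmoid_offset: float = SIGMOID_OFFSET
    sigmoid_coef: float = SIGMOID_COEF
    sigmoid_scale: float = SIGMOID_SCALE

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown gradient kind {self.kind!r}; expected one of {KINDS}")
        if self.b < 0:
            raise ValueError("gradient slope b must be non-negative")
        if self.w < 0:
            raise ValueError("flat-portion width w must be non-negative")
        if self.centre_x <= 0:
            raise ValueError("centre_x must be positive")
        if self.x_max is None:
            object.__setattr__(self, "x_max", 2.0 * self.centre_x)
        if self.x_max <= 0:
            raise ValueError("x_max must be positive")

    @property
    def centre_optimum(self) -> float:
        """Optimum value at ``centre_x``."""
        return float(optimum_at(self.centre_x, self))


def _check_range(x: np.ndarray, spec: GradientSpec) -> None:
    if np.any(x < 0) or np.any(x > spec.x_max):
        raise ValueError(
            f"position outside habitat [0, {spec.x_max}]: "
            f"range queried was [{np.min(x)}, {np.max(x)}]"
        )


def optimum_at(x, spec: GradientSpec):
    """Phenotypic optimum ``U(x)``; scalar or array in, like out."""
    xa = np.asarray(x, dtype=float)
    _check_range(xa, spec)
    if spec.kind == "linear":
        u = spec.b * xa
    elif spec.kind == "sigmoid":
        u = spec.sigmoid_offset + spec.sigmoid_coef * (xa - spec.centre_x) ** 3 / spec.sigmoid_scale
    elif spec.w == 0.0:  # flat_linear with no flat portion degenerates to linear
        u = spec.b * xa
    else:  # flat_linear
        d = xa - spec.centre_x
        u = spec.b * spec.centre_x + spec.b * np.sign(d) * np.maximum(0.0, np.abs(d) - 0.5 * spec.w)
    return u if isinstance(x, np.ndarray) else float(u)


def local_slope(x, spec: GradientSpec):
    """Derivative dU/dx of the optimum profile.

    For ``flat_linear`` the slope jumps at the flat edges; a query exactly
    on an edge returns the outward (steep) side, ``b``.
    """
    xa = np.asarray(x, dtype=float)
    _check_range(xa, spec)
    if spec.kind == "linear":
        s = np.full_like(xa, spec.b)
    elif spec.kind == "sigmoid":
        s = 3.0 * spec.sigmoid_coef * (xa - spec.centre_x) ** 2 / spec.sigmoid_scale
    else:
        s = np.where(np.abs(xa - spec.centre_x) >= 0.5 * spec.w, spec.b, 0.0)
    return s if isinstance(x, np.ndarray) else float(s)
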