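"""Numba kernels for neighborhood queries on the cylindrical habitat.

Both kernels use a uniform cell grid whose cell edge is at least the
query radius, so a 3x3 cell scan around the query's cell is exhaustive.
The y axis wraps (minimum-image distance); x does not.  Cells are
addressed as ``cx*ncy + cy`` and points are pre-sorted by cell id in
numpy (``build_grid``).  The kernels are pure functions of their inputs
— any randomness is supplied as a pre-drawn uniform array — which keeps
whole runs reproducible from a single generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grid_layout", "build_grid", "count_within", "pick_mates"]


def grid_layout(extent_x: float, extent_y: float, min_cell: float):
    """Number and size of grid cells; cell edges never smaller than
    ``min_cell`` (so a 3x3 scan covers the query circle)."""
    ncx = max(1, int(extent_x // min_cell))
    ncy = max(1, int(extent_y // min_cell))
    return ncx, ncy, extent_x / ncx, extent_y / ncy


def build_grid(x, y, ncx, ncy, cell_x, cell_y):
    """Sort points by cell id; returns (order, starts) CSR-style."""
    cx = np.clip((x // cell_x).astype(np.int64), 0, ncx - 1)
    cy = np.clip((y // cell_y).astype(np.int64), 0, ncy - 1)
    cid = cx * ncy + cy
    order = np.argsort(cid, kind="stable")
    starts = np.zeros(ncx * ncy + 1, dtype=np.int64)
    np.cumsum(np.bincount(cid, minlength=ncx * ncy), out=starts[1:])
    return order, starts


@njit(cache=True)
def count_within(qx, qy, self_member, px, py, order, starts,
                 ncx, ncy, cell_x, cell_y, radius, wrap_y, count_self):
    """Exact count of points within ``radius`` of each query.

    ``self_member[i]`` marks queries that are themselves rows of the
    point set; those contribute a zero-distance hit which is removed
    when ``count_self`` is False.
    """
    n = qx.shape[0]
    out = np.empty(n, np.int64)
    r2 = radius * radius
    for i in range(n):
        cx = int(qx[i] // cell_x)
        if cx < 0:
            cx = 0
        elif cx >= ncx:
            cx = ncx - 1
        cy = int(qy[i] // cell_y)
        if cy < 0:
            cy = 0
        elif cy >= ncy:
            cy = ncy - 1
        total = 0
        seen_a = -1
        seen_b = -1
        for dy in range(-1, 2):
            ccy = (cy + dy) % ncy
            if ccy == seen_a or ccy == seen_b:
                continue  # tiny habitats: same wrapped cell revisited
            if dy == -1:
                seen_a = ccy
            elif dy == 0:
                seen_b = ccy
            for dx in range(-1, 2):
                ccx = cx + dx
                if ccx < 0 or ccx >= ncx:
                    continue
                c0 = starts[ccx * ncy + ccy]
                c1 = starts[ccx * ncy + ccy + 1]
                for k in range(c0, c1):
                    j = order[k]
                    ddx = px[j] - qx[i]
                    ddy = abs(py[j] - qy[i])
                    if ddy > wrap_y - ddy:
                        ddy = wrap_y - ddy
                    if ddx * ddx + ddy * ddy <= r2:
                        total += 1
        if self_member[i] and not count_self:
            total -= 1
        out[i] = total
    return out


@njit(cache=True)
def pick_mates(fx, fy, mx, my, mw, order, starts,
               ncx, ncy, cell_x, cell_y, radius, wrap_y, u):
    """Fitness-weighted mate choice for every female.

    Candidates are the males within ``radius`` (cylinder metric); each is
    chosen with probability proportional to its weight ``mw``.  ``u`` is
    one pre-drawn Uniform[0,1) variate per female.  Returns the index of
    the chosen male within the male arrays, or -1 when there is no
    candidate or all candidate weights are zero.
    """
    nf = fx.shape[0]
    out = np.full(nf, -1, np.int64)
    r2 = radius * radius
    for i in range(nf):
        cx = int(fx[i] // cell_x)
        if cx < 0:
            cx = 0
        elif cx >= ncx:
            cx = ncx - 1
        cy = int(fy[i] // cell_y)
        if cy < 0:
            cy = 0
        elif cy >= ncy:
            cy = ncy - 1

        # pass 1: total candidate weight
        total = 0.0
        seen_a = -1
        seen_b = -1
        for dy in range(-1, 2):
            ccy = (cy + dy) % ncy
            if ccy == seen_a or ccy == seen_b:
                continue
            if dy == -1:
                seen_a = ccy
            elif dy == 0:
                seen_b = ccy
            for dx in range(-1, 2):
                ccx = cx + dx
                if ccx < 0 or ccx >= ncx:
                    continue
                c0 = starts[ccx * ncy + ccy]
                c1 = starts[ccx * ncy + ccy + 1]
                for k in range(c0, c1):
                    j = order[k]
                    ddx = mx[j] - fx[i]
                    ddy = abs(my[j] - fy[i])
                    if ddy > wrap_y - ddy:
                        ddy = wrap_y - ddy
                    if ddx * ddx + ddy * ddy <= r2:
                        total += mw[j]
        if total <= 0.0:
            continue

        # pass 2: walk the same candidates to the sampled threshold
        thresh = u[i] * total
        acc = 0.0
        chosen = -1
        last_pos = -1
        done = False
        seen_a = -1
        seen_b = -1
        for dy in range(-1, 2):
            if done:
                break
            ccy = (cy + dy) % ncy
            if ccy == seen_a or ccy == seen_b:
                continue
            if dy == -1:
                seen_a = ccy
            elif dy == 0:
                seen_b = ccy
            for dx in range(-1, 2):
                if done:
                    break
                ccx = cx + dx
                if ccx < 0 or ccx >= ncx:
                    continue
                c0 = starts[ccx * ncy + ccy]
                c1 = starts[ccx * ncy + ccy + 1]
                for k in range(c0, c1):
                    j = order[k]
                    ddx = mx[j] - fx[i]
                    ddy = abs(my[j] - fy[i])
                    if ddy > wrap_y - ddy:
                        ddy = wrap_y - ddy
                    if ddx * ddx + ddy * ddy <= r2 and mw[j] > 0.0:
                        acc += mw[j]
                        last_pos = j
                        if acc >= thresh:
                            chosen = j
                            done = True
                            break
        if chosen < 0:
            chosen = last_pos  # guard against floating-point shortfall
        out[i] = chosen
    return out
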