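"""Geometric spiral-induction initial conditions.

Spiral waves are induced by breaking the symmetry of an expanding wave:
a super-threshold perturbation in part of the domain plus a refractory
region (or an angular phase gradient) that truncates the wavefront so its
free end can curl.  Three geometry kinds cover the protocols used by the
shipped models: a rectangle perturbation, a refractory half plane, and a
polar wedge about the domain center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from ..network import GridSpec

__all__ = ["SpiralInit", "apply_spiral_inits", "cell_centers", "polar_angle"]


@dataclass
class SpiralInit:
    """One region override: where, and what values each species takes there.

    kind
        ``rectangle_perturbation`` — bounds (x0, x1, y0, y1) as fractions of
        the domain side; ``half_plane_refractory`` — bounds (x_frac,), the
        region x > x_frac·L; ``polar_wedge`` — bounds (theta0, theta1) in
        radians about the domain center.
    overrides
        species name → value (per-subvolume copy count at Ω = 1) set inside
        the region.
    """

    kind: str
    bounds: tuple
    overrides: Dict[str, float] = field(default_factory=dict)


def cell_centers(grid: GridSpec):
    x = (np.arange(grid.nx) + 0.5) * grid.lambda_
    y = (np.arange(grid.ny) + 0.5) * grid.lambda_
    return np.meshgrid(x, y)


def polar_angle(grid: GridSpec) -> np.ndarray:
    """Polar angle in [0, 2π) about the domain center, per cell."""
    X, Y = cell_centers(grid)
    cx = grid.nx * grid.lambda_ / 2.0
    cy = grid.ny * grid.lambda_ / 2.0
    th = np.arctan2(Y - cy, X - cx)
    return np.where(th < 0, th + 2 * np.pi, th)


def region_mask(init: SpiralInit, grid: GridSpec) -> np.ndarray:
    Lx = grid.nx * grid.lambda_
    Ly = grid.ny * grid.lambda_
    X, Y = cell_centers(grid)
    if init.kind == "rectangle_perturbation":
        x0, x1, y0, y1 = init.bounds
        if not (0 <= x0 <= x1 <= 1 and 0 <= y0 <= y1 <= 1):
            raise ValueError("rectangle bounds must lie within the domain")
        return ((X >= x0 * Lx) & (X <= x1 * Lx)
                & (Y >= y0 * Ly) & (Y <= y1 * Ly))
    if init.kind == "half_plane_refractory":
        (x_frac,) = init.bounds
        if not 0 <= x_frac <= 1:
            raise ValueError("half-plane bound must lie within the domain")
        return X > x_frac * Lx
    if init.kind == "polar_wedge":
        th0, th1 = init.bounds
        th = polar_angle(grid)
        return (th >= th0) & (th < th1)
    raise ValueError(f"unknown spiral-init kind {init.kind!r}")


def apply_spiral_inits(values: np.ndarray, grid: GridSpec, inits,
                       species_names) -> np.ndarray:
    """Apply region overrides to a (n_species, ny, nx) base field, in order."""
    out = values.copy()
    index = {n: i for i, n in enumerate(species_names)}
    for init in inits:
        mask = region_mask(init, grid)
        for name, val in init.overrides.items():
            out[index[name]][mask] = val
    return out
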