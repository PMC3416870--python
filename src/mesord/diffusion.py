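"""Synchronous multiparticle jump diffusion between neighboring subvolumes.

On a lattice of spacing λ a species with diffusivity D hops on the time scale

    τ = λ² / (2 d D)          (d = 2 here),

after which every particle moves to a uniformly random one of the 2d nearest
neighbors.  The mean-squared displacement of this process is exactly 2dD·t.
The engine advances all subvolumes with the common global step
τ* = min_s τ_s; a species with a larger individual step hops only every
``m = round(τ_s / τ*)``-th step, which keeps its realized diffusivity within
rounding of nominal (the realized value is reported in the schedule).
Reflecting boundaries are implemented by rejection: moves that would leave
the domain keep the particle in its subvolume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from . import _kernels
from .network import GridState, ModelValidationError, ScaledNetwork

__all__ = [
    "NO_DIFFUSION",
    "diffusion_timestep",
    "global_timestep",
    "DiffusionSchedule",
    "build_schedule",
    "diffuse_step",
]

#: Sentinel returned for a spatially pinned species (D = 0): it never hops.
NO_DIFFUSION = np.inf


def diffusion_timestep(lambda_: float, D: float, d: int = 2) -> float:
    """Multiparticle hop interval λ²/(2dD); ``NO_DIFFUSION`` if D = 0."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if D < 0:
        raise ValueError("diffusivity must be >= 0")
    if D == 0:
        return NO_DIFFUSION
    return lambda_ ** 2 / (2 * d * D)


@dataclass
class DiffusionSchedule:
    """Per-species hop schedule for the common global step."""

    tau: float                   # global step (min over diffusing species)
    multiples: List[int]         # hop every m-th step; 0 = pinned
    effective_D: List[float]     # realized diffusivity under the schedule


def global_timestep(net: ScaledNetwork) -> float:
    """Common global time step: minimum hop interval over diffusing species."""
    return build_schedule(net).tau


def build_schedule(net: ScaledNetwork) -> DiffusionSchedule:
    grid = net.grid
    taus = [diffusion_timestep(grid.lambda_, s.diffusivity, grid.d)
            for s in net.base.species]
    finite = [t for t in taus if np.isfinite(t)]
    if not finite:
        raise ModelValidationError(
            "all species are spatially pinned; no diffusion time step exists")
    tau = min(finite)
    multiples, eff = [], []
    for s, t in zip(net.base.species, taus):
        if not np.isfinite(t):
            multiples.append(0)
            eff.append(0.0)
        else:
            m = max(1, int(round(t / tau)))
            multiples.append(m)
            eff.append(grid.lambda_ ** 2 / (2 * grid.d * m * tau))
    return DiffusionSchedule(tau=tau, multiples=multiples, effective_D=eff)


def diffuse_step(state: GridState, species_idx: int,
                 seed: int | None = None) -> None:
    """Apply one multiparticle hop to one species, in place.

    Every particle is assigned one of the 4 neighbor directions with
    probability 1/4 (multinomial split per cell); moves crossing the domain
    boundary are rejected in place.  The species' total count is conserved
    exactly.
    """
    if seed is not None:
        _kernels.seed_rng(seed)
    state.counts[species_idx] = _kernels.diffuse_lattice(
        state.counts[species_idx])
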