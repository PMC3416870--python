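"""Oregonator scheme for the Belousov-Zhabotinsky reaction.

With the constant pools A (bromate) and B (organic substrate) absorbed into
effective unimolecular constants, the scheme is::

    Y -> X         (c1)         X + X -> 0    (c4)
    X + Y -> 0     (c2)         Z -> f Y      (c5)
    X -> 2X + Z    (c3)

X = HBrO₂ is the activator, Y = Br⁻ the fast inhibitor, Z the oxidized
catalyst (slow recovery variable).  The catalyst reset step carries a
fractional stoichiometric factor f — a lumped representation of
intermediate chemistry — which a discrete particle scheme cannot fire
directly.  For the shipped f = 3/2 it is realized exactly by two helper
species and fast conversions::

    Z -> S1            (c5)
    S1 + S1 -> S2 + 2Y (k_a, fast)
    S2 -> Y            (k_b, fast)

(per 2 Z consumed, 3 Y appear).  Provided k_a, k_b exceed every other
effective rate, the helper pool stays negligibly small and the chemistry of
the fractional step is reproduced; the helper rates are deliberately left
un-scaled by Ω so they remain dominant at every system size.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import yaml

from ..network import (
    GridSpec,
    GridState,
    ModelValidationError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    scale_network,
)
from ..pde import MeanFieldArrays
from .gray_scott import _load_defaults
from .spiral_init import polar_angle

__all__ = ["OregonatorParams", "oregonator_network", "oregonator_init",
           "build_oregonator", "fractional_mean_field"]


@dataclass
class OregonatorParams:
    """Effective unimolecular constants (A, B absorbed), copy-count units."""

    c1: float = 0.5
    c2: float = 100.0
    c3: float = 1.0
    c4: float = 0.2
    c5: float = 0.1
    f: float = 1.5
    helper_separation: float = 1000.0
    min_helper_separation: float = 100.0
    diffusivity_x: float = 1.0
    diffusivity_z: float = 0.6
    nx: int = 128
    ny: int = 128
    lambda_: float = 1.0
    wedge_angle: float = 0.5
    x_wedge_fraction: float = 0.8
    z_angle_scale: float = 8.0
    z_floor_fraction: float = 1e-3

    @classmethod
    def from_file(cls, path=None) -> "OregonatorParams":
        doc = (_load_defaults("oregonator.yaml") if path is None
               else yaml.safe_load(open(path).read()))
        doc = dict(doc)
        doc["lambda_"] = doc.pop("lambda", 1.0)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ModelValidationError(f"unknown parameters {sorted(unknown)}")
        return cls(**doc)

    @property
    def x_scale(self) -> float:
        """X0 = c3/(2 c4), the activator amplitude scale."""
        return self.c3 / (2 * self.c4)

    @property
    def z_scale(self) -> float:
        """Z0 = c3 X0/c5, the catalyst amplitude scale."""
        return self.c3 * self.x_scale / self.c5

    @property
    def eps(self) -> float:
        """Tyson-Fife time-scale ratio c5/c3."""
        return self.c5 / self.c3

    @property
    def q(self) -> float:
        """Tyson-Fife excitability parameter 2 c1 c4/(c2 c3)."""
        return 2 * self.c1 * self.c4 / (self.c2 * self.c3)

    @property
    def helper_rate(self) -> float:
        return self.helper_separation * max(self.c1, self.c2, self.c3,
                                            self.c4, self.c5)


def default_params() -> OregonatorParams:
    return OregonatorParams.from_file()


def oregonator_network(params: OregonatorParams) -> ReactionNetwork:
    p = params
    if abs(p.f - 1.5) > 1e-12:
        raise ModelValidationError(
            "the helper discretization realizes exactly f = 3/2; "
            f"got f = {p.f}")
    if p.helper_separation < p.min_helper_separation:
        raise ModelValidationError(
            f"helper rates must dominate by at least "
            f"{p.min_helper_separation}x (got {p.helper_separation}x)")
    ka = kb = p.helper_rate
    no_scale = {"no_scale": True}
    return ReactionNetwork(
        species=[
            SpeciesSpec("X", p.diffusivity_x, 0.0),
            SpeciesSpec("Y", 0.0, 0.0),
            SpeciesSpec("Z", p.diffusivity_z, 0.0),
            SpeciesSpec("S1", 0.0, 0.0),
            SpeciesSpec("S2", 0.0, 0.0),
        ],
        reactions=[
            Reaction({"Y": 1}, {"X": 1}, RateLaw("mass_action", p.c1, 1),
                     "bromide consumption"),
            Reaction({"X": 1, "Y": 1}, {}, RateLaw("mass_action", p.c2, 2),
                     "mutual annihilation"),
            Reaction({"X": 1}, {"X": 2, "Z": 1},
                     RateLaw("mass_action", p.c3, 1), "autocatalysis"),
            Reaction({"X": 2}, {}, RateLaw("mass_action", p.c4, 2),
                     "activator self-limitation"),
            Reaction({"Z": 1}, {"S1": 1}, RateLaw("mass_action", p.c5, 1),
                     "catalyst reset (slow step)"),
            Reaction({"S1": 2}, {"S2": 1, "Y": 2},
                     RateLaw("mass_action", ka, 2, dict(no_scale)),
                     "helper pairing (fast)"),
            Reaction({"S2": 1}, {"Y": 1},
                     RateLaw("mass_action", kb, 1, dict(no_scale)),
                     "helper conversion (fast)"),
        ],
        grid=GridSpec(p.nx, p.ny, p.lambda_),
    )


def rest_state(params: OregonatorParams):
    """Low-X rest values used outside the wedge.

    In Tyson-Fife variables the excitable rest sits near
    u = q (f+1)/(f−1); Y follows its dynamic equilibrium
    y = f c5 z/(c1 + c2 x) and Z the stationary value z = c3 x/c5.
    """
    p = params
    x = p.q * (p.f + 1) / (p.f - 1) * p.x_scale
    z = p.c3 * x / p.c5
    y = p.f * p.c5 * z / (p.c1 + p.c2 * x)
    return x, y, z


def oregonator_init(params: OregonatorParams) -> np.ndarray:
    """Ω = 1 wedge initial condition (Jahnke-type spiral recipe).

    X gets an overdensity inside the polar wedge; Z is proportional to the
    polar angle (an angular phase gradient, so the wave end is refractory on
    one side and curls); Y is set to its local dynamic equilibrium.
    """
    p = params
    grid = GridSpec(p.nx, p.ny, p.lambda_)
    th = polar_angle(grid)
    x_rest, _, _ = rest_state(p)
    vals = np.zeros((5, p.ny, p.nx))
    vals[0] = np.where(th < p.wedge_angle, p.x_wedge_fraction * p.x_scale,
                       x_rest)
    vals[2] = (th / (p.z_angle_scale * np.pi * p.f)
               + p.z_floor_fraction) * p.z_scale
    vals[1] = p.f * p.c5 * vals[2] / (p.c1 + p.c2 * vals[0])
    return vals


def build_oregonator(params: OregonatorParams | None = None,
                     omega: float = 1.0):
    """Scaled 7-reaction helper network plus integer wedge initial state."""
    p = params if params is not None else default_params()
    net = oregonator_network(p)
    scaled = scale_network(net, omega)
    counts = np.floor(oregonator_init(p) * omega + 0.5).astype(np.int64)
    return scaled, GridState(0.0, counts)


def fractional_mean_field(params: OregonatorParams | None = None
                          ) -> MeanFieldArrays:
    """Mean-field arrays of the reduced fractional-stoichiometry scheme.

    Species order (X, Y, Z); the catalyst reset contributes +f to Y
    directly, which is the deterministic limit the helper construction
    reproduces when its rates dominate.
    """
    p = params if params is not None else default_params()
    kinds = np.zeros(5, dtype=np.int64)
    consts = np.array([p.c1, p.c2, p.c3, p.c4, p.c5])
    stoich_r = np.array([[0, 1, 0], [1, 1, 0], [1, 0, 0], [2, 0, 0],
                         [0, 0, 1]], dtype=np.int64)
    change = np.array([[1.0, -1.0, 0.0], [-1.0, -1.0, 0.0], [1.0, 0.0, 1.0],
                       [-2.0, 0.0, 0.0], [0.0, p.f, -1.0]])
    return MeanFieldArrays(kinds=kinds, consts=consts, stoich_r=stoich_r,
                           change=change, par=np.zeros((5, 8)))


def fractional_network(params: OregonatorParams | None = None
                       ) -> ReactionNetwork:
    """Three-species carrier network (X, Y, Z with diffusivities) for the
    deterministic twin; kinetics are supplied by
    :func:`fractional_mean_field`."""
    p = params if params is not None else default_params()
    return ReactionNetwork(
        species=[SpeciesSpec("X", p.diffusivity_x, 0.0),
                 SpeciesSpec("Y", 0.0, 0.0),
                 SpeciesSpec("Z", p.diffusivity_z, 0.0)],
        reactions=[Reaction({"X": 1}, {}, RateLaw("mass_action", 0.0, 1),
                            "placeholder (kinetics via mean-field arrays)")],
        grid=GridSpec(p.nx, p.ny, p.lambda_),
    )
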