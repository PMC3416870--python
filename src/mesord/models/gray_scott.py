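"""Gray-Scott cubic-autocatalysis model (spike spiral waves).

The scheme couples a spatially pinned substrate U (the inhibitor role) to a
diffusing activator V::

    U + 2V -> 3V   (k1)      0 -> U   (k3)
        V -> 0     (k2)      U -> 0   (k4)

with mean-field point kinetics du/dt = k3 − k4·u − k1·u·v² and
dv/dt = k1·u·v² − k2·v (per-subvolume copy counts).  The trivial state
(u = k3/k4, v = 0) is linearly stable; for excitability parameter
a = k1 k3²/(4 k2² k4) ≥ 1 the activator nullcline admits further
homogeneous states and super-threshold perturbations trigger a large
excursion.  A spiral is induced by a super-threshold activator rectangle
plus a substrate-depleted refractory right half plane.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import yaml

from ..network import (
    GridSpec,
    GridState,
    ModelValidationError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    ScaledNetwork,
    SpeciesSpec,
    scale_network,
)
from .spiral_init import SpiralInit, apply_spiral_inits

__all__ = ["GrayScottParams", "gray_scott_network", "gray_scott_init",
           "build_gray_scott"]


def _load_defaults(name: str) -> dict:
    text = (resources.files("mesord.models") / "data" / name).read_text()
    return yaml.safe_load(text)


@dataclass
class GrayScottParams:
    """Parameters in the per-subvolume copy-count representation (Ω = 1)."""

    k1: float = 1.0
    k2: float = 1.0
    k3: float = 0.5
    k4: float = 0.04
    diffusivity_v: float = 2.0
    nx: int = 128
    ny: int = 128
    lambda_: float = 1.0
    rect: tuple = (0.25, 0.45, 0.48, 0.55)
    v_perturb: float = 2.0
    u_refractory: float = 0.04
    v_refractory: float = 0.0
    n_fixed_points: int = 3

    @classmethod
    def from_file(cls, path=None) -> "GrayScottParams":
        doc = (_load_defaults("gray_scott.yaml") if path is None
               else yaml.safe_load(open(path).read()))
        doc = dict(doc)
        doc["lambda_"] = doc.pop("lambda", 1.0)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ModelValidationError(f"unknown parameters {sorted(unknown)}")
        doc["rect"] = tuple(doc.get("rect", cls.rect))
        return cls(**doc)

    @property
    def u_background(self) -> float:
        return self.k3 / self.k4

    @property
    def excitability(self) -> float:
        """a = k1 k3²/(4 k2² k4); number of homogeneous states: 1/2/3 for
        a below / at / above 1."""
        return self.k1 * self.k3 ** 2 / (4 * self.k2 ** 2 * self.k4)


def default_params() -> GrayScottParams:
    return GrayScottParams.from_file()


def gray_scott_network(params: GrayScottParams) -> ReactionNetwork:
    p = params
    if min(p.k1, p.k2, p.k3, p.k4) < 0:
        raise ModelValidationError("rates must be non-negative")
    return ReactionNetwork(
        species=[
            SpeciesSpec("U", 0.0, p.u_background),     # pinned substrate
            SpeciesSpec("V", p.diffusivity_v, 0.0),    # diffusing activator
        ],
        reactions=[
            Reaction({"U": 1, "V": 2}, {"V": 3},
                     RateLaw("mass_action", p.k1, 3), "cubic autocatalysis"),
            Reaction({"V": 1}, {}, RateLaw("mass_action", p.k2, 1),
                     "activator decay"),
            Reaction({}, {"U": 1}, RateLaw("zeroth_order", p.k3),
                     "substrate inflow"),
            Reaction({"U": 1}, {}, RateLaw("mass_action", p.k4, 1),
                     "substrate decay"),
        ],
        grid=GridSpec(p.nx, p.ny, p.lambda_),
    )


def spiral_inits(params: GrayScottParams):
    return [
        SpiralInit("rectangle_perturbation", tuple(params.rect),
                   {"V": params.v_perturb}),
        SpiralInit("half_plane_refractory", (0.5,),
                   {"U": params.u_refractory * params.u_background,
                    "V": params.v_refractory}),
    ]


def gray_scott_init(params: GrayScottParams) -> np.ndarray:
    """Ω = 1 initial field: stable homogeneous state + induction protocol."""
    grid = GridSpec(params.nx, params.ny, params.lambda_)
    vals = np.zeros((2, params.ny, params.nx))
    vals[0] = params.u_background
    return apply_spiral_inits(vals, grid, spiral_inits(params), ["U", "V"])


def build_gray_scott(params: GrayScottParams | None = None,
                     omega: float = 1.0):
    """Scaled network plus integer initial state at system size Ω.

    Raises a build error if the parameter point does not admit the
    configured number of homogeneous states (checked via the nullcline
    fixed-point solver).
    """
    from .nullclines import nullclines

    p = params if params is not None else default_params()
    net = gray_scott_network(p)
    fps = nullclines("gray_scott", p).fixed_points
    if len(fps) != p.n_fixed_points:
        raise ModelValidationError(
            f"parameter point admits {len(fps)} homogeneous states, "
            f"expected {p.n_fixed_points}")
    if not any(fp.stable for fp in fps):
        raise ModelValidationError("no stable homogeneous state")
    scaled = scale_network(net, omega)
    counts = np.floor(gray_scott_init(p) * omega + 0.5).astype(np.int64)
    return scaled, GridState(0.0, counts)
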