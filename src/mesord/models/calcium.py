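"""Single-pool intracellular Ca²⁺ wave model (Atri-type, Xenopus oocyte).

Cytosolic Ca²⁺ (c) is released from the endoplasmic reticulum through
IP₃-receptor channels, pumped back by a Michaelis-Menten SERCA sink, and
leaks in across the plasma membrane.  Each subvolume carries a number n of
*open* channels out of N receptors; channels open at a rate set by the fast
activation equilibrium (single Ca²⁺ site and IP₃ site bound) damped by the
cooperative two-site Ca²⁺ inhibition Hill term, and close on the slow
inactivation time scale τ_h.  IP₃ (p) diffuses and is slowly broken down.

Reaction channels (copy counts; concentrations converted with
ξ = 602.2·λ³ counts per μM):

    0 -> c                        leak, zeroth order, rate β
    c -> 0                        SERCA pump, MM law γ c/(k_γ + c)
    n -> n + c                    channel flux, k_f μ(p)(b + (1−b)c/(k₁+c)) n/N
    0 -> n   (capped at N)        opening, (N/τ_h)·k₂²/(k₂² + c²)
    n -> 0                        closing, rate 1/τ_h
    p -> 0                        IP₃ breakdown, rate k_p

whose deterministic limit is the classic single-pool model: with
h = n/N,  τ_h dh/dt = k₂²/(k₂²+c²) − h.
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
from .gray_scott import _load_defaults
from .spiral_init import SpiralInit, apply_spiral_inits

__all__ = ["CalciumParams", "calcium_network", "calcium_init",
           "build_calcium"]


@dataclass
class CalciumParams:
    """Rate constants in μM and seconds; converted to copy counts via
    ``counts_per_uM``."""

    k_flux: float = 16.2
    b: float = 0.03
    k_act: float = 1.2
    k_mu: float = 0.7
    gamma: float = 2.6
    k_gamma: float = 0.1
    k_inhib: float = 1.5
    tau_h: float = 2.0
    beta: float = 0.05
    k_p: float = 0.005
    n_channels: int = 20
    p_background: float = 0.855
    diffusivity_ca: float = 20.0
    diffusivity_ip3: float = 300.0
    domain_length: float = 250.0
    nx: int = 128
    ny: int = 128
    rect: tuple = (0.25, 0.45, 0.48, 0.55)
    c_perturb: float = 1.0
    c_refractory: float = 0.8
    n_refractory: float = 0.0

    @classmethod
    def from_file(cls, path=None) -> "CalciumParams":
        doc = (_load_defaults("calcium.yaml") if path is None
               else yaml.safe_load(open(path).read()))
        doc = dict(doc)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ModelValidationError(f"unknown parameters {sorted(unknown)}")
        doc["rect"] = tuple(doc.get("rect", cls.rect))
        return cls(**doc)

    @property
    def lambda_(self) -> float:
        return self.domain_length / self.nx

    @property
    def counts_per_uM(self) -> float:
        """Concentration base: 1 μM ≈ 602.2 particles/μm³ times the
        subvolume volume λ³."""
        return 602.2 * self.lambda_ ** 3

    @property
    def mu(self) -> float:
        """Resting IP₃ potentiation μ(p₀) = p₀/(k_μ + p₀)."""
        return self.p_background / (self.k_mu + self.p_background)

    def rest_state(self):
        """(c_rest, h_rest) in μM / fraction from the phase-plane solver."""
        from .nullclines import nullclines

        fps = nullclines("calcium", self).fixed_points
        stable = [fp for fp in fps if fp.stable]
        if not stable:
            raise ModelValidationError("no stable resting state")
        return min(stable, key=lambda fp: fp.x).point


def default_params() -> CalciumParams:
    return CalciumParams.from_file()


def calcium_network(params: CalciumParams) -> ReactionNetwork:
    p = params
    xi = p.counts_per_uM
    if min(p.k_flux, p.gamma, p.k_gamma, p.k_inhib, p.tau_h, p.k_act,
           p.k_mu) <= 0:
        raise ModelValidationError("rates and saturation constants must be > 0")
    return ReactionNetwork(
        species=[
            SpeciesSpec("c", p.diffusivity_ca, 0.0),
            SpeciesSpec("n", 0.0, 0.0),
            SpeciesSpec("p", p.diffusivity_ip3, p.p_background * xi),
        ],
        reactions=[
            Reaction({}, {"c": 1}, RateLaw("zeroth_order", p.beta * xi),
                     "membrane leak"),
            Reaction({"c": 1}, {},
                     RateLaw("mm_pump", p.gamma * xi,
                             params={"km": p.k_gamma * xi}),
                     "SERCA pump"),
            Reaction({"n": 1}, {"n": 1, "c": 1},
                     RateLaw("cooperative_flux", p.k_flux * xi / p.n_channels,
                             params={"k_act": p.k_act * xi, "b": p.b,
                                     "k_ip3": p.k_mu * xi,
                                     "ca_species": "c", "ip3_species": "p"}),
                     "IP3R channel flux"),
            Reaction({}, {"n": 1},
                     RateLaw("channel_equilibrium", p.n_channels / p.tau_h,
                             params={"k_inhib": p.k_inhib * xi,
                                     "n_max": float(p.n_channels),
                                     "ca_species": "c",
                                     "channel_species": "n"}),
                     "channel opening"),
            Reaction({"n": 1}, {}, RateLaw("linear_decay", 1.0 / p.tau_h),
                     "channel inactivation"),
            Reaction({"p": 1}, {}, RateLaw("linear_decay", p.k_p),
                     "IP3 breakdown"),
        ],
        grid=GridSpec(p.nx, p.ny, p.lambda_),
    )


def spiral_inits(params: CalciumParams, c_rest_counts: float,
                 n_rest_counts: float):
    xi = params.counts_per_uM
    return [
        SpiralInit("rectangle_perturbation", tuple(params.rect),
                   {"c": params.c_perturb * xi}),
        SpiralInit("half_plane_refractory", (0.5,),
                   {"c": params.c_refractory * xi,
                    "n": params.n_refractory}),
    ]


def calcium_init(params: CalciumParams) -> np.ndarray:
    """Ω = 1 initial field: resting state + Ca²⁺ overdensity rectangle +
    refractory (channels shut, Ca²⁺ elevated) right half."""
    p = params
    xi = p.counts_per_uM
    c_rest, h_rest = p.rest_state()
    grid = GridSpec(p.nx, p.ny, p.lambda_)
    vals = np.zeros((3, p.ny, p.nx))
    vals[0] = c_rest * xi
    vals[1] = h_rest * p.n_channels
    vals[2] = p.p_background * xi
    return apply_spiral_inits(vals, grid,
                              spiral_inits(p, c_rest * xi,
                                           h_rest * p.n_channels),
                              ["c", "n", "p"])


def build_calcium(params: CalciumParams | None = None, omega: float = 1.0):
    """Scaled 6-channel network plus integer initial state at system size Ω.

    The builder refuses initial states that violate the per-subvolume
    channel cap n ≤ N·Ω.
    """
    p = params if params is not None else default_params()
    net = calcium_network(p)
    scaled = scale_network(net, omega)
    counts = np.floor(calcium_init(p) * omega + 0.5).astype(np.int64)
    cap = int(round(p.n_channels * omega))
    if counts[1].max() > cap:
        raise ModelValidationError(
            f"initial open-channel count {counts[1].max()} exceeds the "
            f"per-subvolume cap {cap}")
    return scaled, GridState(0.0, counts)
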