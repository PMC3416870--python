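"""Reaction-network data model shared by the stochastic and deterministic engines.

A :class:`ReactionNetwork` is the single source of truth for a model: species
with diffusivities, reactions with rate laws, and the 2-D subvolume grid.
Scaling by the system-size parameter Ω produces a :class:`ScaledNetwork` whose
propensity constants follow the system-size-expansion convention

    k_scaled = k * Ω**(1 - n_mu)

for an ``n_mu``-th order mass-action reaction, while concentrations (copy
counts per subvolume) scale up as ``n = Ω * x``.  The deterministic mean-field
dynamics of the concentrations are invariant under this joint scaling; Ω only
controls the strength of the intrinsic fluctuations.

All quantities are carried in the per-subvolume copy-count representation:
copy counts are dimensionless, rate constants have dimension 1/time, and
diffusivities are in length²/time with the subvolume side ``lambda_`` setting
the length unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "InvalidParameterError",
    "UnsupportedLawError",
    "ModelValidationError",
    "NumericalSignalError",
    "RATE_LAW_KINDS",
    "SpeciesSpec",
    "RateLaw",
    "Reaction",
    "GridSpec",
    "ReactionNetwork",
    "ScaledNetwork",
    "GridState",
    "scale_rate",
    "scale_initial_counts",
    "validate_network",
]


class InvalidParameterError(ValueError):
    """A parameter is outside its admissible domain (e.g. Ω <= 0)."""


class UnsupportedLawError(ValueError):
    """A rate-law kind is not recognized by the engine."""


class ModelValidationError(ValueError):
    """A network failed structural validation before a run."""


class NumericalSignalError(ArithmeticError):
    """Non-finite propensities or field values were encountered."""


#: Recognized rate-law kinds.  ``mass_action`` covers arbitrary integer
#: stoichiometry with falling-factorial propensities; the named functional
#: forms implement the calcium-model pump/channel kinetics.
RATE_LAW_KINDS = (
    "mass_action",
    "zeroth_order",
    "linear_decay",
    "mm_pump",
    "cooperative_flux",
    "channel_equilibrium",
)

#: Extra parameters each non-mass-action kind requires.
_REQUIRED_PARAMS: Dict[str, tuple] = {
    "mass_action": (),
    "zeroth_order": (),
    "linear_decay": (),
    "mm_pump": ("km",),
    "cooperative_flux": ("k_act", "b", "k_ip3", "ca_species", "ip3_species"),
    "channel_equilibrium": ("k_inhib", "n_max", "ca_species", "channel_species"),
}


@dataclass
class SpeciesSpec:
    """One chemical species.

    Parameters
    ----------
    name
        Unique identifier within the network.
    diffusivity
        Macroscopic diffusion coefficient in length²/time.  ``0`` means the
        species is spatially pinned and never hops between subvolumes.
    initial_background
        Homogeneous background copy count per subvolume at Ω = 1 (a real
        number; multiplied by Ω and rounded when a run is initialized).
    """

    name: str
    diffusivity: float = 0.0
    initial_background: float = 0.0


@dataclass
class RateLaw:
    """Functional form of a reaction rate.

    ``base_constant`` is the Ω = 1 constant (units depend on the reaction
    order); ``n_mu`` is the number of reactant particles entering the
    propensity, which fixes the Ω-scaling exponent ``1 - n_mu``.  Named
    functional forms (``mm_pump``, ``cooperative_flux``,
    ``channel_equilibrium``) carry their shape parameters in ``params`` and
    scale by the general rule a(n) = Ω · v(n / Ω).
    """

    kind: str
    base_constant: float
    n_mu: int = 0
    params: Dict[str, object] = field(default_factory=dict)


@dataclass
class Reaction:
    """A single reaction channel: stoichiometry plus rate law."""

    reactants: Dict[str, int]
    products: Dict[str, int]
    rate_law: RateLaw
    label: str = ""


@dataclass
class GridSpec:
    """Regular 2-D grid of cubic subvolumes with reflecting boundaries."""

    nx: int
    ny: int
    lambda_: float = 1.0

    #: spatial dimensionality of the lattice (the domain is a 2-D sheet of
    #: cubic subvolumes, as in the simulations this package reproduces)
    d: int = 2

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx)


@dataclass
class ReactionNetwork:
    species: List[SpeciesSpec]
    reactions: List[Reaction]
    grid: GridSpec

    def species_index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(name)

    @property
    def species_names(self) -> List[str]:
        return [s.name for s in self.species]


@dataclass
class ScaledNetwork:
    """A network together with its system-size parameter Ω.

    ``scaled_constants[j]`` is the effective propensity constant of reaction
    ``j`` after Ω-scaling; Ω = 1 is the identity.
    """

    base: ReactionNetwork
    omega: float
    scaled_constants: np.ndarray

    @property
    def grid(self) -> GridSpec:
        return self.base.grid


@dataclass
class GridState:
    """Integer copy-count lattice per species at a simulation time.

    ``counts`` has shape ``(n_species, ny, nx)`` with species ordered as in
    the owning network.
    """

    time: float
    counts: np.ndarray

    def total(self, species_idx: Optional[int] = None):
        if species_idx is None:
            return self.counts.sum(axis=(1, 2))
        return int(self.counts[species_idx].sum())

    def copy(self) -> "GridState":
        return GridState(self.time, self.counts.copy())


def scale_rate(base_constant: float, n_mu: int, omega: float) -> float:
    """Scale a rate constant with the system size.

    For an ``n_mu``-th order reaction the propensity constant becomes
    ``base_constant * omega**(1 - n_mu)``: zeroth-order production scales up
    with Ω, first-order rates are unchanged, higher orders scale down.  This
    is exactly the scaling that leaves the deterministic concentration
    dynamics invariant when copy counts are scaled up by Ω.
    """
    if not (omega > 0):
        raise InvalidParameterError(f"omega must be positive, got {omega!r}")
    if n_mu < 0:
        raise InvalidParameterError(f"n_mu must be >= 0, got {n_mu!r}")
    if base_constant < 0:
        raise InvalidParameterError("base_constant must be >= 0")
    return base_constant * omega ** (1 - n_mu)


def scale_initial_counts(background: float, omega: float, shape: tuple) -> np.ndarray:
    """Integer lattice realizing a homogeneous background at system size Ω.

    The product ``background * omega`` is rounded deterministically to the
    nearest integer (ties up, not drawn from a distribution), so the Ω → ∞
    limit matches the deterministic initial condition exactly.
    """
    if background < 0:
        raise InvalidParameterError("background must be >= 0")
    if not (omega > 0):
        raise InvalidParameterError("omega must be positive")
    value = int(np.floor(background * omega + 0.5))
    return np.full(shape, value, dtype=np.int64)


def scale_network(net: ReactionNetwork, omega: float) -> ScaledNetwork:
    """Attach Ω to a network, precomputing scaled propensity constants.

    Mass-action (and zeroth-order / linear-decay) constants follow
    Ω**(1 - n_mu); the named concentration-form laws keep their base constant
    and are evaluated as a(n) = Ω · v(n/Ω) at propensity time.
    """
    if not (omega > 0):
        raise InvalidParameterError("omega must be positive")
    problems = validate_network(net)
    if problems:
        raise ModelValidationError("; ".join(problems))
    consts = np.empty(len(net.reactions))
    for j, rxn in enumerate(net.reactions):
        law = rxn.rate_law
        if law.kind in ("mass_action", "zeroth_order", "linear_decay"):
            if law.params.get("no_scale"):
                # e.g. fast helper conversions: kept dominant at every Ω
                consts[j] = law.base_constant
            else:
                consts[j] = scale_rate(law.base_constant, law.n_mu, omega)
        else:
            consts[j] = law.base_constant
    return ScaledNetwork(base=net, omega=omega, scaled_constants=consts)


def _effective_n_mu(rxn: Reaction) -> int:
    return int(sum(rxn.reactants.values()))


def validate_network(net: ReactionNetwork) -> List[str]:
    """Return a list of invariant violations (empty iff the network is valid)."""
    problems: List[str] = []
    names = [s.name for s in net.species]
    if len(set(names)) != len(names):
        problems.append("species names are not unique")
    for s in net.species:
        if s.diffusivity < 0:
            problems.append(f"species {s.name!r}: negative diffusivity")
        if s.initial_background < 0:
            problems.append(f"species {s.name!r}: negative initial background")
    if net.grid.nx < 1 or net.grid.ny < 1:
        problems.append("grid must have nx, ny >= 1")
    if not (net.grid.lambda_ > 0):
        problems.append("grid lambda must be positive")
    for j, rxn in enumerate(net.reactions):
        tag = rxn.label or f"reaction {j}"
        if not rxn.reactants and not rxn.products:
            problems.append(f"{tag}: both reactants and products empty")
        for side in (rxn.reactants, rxn.products):
            for name, stoich in side.items():
                if name not in names:
                    problems.append(f"{tag}: unknown species {name!r}")
                if stoich < 0:
                    problems.append(f"{tag}: negative stoichiometry for {name!r}")
        law = rxn.rate_law
        if law.kind not in RATE_LAW_KINDS:
            problems.append(f"{tag}: unknown rate-law kind {law.kind!r}")
            continue
        if law.base_constant < 0:
            problems.append(f"{tag}: negative rate constant")
        for p in _REQUIRED_PARAMS[law.kind]:
            if p not in law.params:
                problems.append(f"{tag}: {law.kind} law missing param {p!r}")
        for key in ("ca_species", "ip3_species", "channel_species"):
            if key in law.params and law.params[key] not in names:
                problems.append(f"{tag}: {key} references unknown species "
                                f"{law.params[key]!r}")
        if law.kind == "mass_action" and law.n_mu != _effective_n_mu(rxn):
            problems.append(f"{tag}: n_mu={law.n_mu} inconsistent with reactant "
                            f"stoichiometry ({_effective_n_mu(rxn)})")
        if law.kind == "linear_decay":
            if _effective_n_mu(rxn) != 1:
                problems.append(f"{tag}: linear_decay requires exactly one "
                                "reactant particle")
    return problems
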