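"""Exact Gillespie direct-method simulation of the reaction subsystem.

Reactions inside one well-stirred subvolume form a jump process governed by
the chemical master equation; the direct method samples it exactly by drawing
exponential waiting times at the total propensity and picking the firing
channel categorically.  :func:`ssa_advance` evolves a cell for a fixed time
budget, as required by the multiparticle operator-splitting loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .network import (
    NumericalSignalError,
    Reaction,
    ScaledNetwork,
    UnsupportedLawError,
    scale_network,
)

__all__ = ["CompiledNetwork", "compile_network", "propensity", "ssa_advance"]

_KIND_CODES = {
    "mass_action": _kernels.MASS_ACTION,
    "zeroth_order": _kernels.ZEROTH_ORDER,
    "linear_decay": _kernels.LINEAR_DECAY,
    "mm_pump": _kernels.MM_PUMP,
    "cooperative_flux": _kernels.COOPERATIVE_FLUX,
    "channel_equilibrium": _kernels.CHANNEL_EQUILIBRIUM,
}

#: number of per-reaction parameter slots handed to the kernels
_NPAR = 8


@dataclass
class CompiledNetwork:
    """Flat array encoding of a :class:`~mesord.network.ScaledNetwork`."""

    omega: float
    kinds: np.ndarray          # (nr,) int64 kind codes
    consts: np.ndarray         # (nr,) float64 scaled constants
    stoich_r: np.ndarray       # (nr, ns) int64 reactant stoichiometry
    stoich_change: np.ndarray  # (nr, ns) int64 products - reactants
    par: np.ndarray            # (nr, _NPAR) float64 law parameters

    @property
    def n_reactions(self) -> int:
        return self.kinds.shape[0]


def compile_network(net: ScaledNetwork) -> CompiledNetwork:
    base = net.base
    ns = len(base.species)
    nr = len(base.reactions)
    kinds = np.zeros(nr, dtype=np.int64)
    consts = np.asarray(net.scaled_constants, dtype=np.float64).copy()
    stoich_r = np.zeros((nr, ns), dtype=np.int64)
    stoich_change = np.zeros((nr, ns), dtype=np.int64)
    par = np.zeros((nr, _NPAR), dtype=np.float64)
    for j, rxn in enumerate(base.reactions):
        law = rxn.rate_law
        try:
            kinds[j] = _KIND_CODES[law.kind]
        except KeyError:
            raise UnsupportedLawError(f"unknown rate-law kind {law.kind!r}")
        for name, nu in rxn.reactants.items():
            stoich_r[j, base.species_index(name)] = nu
            stoich_change[j, base.species_index(name)] -= nu
        for name, nu in rxn.products.items():
            stoich_change[j, base.species_index(name)] += nu
        p = law.params
        if law.kind in ("linear_decay", "mm_pump", "cooperative_flux"):
            # index of the single consumed / catalytic reactant
            par[j, 6] = float(base.species_index(next(iter(rxn.reactants))))
        if law.kind == "mm_pump":
            par[j, 0] = float(p["km"])
        elif law.kind == "cooperative_flux":
            par[j, 0] = float(p["k_act"])
            par[j, 1] = float(p["b"])
            par[j, 2] = float(p["k_ip3"])
            par[j, 3] = float(base.species_index(p["ca_species"]))
            par[j, 4] = float(base.species_index(p["ip3_species"]))
        elif law.kind == "channel_equilibrium":
            par[j, 0] = float(p["k_inhib"])
            par[j, 1] = float(p["n_max"])
            par[j, 3] = float(base.species_index(p["ca_species"]))
            par[j, 4] = float(base.species_index(p["channel_species"]))
    return CompiledNetwork(omega=float(net.omega), kinds=kinds, consts=consts,
                           stoich_r=stoich_r, stoich_change=stoich_change,
                           par=par)


def propensity(reaction: Reaction, counts: dict, omega: float = 1.0) -> float:
    """Propensity (events/time) of a single reaction at given copy counts.

    ``counts`` maps species names to non-negative integers; species absent
    from the map default to 0.  The reaction is evaluated inside a minimal
    scaled network, so mass-action constants are Ω-scaled here.
    """
    from .network import GridSpec, ReactionNetwork, SpeciesSpec

    names = set(counts) | set(reaction.reactants) | set(reaction.products)
    for key in ("ca_species", "ip3_species", "channel_species"):
        if key in reaction.rate_law.params:
            names.add(reaction.rate_law.params[key])
    species = [SpeciesSpec(n) for n in sorted(names)]
    net = ReactionNetwork(species=species, reactions=[reaction],
                          grid=GridSpec(1, 1))
    comp = compile_network(scale_network(net, omega))
    local = np.array([int(counts.get(s.name, 0)) for s in species],
                     dtype=np.int64)
    out = np.empty(1, dtype=np.float64)
    status = _kernels.propensities(local, comp.kinds, comp.consts,
                                   comp.stoich_r, comp.par, comp.omega, out)
    if status != 0:
        raise NumericalSignalError("non-finite propensity")
    return float(out[0])


def ssa_advance(counts, compiled: CompiledNetwork, duration: float,
                seed: int | None = None) -> np.ndarray:
    """Evolve copy counts of one cell by direct-method SSA for ``duration``.

    ``counts`` is a 1-D integer vector ordered as the network's species; a
    fresh array is returned.  If ``seed`` is given the kernel RNG is
    re-seeded first (otherwise the current stream continues).
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if seed is not None:
        _kernels.seed_rng(seed)
    local = np.asarray(counts, dtype=np.int64).copy()
    a = np.empty(compiled.n_reactions, dtype=np.float64)
    status = _kernels.ssa_cell(local, compiled.kinds, compiled.consts,
                               compiled.stoich_r, compiled.stoich_change,
                               compiled.par, compiled.omega, float(duration), a)
    if status != 0:
        raise NumericalSignalError("non-finite propensity during SSA")
    return local
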