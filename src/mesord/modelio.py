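"""Model-file (YAML/JSON) and trajectory (HDF5) input/output.

A model document mirrors :class:`~mesord.network.ReactionNetwork`::

    species:
      - {name: U, diffusivity: 0.0, initial_background: 10.0}
    reactions:
      - reactants: {U: 1, V: 2}
        products: {V: 3}
        rate_law: {kind: mass_action, base_constant: 1.0, n_mu: 3}
        label: autocatalysis
    grid: {nx: 128, ny: 128, lambda: 1.0}

Round trips are lossless.  Trajectories go to HDF5 with one dataset per
(snapshot, species) lattice plus config/seed/model-hash attributes, so every
stored run can be reproduced from its file alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import yaml

from .network import (
    GridSpec,
    GridState,
    ModelValidationError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    SpeciesSpec,
    validate_network,
)

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "load_model",
    "save_model",
    "save_trajectory",
    "load_trajectory",
]

_SPECIES_KEYS = {"name", "diffusivity", "initial_background"}
_REACTION_KEYS = {"reactants", "products", "rate_law", "label"}
_LAW_KEYS = {"kind", "base_constant", "n_mu", "params"}
_GRID_KEYS = {"nx", "ny", "lambda"}


def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "species": [
            {"name": s.name, "diffusivity": float(s.diffusivity),
             "initial_background": float(s.initial_background)}
            for s in net.species
        ],
        "reactions": [
            {"reactants": {k: int(v) for k, v in r.reactants.items()},
             "products": {k: int(v) for k, v in r.products.items()},
             "rate_law": {"kind": r.rate_law.kind,
                          "base_constant": float(r.rate_law.base_constant),
                          "n_mu": int(r.rate_law.n_mu),
                          "params": dict(r.rate_law.params)},
             "label": r.label}
            for r in net.reactions
        ],
        "grid": {"nx": net.grid.nx, "ny": net.grid.ny,
                 "lambda": float(net.grid.lambda_)},
    }


def _check_keys(doc: dict, allowed: set, where: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ModelValidationError(
            f"{where}: unknown keys {sorted(unknown)}")


def network_from_dict(doc: dict) -> ReactionNetwork:
    _check_keys(doc, {"species", "reactions", "grid"}, "model")
    for need in ("species", "reactions", "grid"):
        if need not in doc:
            raise ModelValidationError(f"model: missing section {need!r}")
    species = []
    for i, s in enumerate(doc["species"]):
        _check_keys(s, _SPECIES_KEYS, f"species[{i}]")
        if "name" not in s:
            raise ModelValidationError(f"species[{i}]: missing name")
        species.append(SpeciesSpec(
            name=s["name"], diffusivity=float(s.get("diffusivity", 0.0)),
            initial_background=float(s.get("initial_background", 0.0))))
    reactions = []
    for i, r in enumerate(doc["reactions"]):
        where = f"reactions[{i}]"
        _check_keys(r, _REACTION_KEYS, where)
        law_doc = r.get("rate_law")
        if law_doc is None:
            raise ModelValidationError(f"{where}: missing rate_law")
        _check_keys(law_doc, _LAW_KEYS, f"{where}.rate_law")
        if "kind" not in law_doc or "base_constant" not in law_doc:
            raise ModelValidationError(
                f"{where}.rate_law: kind and base_constant are required")
        law = RateLaw(kind=law_doc["kind"],
                      base_constant=float(law_doc["base_constant"]),
                      n_mu=int(law_doc.get("n_mu", 0)),
                      params=dict(law_doc.get("params", {})))
        reactions.append(Reaction(
            reactants={k: int(v) for k, v in (r.get("reactants") or {}).items()},
            products={k: int(v) for k, v in (r.get("products") or {}).items()},
            rate_law=law, label=r.get("label", "")))
    g = doc["grid"]
    _check_keys(g, _GRID_KEYS, "grid")
    grid = GridSpec(nx=int(g["nx"]), ny=int(g["ny"]),
                    lambda_=float(g.get("lambda", 1.0)))
    net = ReactionNetwork(species=species, reactions=reactions, grid=grid)
    problems = validate_network(net)
    if problems:
        raise ModelValidationError("; ".join(problems))
    return net


def load_model(path) -> ReactionNetwork:
    """Load and validate a YAML/JSON model document."""
    path = Path(path)
    text = path.read_text()
    doc = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text))
    if not isinstance(doc, dict):
        raise ModelValidationError(f"{path}: not a mapping document")
    try:
        return network_from_dict(doc)
    except ModelValidationError as exc:
        raise ModelValidationError(f"{path}: {exc}") from None


def save_model(net: ReactionNetwork, path) -> None:
    path = Path(path)
    doc = network_to_dict(net)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def save_trajectory(traj, path) -> None:
    """Write a trajectory (stochastic integer or deterministic float) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        cfg = traj.config
        f.attrs["t_end"] = cfg.t_end
        f.attrs["master_seed"] = int(cfg.master_seed)
        f.attrs["omega"] = float(cfg.omega)
        f.attrs["snapshot_times"] = np.asarray(list(cfg.snapshot_times), float)
        f.attrs["model_hash"] = traj.provenance.get("model_hash", "")
        f.attrs["deterministic"] = bool(traj.provenance.get("deterministic",
                                                            False))
        for i, snap in enumerate(traj.snapshots):
            grp = f.create_group(f"snapshot_{i:04d}")
            grp.attrs["time"] = snap.time
            data = snap.counts if hasattr(snap, "counts") else snap.values
            grp.create_dataset("lattice", data=data)


def load_trajectory(path) -> Tuple:
    """Invert :func:`save_trajectory`; returns (snapshots, attrs)."""
    import h5py

    from .pde import Field

    snapshots = []
    with h5py.File(path, "r") as f:
        for need in ("master_seed", "model_hash", "omega"):
            if need not in f.attrs:
                raise IOError(f"{path}: missing attribute {need!r}")
        attrs = {k: f.attrs[k] for k in f.attrs}
        for key in sorted(k for k in f if k.startswith("snapshot_")):
            grp = f[key]
            if "lattice" not in grp:
                raise IOError(f"{path}: corrupt snapshot {key!r} "
                              "(missing dataset 'lattice')")
            data = grp["lattice"][...]
            t = float(grp.attrs["time"])
            if np.issubdtype(data.dtype, np.integer):
                snapshots.append(GridState(t, data))
            else:
                snapshots.append(Field(t, data))
    return snapshots, attrs
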