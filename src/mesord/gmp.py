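"""Gillespie-multiparticle engine: operator-split reaction/diffusion loop.

One global step of length τ (set by the fastest-diffusing species) first
advances the reaction subsystem in every subvolume independently with the
exact SSA, then performs synchronous multiparticle diffusion for each species
whose hop is due.  Identical (seed, config, model) triples give identical
trajectories.
"""

from __future__ import annotations

import hashlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import _kernels
from .diffusion import build_schedule
from .network import (
    GridState,
    ModelValidationError,
    ReactionNetwork,
    ScaledNetwork,
    scale_network,
    validate_network,
)
from .ssa import compile_network

__all__ = ["RunConfig", "Trajectory", "gmp_run", "sweep", "derive_seed"]


@dataclass
class RunConfig:
    t_end: float
    snapshot_times: Sequence[float] = field(default_factory=list)
    master_seed: int = 0
    omega: float = 1.0
    replicate_count: int = 1
    #: explicit step for models where no species diffuses (otherwise the
    #: diffusion step sets the loop cadence and this field is ignored)
    dt: Optional[float] = None

    def validate(self) -> None:
        ts = list(self.snapshot_times)
        if any(t < 0 or t > self.t_end for t in ts):
            raise ValueError("snapshot times must lie in [0, t_end]")
        if sorted(ts) != ts:
            raise ValueError("snapshot times must be sorted")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass
class Trajectory:
    """Time-stamped snapshots plus the config and provenance of the run."""

    snapshots: List[GridState]
    config: RunConfig
    provenance: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def final(self) -> GridState:
        return self.snapshots[-1]


def model_hash(net: ReactionNetwork) -> str:
    from .modelio import network_to_dict
    import json

    blob = json.dumps(network_to_dict(net), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()


def derive_seed(master_seed: int, *indices: int) -> int:
    """Derive an independent 31-bit seed from a master seed and run indices."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(indices))
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def gmp_run(net: ScaledNetwork, init: GridState, config: RunConfig,
            log: Optional[dict] = None) -> Trajectory:
    """Run the coupled SSA-reaction / multiparticle-diffusion loop.

    Snapshots are recorded at the first loop boundary at or after each
    requested time (the recorded time is stored on the snapshot).  ``log``,
    if given, is filled with the realized diffusion schedule and step count.
    """
    config.validate()
    problems = validate_network(net.base)
    if problems:
        raise ModelValidationError("; ".join(problems))
    if init.counts.shape != (len(net.base.species),) + net.grid.shape:
        raise ModelValidationError("initial state does not match grid")
    if np.any(init.counts < 0):
        raise ModelValidationError("initial counts must be non-negative")

    any_diffusing = any(s.diffusivity > 0 for s in net.base.species)
    if any_diffusing:
        sched = build_schedule(net)
        tau = sched.tau
        multiples = sched.multiples
    else:
        if config.dt is None or config.dt <= 0:
            raise ModelValidationError(
                "all species pinned: config.dt must set the loop step")
        tau = config.dt
        multiples = [0] * len(net.base.species)
        sched = None

    comp = compile_network(net)
    _kernels.seed_rng(int(config.master_seed) % (2 ** 31))

    state = GridState(0.0, init.counts.astype(np.int64).copy())
    pending = list(config.snapshot_times)
    snapshots: List[GridState] = []

    def record_due():
        while pending and state.time >= pending[0] - 1e-12:
            snapshots.append(state.copy())
            pending.pop(0)

    record_due()
    step = 0
    while state.time < config.t_end - 1e-12:
        dt = min(tau, config.t_end - state.time)
        status = _kernels.ssa_all_cells(
            state.counts, comp.kinds, comp.consts, comp.stoich_r,
            comp.stoich_change, comp.par, comp.omega, dt)
        if status != 0:
            raise ArithmeticError("non-finite propensity encountered")
        step += 1
        for s_idx, m in enumerate(multiples):
            if m > 0 and step % m == 0:
                state.counts[s_idx] = _kernels.diffuse_lattice(
                    state.counts[s_idx])
        state.time += dt
        record_due()
    while pending:  # t_end boundary snapshots
        snapshots.append(state.copy())
        pending.pop(0)

    if log is not None:
        log["steps"] = step
        log["tau"] = tau
        if sched is not None:
            log["hop_multiples"] = list(sched.multiples)
            log["effective_D"] = list(sched.effective_D)
    prov = {"model_hash": model_hash(net.base), "omega": net.omega}
    return Trajectory(snapshots=snapshots, config=config, provenance=prov)


def _sweep_worker(payload):
    (net, omega, oi, ri, config) = payload
    from .network import scale_initial_counts

    scaled = scale_network(net, omega)
    shape = net.grid.shape
    counts = np.stack([scale_initial_counts(s.initial_background, omega, shape)
                       for s in net.species])
    cfg = RunConfig(t_end=config.t_end,
                    snapshot_times=list(config.snapshot_times),
                    master_seed=derive_seed(config.master_seed, oi, ri),
                    omega=omega, dt=config.dt)
    return gmp_run(scaled, GridState(0.0, counts), cfg)


def sweep(net: ReactionNetwork, omegas: Sequence[float], config: RunConfig,
          n_workers: int = 1, init_factory=None):
    """Independent trajectories for each (Ω, replicate) pair.

    Each run gets its own seed derived from ``(master_seed, Ω index,
    replicate index)``, so results are order-stable regardless of worker
    scheduling.  ``init_factory(omega) -> GridState`` overrides the
    homogeneous background initialization.  Returns ``(results, failures)``
    where ``results[i][r]`` is the trajectory for ``omegas[i]``, replicate
    ``r``, and failures is a list of ``(omega, replicate, message)`` for
    runs that raised.
    """
    if not len(omegas):
        raise ValueError("omegas must be non-empty")
    config.validate()
    jobs = []
    for oi, om in enumerate(omegas):
        for ri in range(config.replicate_count):
            jobs.append((oi, ri, om))
    results = [[None] * config.replicate_count for _ in omegas]
    failures = []

    def run_job(oi, ri, om):
        if init_factory is not None:
            scaled = scale_network(net, om)
            init = init_factory(om)
            cfg = RunConfig(t_end=config.t_end,
                            snapshot_times=list(config.snapshot_times),
                            master_seed=derive_seed(config.master_seed, oi, ri),
                            omega=om, dt=config.dt)
            return gmp_run(scaled, init, cfg)
        return _sweep_worker((net, om, oi, ri, config))

    if n_workers <= 1 or init_factory is not None:
        for oi, ri, om in jobs:
            try:
                results[oi][ri] = run_job(oi, ri, om)
            except Exception as exc:  # noqa: BLE001 - reported, not hidden
                failures.append((om, ri, str(exc)))
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            futs = {pool.submit(_sweep_worker, (net, om, oi, ri, config)):
                    (oi, ri, om) for oi, ri, om in jobs}
            for fut, (oi, ri, om) in futs.items():
                try:
                    results[oi][ri] = fut.result()
                except Exception as exc:  # noqa: BLE001
                    failures.append((om, ri, str(exc)))
    return results, failures
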