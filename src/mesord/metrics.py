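"""Quantifying the stochastic-to-deterministic transition.

The central comparison is the Pearson correlation ("coherence") between a
stochastic snapshot and the matching deterministic field.  Fields are block
averaged (default 2×2) before correlating to suppress per-subvolume shot
noise, mirroring how density maps are compared at figure resolution.  A
transition curve collects coherence against Ω; as Ω grows the stochastic
pattern locks onto the deterministic one and the curve rises towards 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["field_stats", "block_average", "coherence", "transition_curve",
           "UndefinedCoherenceError"]


class UndefinedCoherenceError(ArithmeticError):
    """Coherence is undefined when one field has zero spatial variance."""


def field_stats(state) -> pd.DataFrame:
    """Spatial mean, variance and total per species of a state or field.

    Accepts a :class:`~mesord.network.GridState`, :class:`~mesord.pde.Field`
    or a bare ``(n_species, ny, nx)`` array.
    """
    data = getattr(state, "counts", None)
    if data is None:
        data = getattr(state, "values", state)
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    return pd.DataFrame({
        "mean": data.mean(axis=(1, 2)),
        "variance": data.var(axis=(1, 2)),
        "total": data.sum(axis=(1, 2)),
    })


def block_average(field: np.ndarray, block: int) -> np.ndarray:
    """Average a 2-D lattice over non-overlapping block×block tiles.

    Trailing rows/columns that do not fill a block are dropped.
    """
    if block <= 1:
        return np.asarray(field, dtype=float)
    a = np.asarray(field, dtype=float)
    ny, nx = a.shape
    ny2, nx2 = ny // block, nx // block
    a = a[:ny2 * block, :nx2 * block]
    return a.reshape(ny2, block, nx2, block).mean(axis=(1, 3))


def _lattice(state, species_idx: int) -> np.ndarray:
    data = getattr(state, "counts", None)
    if data is None:
        data = getattr(state, "values", state)
    data = np.asarray(data, dtype=float)
    return data if data.ndim == 2 else data[species_idx]


def coherence(stoch, det, species_idx: int = 0, block: int = 2) -> float:
    """Pearson correlation between stochastic and deterministic lattices.

    Both fields are block averaged first (``block=1`` disables smoothing).
    The value is invariant under common affine rescaling of either field.
    """
    a = block_average(_lattice(stoch, species_idx), block)
    b = block_average(_lattice(det, species_idx), block)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCoherenceError("zero-variance field")
    return float(np.dot(a, b) / (na * nb))


def transition_curve(trajectories_by_omega, det_reference, omegas: Sequence,
                     species_idx: int = 0, block: int = 2,
                     snapshot: int = -1, n_boot: int = 1000,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Coherence-vs-Ω table for an ensemble of stochastic runs.

    ``trajectories_by_omega[i]`` is the replicate list for ``omegas[i]``;
    the chosen snapshot of each is correlated against the same snapshot of
    the deterministic reference.  Confidence intervals are percentile
    bootstrap over replicates (omitted for a single replicate).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    det_snap = det_reference.snapshots[snapshot]
    rows = []
    for om, reps in zip(omegas, trajectories_by_omega):
        vals = np.array([
            coherence(tr.snapshots[snapshot], det_snap, species_idx, block)
            for tr in reps if tr is not None])
        row = {"omega": om, "mean_coherence": vals.mean(),
               "n_replicates": len(vals)}
        if len(vals) > 1:
            boots = np.array([
                vals[rng.integers(0, len(vals), len(vals))].mean()
                for _ in range(n_boot)])
            row["ci_low"], row["ci_high"] = np.percentile(boots, [2.5, 97.5])
        else:
            row["ci_low"] = row["ci_high"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
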