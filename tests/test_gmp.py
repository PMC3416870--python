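"""Coupled GMP loop: determinism, splitting consistency, sweeps."""

import numpy as np
import pytest
from scipy import stats

from mesord._kernels import seed_rng
from mesord.gmp import RunConfig, derive_seed, gmp_run, sweep
from mesord.network import (GridSpec, GridState, ModelValidationError,
                            RateLaw, Reaction, ReactionNetwork, SpeciesSpec,
                            scale_network)
from mesord.ssa import compile_network, ssa_advance


def _state(net, rng=None, background=None):
    shape = (len(net.species),) + net.grid.shape
    if rng is None:
        vals = np.full(shape, 5, dtype=np.int64)
    else:
        vals = rng.integers(0, 20, size=shape).astype(np.int64)
    if background is not None:
        vals[:] = background
    return GridState(0.0, vals)


@pytest.fixture
def reacting_diffusing_net():
    return ReactionNetwork(
        species=[SpeciesSpec("A", 1.0, 5.0), SpeciesSpec("B", 0.5, 2.0)],
        reactions=[
            Reaction({"A": 1}, {"B": 1}, RateLaw("mass_action", 0.4, 1)),
            Reaction({"B": 1}, {}, RateLaw("mass_action", 0.1, 1)),
            Reaction({}, {"A": 1}, RateLaw("zeroth_order", 1.0)),
        ],
        grid=GridSpec(8, 8, 1.0))


def test_identical_seed_gives_byte_identical_trajectories(
        reacting_diffusing_net, rng):
    net = scale_network(reacting_diffusing_net, 1.0)
    init = _state(reacting_diffusing_net, rng)
    cfg = RunConfig(t_end=2.0, snapshot_times=[1.0, 2.0], master_seed=99)
    t1 = gmp_run(net, init.copy(), cfg)
    t2 = gmp_run(net, init.copy(), cfg)
    for s1, s2 in zip(t1.snapshots, t2.snapshots):
        assert np.array_equal(s1.counts, s2.counts)
    t3 = gmp_run(net, init.copy(),
                 RunConfig(t_end=2.0, snapshot_times=[1.0, 2.0],
                           master_seed=100))
    assert not np.array_equal(t1.final.counts, t3.final.counts)


def test_diffusion_only_run_conserves_every_species(diffusion_only_net, rng):
    net = diffusion_only_net(D=1.0, nx=16, ny=16)
    scaled = scale_network(net, 1.0)
    init = _state(net, rng)
    totals = init.counts.sum(axis=(1, 2))
    cfg = RunConfig(t_end=5.0, snapshot_times=[1.0, 3.0, 5.0], master_seed=4)
    traj = gmp_run(scaled, init, cfg)
    for snap in traj.snapshots:
        np.testing.assert_array_equal(snap.counts.sum(axis=(1, 2)), totals)


def test_invalid_model_rejected_before_stepping(reacting_diffusing_net):
    net = scale_network(reacting_diffusing_net, 1.0)
    bad = reacting_diffusing_net.reactions[0]
    bad.reactants = {"missing": 1}
    with pytest.raises(ModelValidationError):
        gmp_run(net, _state(reacting_diffusing_net),
                RunConfig(t_end=1.0, snapshot_times=[1.0]))


def test_reaction_only_grid_reduces_to_pure_ssa(immigration_death):
    """On a 1x1 grid the operator-split loop must be distributionally
    identical to plain SSA (two-sample KS, alpha = 0.01)."""
    net, a, k = immigration_death
    scaled = scale_network(net, 1.0)
    comp = compile_network(scaled)
    t_end, reps = 6.0, 4000
    seed_rng(1234)
    direct = np.array([ssa_advance([0], comp, t_end)[0] for _ in range(reps)])
    via_gmp = []
    for r in range(reps // 10):
        cfg = RunConfig(t_end=t_end, snapshot_times=[t_end],
                        master_seed=derive_seed(7, r), dt=0.5)
        init = GridState(0.0, np.zeros((1, 1, 1), dtype=np.int64))
        via_gmp.append(gmp_run(scaled, init, cfg).final.counts[0, 0, 0])
    res = stats.ks_2samp(direct, np.array(via_gmp))
    assert res.pvalue > 0.01


def test_two_cell_splitting_matches_exact_hybrid_mean():
    """Decay + hopping on a 1x2 grid: the ensemble mean follows the exact
    per-step linear map (decay factor then mixing matrix) within 3 SE.

    On a 1x2 grid a particle hops to the other cell with probability 1/4
    per global step (two directions rejected, one stays), so the mean obeys
    n(s+1) = M (e^{-k tau} n(s)) with M = [[3/4, 1/4], [1/4, 3/4]]; this
    equals the 2-compartment continuum ODE only in the fine-grid limit.
    """
    k, D, n0 = 0.3, 1.0, 200
    net = ReactionNetwork(
        species=[SpeciesSpec("A", D, 0.0)],
        reactions=[Reaction({"A": 1}, {}, RateLaw("mass_action", k, 1))],
        grid=GridSpec(2, 1, 1.0))
    scaled = scale_network(net, 1.0)
    tau = 0.25
    steps = 4
    M = np.array([[0.75, 0.25], [0.25, 0.75]])
    mean = np.array([n0, 0.0])
    for _ in range(steps):
        mean = M @ (np.exp(-k * tau) * mean)
    reps = 10_000
    seed_rng(2024)
    finals = np.empty((reps, 2))
    init = np.zeros((1, 1, 2), dtype=np.int64)
    init[0, 0, 0] = n0
    cfg_t = steps * tau
    for r in range(reps):
        traj = gmp_run(scaled, GridState(0.0, init.copy()),
                       RunConfig(t_end=cfg_t, snapshot_times=[cfg_t],
                                 master_seed=derive_seed(11, r)))
        finals[r] = traj.final.counts[0, 0]
    se = finals.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(finals.mean(axis=0) - mean) < 3 * se + 1e-9)


def test_sweep_single_omega_matches_direct_run(immigration_death):
    net, a, k = immigration_death
    cfg = RunConfig(t_end=3.0, snapshot_times=[3.0], master_seed=5, dt=0.5)
    results, failures = sweep(net, [1.0], cfg)
    assert not failures
    direct_cfg = RunConfig(t_end=3.0, snapshot_times=[3.0],
                           master_seed=derive_seed(5, 0, 0), omega=1.0,
                           dt=0.5)
    init = GridState(0.0, np.zeros((1, 1, 1), dtype=np.int64))
    direct = gmp_run(scale_network(net, 1.0), init, direct_cfg)
    assert np.array_equal(results[0][0].final.counts, direct.final.counts)


def test_sweep_replicates_are_independent(immigration_death):
    net, a, k = immigration_death
    cfg = RunConfig(t_end=5.0, snapshot_times=[5.0], master_seed=5,
                    replicate_count=2, dt=0.5)
    results, failures = sweep(net, [1.0, 10.0], cfg)
    assert not failures
    assert not np.array_equal(results[0][0].final.counts,
                              results[0][1].final.counts)
    # scaling: the omega=10 run carries ~10x the particles
    assert results[1][0].final.counts.sum() > 3 * results[0][0].final.counts.sum()


def test_sweep_reports_partial_failures(immigration_death):
    net, a, k = immigration_death
    cfg = RunConfig(t_end=1.0, snapshot_times=[1.0], master_seed=5, dt=0.5)

    def bad_init(omega):
        if omega > 5:
            raise RuntimeError("boom")
        return GridState(0.0, np.zeros((1, 1, 1), dtype=np.int64))

    results, failures = sweep(net, [1.0, 10.0], cfg, init_factory=bad_init)
    assert results[0][0] is not None
    assert results[1][0] is None
    assert len(failures) == 1 and failures[0][0] == 10.0
    assert "boom" in failures[0][2]


def test_snapshot_semantics_first_boundary_at_or_after():
    net = ReactionNetwork([SpeciesSpec("A", 1.0, 3.0)], [],
                          GridSpec(4, 4, 1.0))
    scaled = scale_network(net, 1.0)
    init = GridState(0.0, np.full((1, 4, 4), 3, dtype=np.int64))
    # tau = 0.25; requesting t=0.3 must record at the 0.5 boundary
    cfg = RunConfig(t_end=1.0, snapshot_times=[0.0, 0.3, 1.0], master_seed=1)
    traj = gmp_run(scaled, init, cfg)
    times = [s.time for s in traj.snapshots]
    assert times == pytest.approx([0.0, 0.5, 1.0])
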