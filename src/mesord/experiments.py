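"""Study protocols: the quantitative experiments behind the package's claims.

Each function runs one self-contained experiment from scratch — generating
its inputs, running the stochastic engine and/or its deterministic twin, and
measuring the result — and returns a flat dict of numbers.  The reduced
problem sizes (64–128 grids, hundreds of replicates, Ω up to 250) are chosen
so a complete verification pass runs on a single CPU in minutes; the methods
note discusses what these scales do and do not probe.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import _kernels
from .diffusion import global_timestep
from .gmp import RunConfig, derive_seed, gmp_run
from .metrics import UndefinedCoherenceError, coherence
from .network import (GridSpec, GridState, RateLaw, Reaction,
                      ReactionNetwork, SpeciesSpec, scale_network)
from .pde import Field, integrate_reactions, laplacian_step, pde_run
from .ssa import compile_network, ssa_advance

__all__ = [
    "diffusion_experiment",
    "ssa_experiment",
    "boundary_experiment",
    "omega_convergence_experiment",
    "deterministic_solver_experiment",
    "self_convergence_experiment",
    "helper_reaction_experiment",
    "mean_field_fidelity_experiment",
    "gray_scott_transition_experiment",
    "calcium_structure_experiment",
]


def _seed(master: int, k: int) -> int:
    return derive_seed(master, k)


def diffusion_experiment(seed: int = 0) -> dict:
    """Diffusion-only GMP on 64x64: exact conservation over 10^3 steps and
    the MSD slope of a 10^4-walker cloud against 2dD per hop."""
    n = 64
    net = ReactionNetwork([SpeciesSpec("A", 1.0, 0.0)], [],
                          GridSpec(n, n, 1.0))
    rng = np.random.default_rng(_seed(seed, 1))
    counts = rng.integers(0, 30, size=(1, n, n)).astype(np.int64)
    total0 = int(counts.sum())
    _kernels.seed_rng(_seed(seed, 2))
    state = GridState(0.0, counts)
    drift = 0
    for _ in range(1000):
        state.counts[0] = _kernels.diffuse_lattice(state.counts[0])
        drift = max(drift, abs(int(state.counts.sum()) - total0))

    # MSD: cloud released at the center, measured before boundary contact
    cloud = np.zeros((n, n), dtype=np.int64)
    cloud[n // 2, n // 2] = 10_000
    _kernels.seed_rng(_seed(seed, 3))
    x = np.arange(n) - n // 2
    X, Y = np.meshgrid(x, x)
    r2 = X ** 2 + Y ** 2
    steps = np.arange(1, 257)
    msd = np.empty(len(steps))
    for i in range(len(steps)):
        cloud = _kernels.diffuse_lattice(cloud)
        msd[i] = (cloud * r2).sum() / cloud.sum()
    slope = np.polyfit(steps, msd, 1)[0]
    # one hop per step of tau = lam^2/(2dD): expected slope is lam^2 = 1
    return {"max_total_drift": float(drift),
            "msd_slope_ratio": float(slope / 1.0)}


def ssa_experiment(seed: int = 0) -> dict:
    """Immigration-death stationarity (chi-square vs Poisson, 1e5 samples)
    and the linear-death mean-decay z-score (1e4 replicates)."""
    a, k = 5.0, 0.5
    net = ReactionNetwork(
        [SpeciesSpec("A")],
        [Reaction({}, {"A": 1}, RateLaw("zeroth_order", a)),
         Reaction({"A": 1}, {}, RateLaw("mass_action", k, 1))],
        GridSpec(1, 1))
    comp = compile_network(scale_network(net, 1.0))
    lam = a / k
    _kernels.seed_rng(_seed(seed, 4))
    reps = 100_000
    samples = np.array([ssa_advance([int(lam)], comp, 12.0 / k)[0]
                        for _ in range(reps)])
    hi = int(lam + 6 * np.sqrt(lam))
    counts = np.bincount(samples, minlength=hi + 1)
    pmf = stats.poisson.pmf(np.arange(hi + 1), lam)
    obs = np.append(counts[:hi], counts[hi:].sum())
    exp = np.append(pmf[:hi], 1 - pmf[:hi].sum()) * reps
    keep = exp > 5
    stat = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
    pval = float(stats.chi2.sf(stat, keep.sum() - 1))

    death = ReactionNetwork(
        [SpeciesSpec("A")],
        [Reaction({"A": 1}, {}, RateLaw("mass_action", k, 1))],
        GridSpec(1, 1))
    dcomp = compile_network(scale_network(death, 1.0))
    n0, t = 1000, 2.0
    _kernels.seed_rng(_seed(seed, 5))
    dreps = 10_000
    finals = np.array([ssa_advance([n0], dcomp, t)[0] for _ in range(dreps)])
    p = np.exp(-k * t)
    se = np.sqrt(n0 * p * (1 - p) / dreps)
    z = float((finals.mean() - n0 * p) / se)
    return {"poisson_chi2_pvalue": pval, "death_mean_zscore": z}


def boundary_experiment(seed: int = 0) -> dict:
    """Reflecting corner: a particle stays put when 2 of 4 moves reject."""
    _kernels.seed_rng(_seed(seed, 6))
    reps = 100_000
    stays = 0
    g = np.zeros((4, 4), dtype=np.int64)
    for _ in range(reps):
        g[:] = 0
        g[0, 0] = 1
        out = _kernels.diffuse_lattice(g)
        stays += int(out[0, 0] == 1)
    return {"corner_stay_frequency": stays / reps}


def omega_convergence_experiment(seed: int = 0, replicates: int = 1000,
                                 omegas=(10.0, 100.0, 1000.0)) -> dict:
    """Well-mixed Gray-Scott: the ensemble-mean trajectory of an excited
    subvolume approaches the ODE solution as Ω grows, and the stationary
    spread of the substrate scales as Ω^(-1/2).

    The deviation is averaged over six checkpoints along the excursion
    (not just the endpoint), with the species scale floored at 5% of its
    trajectory maximum, so the estimator tracks the O(1/Ω) bias of the
    mean rather than Monte Carlo noise.
    """
    from .models.gray_scott import GrayScottParams, gray_scott_network
    from .pde import make_rhs_split

    params = GrayScottParams(nx=1, ny=1)
    net = gray_scott_network(params)
    split = make_rhs_split(net)
    comp_by_omega = {om: compile_network(scale_network(net, om))
                     for om in omegas}
    checkpoints = np.linspace(1.0, 6.0, 6)
    y0 = np.array([params.u_background, 2.0])
    ode = np.empty((len(checkpoints), 2))
    y = y0.copy()
    for i in range(len(checkpoints)):
        y = integrate_reactions(y, split, 1.0, rtol=1e-8)
        ode[i] = y
    scale = np.maximum(np.abs(ode), 0.05 * np.abs(ode).max(axis=0))
    out = {}
    deviations = []
    for j, om in enumerate(omegas):
        comp = comp_by_omega[om]
        start = np.array([int(round(params.u_background * om)),
                          int(round(2.0 * om))], dtype=np.int64)
        _kernels.seed_rng(_seed(seed, 10 + j))
        acc = np.zeros((len(checkpoints), 2))
        for _ in range(replicates):
            counts = start.copy()
            for i in range(len(checkpoints)):
                counts = ssa_advance(counts, comp, 1.0)
                acc[i] += counts
        mean = acc / (replicates * om)
        dev = float(np.mean(np.abs(mean - ode) / scale))
        deviations.append(dev)
        out[f"mean_rel_deviation_omega_{om:g}"] = dev
    out["deviation_monotone_decreasing"] = float(
        all(a > b for a, b in zip(deviations, deviations[1:])))

    # stationary substrate spread at the quiescent background (v = 0)
    sds = []
    for j, om in enumerate(omegas):
        comp = comp_by_omega[om]
        start = np.array([int(round(params.u_background * om)), 0],
                         dtype=np.int64)
        _kernels.seed_rng(_seed(seed, 20 + j))
        finals = np.array([ssa_advance(start, comp, 50.0)[0]
                           for _ in range(replicates)]) / om
        sds.append(finals.std(ddof=1))
    slope = float(np.polyfit(np.log10(omegas), np.log10(sds), 1)[0])
    out["sd_loglog_slope"] = slope
    return out


def deterministic_solver_experiment(seed: int = 0) -> dict:
    """Heat-kernel accuracy of the diffusion step and transient accuracy of
    the stiff reaction integrator."""
    n, D, lam, T = 101, 1.0, 1.0, 40.0
    v = np.zeros((n, n))
    v[n // 2, n // 2] = 1.0
    dt = 0.2 * lam ** 2 / (4 * D)
    t = 0.0
    while t < T - 1e-12:
        h = min(dt, T - t)
        v = laplacian_step(v, D, lam, h)
        t += h
    x = np.arange(n) - n // 2
    X, Y = np.meshgrid(x, x)
    ref = np.exp(-(X ** 2 + Y ** 2) / (4 * D * T)) / (4 * np.pi * D * T)
    l2 = float(np.linalg.norm(v - ref) / np.linalg.norm(ref))

    k = 3.0
    y = integrate_reactions(np.array([100.0]),
                            lambda w: (np.zeros_like(w), k * w), 5.0 / k)
    exact = 100.0 * np.exp(-5.0)
    return {"heat_kernel_l2_error": l2,
            "linear_decay_rel_error": float(abs(y[0] - exact) / exact)}


def self_convergence_experiment(seed: int = 0, n: int = 64) -> dict:
    """Halving the splitting step changes the final fields of all three
    model reference runs by the returned relative L2 amounts."""
    from .models.calcium import CalciumParams, calcium_init, calcium_network
    from .models.gray_scott import (GrayScottParams, gray_scott_init,
                                    gray_scott_network)
    from .models.oregonator import (OregonatorParams, fractional_mean_field,
                                    fractional_network, oregonator_init)

    def rel(a, b):
        return float(np.linalg.norm(a - b) / np.linalg.norm(b))

    out = {}
    gp = GrayScottParams(nx=n, ny=n)
    net, init = gray_scott_network(gp), gray_scott_init(gp)
    cfg = RunConfig(t_end=20.0, snapshot_times=[20.0])
    log = {}
    a = pde_run(net, Field(0.0, init), cfg, log=log)
    b = pde_run(net, Field(0.0, init), cfg, dt=log["tau"] / 2)
    out["self_convergence_gray_scott"] = rel(a.final.values, b.final.values)

    op = OregonatorParams(nx=n, ny=n)
    fnet, mf = fractional_network(op), fractional_mean_field(op)
    finit = oregonator_init(op)[:3]
    cfg = RunConfig(t_end=30.0, snapshot_times=[30.0])
    log = {}
    a = pde_run(fnet, Field(0.0, finit), cfg, mean_field=mf, log=log)
    b = pde_run(fnet, Field(0.0, finit), cfg, mean_field=mf,
                dt=log["tau"] / 2)
    out["self_convergence_oregonator"] = rel(a.final.values, b.final.values)

    cp = CalciumParams(nx=n, ny=n)
    cnet, cinit = calcium_network(cp), calcium_init(cp)
    cfg = RunConfig(t_end=2.0, snapshot_times=[2.0])
    log = {}
    a = pde_run(cnet, Field(0.0, cinit), cfg, log=log)
    b = pde_run(cnet, Field(0.0, cinit), cfg, dt=log["tau"] / 2)
    out["self_convergence_calcium"] = rel(a.final.values, b.final.values)
    return out


def helper_reaction_experiment(seed: int = 0) -> dict:
    """Helper-discretized vs direct fractional Oregonator kinetics over one
    oscillation period (both integrated by a reference stiff solver)."""
    from scipy.integrate import solve_ivp

    from .models.oregonator import (default_params, oregonator_network,
                                    rest_state)
    from .pde import make_rhs_split

    p = default_params()
    split5 = make_rhs_split(oregonator_network(p))

    def rhs5(t, w):
        q, loss = split5(w)
        return q - loss

    def rhs3(t, w):
        x, y, z = w
        return [p.c1 * y - p.c2 * x * y + p.c3 * x - 2 * p.c4 * x * x,
                -p.c1 * y - p.c2 * x * y + p.f * p.c5 * z,
                p.c3 * x - p.c5 * z]

    x0, y0, z0 = rest_state(p)
    start = [0.5 * p.x_scale, y0, z0]
    T = 62.0
    ts = np.linspace(0, T, 400)
    s5 = solve_ivp(rhs5, [0, T], start + [0.0, 0.0], method="LSODA",
                   t_eval=ts, rtol=1e-10, atol=1e-13)
    s3 = solve_ivp(rhs3, [0, T], start, method="LSODA", t_eval=ts,
                   rtol=1e-10, atol=1e-13)
    scale = np.abs(s3.y).max(axis=1)
    err = float(np.max(np.abs(s5.y[:3] - s3.y) / scale[:, None]))
    pool = float((s5.y[3] + s5.y[4]).max() / s5.y[2].max())
    return {"helper_vs_fractional_max_rel_error": err,
            "helper_pool_fraction_of_z_peak": pool}


def mean_field_fidelity_experiment(seed: int = 0) -> dict:
    """Builder mean-field rates vs hand-coded oracles at random states."""
    from .models.calcium import calcium_network
    from .models.calcium import default_params as ca_defaults
    from .models.gray_scott import default_params as gs_defaults
    from .models.gray_scott import gray_scott_network
    from .models.oregonator import default_params as or_defaults
    from .models.oregonator import fractional_mean_field
    from .pde import reaction_rhs

    rng = np.random.default_rng(_seed(seed, 30))
    worst = 0.0

    gp = gs_defaults()
    gnet = gray_scott_network(gp)
    for _ in range(5):
        u, v = rng.uniform(0.1, 10.0, 2)
        got = reaction_rhs(gnet, np.array([u, v]))
        auto = gp.k1 * u * v ** 2
        ref = np.array([gp.k3 - gp.k4 * u - auto, auto - gp.k2 * v])
        worst = max(worst, float(np.max(np.abs(got - ref)
                                        / np.maximum(np.abs(ref), 1e-12))))

    op = or_defaults()
    mf = fractional_mean_field(op)
    q = np.empty(3)
    loss = np.empty(3)
    for _ in range(5):
        x, y, z = rng.uniform(0.05, 5.0, 3)
        _kernels.mf_split_cell(np.array([x, y, z]), mf.kinds, mf.consts,
                               mf.stoich_r, mf.change, mf.par, q, loss)
        ref = np.array([
            op.c1 * y - op.c2 * x * y + op.c3 * x - 2 * op.c4 * x * x,
            -op.c1 * y - op.c2 * x * y + op.f * op.c5 * z,
            op.c3 * x - op.c5 * z])
        worst = max(worst, float(np.max(np.abs((q - loss) - ref)
                                        / np.maximum(np.abs(ref), 1e-12))))

    cp = ca_defaults()
    cnet = calcium_network(cp)
    xi = cp.counts_per_uM
    for _ in range(5):
        c = rng.uniform(0.01, 2.0) * xi
        nch = rng.uniform(0, cp.n_channels)
        ip3 = rng.uniform(0.1, 1.5) * xi
        got = reaction_rhs(cnet, np.array([c, nch, ip3]))
        mu = (ip3 / xi) / (cp.k_mu + ip3 / xi)
        act = cp.b + (1 - cp.b) * (c / xi) / (cp.k_act + c / xi)
        release = cp.k_flux * xi / cp.n_channels * mu * act * nch
        pump = cp.gamma * xi * (c / xi) / (cp.k_gamma + c / xi)
        hinf = cp.k_inhib ** 2 / (cp.k_inhib ** 2 + (c / xi) ** 2)
        ref = np.array([cp.beta * xi + release - pump,
                        (cp.n_channels * hinf - nch) / cp.tau_h,
                        -cp.k_p * ip3])
        worst = max(worst, float(np.max(np.abs(got - ref)
                                        / np.maximum(np.abs(ref), 1e-12))))
    return {"mean_field_max_rel_error": worst}


def gray_scott_transition_experiment(seed: int = 0, t_end: float = 50.0,
                                     omegas=(0.25, 25.0, 250.0),
                                     replicates=(4, 3, 2)) -> dict:
    """The noise-to-determinism transition on the 128x128 Gray-Scott spiral.

    The deterministic twin is run with the same operator cadence as the
    stochastic loop (Lie splitting at the GMP global step), so the
    comparison isolates intrinsic fluctuations rather than discretization
    differences.  Coherence is reported on the substrate field (always
    populated); at the highest Ω the activator coherence is reported too.
    """
    from .models.gray_scott import (build_gray_scott, default_params,
                                    gray_scott_init, gray_scott_network)

    p = default_params()
    net = gray_scott_network(p)
    tau = global_timestep(scale_network(net, 1.0))
    cfg = RunConfig(t_end=t_end, snapshot_times=[t_end])
    det = pde_run(net, Field(0.0, gray_scott_init(p)), cfg, rtol=1e-5,
                  r_cap=1.0, dt=tau, splitting="lie")
    out = {}
    means = []
    for j, (om, reps) in enumerate(zip(omegas, replicates)):
        rs_u, rs_v = [], []
        for r in range(reps):
            scaled, init = build_gray_scott(p, om)
            run_cfg = RunConfig(t_end=t_end, snapshot_times=[t_end],
                                master_seed=derive_seed(seed, 40 + j, r),
                                omega=om)
            tr = gmp_run(scaled, init, run_cfg)
            rs_u.append(coherence(tr.final, det.final, 0, block=2))
            try:
                rs_v.append(coherence(tr.final, det.final, 1, block=2))
            except UndefinedCoherenceError:
                pass
        mean_u = float(np.mean(rs_u))
        means.append(mean_u)
        out[f"coherence_substrate_omega_{om:g}"] = mean_u
        out[f"coherence_substrate_sd_omega_{om:g}"] = float(np.std(rs_u))
        if rs_v:
            out[f"coherence_activator_omega_{om:g}"] = float(np.mean(rs_v))
    out["curve_non_decreasing"] = float(
        all(b >= a - 0.02 for a, b in zip(means, means[1:])))
    out["lowest_omega_abs_coherence"] = float(abs(means[0]))
    return out


def calcium_structure_experiment(seed: int = 0) -> dict:
    """Phase-plane fixed-point count and the open-channel cap in SSA."""
    from .models.calcium import build_calcium, default_params
    from .models.nullclines import nullclines

    p = default_params()
    plane = nullclines("calcium", p)
    omega = 0.25
    scaled, state = build_calcium(p, omega)
    comp = compile_network(scaled)
    cap = int(round(p.n_channels * omega))
    counts = state.counts[:, 0, 0].copy()
    counts[0] //= 4
    _kernels.seed_rng(_seed(seed, 60))
    violations = 0
    events = 0
    for _ in range(3000):
        new = ssa_advance(counts, comp, 0.05)
        events += int(np.abs(new - counts).sum())
        counts = new
        if counts[1] > cap:
            violations += 1
    return {"calcium_fixed_points": float(len(plane.fixed_points)),
            "calcium_stable_fixed_points": float(
                sum(fp.stable for fp in plane.fixed_points)),
            "channel_cap_violations": float(violations),
            "calcium_ssa_events_observed": float(events)}
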