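"""Numba kernels: per-cell Gillespie SSA and multiparticle lattice diffusion.

The kernels operate on a flat array encoding of a scaled network (see
:mod:`mesord.ssa`).  All randomness goes through numba's internal
``np.random`` state, seeded once per run via :func:`seed_rng`; kernels are
single-threaded, so a run is fully determined by its seed.
"""

import numpy as np
from numba import njit

# rate-law kind codes (must match mesord.ssa._KIND_CODES)
MASS_ACTION = 0
ZEROTH_ORDER = 1
LINEAR_DECAY = 2
MM_PUMP = 3
COOPERATIVE_FLUX = 4
CHANNEL_EQUILIBRIUM = 5


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _falling_factorial(n, k):
    """Number of ordered k-tuples of distinct particles out of n."""
    out = 1.0
    for i in range(k):
        out *= n - i
    return out if out > 0.0 else 0.0


@njit(cache=True)
def propensities(local, kinds, consts, stoich_r, par, omega, out):
    """Fill ``out[j]`` with the propensity of reaction j at copy counts ``local``.

    Mass-action propensities use the falling-factorial count of distinct
    reactant tuples; named concentration-form laws follow a(n) = Ω · v(n/Ω).
    Returns 0 on success, 1 if any propensity is non-finite.
    """
    nr = kinds.shape[0]
    ns = local.shape[0]
    status = 0
    for j in range(nr):
        k = kinds[j]
        if k == MASS_ACTION:
            a = consts[j]
            for s in range(ns):
                nu = stoich_r[j, s]
                if nu > 0:
                    a *= _falling_factorial(local[s], nu)
                    if a == 0.0:
                        break
        elif k == ZEROTH_ORDER:
            a = consts[j]
        elif k == LINEAR_DECAY:
            a = consts[j] * local[int(par[j, 6])]
        elif k == MM_PUMP:
            # a = Omega * v(n/Omega) with v(c) = g c/(km + c)
            n_c = local[int(par[j, 6])]
            a = omega * consts[j] * n_c / (par[j, 0] * omega + n_c)
        elif k == COOPERATIVE_FLUX:
            # v = k * n_chan * mu(p) * (b + (1-b) c/(k_act+c)) with
            # concentrations n/omega; a = omega * v(n/omega)
            c = local[int(par[j, 3])] / omega
            p = local[int(par[j, 4])] / omega
            n_chan = local[int(par[j, 6])]
            mu = p / (par[j, 2] + p)
            act = par[j, 1] + (1.0 - par[j, 1]) * c / (par[j, 0] + c)
            a = consts[j] * n_chan * mu * act
        elif k == CHANNEL_EQUILIBRIUM:
            c = local[int(par[j, 3])] / omega
            n_chan = local[int(par[j, 4])]
            cap = par[j, 1] * omega
            if n_chan < int(round(cap)):
                k2 = par[j, 0]
                a = omega * consts[j] * k2 * k2 / (k2 * k2 + c * c)
            else:
                a = 0.0
        else:
            a = np.nan
        if not np.isfinite(a):
            status = 1
            a = 0.0
        out[j] = a if a > 0.0 else 0.0
    return status


@njit(cache=True)
def ssa_cell(local, kinds, consts, stoich_r, stoich_change, par, omega,
             duration, a):
    """Advance one well-stirred cell by direct-method SSA for ``duration``.

    The event that would cross the time budget is rejected and the clock
    truncated at the budget; this is exact because exponential clocks are
    memoryless.  Propensities are recomputed after every firing.
    Returns 0 on success, 1 on a non-finite propensity.
    """
    nr = kinds.shape[0]
    ns = local.shape[0]
    t = 0.0
    while True:
        status = propensities(local, kinds, consts, stoich_r, par, omega, a)
        if status != 0:
            return 1
        a0 = 0.0
        for j in range(nr):
            a0 += a[j]
        if a0 <= 0.0:
            return 0
        t += -np.log(np.random.random()) / a0
        if t > duration:
            return 0
        u = np.random.random() * a0
        acc = 0.0
        jsel = nr - 1
        for j in range(nr):
            acc += a[j]
            if u < acc:
                jsel = j
                break
        for s in range(ns):
            local[s] += stoich_change[jsel, s]


@njit(cache=True)
def ssa_all_cells(counts, kinds, consts, stoich_r, stoich_change, par, omega,
                  duration):
    """Run :func:`ssa_cell` independently in every subvolume (in place)."""
    ns, ny, nx = counts.shape
    local = np.empty(ns, dtype=np.int64)
    a = np.empty(kinds.shape[0], dtype=np.float64)
    for iy in range(ny):
        for ix in range(nx):
            for s in range(ns):
                local[s] = counts[s, iy, ix]
            status = ssa_cell(local, kinds, consts, stoich_r, stoich_change,
                              par, omega, duration, a)
            if status != 0:
                return 1
            for s in range(ns):
                counts[s, iy, ix] = local[s]
    return 0


@njit(cache=True)
def diffuse_lattice(grid):
    """One synchronous multiparticle diffusion step on a 2-D lattice.

    Every particle independently picks one of the 4 neighbor directions with
    probability 1/4 (multinomial split per cell).  Moves that would leave the
    domain are rejected: the particle stays in its subvolume (reflecting
    boundary by rejection sampling).  Total count is conserved exactly.
    """
    ny, nx = grid.shape
    out = np.zeros_like(grid)
    for iy in range(ny):
        for ix in range(nx):
            n = grid[iy, ix]
            if n == 0:
                continue
            n_up = np.random.binomial(n, 0.25)
            rem = n - n_up
            n_down = np.random.binomial(rem, 1.0 / 3.0) if rem > 0 else 0
            rem -= n_down
            n_left = np.random.binomial(rem, 0.5) if rem > 0 else 0
            n_right = rem - n_left
            if iy > 0:
                out[iy - 1, ix] += n_up
            else:
                out[iy, ix] += n_up
            if iy < ny - 1:
                out[iy + 1, ix] += n_down
            else:
                out[iy, ix] += n_down
            if ix > 0:
                out[iy, ix - 1] += n_left
            else:
                out[iy, ix] += n_left
            if ix < nx - 1:
                out[iy, ix + 1] += n_right
            else:
                out[iy, ix] += n_right
    return out


# ---------------------------------------------------------------------------
# deterministic mean-field kernels (concentration-form rates, per-cell α-QSS)

@njit(cache=True, inline="always")
def _alpha_qss(r):
    return ((180.0 + r * (60.0 + r * (11.0 + r)))
            / (360.0 + r * (60.0 + r * (12.0 + r))))


@njit(cache=True)
def mf_split_cell(y, kinds, consts, stoich_r, change, par, q, loss):
    """Production/loss split of the mean-field rhs at one cell (Ω = 1 form)."""
    nr = kinds.shape[0]
    ns = y.shape[0]
    for s in range(ns):
        q[s] = 0.0
        loss[s] = 0.0
    for j in range(nr):
        k = kinds[j]
        if k == MASS_ACTION or k == ZEROTH_ORDER:
            v = consts[j]
            for s in range(ns):
                nu = stoich_r[j, s]
                for _ in range(nu):
                    v *= y[s]
        elif k == LINEAR_DECAY:
            v = consts[j] * y[int(par[j, 6])]
        elif k == MM_PUMP:
            x = y[int(par[j, 6])]
            v = consts[j] * x / (par[j, 0] + x)
        elif k == COOPERATIVE_FLUX:
            c = y[int(par[j, 3])]
            p = y[int(par[j, 4])]
            mu = p / (par[j, 2] + p)
            act = par[j, 1] + (1.0 - par[j, 1]) * c / (par[j, 0] + c)
            v = consts[j] * y[int(par[j, 6])] * mu * act
        else:  # CHANNEL_EQUILIBRIUM
            c = y[int(par[j, 3])]
            k2 = par[j, 0]
            v = consts[j] * k2 * k2 / (k2 * k2 + c * c)
        for s in range(ns):
            d = change[j, s]
            if d > 0.0:
                q[s] += d * v
            elif d < 0.0:
                loss[s] -= d * v


@njit(cache=True)
def alpha_qss_cell(y, kinds, consts, stoich_r, change, par, dt, rtol, r_cap,
                   q0, l0, qp, lp, yp, yc):
    """Advance one cell's reaction ODEs by dt; returns (status, clips).

    Work buffers (q0..yc, each of length n_species) are supplied by the
    caller so the lattice loop does no per-cell allocation.
    status: 0 ok, 1 non-finite, 2 substep underflow.
    """
    ns = y.shape[0]
    tiny = 1e-300
    t = 0.0
    h = dt
    clips = 0
    while t < dt * (1.0 - 1e-14):
        if h > dt - t:
            h = dt - t
        mf_split_cell(y, kinds, consts, stoich_r, change, par, q0, l0)
        # quiescent cell: rhs negligible over the whole step, nothing to do
        quiet = True
        for s in range(ns):
            if abs(q0[s] - l0[s]) * (dt - t) > 1e-12 * (y[s] + 1.0):
                quiet = False
                break
        if quiet:
            break
        # cap r = p*h by distance from quasi-steady state
        cap = 1e300
        for s in range(ns):
            p = l0[s] / (y[s] + tiny)
            d = abs(q0[s] - p * y[s]) / (q0[s] + p * y[s] + tiny)
            pd = p * d
            if pd > 0.0 and r_cap / pd < cap:
                cap = r_cap / pd
        if h > cap:
            h = cap
        for s in range(ns):
            p = l0[s] / (y[s] + tiny)
            r = p * h
            v = y[s] + h * (q0[s] - p * y[s]) / (1.0 + _alpha_qss(r) * r)
            yp[s] = v if v > 0.0 else 0.0
        mf_split_cell(yp, kinds, consts, stoich_r, change, par, qp, lp)
        err = 0.0
        ymax = tiny
        for s in range(ns):
            p0 = l0[s] / (y[s] + tiny)
            pp = lp[s] / (yp[s] + tiny)
            pbar = 0.5 * (p0 + pp)
            rbar = pbar * h
            ab = _alpha_qss(rbar)
            qt = ab * qp[s] + (1.0 - ab) * q0[s]
            yc[s] = y[s] + h * (qt - pbar * y[s]) / (1.0 + ab * rbar)
            if not np.isfinite(yc[s]):
                return 1, clips
            if abs(yc[s]) > ymax:
                ymax = abs(yc[s])
        for s in range(ns):
            scale = abs(yc[s])
            if scale < 1e-3 * ymax:
                scale = 1e-3 * ymax
            e = abs(yc[s] - yp[s]) / scale
            if e > err:
                err = e
        if err <= rtol:
            for s in range(ns):
                if yc[s] < 0.0:
                    yc[s] = 0.0
                    clips += 1
                y[s] = yc[s]
            t += h
            fac = 0.9 * (rtol / (err + 1e-30)) ** 0.5
            if fac > 3.0:
                fac = 3.0
            h *= fac
        else:
            fac = 0.9 * (rtol / err) ** 0.5
            if fac < 0.1:
                fac = 0.1
            h *= fac
            if h < dt * 1e-13:
                return 2, clips
    return 0, clips


@njit(cache=True)
def mf_integrate_lattice(values, kinds, consts, stoich_r, change, par, dt,
                         rtol, r_cap):
    """Per-cell adaptive α-QSS over the whole lattice (in place).

    Returns (status, clips); status 0 ok, 1 non-finite, 2 underflow.
    """
    ns, ny, nx = values.shape
    y = np.empty(ns)
    q0 = np.empty(ns)
    l0 = np.empty(ns)
    qp = np.empty(ns)
    lp = np.empty(ns)
    yp = np.empty(ns)
    yc = np.empty(ns)
    clips = 0
    for iy in range(ny):
        for ix in range(nx):
            for s in range(ns):
                y[s] = values[s, iy, ix]
            status, c = alpha_qss_cell(y, kinds, consts, stoich_r, change,
                                       par, dt, rtol, r_cap,
                                       q0, l0, qp, lp, yp, yc)
            clips += c
            if status != 0:
                return status, clips
            for s in range(ns):
                values[s, iy, ix] = y[s]
    return 0, clips
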