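"""The three model builders: structure, mean-field fidelity, phase planes."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mesord._kernels import seed_rng
from mesord.network import ModelValidationError
from mesord.pde import make_rhs_split, reaction_rhs
from mesord.ssa import compile_network, ssa_advance

from mesord.models.calcium import (CalciumParams, build_calcium,
                                   calcium_network)
from mesord.models.calcium import default_params as ca_defaults
from mesord.models.gray_scott import (GrayScottParams, build_gray_scott,
                                      gray_scott_network)
from mesord.models.gray_scott import default_params as gs_defaults
from mesord.models.nullclines import nullclines
from mesord.models.oregonator import (OregonatorParams, build_oregonator,
                                      oregonator_network, rest_state)
from mesord.models.oregonator import default_params as or_defaults


# hand-coded mean-field oracles, written independently of the builders

def gs_oracle(p, u, v):
    auto = p.k1 * u * v ** 2
    return np.array([p.k3 - p.k4 * u - auto, auto - p.k2 * v])


def oregonator_oracle(p, x, y, z):
    return np.array([
        p.c1 * y - p.c2 * x * y + p.c3 * x - 2 * p.c4 * x ** 2,
        -p.c1 * y - p.c2 * x * y + p.f * p.c5 * z,
        p.c3 * x - p.c5 * z,
    ])


def calcium_oracle(p, c, n, ip3):
    """Counts-form rates for (Ca2+, open channels, IP3)."""
    xi = p.counts_per_uM
    mu = (ip3 / xi) / (p.k_mu + ip3 / xi)
    act = p.b + (1 - p.b) * (c / xi) / (p.k_act + c / xi)
    release = p.k_flux * xi / p.n_channels * mu * act * n
    pump = p.gamma * xi * (c / xi) / (p.k_gamma + c / xi)
    hinf = p.k_inhib ** 2 / (p.k_inhib ** 2 + (c / xi) ** 2)
    return np.array([
        p.beta * xi + release - pump,
        (p.n_channels * hinf - n) / p.tau_h,
        -p.k_p * ip3,
    ])


class TestGrayScott:
    def test_reaction_count(self):
        assert len(gray_scott_network(gs_defaults()).reactions) == 4

    def test_mean_field_matches_oracle(self, rng):
        p = gs_defaults()
        net = gray_scott_network(p)
        for _ in range(5):
            u, v = rng.uniform(0.1, 10.0, 2)
            got = reaction_rhs(net, np.array([u, v]))
            np.testing.assert_allclose(got, gs_oracle(p, u, v), rtol=1e-12)

    def test_build_initial_state_geometry(self):
        p = gs_defaults()
        scaled, state = build_gray_scott(p, 2.5)
        u0 = int(round(p.u_background * 2.5))
        # left half background, right half refractory
        assert state.counts[0, 0, 0] == u0
        assert state.counts[0, 0, -1] < u0 / 2
        # perturbation rectangle carries activator; elsewhere none
        assert state.counts[1].max() == int(round(p.v_perturb * 2.5))
        assert state.counts[1, 0, 0] == 0

    def test_build_rejects_wrong_fixed_point_count(self):
        # far below the saddle-node curve only the trivial state remains
        p = gs_defaults()
        p.k3 = 0.1
        with pytest.raises(ModelValidationError):
            build_gray_scott(p, 1.0)

    def test_omega_scaling_identity_on_concentration_dynamics(self, rng):
        p = gs_defaults()
        net = gray_scott_network(p)
        from mesord.network import scale_network

        scaled = scale_network(net, 100.0)
        # propensity constants: zeroth *100, first unchanged, third /100^2
        base = [r.rate_law.base_constant for r in net.reactions]
        np.testing.assert_allclose(
            scaled.scaled_constants,
            [base[0] / 100.0 ** 2, base[1], base[2] * 100.0, base[3]])


class TestOregonator:
    def test_reaction_count_with_helpers(self):
        assert len(oregonator_network(or_defaults()).reactions) == 7

    def test_mean_field_matches_fractional_oracle(self, rng):
        """The reduced 3-variable kinetics equal the hand-coded fractional
        rhs; the helper network's X/Z rates agree with it exactly and its
        Y rate reduces to it when the helper pool is at QSS."""
        from mesord.models.oregonator import fractional_mean_field
        from mesord import _kernels

        p = or_defaults()
        mf = fractional_mean_field(p)
        q = np.empty(3)
        loss = np.empty(3)
        for _ in range(5):
            x, y, z = rng.uniform(0.05, 5.0, 3)
            _kernels.mf_split_cell(np.array([x, y, z]), mf.kinds, mf.consts,
                                   mf.stoich_r, mf.change, mf.par, q, loss)
            np.testing.assert_allclose(q - loss,
                                       oregonator_oracle(p, x, y, z),
                                       rtol=1e-12)

    def test_helper_network_matches_fractional_ode_over_a_period(self):
        """Criterion for the helper construction: with 1000x dominant
        helper rates the 5-species kinetics track the fractional ODE
        within 1% over one oscillation period."""
        p = or_defaults()
        net = oregonator_network(p)
        split5 = make_rhs_split(net)

        def rhs5(t, w):
            qq, ll = split5(w)
            return qq - ll

        def rhs3(t, w):
            return oregonator_oracle(p, *w)

        x0, y0, z0 = rest_state(p)
        start = [0.5 * p.x_scale, y0, z0]
        T = 62.0
        ts = np.linspace(0, T, 300)
        s5 = solve_ivp(rhs5, [0, T], start + [0.0, 0.0], method="LSODA",
                       t_eval=ts, rtol=1e-10, atol=1e-13)
        s3 = solve_ivp(rhs3, [0, T], start, method="LSODA", t_eval=ts,
                       rtol=1e-10, atol=1e-13)
        scale = np.abs(s3.y).max(axis=1)
        err = np.max(np.abs(s5.y[:3] - s3.y) / scale[:, None])
        assert err < 0.01
        # helper pools stay tiny relative to the catalyst peak
        assert (s5.y[3] + s5.y[4]).max() < 0.01 * s5.y[2].max()

    def test_build_rejects_weak_helper_separation(self):
        p = or_defaults()
        p.helper_separation = 10.0
        with pytest.raises(ModelValidationError):
            build_oregonator(p, 1.0)

    def test_build_rejects_unsupported_fraction(self):
        p = or_defaults()
        p.f = 1.4
        with pytest.raises(ModelValidationError):
            build_oregonator(p, 1.0)

    def test_wedge_init_geometry(self):
        p = or_defaults()
        scaled, state = build_oregonator(p, 10.0)
        x_rest, _, _ = rest_state(p)
        # the wedge is a small angular sector: a minority of cells excited
        excited = (state.counts[0] > 5 * x_rest * 10).sum()
        assert 0 < excited < 0.2 * p.nx * p.ny
        # catalyst carries the angular gradient
        assert state.counts[2].max() > 10 * max(state.counts[2].min(), 1)


class TestCalcium:
    def test_reaction_count(self):
        assert len(calcium_network(ca_defaults()).reactions) == 6

    def test_mean_field_matches_oracle(self, rng):
        p = ca_defaults()
        net = calcium_network(p)
        xi = p.counts_per_uM
        for _ in range(5):
            c = rng.uniform(0.01, 2.0) * xi
            n = rng.uniform(0, p.n_channels)
            ip3 = rng.uniform(0.1, 1.5) * xi
            got = reaction_rhs(net, np.array([c, n, ip3]))
            np.testing.assert_allclose(got, calcium_oracle(p, c, n, ip3),
                                       rtol=1e-12)

    def test_three_phase_plane_fixed_points(self):
        """The (Ca2+, open fraction) plane exhibits three fixed points:
        stable rest, saddle, unstable focus."""
        plane = nullclines("calcium", ca_defaults())
        assert len(plane.fixed_points) == 3
        stable = [fp.stable for fp in plane.fixed_points]
        assert stable == [True, False, False]
        for fp in plane.fixed_points:
            assert np.max(np.abs(plane.rhs(np.array(fp.point)))) < 1e-10

    def test_open_channel_cap_never_violated_in_ssa(self):
        """Stochastic opening shuts off at n = N*Omega: no trajectory may
        exceed the per-subvolume channel cap."""
        p = ca_defaults()
        omega = 0.25
        scaled, state = build_calcium(p, omega)
        comp = compile_network(scaled)
        cap = int(round(p.n_channels * omega))
        counts = state.counts[:, 0, 0].copy()
        counts[0] //= 4   # drop Ca below rest: opening rate near maximal
        seed_rng(31)
        for _ in range(300):
            counts = ssa_advance(counts, comp, 0.05)
            assert counts[1] <= cap

    def test_build_rejects_cap_violating_init(self):
        p = ca_defaults()
        p.n_refractory = 2 * p.n_channels
        with pytest.raises(ModelValidationError):
            build_calcium(p, 1.0)


def test_shipped_parameter_files_match_code_defaults():
    """The YAML parameter files and the dataclass defaults agree, so a
    model built either way is the same model."""
    assert gs_defaults() == GrayScottParams()
    assert or_defaults() == OregonatorParams()
    assert ca_defaults() == CalciumParams()


class TestNullclines:
    def test_gray_scott_trivial_state_on_activator_nullcline(self):
        plane = nullclines("gray_scott", gs_defaults())
        # v = 0 is a structural zero of the activator rhs
        assert abs(plane.rhs(np.array([3.7, 0.0]))[1]) < 1e-12

    def test_all_reported_fixed_points_are_roots(self):
        for kind, params in [("gray_scott", gs_defaults()),
                             ("oregonator", or_defaults()),
                             ("calcium", ca_defaults())]:
            plane = nullclines(kind, params)
            assert plane.fixed_points, kind
            for fp in plane.fixed_points:
                assert np.max(np.abs(plane.rhs(np.array(fp.point)))) < 1e-10

    def test_gray_scott_counts_three_states_above_saddle_node(self):
        plane = nullclines("gray_scott", gs_defaults())
        assert len(plane.fixed_points) == 3
        # the trivial (background, 0) state is the stable one
        p = gs_defaults()
        trivial = max(plane.fixed_points, key=lambda f: f.x)
        assert trivial.stable
        assert trivial.point == pytest.approx((p.u_background, 0.0), abs=1e-8)

    def test_oregonator_steady_state_is_unstable(self):
        plane = nullclines("oregonator", or_defaults())
        assert len(plane.fixed_points) == 1
        assert not plane.fixed_points[0].stable


class TestExcitability:
    def test_gray_scott_super_threshold_excursion_returns_to_rest(self):
        p = gs_defaults()
        plane = nullclines("gray_scott", p)
        sol = solve_ivp(lambda t, w: plane.rhs(w), [0, 150],
                        [p.u_background, 2.0], method="LSODA", rtol=1e-9)
        assert sol.y[1].max() > 3.0           # large excursion
        assert sol.y[1, -1] < 1e-6            # back at the rest state
        assert sol.y[0, -1] == pytest.approx(p.u_background, rel=0.05)

    def test_calcium_super_threshold_excursion_returns_to_rest(self):
        p = ca_defaults()
        plane = nullclines("calcium", p)
        rest = [fp for fp in plane.fixed_points if fp.stable][0]
        sol = solve_ivp(lambda t, w: plane.rhs(w), [0, 60],
                        [rest.x + 0.4, rest.y], method="LSODA", rtol=1e-9)
        assert sol.y[0].max() > 10 * rest.x   # large release transient
        assert sol.y[0, -1] == pytest.approx(rest.x, rel=0.01)

    def test_oregonator_perturbation_enters_limit_cycle(self):
        p = or_defaults()
        plane = nullclines("oregonator", p)
        x0, _, z0 = rest_state(p)
        sol = solve_ivp(lambda t, w: plane.rhs(w), [0, 600],
                        [0.5 * p.x_scale, 0.2 * p.z_scale], method="LSODA",
                        rtol=1e-9, max_step=1.0)
        # sustained oscillations: excursions keep recurring in the last
        # two thirds of the run
        late = sol.t > 200
        assert sol.y[0][late].max() > 0.5 * p.x_scale
        assert sol.y[0][late].min() < 0.05 * p.x_scale
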