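"""Deterministic twin: stiff reaction integrator, diffusion step, full runs."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mesord.gmp import RunConfig
from mesord.network import (GridSpec, RateLaw, Reaction, ReactionNetwork,
                            SpeciesSpec)
from mesord.pde import (Field, UnstableStepError, integrate_reactions,
                        laplacian_step, make_rhs_split, pde_run,
                        reaction_rhs)


class TestReactionRHS:
    def test_zero_state_without_sources_is_stationary(self):
        net = ReactionNetwork(
            [SpeciesSpec("A"), SpeciesSpec("B")],
            [Reaction({"A": 1, "B": 1}, {}, RateLaw("mass_action", 1.0, 2)),
             Reaction({"A": 1}, {"B": 1}, RateLaw("mass_action", 2.0, 1))],
            GridSpec(1, 1))
        np.testing.assert_array_equal(reaction_rhs(net, [0.0, 0.0]), [0, 0])

    def test_single_decay(self):
        net = ReactionNetwork(
            [SpeciesSpec("A")],
            [Reaction({"A": 1}, {}, RateLaw("mass_action", 0.7, 1))],
            GridSpec(1, 1))
        assert reaction_rhs(net, [3.0])[0] == pytest.approx(-2.1)

    def test_fixed_point_of_gray_scott_has_zero_rhs(self):
        from mesord.models.gray_scott import default_params, gray_scott_network
        from mesord.models.nullclines import nullclines

        p = default_params()
        net = gray_scott_network(p)
        for fp in nullclines("gray_scott", p).fixed_points:
            rates = reaction_rhs(net, np.array(fp.point))
            assert np.max(np.abs(rates)) < 1e-9


class TestIntegrateReactions:
    def test_linear_decay_accuracy(self):
        """Relative error < 1e-5 at t = 5/k for the pure decay transient."""
        k = 3.0
        split = lambda y: (np.zeros_like(y), k * y)  # noqa: E731
        y = integrate_reactions(np.array([100.0]), split, 5.0 / k)
        exact = 100.0 * np.exp(-5.0)
        assert abs(y[0] - exact) / exact < 1e-5

    def test_zero_rhs_leaves_values(self):
        split = lambda y: (np.zeros_like(y), np.zeros_like(y))  # noqa: E731
        y0 = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(integrate_reactions(y0, split, 1.0), y0)

    def test_stiff_relaxation_reaches_equilibrium(self):
        split = lambda y: (np.full_like(y, 1e5), 1e5 * y)  # noqa: E731
        y = integrate_reactions(np.array([0.0]), split, 1.0)
        assert y[0] == pytest.approx(1.0, rel=1e-6)

    def test_oregonator_point_kinetics_bounded_limit_cycle(self):
        """Ten oscillation periods stay on the limit cycle; the orbit's
        range matches a reference stiff integrator at rtol 1e-9."""
        from mesord.models.oregonator import default_params, fractional_mean_field
        from mesord import _kernels

        p = default_params()
        mf = fractional_mean_field(p)

        def rhs(t, w):
            x, y, z = w
            return [p.c1 * y - p.c2 * x * y + p.c3 * x - 2 * p.c4 * x * x,
                    -p.c1 * y - p.c2 * x * y + p.f * p.c5 * z,
                    p.c3 * x - p.c5 * z]

        period = 62.0  # one relaxation oscillation at these constants
        T = 10 * period
        y0 = np.array([0.5 * p.x_scale, 0.01, 0.2 * p.z_scale])
        ts = np.linspace(0, T, 2000)
        ref = solve_ivp(rhs, [0, T], y0, method="LSODA", t_eval=ts,
                        rtol=1e-9, atol=1e-13)
        vals = y0.reshape(3, 1, 1).copy()
        qss = np.empty_like(ref.y)
        dt = T / 2000
        for i in range(2000):
            status, _ = _kernels.mf_integrate_lattice(
                vals, mf.kinds, mf.consts, mf.stoich_r, mf.change, mf.par,
                dt, 1e-6, 0.4)
            assert status == 0
            qss[:, i] = vals[:, 0, 0]
        assert np.all(np.isfinite(qss))
        # same attractor: per-species orbit ranges over the last 3 periods
        tail = ts > T - 3 * period
        for s in range(3):
            assert qss[s].max() < 10 * ref.y[s].max()  # no blow-up
            assert qss[s, tail].max() == pytest.approx(
                ref.y[s, tail].max(), rel=0.05)
            assert qss[s, tail].min() == pytest.approx(
                ref.y[s, tail].min(), rel=0.05, abs=1e-4)


class TestLaplacianStep:
    def test_uniform_field_unchanged(self):
        v = np.full((9, 9), 4.2)
        out = laplacian_step(v, D=1.0, lambda_=1.0, dt=0.2)
        np.testing.assert_allclose(out, v, rtol=1e-14)

    def test_mass_conserved_to_rounding(self, rng):
        v = rng.uniform(0, 10, size=(33, 21))
        out = laplacian_step(v, D=0.7, lambda_=1.0, dt=0.3)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-12)

    def test_unstable_step_rejected(self):
        with pytest.raises(UnstableStepError):
            laplacian_step(np.ones((4, 4)), D=1.0, lambda_=1.0, dt=0.3)

    def test_delta_matches_heat_kernel(self):
        """Free spreading of a point source matches the 2-D Gaussian kernel
        in relative L2 before boundary contact."""
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
        assert np.linalg.norm(v - ref) / np.linalg.norm(ref) < 0.01


class TestPdeRun:
    def test_pure_diffusion_run_is_heat_kernel(self):
        n, D, T = 65, 1.0, 12.0
        net = ReactionNetwork([SpeciesSpec("A", D, 0.0)], [],
                              GridSpec(n, n, 1.0))
        vals = np.zeros((1, n, n))
        vals[0, n // 2, n // 2] = 1.0
        traj = pde_run(net, Field(0.0, vals),
                       RunConfig(t_end=T, snapshot_times=[T]))
        x = np.arange(n) - n // 2
        X, Y = np.meshgrid(x, x)
        ref = np.exp(-(X ** 2 + Y ** 2) / (4 * D * T)) / (4 * np.pi * D * T)
        got = traj.final.values[0]
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) < 0.01

    def test_homogeneous_no_diffusion_equals_point_kinetics(self):
        net = ReactionNetwork(
            [SpeciesSpec("A", 0.0, 5.0)],
            [Reaction({"A": 1}, {}, RateLaw("mass_action", 0.5, 1))],
            GridSpec(6, 6, 1.0))
        vals = np.full((1, 6, 6), 5.0)
        traj = pde_run(net, Field(0.0, vals),
                       RunConfig(t_end=4.0, snapshot_times=[4.0], dt=0.25))
        expected = 5.0 * np.exp(-0.5 * 4.0)
        np.testing.assert_allclose(traj.final.values[0], expected, rtol=1e-5)
        # spatial symmetry preserved exactly
        assert np.ptp(traj.final.values[0]) == 0.0

    def test_fields_stay_non_negative(self):
        # rapid consumption near zero must not drive values negative
        net = ReactionNetwork(
            [SpeciesSpec("A", 1.0, 0.0)],
            [Reaction({"A": 1}, {}, RateLaw("mass_action", 50.0, 1))],
            GridSpec(8, 8, 1.0))
        vals = np.zeros((1, 8, 8))
        vals[0, 4, 4] = 1e-6
        traj = pde_run(net, Field(0.0, vals),
                       RunConfig(t_end=1.0, snapshot_times=[1.0]))
        assert np.all(traj.final.values >= 0)
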