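"""Cost functionals, H1 machinery and the Nash solver on small grids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fpnash as fp
from fpnash.grid import DensityField
from fpnash.nash import _evaluate
from conftest import random_admissible


@pytest.fixture(scope="module")
def small(huber):
    grid = fp.build_grid(huber.bounds, 16, huber.horizon, 16)
    return huber.players, grid


class TestTerminalCost:
    def test_point_mass_at_target_costs_nothing(self):
        grid = fp.build_grid([(-3, 3), (-3, 3)], 20, 3.0, 4)
        cx, cy = grid.centers
        player = fp.PlayerSpec((-1, 0), (cx[15], cy[10]))
        values = np.zeros((5, 20, 20))
        values[-1, 15, 10] = 1.0 / grid.cell_area
        f = DensityField(values, grid)
        assert fp.terminal_cost(f, player, 100.0, grid) == 0.0
        assert fp.terminal_cost(f, fp.PlayerSpec((-1, 0), (0.3, -0.7)), 0.0, grid) == 0.0

    def test_gaussian_moment(self):
        # E|X - x_T|^2 = 2 s^2 for an isotropic Gaussian centered at x_T
        grid = fp.build_grid([(-3, 3), (-3, 3)], 100, 3.0, 2)
        player = fp.PlayerSpec((0.0, 0.0), (0.0, 0.0), width=0.5)
        f0 = fp.initial_density(player, grid)
        values = np.broadcast_to(f0, (3, 100, 100))
        cost = fp.terminal_cost(DensityField(np.array(values), grid), player, 100.0, grid)
        s2 = player.width / 2.0
        assert cost == pytest.approx(100.0 * 2 * s2, rel=1e-3)


class TestControlCost:
    def test_zero_and_homogeneity(self):
        grid = fp.build_grid([(0, 1), (0, 1)], 4, 2.0, 20)
        u = np.zeros((21, 2))
        assert fp.control_cost(u, 1.0, grid) == 0.0
        rng = np.random.default_rng(0)
        u = random_admissible(grid, rng)
        assert fp.control_cost(2 * u, 1.0, grid) == pytest.approx(
            4 * fp.control_cost(u, 1.0, grid)
        )

    def test_sine_closed_form(self):
        T = 3.0
        grid = fp.build_grid([(0, 1), (0, 1)], 4, T, 400)
        u = np.zeros((401, 2))
        u[:, 0] = np.sin(np.pi * grid.times / T)
        expected = 0.5 * (T / 2 + np.pi**2 / (2 * T))
        assert fp.control_cost(u, 1.0, grid) == pytest.approx(expected, rel=1e-4)


class TestInteractionAndCollision:
    def test_zero_rho_and_disjoint_supports(self):
        grid = fp.build_grid([(-3, 3), (-3, 3)], 10, 3.0, 4)
        a = np.zeros((5, 10, 10))
        b = np.zeros((5, 10, 10))
        a[:, :3] = 1.0
        b[:, 7:] = 1.0
        fa, fb = DensityField(a, grid), DensityField(b, grid)
        assert fp.interaction_cost(fa, fb, 0.0, grid) == 0.0
        assert fp.interaction_cost(fa, fb, 5.0, grid) == 0.0

    def test_uniform_densities_direct_integral(self):
        # f1 = f2 = 1/36 on |Omega| = 36 for T = 3: W = rho * T / 36
        grid = fp.build_grid([(-3, 3), (-3, 3)], 12, 3.0, 6)
        vals = np.full((7, 12, 12), 1.0 / 36.0)
        f = DensityField(vals, grid)
        assert fp.interaction_cost(f, f, 1.0, grid) == pytest.approx(3.0 / 36.0)
        assert fp.collision_probability(f, f, 0.6, grid, 3) == pytest.approx(0.01)

    def test_collision_probability_against_double_integral(self):
        """r^2 overlap vs the brute-force pair integral over |y - x| < r.

        The r^D prefactor of the model drops the unit-ball volume (pi in
        2-D) — it is an order-of-magnitude surrogate whose scale is
        absorbed into the interaction strength C.  Up to that factor the
        small-r estimate matches the exact double integral.
        """
        grid = fp.build_grid([(-2, 2), (-2, 2)], 80, 1.0, 2)
        p1 = fp.PlayerSpec((-0.3, 0.0), (0, 0), width=1.0)
        p2 = fp.PlayerSpec((0.3, 0.2), (0, 0), width=1.0)
        f1 = fp.initial_density(p1, grid)
        f2 = fp.initial_density(p2, grid)
        r = 0.35
        approx = fp.collision_probability(f1, f2, r, grid, 0)
        gx, gy = grid.meshgrid()
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        inside = d2 < r * r
        brute = float(
            (f1.ravel()[:, None] * f2.ravel()[None, :] * inside).sum()
            * grid.cell_area**2
        )
        assert np.pi * approx == pytest.approx(brute, rel=0.10)


class TestCompositeCost:
    def test_trivial_zero(self, small):
        players, grid = small
        params = fp.GameParameters(sigma=0.3, alpha=0.0, rho=0.0)
        z = np.zeros((grid.n_steps + 1, 2))
        assert fp.composite_cost(z, z, params, players, grid).jhat == 0.0

    def test_separates_at_rho_zero(self, small):
        players, grid = small
        params = fp.GameParameters(sigma=0.3, rho=0.0)
        rng = np.random.default_rng(5)
        u1, u2 = random_admissible(grid, rng), random_admissible(grid, rng)
        bd = fp.composite_cost(u1, u2, params, players, grid)
        # independent single-player costs
        singles = []
        for player, u in zip(players, (u1, u2)):
            f = fp.solve_fp(player, u, params, grid)
            singles.append(
                fp.terminal_cost(f, player, params.alpha, grid)
                + fp.control_cost(u, params.nu, grid)
            )
        assert bd.jhat == pytest.approx(sum(singles), rel=1e-12)

    def test_bookkeeping_identity(self, small):
        # J1 + J2 = Jhat + W for any control pair
        players, grid = small
        params = fp.GameParameters(sigma=0.3, rho=40.0)
        rng = np.random.default_rng(9)
        bd = fp.composite_cost(
            random_admissible(grid, rng), random_admissible(grid, rng),
            params, players, grid,
        )
        assert bd.j[0] + bd.j[1] == pytest.approx(bd.jhat + bd.interaction, rel=1e-12)


class TestGradientPieces:
    def test_reduced_gradient_trivial(self, small):
        players, grid = small
        params = fp.GameParameters(sigma=0.3, alpha=0.0, rho=0.0)
        from fpnash.adjoint import solve_adjoint

        u = np.zeros((grid.n_steps + 1, 2))
        f = fp.solve_fp(players[0], u, params, grid)
        adj = solve_adjoint(players[0], None, u, params, grid)
        g = fp.reduced_gradient(f, adj, u, 1.0, grid)
        assert np.allclose(g, 0.0)

        # with zero coupling the gradient is nu*u - nu*u''
        rng = np.random.default_rng(2)
        u = random_admissible(grid, rng)
        g = fp.reduced_gradient(f, adj, u, 2.0, grid)
        dt = grid.dt
        upp = (u[2:] - 2 * u[1:-1] + u[:-2]) / dt**2
        assert np.allclose(g[1:-1], 2.0 * (u[1:-1] - upp))

    def test_h1_smooth_constant_load(self):
        T = 2.0
        grid = fp.build_grid([(0, 1), (0, 1)], 4, T, 200)
        c = 1.7
        g = np.full((201, 2), c)
        w = fp.h1_smooth(g, grid)
        t = grid.times
        exact = c * (1 - np.cosh(t - T / 2) / np.cosh(T / 2))
        assert np.abs(w[:, 0] - exact).max() < 1e-4
        assert np.allclose(fp.h1_smooth(np.zeros_like(g), grid), 0.0)

    def test_h1_smooth_positive_definite(self):
        grid = fp.build_grid([(0, 1), (0, 1)], 4, 1.0, 30)
        rng = np.random.default_rng(4)
        for _ in range(5):
            g = random_admissible(grid, rng)
            w = fp.h1_smooth(g, grid)
            assert (w * g).sum() * grid.dt >= 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_projection_idempotent_and_clipping(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.uniform(-10, 10, (12, 2))
        p1 = fp.project(u, (-5, 5))
        assert p1.min() >= -5 and p1.max() <= 5
        assert np.all(p1[0] == 0) and np.all(p1[-1] == 0)
        assert np.array_equal(fp.project(p1, (-5, 5)), p1)


class TestSolveNash:
    @pytest.fixture(scope="class")
    def quick_settings(self):
        return fp.OptimizerSettings(max_iters=400)

    @pytest.fixture(scope="class")
    def rho_zero_solution(self, small, quick_settings):
        players, grid = small
        params = fp.GameParameters(sigma=0.3, rho=0.0)
        return fp.solve_nash(players, params, grid, quick_settings)

    def test_rho_zero_with_matching_drift_needs_little_control(
        self, rho_zero_solution
    ):
        # the straight-line drift already reaches the target; the small
        # residual controls only compensate wall-truncation drag
        for c in rho_zero_solution.controls:
            assert np.abs(c.values).max() < 0.5

    def test_descent_is_monotone(self, small):
        # restarts disabled: the history is a single Armijo descent segment
        players, grid = small
        params = fp.GameParameters(sigma=0.3, rho=0.0)
        sol = fp.solve_nash(players, params, grid,
                            fp.OptimizerSettings(max_iters=120, n_restarts=0))
        jhats = sol.history[:, 1]
        assert np.all(np.diff(jhats) <= 1e-12)

    def test_separability_matches_best_response(self, small, quick_settings,
                                                rho_zero_solution):
        """At rho = 0 the joint solve decouples into the two single-player
        problems.  Controls are compared within the optimizer's own accuracy
        guarantee |u - u*| <= ||proj grad|| / nu (strong H1 convexity of the
        control cost), and the individual costs must coincide tightly."""
        players, grid = small
        params = fp.GameParameters(sigma=0.3, rho=0.0)
        joint = rho_zero_solution
        z = np.zeros((grid.n_steps + 1, 2))
        for p in range(2):
            single = fp.solve_best_response(p, players, z, params, grid,
                                            quick_settings)
            gn_joint = joint.history[np.isfinite(joint.history[:, 2]), 2]
            gn_single = single.history[np.isfinite(single.history[:, 2]), 2]
            bound = (gn_joint[-1] + gn_single[-1]) / params.nu
            diff = np.abs(
                joint.controls[p].values - single.controls[p].values
            ).max()
            assert diff <= max(bound, 1e-6)
            # cost-level separability: the independently optimized G_p
            # matches the joint solve's G_p component
            # flat-valley equivalence: both runs stall within the same
            # shallow basin, so costs match to ~1e-4 relative even where
            # the control gap is at the bound above
            gp_joint = joint.breakdown.g[p]
            gp_single = single.breakdown.g[p]
            assert gp_single == pytest.approx(gp_joint, rel=2e-3)

    def test_high_rho_increases_separation(self, small):
        players, grid = small
        lo = fp.solve_nash(players, fp.GameParameters(sigma=0.3, rho=0.01), grid,
                           fp.OptimizerSettings(max_iters=60))
        hi = fp.solve_nash(players, fp.GameParameters(sigma=0.3, rho=200.0), grid,
                           fp.OptimizerSettings(max_iters=120))
        d_lo = fp.min_mean_distance(*lo.mean_trajectories())
        d_hi = fp.min_mean_distance(*hi.mean_trajectories())
        assert d_hi > d_lo

    def test_verify_nash_flags_perturbed_solution(self, small, quick_settings):
        players, grid = small
        params = fp.GameParameters(sigma=0.3, rho=0.0)
        sol = fp.solve_nash(players, params, grid, quick_settings)
        cert = fp.verify_nash(sol, n_probes=20, seed=0)
        assert cert.passed

        # deliberately non-equilibrium control: improving deviations exist
        bad = np.zeros((grid.n_steps + 1, 2))
        bad[1:-1, 0] = 3.0
        bd, fields, _ = _evaluate(players, (bad, bad), params, grid)
        from fpnash.nash import ControlTrajectory, NashSolution

        fake = NashSolution(
            players=players, params=params, grid=grid,
            controls=(ControlTrajectory(bad, (-5, 5)),
                      ControlTrajectory(bad, (-5, 5))),
            fields=tuple(fields), breakdown=bd,
            history=np.zeros((1, 3)), converged=True, message="fake",
        )
        cert = fp.verify_nash(fake, n_probes=30, probe_scale=0.5, seed=0)
        assert not cert.passed
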