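"""Cost functionals and the Nash-equilibrium solver.

The avoidance game assigns pedestrian p the cost

    J_p = alpha int V(x - x_T^p) f_p(x, T) dx            (terminal)
        + (nu/2) ||u_p||_{H1(0,T)}^2                     (control effort)
        + rho int_0^T int f_1 f_2 dx dt                  (collision term W),

and an open-loop Nash equilibrium is computed by jointly minimizing the
composite functional Jhat = G_1 + G_2 + W (whose minimizers are equilibria
of the separable game) with a projected, H1-smoothed gradient descent under
box constraints and pinned-to-zero endpoint controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .adjoint import AdjointField, _trapezoid_weights, adjoint_sweep, solve_adjoint
from .forward import GameParameters, PlayerSpec, _control_values, solve_fp
from .grid import DensityField, SpaceTimeGrid, mean_trajectory, overlap

__all__ = [
    "ControlTrajectory",
    "OptimizerSettings",
    "CostBreakdown",
    "NashSolution",
    "NashCertificate",
    "terminal_cost",
    "control_cost",
    "interaction_cost",
    "collision_probability",
    "composite_cost",
    "reduced_gradient",
    "h1_smooth",
    "project",
    "solve_nash",
    "solve_best_response",
    "verify_nash",
]


@dataclass
class ControlTrajectory:
    """Time-dependent control u(t) in R^2 sampled at the M+1 time nodes.

    Admissibility: u(0) = u(T) = 0 and every component in [u_a, u_b].
    """

    values: np.ndarray
    bounds: tuple[float, float] = (-5.0, 5.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError(f"control must have shape (M+1, 2), got {self.values.shape}")

    @classmethod
    def zeros(cls, grid: SpaceTimeGrid, bounds=(-5.0, 5.0)) -> "ControlTrajectory":
        return cls(np.zeros((grid.n_steps + 1, 2)), bounds)

    def is_admissible(self, atol: float = 1e-12) -> bool:
        ua, ub = self.bounds
        ok_ends = np.all(np.abs(self.values[[0, -1]]) <= atol)
        return bool(ok_ends and self.values.min() >= ua - atol and self.values.max() <= ub + atol)


def project(u, bounds) -> np.ndarray:
    """Componentwise clip into [u_a, u_b] with endpoints forced to zero."""
    values = np.asarray(getattr(u, "values", u), dtype=float)
    ua, ub = bounds
    out = np.clip(values, ua, ub)
    out[0] = 0.0
    out[-1] = 0.0
    return out


# --- cost functionals ----------------------------------------------------

def terminal_cost(density: DensityField, player: PlayerSpec, alpha: float,
                  grid: SpaceTimeGrid) -> float:
    """alpha * int V(x - x_T) f(x, T) dx with V(y) = |y|^2."""
    v_pot = player.terminal_potential(grid)
    return float(alpha * (v_pot * density.values[-1]).sum() * grid.cell_area)


def control_cost(u, nu: float, grid: SpaceTimeGrid) -> float:
    """(nu/2) (int |u|^2 dt + int |u'|^2 dt), trapezoid + forward differences."""
    values = np.asarray(getattr(u, "values", u), dtype=float)
    dt = grid.dt
    l2 = np.trapezoid((values**2).sum(axis=1), dx=dt)
    h1 = (np.diff(values, axis=0) ** 2).sum() / dt
    return float(0.5 * nu * (l2 + h1))


def interaction_cost(f1: DensityField, f2: DensityField, rho: float,
                     grid: SpaceTimeGrid) -> float:
    """W = rho * int_0^T int f1 f2 dx dt (trapezoid in time)."""
    if f1.values.shape != f2.values.shape:
        raise ValueError("densities live on different grids")
    overlaps = (f1.values * f2.values).sum(axis=(1, 2)) * grid.cell_area
    return float(rho * np.trapezoid(overlaps, dx=grid.dt))


def collision_probability(f1, f2, r: float, grid: SpaceTimeGrid,
                          time_index: int) -> float:
    """Small-radius estimate r^2 * int f1 f2 dx of Prob{|X2 - X1| < r}."""
    return r**2 * overlap(f1, f2, grid, time_index)


@dataclass
class CostBreakdown:
    """Component values of the game costs for a control pair."""

    terminal: tuple[float, float]
    control: tuple[float, float]
    interaction: float

    @property
    def g(self) -> tuple[float, float]:
        return tuple(t + c for t, c in zip(self.terminal, self.control))

    @property
    def j(self) -> tuple[float, float]:
        """Individual costs J_p = G_p + W."""
        return tuple(gp + self.interaction for gp in self.g)

    @property
    def jhat(self) -> float:
        """Composite cost Jhat = G1 + G2 + W = J1 + J2 - W."""
        return sum(self.g) + self.interaction

    def as_dict(self) -> dict:
        return {
            "J1": self.j[0],
            "J2": self.j[1],
            "Jhat": self.jhat,
            "terminal_1": self.terminal[0],
            "terminal_2": self.terminal[1],
            "control_1": self.control[0],
            "control_2": self.control[1],
            "interaction": self.interaction,
        }


def _evaluate(players, controls, params, grid, densities=None):
    """Solve both forward problems (reusing cached ones) and price them.

    Freshly solved players keep their sub-step records (``auxes``) so a
    later adjoint sweep does not repeat the forward solve.
    """
    fields = []
    auxes = [None, None]
    for p, (player, u) in enumerate(zip(players, controls)):
        if densities is not None and densities[p] is not None:
            fields.append(densities[p])
        else:
            f, aux = solve_fp(player, u, params, grid, store_intermediates=True)
            fields.append(f)
            auxes[p] = aux
    breakdown = CostBreakdown(
        terminal=tuple(
            terminal_cost(f, player, params.alpha, grid)
            for f, player in zip(fields, players)
        ),
        control=tuple(control_cost(u, params.nu, grid) for u in controls),
        interaction=interaction_cost(fields[0], fields[1], params.rho, grid),
    )
    return breakdown, fields, auxes


def composite_cost(u1, u2, params: GameParameters, players, grid: SpaceTimeGrid):
    """Run both forward solves and return the CostBreakdown (incl. Jhat)."""
    u1 = _control_values(u1, grid.n_steps + 1)
    u2 = _control_values(u2, grid.n_steps + 1)
    breakdown, _, _ = _evaluate(players, (u1, u2), params, grid)
    return breakdown


# --- gradient machinery --------------------------------------------------

def reduced_gradient(f: DensityField, p_adj: AdjointField, u, nu: float,
                     grid: SpaceTimeGrid) -> np.ndarray:
    """Reduced L2 gradient nu u - nu u'' - int (dp/dx_k) f dx per time node.

    The coupling term is the exact discrete contraction precomputed by the
    adjoint sweep; the time Laplacian uses second differences.  Endpoint
    nodes (where the control is pinned to zero) carry zero gradient.
    """
    values = np.asarray(getattr(u, "values", u), dtype=float)
    if p_adj.coupling.shape != values.shape:
        raise ValueError("control and adjoint live on different time grids")
    dt = grid.dt
    g = np.zeros_like(values)
    upp = (values[2:] - 2.0 * values[1:-1] + values[:-2]) / dt**2
    g[1:-1] = nu * values[1:-1] - nu * upp + p_adj.coupling[1:-1] / dt
    return g


def h1_smooth(g, grid: SpaceTimeGrid) -> np.ndarray:
    """Solve -w'' + w = g on (0, T), w(0) = w(T) = 0 (H1 Riesz lift)."""
    g = np.asarray(getattr(g, "values", g), dtype=float)
    dt = grid.dt
    n = g.shape[0] - 2  # interior nodes
    if n < 1:
        return np.zeros_like(g)
    ab = np.zeros((3, n))
    ab[0, 1:] = -1.0 / dt**2
    ab[1, :] = 1.0 + 2.0 / dt**2
    ab[2, :-1] = -1.0 / dt**2
    w = np.zeros_like(g)
    w[1:-1] = solve_banded((1, 1), ab, g[1:-1])
    return w


def _h1_norm_sq(values: np.ndarray, dt: float) -> float:
    l2 = np.trapezoid((values**2).sum(axis=-1), dx=dt, axis=0)
    h1 = (np.diff(values, axis=0) ** 2).sum() / dt
    return float(np.sum(l2) + h1)


def _player_gradient(p, players, controls, fields, auxes, params, grid):
    """H1-smoothed reduced gradient of Jhat w.r.t. player p's control."""
    other = fields[1 - p] if params.rho > 0 else None
    if auxes is not None and auxes[p] is not None:
        adj = adjoint_sweep(players[p], other, params, grid, fields[p], auxes[p])
    else:
        adj = solve_adjoint(players[p], other, controls[p], params, grid)
    g = reduced_gradient(fields[p], adj, controls[p], params.nu, grid)
    return h1_smooth(g, grid)


# --- optimizer -----------------------------------------------------------

@dataclass(frozen=True)
class OptimizerSettings:
    """Projected-gradient settings (Armijo backtracking on Jhat)."""

    max_iters: int = 600
    tol: float = 1e-5  # stop when ||proj grad||_H1 < tol * (1 + |Jhat|)
    armijo_init: float = 1.0
    armijo_shrink: float = 0.5
    armijo_slope: float = 1e-4
    max_backtracks: int = 30
    # spectral (Barzilai-Borwein) scaling of the first Armijo trial step;
    # plain steepest descent crawls on the ill-conditioned tail without it
    bb_step: bool = True
    bb_step_max: float = 1e3
    # also declare convergence when accepted steps stop making progress:
    # relative Jhat decrease below stall_tol on stall_window consecutive
    # accepted iterations
    stall_tol: float = 1e-9
    stall_window: int = 5
    # stall escape: symmetric crossings are stationary points of the
    # interaction term (the overlap is maximal at zero relative shift) and
    # the upwind switch of the transport scheme leaves derivative kinks at
    # vanishing drift components, so after a stall the iterate is perturbed
    # by a small deterministic admissible direction and descent continues;
    # the best iterate over all segments is returned
    n_restarts: int = 2
    restart_scale: float = 0.01  # fraction of the control-bound width
    restart_seed: int = 1234


@dataclass
class NashSolution:
    """Equilibrium control pair with costs, trajectories and diagnostics."""

    players: tuple[PlayerSpec, PlayerSpec]
    params: GameParameters
    grid: SpaceTimeGrid
    controls: tuple[ControlTrajectory, ControlTrajectory]
    fields: tuple[DensityField, DensityField]
    breakdown: CostBreakdown
    history: np.ndarray  # columns: iteration, Jhat, proj-grad H1 norm
    converged: bool
    message: str

    @property
    def jhat(self) -> float:
        return self.breakdown.jhat

    @property
    def j1(self) -> float:
        return self.breakdown.j[0]

    @property
    def j2(self) -> float:
        return self.breakdown.j[1]

    def mean_trajectories(self) -> tuple[np.ndarray, np.ndarray]:
        return tuple(mean_trajectory(f, self.grid) for f in self.fields)


def _restart_direction(rng, grid, scale):
    """Small deterministic admissible perturbation used for saddle escape."""
    t = grid.times / grid.horizon
    delta = np.zeros((grid.n_steps + 1, 2))
    for k in range(3):
        delta += np.outer(np.sin((k + 1) * np.pi * t), rng.standard_normal(2))
    peak = np.abs(delta).max()
    return delta * (scale / peak if peak > 0 else 0.0)


def _optimize(players, params, grid, settings, active, init):
    """Projected H1-gradient descent on Jhat over the active controls.

    Runs descent segments separated by small deterministic perturbations
    (saddle escape, only when rho > 0); the best iterate wins.
    """
    bounds = (params.u_a, params.u_b)
    controls = [project(np.array(c, dtype=float), bounds) for c in init]
    # densities of inactive players never change; cache them
    static = [
        solve_fp(players[p], controls[p], params, grid) if p not in active else None
        for p in (0, 1)
    ]
    rng = np.random.Generator(np.random.Philox(key=settings.restart_seed))
    best = None
    history = []
    it_start = 0
    segments = 0
    while True:
        state = _descend(
            players, params, grid, settings, active, controls, static,
            it_start, history,
        )
        segments += 1
        if best is None or state[1].jhat < best[1].jhat:
            best = state
        controls, breakdown, fields, converged, message, it_end = state
        budget_left = settings.max_iters - it_end
        if (
            segments > settings.n_restarts
            or budget_left < settings.stall_window + 1
        ):
            break
        delta = _restart_direction(
            rng, grid, settings.restart_scale * (params.u_b - params.u_a)
        )
        controls = list(best[0])
        for p in active:
            sgn = 1.0 if p == 0 else -1.0  # opposite nudges break symmetry
            controls[p] = project(controls[p] + sgn * delta, bounds)
        it_start = it_end

    controls, breakdown, fields, converged, message, _ = best
    if segments > 1:
        message += f" ({segments} descent segments)"
    ctrl = tuple(ControlTrajectory(c, bounds) for c in controls)
    return NashSolution(
        players=tuple(players),
        params=params,
        grid=grid,
        controls=ctrl,
        fields=tuple(fields),
        breakdown=breakdown,
        history=np.asarray(history, dtype=float),
        converged=converged,
        message=message,
    )


def _descend(players, params, grid, settings, active, controls, static,
             it_start, history):
    """One monotone descent segment; appends to ``history`` in place."""
    bounds = (params.u_a, params.u_b)
    dt = grid.dt
    controls = list(controls)
    breakdown, fields, auxes = _evaluate(players, controls, params, grid, static)
    seg_rows = [(it_start, breakdown.jhat, np.nan)]
    history.append(seg_rows[0])
    converged = False
    message = "max iterations reached"
    prev_u = prev_w = None

    it = it_start
    for it in range(it_start + 1, settings.max_iters + 1):
        smooth = [np.zeros_like(controls[p]) for p in (0, 1)]
        for p in active:
            smooth[p] = _player_gradient(
                p, players, controls, fields, auxes, params, grid
            )
        pg = np.stack(
            [controls[p] - project(controls[p] - smooth[p], bounds) for p in active]
        )
        pg_norm = np.sqrt(sum(_h1_norm_sq(pgp, dt) for pgp in pg))
        history[-1] = (history[-1][0], history[-1][1], pg_norm)
        if pg_norm < settings.tol * (1.0 + abs(breakdown.jhat)):
            converged = True
            message = f"projected-gradient norm {pg_norm:.3e} below tolerance"
            break

        tau = settings.armijo_init
        cur_u = np.stack([controls[p] for p in active])
        cur_w = np.stack([smooth[p] for p in active])
        if settings.bb_step and prev_u is not None:
            s = cur_u - prev_u
            y = cur_w - prev_w
            sy = float((s * y).sum())
            if sy > 0:
                tau = min(float((s * s).sum()) / sy, settings.bb_step_max)
        prev_u, prev_w = cur_u, cur_w
        accepted = False
        for _ in range(settings.max_backtracks + 1):
            trial = list(controls)
            for p in active:
                trial[p] = project(controls[p] - tau * smooth[p], bounds)
            step_sq = sum(
                float(((trial[p] - controls[p]) ** 2).sum()) * dt for p in active
            )
            if step_sq == 0.0:
                break
            tb, tf, ta = _evaluate(players, trial, params, grid, static)
            if tb.jhat <= breakdown.jhat - settings.armijo_slope / tau * step_sq:
                controls, breakdown, fields, auxes = trial, tb, tf, ta
                accepted = True
                break
            tau *= settings.armijo_shrink
        if not accepted:
            message = f"line search stalled at iteration {it}"
            warnings.warn(
                "Armijo line search could not decrease Jhat; "
                "returning best iterate",
                RuntimeWarning,
            )
            break
        row = (it, breakdown.jhat, np.nan)
        history.append(row)
        seg_rows.append(row)
        if len(seg_rows) > settings.stall_window:
            recent = [h[1] for h in seg_rows[-(settings.stall_window + 1):]]
            if recent[0] - recent[-1] < settings.stall_tol * (1.0 + abs(recent[-1])):
                converged = True
                message = (
                    f"Jhat progress below stall tolerance after {it} iterations"
                )
                break

    return controls, breakdown, fields, converged, message, it


def solve_nash(
    players,
    params: GameParameters,
    grid: SpaceTimeGrid,
    settings: OptimizerSettings | None = None,
    init_controls=None,
) -> NashSolution:
    """Compute an open-loop Nash equilibrium by joint minimization of Jhat.

    Starts from zero controls, runs projected H1-gradient descent with
    Armijo backtracking over both controls simultaneously, and stops when
    the H1 norm of the projected gradient drops below
    ``tol * (1 + |Jhat|)``.
    """
    players = tuple(getattr(players, "players", players))
    settings = settings or OptimizerSettings()
    n_nodes = grid.n_steps + 1
    if init_controls is None:
        init = [np.zeros((n_nodes, 2)), np.zeros((n_nodes, 2))]
    else:
        init = [_control_values(c, n_nodes) for c in init_controls]
    return _optimize(players, params, grid, settings, active=(0, 1), init=init)


def solve_best_response(
    player_index: int,
    players,
    fixed_control,
    params: GameParameters,
    grid: SpaceTimeGrid,
    settings: OptimizerSettings | None = None,
    init_control=None,
) -> NashSolution:
    """Minimize J_p over player p's control with the opponent frozen.

    With rho = 0 this is the independent single-player optimal control
    problem; in general it is one best-response step of the game.
    """
    players = tuple(getattr(players, "players", players))
    settings = settings or OptimizerSettings()
    n_nodes = grid.n_steps + 1
    init = [np.zeros((n_nodes, 2)), np.zeros((n_nodes, 2))]
    init[1 - player_index] = _control_values(fixed_control, n_nodes)
    if init_control is not None:
        init[player_index] = _control_values(init_control, n_nodes)
    return _optimize(
        players, params, grid, settings, active=(player_index,), init=init
    )


# --- equilibrium certificate --------------------------------------------

@dataclass
class NashCertificate:
    """Outcome of the unilateral-deviation check of the equilibrium."""

    n_probes: int
    probe_scale: float
    tolerance: tuple[float, float]
    base_costs: tuple[float, float]
    worst_improvement: tuple[float, float]  # max cost drop seen per player
    violations: tuple[int, int]

    @property
    def passed(self) -> bool:
        return sum(self.violations) == 0


def _random_admissible_perturbation(rng, grid, scale, n_modes=4):
    """Smooth random perturbation vanishing at both endpoints."""
    t = grid.times / grid.horizon
    coeffs = rng.standard_normal((n_modes, 2))
    delta = np.zeros((grid.n_steps + 1, 2))
    for k in range(n_modes):
        delta += np.outer(np.sin((k + 1) * np.pi * t), coeffs[k])
    peak = np.abs(delta).max()
    if peak > 0:
        delta *= scale / peak
    return delta


def verify_nash(
    sol: NashSolution,
    n_probes: int = 50,
    probe_scale: float = 0.1,
    seed: int = 0,
    tol_factor: float = 1e-6,
) -> NashCertificate:
    """Probe the Nash property with random unilateral deviations.

    For each player p, perturbs only u_p by ``n_probes`` random admissible
    directions and checks J_p does not drop below its equilibrium value by
    more than ``tol_factor * |J_p|``.  Improving deviations are findings
    reported in the certificate, not errors.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    players, params, grid = sol.players, sol.params, sol.grid
    bounds = (params.u_a, params.u_b)
    base = sol.breakdown.j
    tol = tuple(tol_factor * abs(j) for j in base)
    violations = [0, 0]
    worst = [0.0, 0.0]
    for p in (0, 1):
        for _ in range(n_probes):
            delta = _random_admissible_perturbation(rng, grid, probe_scale)
            trial = list(c.values for c in sol.controls)
            trial[p] = project(trial[p] + delta, bounds)
            densities = [None, None]
            densities[1 - p] = sol.fields[1 - p]
            tb, _, _ = _evaluate(players, trial, params, grid, densities)
            drop = base[p] - tb.j[p]
            worst[p] = max(worst[p], drop)
            if drop > tol[p]:
                violations[p] += 1
    return NashCertificate(
        n_probes=n_probes,
        probe_scale=probe_scale,
        tolerance=tol,
        base_costs=base,
        worst_improvement=tuple(worst),
        violations=tuple(violations),
    )
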