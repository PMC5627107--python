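"""Particle-level cross-validation of the Fokker-Planck solver.

Simulates the controlled SDE dX = (v + u(t)) dt + sigma dB with reflecting
barriers by Euler-Maruyama with coordinate-wise folding reflection, and
compares ensemble statistics against the grid densities.  Randomness comes
from a counter-based (Philox) generator keyed by the seed, so runs are
bit-exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import GameParameters, PlayerSpec, _control_values
from .grid import DensityField, SpaceTimeGrid, mean_trajectory

__all__ = ["MCEnsemble", "MCReport", "simulate_ensemble", "compare_to_fp"]


@dataclass
class MCEnsemble:
    """Particle positions at every time node; shape (M+1, n, 2)."""

    positions: np.ndarray
    seed: int
    grid: SpaceTimeGrid
    scenario: str | None = None

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def means(self) -> np.ndarray:
        return self.positions.mean(axis=1)

    def standard_errors(self) -> np.ndarray:
        n = self.n_particles
        if n < 2:
            return np.full((self.positions.shape[0], 2), np.inf)
        return self.positions.std(axis=1, ddof=1) / np.sqrt(n)


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect (fold) coordinates into [lo, hi]; valid for any step size."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def simulate_ensemble(
    player: PlayerSpec,
    control,
    params: GameParameters,
    grid: SpaceTimeGrid,
    n_particles: int,
    seed: int = 0,
) -> MCEnsemble:
    """Euler-Maruyama ensemble with folding reflection at the walls.

    Initial positions are drawn from the isotropic Gaussian of the initial
    density (rejection-resampled into the domain); each step uses the drift
    at the left time node, X_{k+1} = X_k + b(t_k) dt + sigma sqrt(dt) xi.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    rng = np.random.Generator(np.random.Philox(key=seed))
    sigma = params.resolve_sigma(grid)
    dt = grid.dt
    v = player.base_drift(grid.horizon)
    u = _control_values(control, grid.n_steps + 1)
    (x_lo, x_hi), (y_lo, y_hi) = grid.bounds

    # rejection sampling of the truncated initial Gaussian
    center = np.asarray(player.departure, dtype=float)
    std = np.sqrt(player.width / 2.0)
    pos = np.empty((n_particles, 2))
    filled = 0
    while filled < n_particles:
        draw = center + std * rng.standard_normal((2 * (n_particles - filled) + 16, 2))
        keep = (
            (draw[:, 0] > x_lo) & (draw[:, 0] < x_hi)
            & (draw[:, 1] > y_lo) & (draw[:, 1] < y_hi)
        )
        good = draw[keep][: n_particles - filled]
        pos[filled : filled + good.shape[0]] = good
        filled += good.shape[0]

    out = np.empty((grid.n_steps + 1, n_particles, 2))
    out[0] = pos
    noise_scale = sigma * np.sqrt(dt)
    for k in range(grid.n_steps):
        b = v + u[k]
        step = out[k] + b * dt
        if sigma > 0:
            step = step + noise_scale * rng.standard_normal((n_particles, 2))
        step[:, 0] = _fold(step[:, 0], x_lo, x_hi)
        step[:, 1] = _fold(step[:, 1], y_lo, y_hi)
        out[k + 1] = step
    return MCEnsemble(out, seed=seed, grid=grid)


@dataclass
class MCReport:
    """Per-time-node agreement between an ensemble and a grid density."""

    mc_means: np.ndarray          # (M+1, 2)
    fp_means: np.ndarray          # (M+1, 2)
    standard_errors: np.ndarray   # (M+1, 2)
    tv_distance: np.ndarray       # (M+1,)
    max_sigma_deviation: float    # max |diff| / SE over nodes and axes

    @property
    def passed(self) -> bool:
        """Mean agreement within 3 standard errors at every node."""
        return bool(self.max_sigma_deviation <= 3.0)


def compare_to_fp(
    ensemble: MCEnsemble, density: DensityField, grid: SpaceTimeGrid
) -> MCReport:
    """Compare ensemble means and histograms against the FP density."""
    if density.values.shape[0] != ensemble.positions.shape[0]:
        raise ValueError("ensemble and density use different time grids")
    mc_means = ensemble.means()
    se = ensemble.standard_errors()
    fp_means = mean_trajectory(density, grid)
    diff = np.abs(mc_means - fp_means)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(diff == 0.0, 0.0, diff / se)
    max_dev = float(np.max(ratio))

    (x_lo, x_hi), (y_lo, y_hi) = grid.bounds
    n1, n2 = grid.n_cells
    edges_x = np.linspace(x_lo, x_hi, n1 + 1)
    edges_y = np.linspace(y_lo, y_hi, n2 + 1)
    tv = np.empty(density.values.shape[0])
    for k in range(tv.shape[0]):
        hist, _, _ = np.histogram2d(
            ensemble.positions[k, :, 0],
            ensemble.positions[k, :, 1],
            bins=(edges_x, edges_y),
        )
        emp = hist / ensemble.n_particles
        model = density.values[k] * grid.cell_area
        tv[k] = 0.5 * np.abs(emp - model).sum()
    return MCReport(
        mc_means=mc_means,
        fp_means=fp_means,
        standard_errors=se,
        tv_distance=tv,
        max_sigma_deviation=max_dev,
    )
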