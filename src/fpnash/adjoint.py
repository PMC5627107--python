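"""Backward adjoint solver supplying gradient information for one player.

The continuous adjoint of the controlled Fokker-Planck equation is the
backward transport-diffusion problem

    -dp/dt - (sigma^2/2) Lap p - b . grad p + rho f_other = 0,
    p(x, T) = -alpha V(x - x_T),

whose solution enters the reduced control gradient through the coupling
term -int (dp/dx_k) f dx.  Here the adjoint is discrete
(discretize-then-optimize): the backward sweep applies the exact
transposes of the linearized forward sub-steps — the implicit diffusion
solves (symmetric, hence self-transposed) and the advection sweeps — so
the finite-dimensional gradient of the reduced cost is exact to solver
roundoff.  Alongside the adjoint field, the sweep contracts the
drift-derivative of each advection sub-step per control node; the result
is stored on the returned :class:`AdjointField` and consumed by
``nash.reduced_gradient``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .forward import (
    GameParameters,
    PlayerSpec,
    _deorient,
    _diffuse,
    _oriented,
    solve_fp,
)
from .grid import DensityField, SpaceTimeGrid

__all__ = ["AdjointField", "solve_adjoint", "adjoint_sweep"]


@dataclass
class AdjointField:
    """Adjoint variable p(x, t_k) plus contracted control couplings.

    ``values`` has shape (M+1, n1, n2); the terminal slice equals
    -alpha V(x - x_T) exactly at cell centers.  ``coupling`` has shape
    (M+1, 2) and holds, per time node and control component, the exact
    discrete counterpart of -int (dp/dx_k) f dx (scaled so that
    ``coupling[m] / dt`` is the functional-gradient contribution of node m).
    """

    values: np.ndarray
    coupling: np.ndarray
    grid: SpaceTimeGrid


def _trapezoid_weights(grid: SpaceTimeGrid) -> np.ndarray:
    w = np.full(grid.n_steps + 1, grid.dt)
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def _advect_axis_adjoint(mu, rec, b_j, dt, h, axis):
    """Transpose the recorded advection substeps; returns (mu_in, dJ/du_j)."""
    inputs, a, n_here, flip = rec
    m = np.ascontiguousarray(_oriented(mu, axis, flip))
    m, dJda = _kernels.advect_adjoint(inputs, m, a)
    sgn = 1.0 if b_j >= 0 else -1.0
    dJdu = dJda * sgn * dt / (h * n_here)
    return np.ascontiguousarray(_deorient(m, axis, flip)), dJdu


def solve_adjoint(
    player: PlayerSpec,
    other_density: DensityField | None,
    control,
    params: GameParameters,
    grid: SpaceTimeGrid,
    *,
    own_density: DensityField | None = None,
) -> AdjointField:
    """Backward sweep of the transposed forward sub-steps for one player.

    ``other_density`` carries the opponent's density entering the
    rho-weighted interaction source; it may be ``None`` only when rho == 0.
    The player's own forward states (including all sub-step intermediates)
    are recomputed internally; ``own_density`` is accepted purely as a
    consistency check.
    """
    own, aux = solve_fp(player, control, params, grid, store_intermediates=True)
    if own_density is not None and not np.allclose(
        own_density.values, own.values, atol=1e-10
    ):
        raise ValueError("own_density does not match the control passed in")
    return adjoint_sweep(player, other_density, params, grid, own, aux)


def adjoint_sweep(
    player: PlayerSpec,
    other_density: DensityField | None,
    params: GameParameters,
    grid: SpaceTimeGrid,
    own: DensityField,
    aux: dict,
) -> AdjointField:
    """Backward sweep given the forward solution and its sub-step records."""
    if params.rho > 0 and other_density is None:
        raise ValueError("other player's density is required when rho > 0")

    h1, h2 = grid.h
    n1, n2 = grid.n_cells
    dt = grid.dt
    m_steps = grid.n_steps
    area = grid.cell_area
    records = aux["records"]
    fac1, fac2 = aux["fac"]

    w = _trapezoid_weights(grid)
    if other_density is None:
        other = np.zeros((m_steps + 1, n1, n2))
    else:
        if other_density.values.shape != own.values.shape:
            raise ValueError("other_density lives on a different grid")
        other = other_density.values

    v_pot = player.terminal_potential(grid)
    p_values = np.empty((m_steps + 1, n1, n2))
    p_values[m_steps] = -params.alpha * v_pot
    coupling = np.zeros((m_steps + 1, 2))

    # lam_k = dJ/df_k (discrete); terminal node carries both the terminal
    # cost and the trapezoid-weighted interaction source.
    lam = area * (params.alpha * v_pot + params.rho * w[m_steps] * other[m_steps])
    for k in range(m_steps - 1, -1, -1):
        rec = records[k]
        b = rec["b"]
        mu = _diffuse(fac2, lam, axis=1)  # symmetric: transpose solve
        mu, dj_y = _advect_axis_adjoint(mu, rec["y"], b[1], dt, h2, axis=1)
        mu = _diffuse(fac1, mu, axis=0)
        mu, dj_x = _advect_axis_adjoint(mu, rec["x"], b[0], dt, h1, axis=0)
        coupling[k, 0] = dj_x
        coupling[k, 1] = dj_y
        lam = mu + area * params.rho * w[k] * other[k]
        p_values[k] = -lam / area

    return AdjointField(p_values, coupling, grid)
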