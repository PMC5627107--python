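"""Cell-centered space-time grids and field reductions.

The spatial domain is a rectangle discretized into a uniform, cell-centered
tensor grid; the time interval [0, T] carries M+1 equispaced nodes.  All
spatial integrals in the package are midpoint (cell-center value times cell
area) sums, which pairs naturally with the conservative finite-volume flux
discretization of the transport solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpaceTimeGrid",
    "DensityField",
    "build_grid",
    "mass",
    "mean_position",
    "overlap",
]


@dataclass(frozen=True)
class SpaceTimeGrid:
    """Uniform cell-centered grid on a rectangle, plus a uniform time grid.

    Attributes
    ----------
    bounds : ((x_lo, x_hi), (y_lo, y_hi))
        Spatial domain in model length units.
    n_cells : (n1, n2)
        Number of cells per axis.
    horizon : float
        Final time T.
    n_steps : int
        Number of time steps M; the grid carries M+1 nodes t_0=0,...,t_M=T.
    """

    bounds: tuple[tuple[float, float], tuple[float, float]]
    n_cells: tuple[int, int]
    horizon: float
    n_steps: int

    @property
    def h(self) -> tuple[float, float]:
        """Cell widths (h1, h2)."""
        return tuple(
            (hi - lo) / n for (lo, hi), n in zip(self.bounds, self.n_cells)
        )

    @property
    def cell_area(self) -> float:
        h1, h2 = self.h
        return h1 * h2

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center coordinates along each axis."""
        out = []
        for (lo, hi), n in zip(self.bounds, self.n_cells):
            h = (hi - lo) / n
            out.append(lo + h * (np.arange(n) + 0.5))
        return tuple(out)

    @property
    def dt(self) -> float:
        return self.horizon / self.n_steps

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_steps + 1)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinate arrays of shape ``n_cells`` (ij indexing)."""
        cx, cy = self.centers
        return np.meshgrid(cx, cy, indexing="ij")

    @property
    def domain_area(self) -> float:
        (x0, x1), (y0, y1) = self.bounds
        return (x1 - x0) * (y1 - y0)

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        return all(lo < v < hi for v, (lo, hi) in zip(p, self.bounds))


@dataclass
class DensityField:
    """Probability density snapshots f(x, t_k) for one player.

    ``values`` has shape (M+1, n1, n2); slice k holds the density at time
    node t_k, evaluated at cell centers.  A well-formed field is nonnegative
    with unit cell-quadrature mass at every node.
    """

    values: np.ndarray
    grid: SpaceTimeGrid
    mass_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_steps + 1, *self.grid.n_cells)
        if self.values.shape != expected:
            raise ValueError(
                f"density array shape {self.values.shape} does not match "
                f"grid shape {expected}"
            )

    def validate(self) -> None:
        """Raise if any slice is negative or off unit mass beyond tolerance."""
        if self.values.min() < -1e-12:
            raise ValueError(
                f"density has negative cells down to {self.values.min():.3e}"
            )
        masses = self.values.sum(axis=(1, 2)) * self.grid.cell_area
        err = np.abs(masses - 1.0).max()
        if err > self.mass_tol:
            raise ValueError(f"mass deviates from 1 by {err:.3e}")


def build_grid(
    bounds,
    n_cells,
    horizon: float,
    n_steps: int,
) -> SpaceTimeGrid:
    """Construct a uniform cell-centered space-time grid.

    Parameters
    ----------
    bounds : pair of (lo, hi) intervals
        Spatial rectangle, one interval per axis.
    n_cells : int or (int, int)
        Cells per axis (>= 4); a scalar is used for both axes.
    horizon : float
        Final time T > 0.
    n_steps : int
        Number of time steps (>= 2 for production grids; >= 1 accepted).
    """
    if np.isscalar(n_cells):
        n_cells = (int(n_cells), int(n_cells))
    n_cells = tuple(int(n) for n in n_cells)
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    if len(bounds) != 2 or len(n_cells) != 2:
        raise ValueError("grid is two-dimensional: need 2 bounds and 2 cell counts")
    for (lo, hi) in bounds:
        if not hi > lo:
            raise ValueError(f"empty interval ({lo}, {hi})")
    for n in n_cells:
        if n < 1:
            raise ValueError(f"non-positive cell count {n}")
    if horizon <= 0:
        raise ValueError(f"non-positive time horizon {horizon}")
    if n_steps < 1:
        raise ValueError(f"non-positive step count {n_steps}")
    return SpaceTimeGrid(bounds, n_cells, float(horizon), int(n_steps))


def _slice(field, time_index: int) -> np.ndarray:
    values = field.values if isinstance(field, DensityField) else np.asarray(field)
    if values.ndim == 2:
        if time_index not in (0, -1):
            raise IndexError("2-D array carries a single time slice")
        return values
    return values[time_index]


def mass(field, grid: SpaceTimeGrid, time_index: int = 0) -> float:
    """Cell-quadrature mass of a density slice: sum(f) * cell area."""
    return float(_slice(field, time_index).sum() * grid.cell_area)


def mean_position(field, grid: SpaceTimeGrid, time_index: int = 0) -> np.ndarray:
    """Mean position of a density slice, sum(x_c f(x_c)) * area.

    Raises ValueError on a (near) zero-mass slice, where the mean is undefined.
    """
    f = _slice(field, time_index)
    m = f.sum() * grid.cell_area
    if abs(m) < 1e-300:
        raise ValueError("mean position undefined for a zero-mass field")
    gx, gy = grid.meshgrid()
    mx = (gx * f).sum() * grid.cell_area / m
    my = (gy * f).sum() * grid.cell_area / m
    return np.array([mx, my])


def overlap(field1, field2, grid: SpaceTimeGrid, time_index: int = 0) -> float:
    """Spatial overlap integral of two densities at one time node.

    Returns the midpoint quadrature of the pointwise product,
    ``sum(f1 * f2) * cell area``; zero exactly when the discrete supports
    are disjoint.
    """
    f1 = _slice(field1, time_index)
    f2 = _slice(field2, time_index)
    if f1.shape != f2.shape:
        raise ValueError(f"grid mismatch: {f1.shape} vs {f2.shape}")
    return float((f1 * f2).sum() * grid.cell_area)


def mean_trajectory(field: DensityField, grid: SpaceTimeGrid) -> np.ndarray:
    """Mean position at every time node; shape (M+1, 2)."""
    return np.stack(
        [mean_position(field, grid, k) for k in range(grid.n_steps + 1)]
    )
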