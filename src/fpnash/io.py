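"""Serialization: HDF5 array container and CSV exports."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .grid import DensityField, SpaceTimeGrid, build_grid

__all__ = [
    "save_fields",
    "load_fields",
    "write_means_csv",
    "write_controls_csv",
    "read_controls_csv",
    "write_history_csv",
]


def save_fields(path, grid: SpaceTimeGrid, f1: DensityField, f2: DensityField) -> None:
    """Write grid geometry and both density stacks to an HDF5 container."""
    cx, cy = grid.centers
    with h5py.File(path, "w") as h5:
        h5.attrs["bounds"] = np.asarray(grid.bounds)
        h5.attrs["horizon"] = grid.horizon
        h5.create_dataset("cell_centers_x", data=cx)
        h5.create_dataset("cell_centers_y", data=cy)
        h5.create_dataset("times", data=grid.times)
        h5.create_dataset("f1", data=f1.values)
        h5.create_dataset("f2", data=f2.values)


def load_fields(path):
    """Read a container written by :func:`save_fields`."""
    with h5py.File(path, "r") as h5:
        bounds = tuple(tuple(b) for b in h5.attrs["bounds"])
        horizon = float(h5.attrs["horizon"])
        f1 = h5["f1"][...]
        f2 = h5["f2"][...]
    n_steps = f1.shape[0] - 1
    grid = build_grid(bounds, f1.shape[1:], horizon, n_steps)
    return grid, DensityField(f1, grid), DensityField(f2, grid)


def _write_rows(path, header, rows) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def write_means_csv(path, times, mean1, mean2) -> None:
    rows = (
        (f"{t:.10g}", *(f"{v:.10g}" for v in (*m1, *m2)))
        for t, m1, m2 in zip(times, mean1, mean2)
    )
    _write_rows(path, ["t", "mx1", "my1", "mx2", "my2"], rows)


def write_controls_csv(path, times, u1, u2) -> None:
    u1 = np.asarray(getattr(u1, "values", u1))
    u2 = np.asarray(getattr(u2, "values", u2))
    rows = (
        (f"{t:.10g}", *(f"{v:.10g}" for v in (*a, *b)))
        for t, a, b in zip(times, u1, u2)
    )
    _write_rows(path, ["t", "u1x", "u1y", "u2x", "u2y"], rows)


def read_controls_csv(path):
    """Read a controls CSV; returns (times, u1, u2) arrays."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    times = np.atleast_1d(data["t"])
    u1 = np.column_stack([np.atleast_1d(data["u1x"]), np.atleast_1d(data["u1y"])])
    u2 = np.column_stack([np.atleast_1d(data["u2x"]), np.atleast_1d(data["u2y"])])
    return times, u1, u2


def write_trajectories_csv(path, times, positions) -> None:
    """Particle trajectories as rows (particle_id, t, x, y).

    ``positions`` has shape (time node, particle, axis).
    """
    positions = np.asarray(positions)
    rows = (
        (str(pid), f"{t:.10g}", f"{positions[k, pid, 0]:.10g}",
         f"{positions[k, pid, 1]:.10g}")
        for pid in range(positions.shape[1])
        for k, t in enumerate(times)
    )
    _write_rows(path, ["particle_id", "t", "x", "y"], rows)


def write_history_csv(path, history) -> None:
    rows = (
        (f"{int(it)}", f"{jhat:.10g}", f"{gn:.10g}")
        for it, jhat, gn in np.asarray(history)
    )
    _write_rows(path, ["iter", "Jhat", "gradnorm"], rows)
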