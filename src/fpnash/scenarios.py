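"""Benchmark scenario registry and trajectory metrics.

Ships the four two-pedestrian crossing benchmarks used to validate the
framework against human avoidance experiments:

* ``huber-135``       — paths crossing at 135 degrees on [-3,3]^2, T = 3;
* ``turnwald-1c-a3``  — diagonal crossing on [-1,8]^2, T = 5;
* ``turnwald-1c-b2``  — narrow-corridor crossing on [-1,1]x[-3,3], T = 5;
* ``gait-posture``    — symmetric X crossing on [-10,10]^2, T = 1 (short
  horizon, hence wide control bounds).

Each scenario fixes the domain, horizon, departure/arrival points, base
drifts (straight-line (A - D)/T where not explicit) and the low/high
interaction strengths rho exercised with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import GameParameters, PlayerSpec
from .grid import SpaceTimeGrid, build_grid

__all__ = [
    "Scenario",
    "SCENARIOS",
    "PRESETS",
    "load_scenario",
    "meeting_time",
    "min_mean_distance",
]


@dataclass(frozen=True)
class Scenario:
    name: str
    bounds: tuple[tuple[float, float], tuple[float, float]]
    horizon: float
    players: tuple[PlayerSpec, PlayerSpec]
    n_cells: tuple[int, int] = (50, 50)
    n_steps: int = 50
    rho_low: float = 0.01
    rho_high: float = 200.0
    control_bounds: tuple[float, float] = (-5.0, 5.0)
    sigma: float | None = None

    def build_grid(self) -> SpaceTimeGrid:
        return build_grid(self.bounds, self.n_cells, self.horizon, self.n_steps)

    def game_parameters(self, rho: float | None = None, **overrides) -> GameParameters:
        ua, ub = self.control_bounds
        kwargs = dict(
            sigma=self.sigma,
            rho=self.rho_low if rho is None else rho,
            u_a=ua,
            u_b=ub,
        )
        kwargs.update(overrides)
        return GameParameters(**kwargs)

    def as_dict(self) -> dict:
        d1, d2 = self.players
        return {
            "name": self.name,
            "bounds": [list(b) for b in self.bounds],
            "horizon": self.horizon,
            "n_cells": list(self.n_cells),
            "n_steps": self.n_steps,
            "rho_low": self.rho_low,
            "rho_high": self.rho_high,
            "control_bounds": list(self.control_bounds),
            "sigma": self.sigma,
            "players": [
                {
                    "departure": [float(v) for v in p.departure],
                    "arrival": [float(v) for v in p.arrival],
                    "drift": [float(v) for v in p.base_drift(self.horizon)],
                    "width": p.width,
                }
                for p in self.players
            ],
        }


SCENARIOS: dict[str, Scenario] = {
    "huber-135": Scenario(
        name="huber-135",
        bounds=((-3.0, 3.0), (-3.0, 3.0)),
        horizon=3.0,
        players=(
            PlayerSpec(departure=(-1.0, 0.0), arrival=(2.0, 0.0), drift=(1.0, 0.0)),
            PlayerSpec(departure=(1.0, 1.0), arrival=(-2.0, -2.0), drift=(-1.0, -1.0)),
        ),
        rho_high=200.0,
    ),
    "turnwald-1c-a3": Scenario(
        name="turnwald-1c-a3",
        bounds=((-1.0, 8.0), (-1.0, 8.0)),
        horizon=5.0,
        players=(
            PlayerSpec(departure=(1.0, 1.0), arrival=(6.0, 4.0)),
            PlayerSpec(departure=(6.0, 1.0), arrival=(1.0, 4.0)),
        ),
        rho_high=200.0,
    ),
    "turnwald-1c-b2": Scenario(
        name="turnwald-1c-b2",
        bounds=((-1.0, 1.0), (-3.0, 3.0)),
        horizon=5.0,
        players=(
            PlayerSpec(departure=(0.0, -2.5), arrival=(0.0, 2.5)),
            PlayerSpec(departure=(-0.5, 2.5), arrival=(0.5, -2.5)),
        ),
        rho_high=150.0,
    ),
    "gait-posture": Scenario(
        name="gait-posture",
        bounds=((-10.0, 10.0), (-10.0, 10.0)),
        horizon=1.0,
        players=(
            PlayerSpec(departure=(-7.5, -7.5), arrival=(7.5, 7.5)),
            PlayerSpec(departure=(-7.5, 7.5), arrival=(7.5, -7.5)),
        ),
        rho_high=200.0,
        # the short horizon needs large avoidance velocities, so the box
        # constraints are widened to stay mostly inactive
        control_bounds=(-40.0, 40.0),
    ),
}

# named override presets on top of registry entries
PRESETS: dict[str, tuple[str, dict]] = {
    # short-horizon variant of the diagonal crossing (active control bounds)
    "turnwald-1c-a3-short": (
        "turnwald-1c-a3",
        {"horizon": 1.0, "control_bounds": (-40.0, 40.0)},
    ),
}

_PLAYER_KEYS = {"departure", "arrival", "drift", "width"}


def load_scenario(name: str, overrides: dict | None = None) -> Scenario:
    """Resolve a scenario by registry name (or preset) plus overrides.

    Override keys are Scenario field names; ``players`` may be a list of
    per-player dicts with departure/arrival/drift/width entries.
    """
    overrides = dict(overrides or {})
    if name in PRESETS:
        base_name, preset = PRESETS[name]
        merged = dict(preset)
        merged.update(overrides)
        return load_scenario(base_name, merged)
    if name not in SCENARIOS:
        known = ", ".join(sorted([*SCENARIOS, *PRESETS]))
        raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}")
    scenario = SCENARIOS[name]
    if "players" in overrides:
        specs = []
        for base, spec in zip(scenario.players, overrides.pop("players")):
            bad = set(spec) - _PLAYER_KEYS
            if bad:
                raise KeyError(f"unknown player keys {sorted(bad)}")
            specs.append(replace(base, **{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in spec.items()}))
        scenario = replace(scenario, players=tuple(specs))
    if overrides:
        valid = {f for f in Scenario.__dataclass_fields__}
        bad = set(overrides) - valid
        if bad:
            raise KeyError(f"unknown scenario overrides {sorted(bad)}")
        fixed = {}
        for k, v in overrides.items():
            if k in ("bounds",):
                v = tuple(tuple(b) for b in v)
            elif k in ("n_cells", "control_bounds"):
                v = tuple(v)
            fixed[k] = v
        scenario = replace(scenario, **fixed)
    return scenario


def meeting_time(mean1: np.ndarray, mean2: np.ndarray, times: np.ndarray):
    """Time node minimizing the inter-mean distance, and that distance.

    Ties break toward the earlier node.  Raises on empty trajectories.
    """
    m1 = np.asarray(mean1, dtype=float)
    m2 = np.asarray(mean2, dtype=float)
    if m1.size == 0 or m2.size == 0:
        raise ValueError("empty trajectory")
    if m1.shape != m2.shape or m1.shape[0] != len(times):
        raise ValueError("trajectories must share the same time nodes")
    dist = np.linalg.norm(m1 - m2, axis=1)
    k = int(np.argmin(dist))  # argmin returns the first minimizer
    return float(times[k]), float(dist[k])


def min_mean_distance(mean1: np.ndarray, mean2: np.ndarray) -> float:
    """Minimal inter-mean distance over the trajectory."""
    return float(np.linalg.norm(np.asarray(mean1) - np.asarray(mean2), axis=1).min())
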