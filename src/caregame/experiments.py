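"""Preset sweep experiments over parameters and initial conditions.

A sweep varies one quantity (a model parameter, or the initial condition
x0 or y0) over a grid, integrates one trajectory per grid value and records
the outcome and convergence time.  The bundled presets, keyed by figure id
("2a" ... "6b"), fix every other input at the reference baseline so each
run is fully reproducible from the id alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .game_model import GameParameters, PARAM_NAMES
from .basin_sensitivity import require_scenario1
from .dynamics import IntegratorSettings, Trajectory, integrate

__all__ = [
    "BASELINE",
    "FIGURE_IDS",
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "run_figure_experiment",
    "convergence_time_ordering",
]

#: Reference parameter set used by every preset experiment (bistable regime).
BASELINE = GameParameters(
    U1=1.0, U2=1.2, P1=2.23, P2=3.0, R1=2.2, R2=2.42,
    C1=4.0, C2=4.21, S1=1.4, S2=1.6, S1p=1.59,
)

_X0_GRID = [round(0.05 + 0.1 * i, 2) for i in range(10)]  # 0.05 ... 0.95

# Preset sweeps: (swept quantity, grid, x0, y0).  x0/y0 of None means the
# swept quantity itself supplies that coordinate.
_FIGURES: dict[str, tuple[str, list[float], Optional[float], Optional[float]]] = {
    "2a": ("x0", _X0_GRID, None, 0.4),
    "2b": ("x0", _X0_GRID, None, 0.6),
    "3a": ("y0", _X0_GRID, 0.5, None),
    "3b": ("y0", _X0_GRID, 0.6, None),
    "4a": ("U1", [0.85, 0.90, 0.95, 1.00, 1.05], 0.5, 0.5),
    "4b": ("R1", [2.0, 2.1, 2.2, 2.3, 2.4], 0.5, 0.5),
    "5ab": ("P1", [1.81, 1.91, 2.01, 2.11, 2.21], 0.5, 0.5),
    "5c": ("C1", [3.8, 3.9, 4.0, 4.1, 4.2], 0.5, 0.5),
    "6a": ("S1", [1.25, 1.30, 1.35, 1.40, 1.45], 0.5, 0.5),
    "6b": ("S1p", [1.3, 1.4, 1.5, 1.6, 1.7], 0.5, 0.5),
}

FIGURE_IDS = tuple(_FIGURES)


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sweep definition.

    ``quantity`` is a parameter name or "x0"/"y0"; the grid must be
    nonempty and strictly increasing.  ``require_scenario1`` asserts the
    bistable-regime conditions at every grid point before integrating.
    """

    quantity: str
    grid: tuple[float, ...]
    params: GameParameters
    x0: Optional[float]
    y0: Optional[float]
    settings: IntegratorSettings = dataclass_field(default_factory=IntegratorSettings)
    require_scenario1: bool = False

    def __post_init__(self) -> None:
        if self.quantity not in PARAM_NAMES + ("x0", "y0"):
            raise ValueError(f"unknown swept quantity {self.quantity!r}")
        grid = tuple(float(v) for v in self.grid)
        if len(grid) == 0:
            raise ValueError("grid must be nonempty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", grid)
        if self.quantity != "x0" and self.x0 is None:
            raise ValueError("x0 must be fixed unless it is the swept quantity")
        if self.quantity != "y0" and self.y0 is None:
            raise ValueError("y0 must be fixed unless it is the swept quantity")

    def cell(self, value: float) -> tuple[GameParameters, float, float]:
        """Inputs (params, x0, y0) for one grid value."""
        params, x0, y0 = self.params, self.x0, self.y0
        if self.quantity == "x0":
            x0 = value
        elif self.quantity == "y0":
            y0 = value
        else:
            params = params.replace(**{self.quantity: value})
        return params, float(x0), float(y0)


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-point outcomes, convergence times and the first flip."""

    spec: SweepSpec
    outcomes: tuple[str, ...]
    convergence_times: tuple[Optional[float], ...]
    final_states: tuple[tuple[float, float], ...]
    flip_threshold: Optional[float]
    change_points: tuple[float, ...]
    nonconvergent_values: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "swept_name": self.spec.quantity,
                "swept_value": list(self.spec.grid),
                "outcome": list(self.outcomes),
                "convergence_time": [
                    np.nan if t is None else t for t in self.convergence_times
                ],
                "final_x": [s[0] for s in self.final_states],
                "final_y": [s[1] for s in self.final_states],
            }
        )

    def summary(self) -> dict:
        """Self-describing JSON summary including full provenance."""
        return {
            "swept_name": self.spec.quantity,
            "grid": list(self.spec.grid),
            "fixed_parameters": self.spec.params.to_dict(),
            "x0": self.spec.x0,
            "y0": self.spec.y0,
            "integrator": {
                "method": self.spec.settings.method,
                "rtol": self.spec.settings.rtol,
                "atol": self.spec.settings.atol,
                "dt": self.spec.settings.dt,
                "t_max": self.spec.settings.t_max,
                "delta": self.spec.settings.delta,
            },
            "outcomes": list(self.outcomes),
            "convergence_times": list(self.convergence_times),
            "flip_threshold": self.flip_threshold,
            "change_points": list(self.change_points),
            "nonconvergent_values": list(self.nonconvergent_values),
        }


def run_sweep(spec: SweepSpec, keep_trajectories: bool = False):
    """Run every grid point of a sweep.

    Returns the :class:`SweepResult`, or ``(result, trajectories)`` when
    ``keep_trajectories`` is set.  Nonconvergent grid points are flagged in
    the result, never dropped.
    """
    outcomes: list[str] = []
    times: list[Optional[float]] = []
    finals: list[tuple[float, float]] = []
    trajs: list[Trajectory] = []
    for value in spec.grid:
        params, x0, y0 = spec.cell(value)
        if spec.require_scenario1:
            require_scenario1(params)
        traj = integrate(params, x0, y0, spec.settings)
        outcomes.append(traj.outcome)
        times.append(traj.convergence_time)
        finals.append(traj.final_state)
        if keep_trajectories:
            trajs.append(traj)

    change_points = tuple(
        spec.grid[i] for i in range(1, len(outcomes)) if outcomes[i] != outcomes[i - 1]
    )
    flip = None
    for value, outcome in zip(spec.grid, outcomes):
        if outcome != outcomes[0]:
            flip = value
            break
    nonconv = tuple(v for v, o in zip(spec.grid, outcomes) if o == "nonconvergent")
    result = SweepResult(
        spec=spec,
        outcomes=tuple(outcomes),
        convergence_times=tuple(times),
        final_states=tuple(finals),
        flip_threshold=flip,
        change_points=change_points,
        nonconvergent_values=nonconv,
    )
    if keep_trajectories:
        return result, trajs
    return result


def figure_spec(figure_id: str, settings: IntegratorSettings | None = None) -> SweepSpec:
    """The preset :class:`SweepSpec` for one bundled experiment id."""
    if figure_id not in _FIGURES:
        raise ValueError(f"unknown figure id {figure_id!r}; known: {', '.join(_FIGURES)}")
    quantity, grid, x0, y0 = _FIGURES[figure_id]
    return SweepSpec(
        quantity=quantity,
        grid=tuple(grid),
        params=BASELINE,
        x0=x0,
        y0=y0,
        settings=settings or IntegratorSettings(),
        require_scenario1=True,
    )


def run_figure_experiment(
    figure_id: str, settings: IntegratorSettings | None = None, keep_trajectories: bool = False
):
    """Run one of the bundled preset sweeps by id."""
    return run_sweep(figure_spec(figure_id, settings), keep_trajectories=keep_trajectories)


def convergence_time_ordering(result: SweepResult) -> dict[str, str]:
    """Monotonicity of convergence time in the swept value, per shared outcome.

    For each outcome label reached by at least two grid points, reports one
    of "strictly_decreasing", "strictly_increasing", "constant" (ties
    allowed throughout), or "nonmonotone".  Raises if no outcome has two
    comparable points with finite convergence times.
    """
    groups: dict[str, list[float]] = {}
    for outcome, t in zip(result.outcomes, result.convergence_times):
        if t is not None:
            groups.setdefault(outcome, []).append(t)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if not groups:
        raise ValueError("fewer than 2 comparable grid points share an outcome")
    report: dict[str, str] = {}
    for outcome, ts in groups.items():
        diffs = np.diff(ts)
        if np.all(diffs < 0):
            report[outcome] = "strictly_decreasing"
        elif np.all(diffs > 0):
            report[outcome] = "strictly_increasing"
        elif np.all(diffs == 0):
            report[outcome] = "constant"
        elif np.all(diffs <= 0):
            report[outcome] = "nonincreasing"
        elif np.all(diffs >= 0):
            report[outcome] = "nondecreasing"
        else:
            report[outcome] = "nonmonotone"
    return report
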