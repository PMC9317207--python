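"""Time integration of the replicator system and outcome classification.

Outcomes are labelled by the corner reached ("O", "A", "B", "C"),
"interior" if the trajectory settles at the interior fixed point, or
"nonconvergent".  Reaching a corner requires both proximity (within
``delta``) and a shrinking field (norm below ``delta**2``), which prevents
slow transits near saddles from being misclassified.  Time is continuous
replicator time; no discrete step count is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .game_model import DomainError, GameParameters, replicator_field
from .equilibria import CORNERS, interior_equilibrium

__all__ = [
    "IntegrationError",
    "IntegratorSettings",
    "Trajectory",
    "integrate",
    "classify_outcome",
]

# Distance below which a pass near the interior saddle voids a corner label.
_SADDLE_GUARD = 1e-9


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class IntegratorSettings:
    """Integration scheme and convergence-detection knobs.

    method: "adaptive" (RK45, default), "rk4" or "euler" (fixed step dt).
    delta: convergence tolerance; a corner is reached when the state is
    within delta of it and the field norm is below delta**2.
    """

    method: str = "adaptive"
    dt: float = 1e-3
    rtol: float = 1e-8
    atol: float = 1e-10
    t_max: float = 500.0
    delta: float = 1e-4
    clamp: bool = True
    sample_dt: float = 0.1
    # Cap on the adaptive step: keeps the dense interpolant accurate at the
    # ~delta**2 scale probed by the convergence test.
    max_step: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("adaptive", "rk4", "euler"):
            raise ValueError(f"unknown method {self.method!r}")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not (0.0 < self.delta < 0.5):
            raise ValueError("delta must lie in (0, 0.5)")
        if not self.t_max > 0:
            raise ValueError("t_max must be positive")


@dataclass(frozen=True)
class Trajectory:
    """A time-indexed path of the system with its classified outcome."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 2)
    outcome: str
    convergence_time: Optional[float]
    params: GameParameters
    settings: IntegratorSettings = dataclass_field(default_factory=IntegratorSettings)

    @property
    def final_state(self) -> tuple[float, float]:
        return float(self.states[-1, 0]), float(self.states[-1, 1])


def _field(params: GameParameters, x: float, y: float) -> tuple[float, float]:
    a, b, c, d = params.reduced()
    return x * (1.0 - x) * (y * a + b), y * (1.0 - y) * (x * c + d)


def _corner_reached(
    params: GameParameters, x: float, y: float, delta: float, field_tol: float | None = None
) -> Optional[str]:
    if field_tol is None:
        field_tol = delta * delta
    for name, (cx, cy) in CORNERS.items():
        if math.hypot(x - cx, y - cy) < delta:
            fx, fy = _field(params, min(max(x, 0.0), 1.0), min(max(y, 0.0), 1.0))
            if math.hypot(fx, fy) < field_tol:
                return name
    return None


# ---------------------------------------------------------------------------
# Fixed-step integrators (numba-accelerated when available)

try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _fixed_step_path(a, b, c, d, x0, y0, dt, n_steps, record_every, use_rk4, clamp, delta):
    n_rec = n_steps // record_every + 2
    out = np.empty((n_rec, 3))
    x = x0
    y = y0
    out[0, 0] = 0.0
    out[0, 1] = x
    out[0, 2] = y
    idx = 1
    for i in range(1, n_steps + 1):
        if use_rk4:
            k1x = x * (1.0 - x) * (y * a + b)
            k1y = y * (1.0 - y) * (x * c + d)
            x2 = x + 0.5 * dt * k1x
            y2 = y + 0.5 * dt * k1y
            k2x = x2 * (1.0 - x2) * (y2 * a + b)
            k2y = y2 * (1.0 - y2) * (x2 * c + d)
            x3 = x + 0.5 * dt * k2x
            y3 = y + 0.5 * dt * k2y
            k3x = x3 * (1.0 - x3) * (y3 * a + b)
            k3y = y3 * (1.0 - y3) * (x3 * c + d)
            x4 = x + dt * k3x
            y4 = y + dt * k3y
            k4x = x4 * (1.0 - x4) * (y4 * a + b)
            k4y = y4 * (1.0 - y4) * (x4 * c + d)
            x += dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
            y += dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
        else:
            fx = x * (1.0 - x) * (y * a + b)
            fy = y * (1.0 - y) * (x * c + d)
            x += dt * fx
            y += dt * fy
        if clamp:
            if x < 0.0:
                x = 0.0
            elif x > 1.0:
                x = 1.0
            if y < 0.0:
                y = 0.0
            elif y > 1.0:
                y = 1.0
        if i % record_every == 0 or i == n_steps:
            out[idx, 0] = i * dt
            out[idx, 1] = x
            out[idx, 2] = y
            idx += 1
            # early exit once a corner is reached with a vanishing field
            converged = False
            for cx in (0.0, 1.0):
                for cy in (0.0, 1.0):
                    dist = ((x - cx) ** 2 + (y - cy) ** 2) ** 0.5
                    if dist < delta:
                        fx = x * (1.0 - x) * (y * a + b)
                        fy = y * (1.0 - y) * (x * c + d)
                        if (fx * fx + fy * fy) ** 0.5 < delta * delta:
                            converged = True
            if converged:
                break
    return out[:idx]


# ---------------------------------------------------------------------------


def _integrate_adaptive(
    params: GameParameters, x0: float, y0: float, s: IntegratorSettings
) -> tuple[np.ndarray, np.ndarray, Optional[Callable[[float], np.ndarray]]]:
    a, b, c, d = params.reduced()

    def rhs(_t, state):
        x, y = state
        if s.clamp:
            x = min(max(x, 0.0), 1.0)
            y = min(max(y, 0.0), 1.0)
        return (x * (1.0 - x) * (y * a + b), y * (1.0 - y) * (x * c + d))

    sol = solve_ivp(
        rhs,
        (0.0, s.t_max),
        (x0, y0),
        method="RK45",
        rtol=s.rtol,
        atol=s.atol,
        max_step=s.max_step,
        dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    times = np.arange(0.0, s.t_max + 0.5 * s.sample_dt, s.sample_dt)
    times[-1] = min(times[-1], s.t_max)
    states = sol.sol(times).T
    if s.clamp:
        states = np.clip(states, 0.0, 1.0)
    return times, states, sol.sol


def integrate(
    params: GameParameters,
    x0: float,
    y0: float,
    settings: IntegratorSettings | None = None,
) -> Trajectory:
    """Integrate the replicator system from (x0, y0) and classify the outcome.

    Stops at convergence (corner within ``delta`` with field norm below
    ``delta**2``) or at ``t_max``.  ``convergence_time`` is the first time
    the convergence test passes (bisection-refined for the adaptive
    method), or None for interior/nonconvergent outcomes.
    """
    s = settings or IntegratorSettings()
    if not (0.0 <= x0 <= 1.0 and 0.0 <= y0 <= 1.0):
        raise DomainError(f"initial state ({x0}, {y0}) outside the unit square")

    dense = None
    if s.method == "adaptive":
        times, states, dense = _integrate_adaptive(params, x0, y0, s)
    else:
        a, b, c, d = params.reduced()
        n_steps = int(round(s.t_max / s.dt))
        record_every = max(1, int(round(s.sample_dt / s.dt)))
        rec = _fixed_step_path(
            a, b, c, d, float(x0), float(y0),
            s.dt, n_steps, record_every, s.method == "rk4", s.clamp, s.delta,
        )
        times, states = rec[:, 0], rec[:, 1:]

    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite state encountered during integration")

    outcome, conv_time = _classify_path(params, times, states, s, dense)
    return Trajectory(
        times=times,
        states=states,
        outcome=outcome,
        convergence_time=conv_time,
        params=params,
        settings=s,
    )


def _classify_path(
    params: GameParameters,
    times: np.ndarray,
    states: np.ndarray,
    s: IntegratorSettings,
    dense: Optional[Callable[[float], np.ndarray]],
) -> tuple[str, Optional[float]]:
    interior = interior_equilibrium(params)

    hit_index = None
    corner = None
    for i in range(len(times)):
        corner = _corner_reached(params, states[i, 0], states[i, 1], s.delta)
        if corner is not None:
            hit_index = i
            break

    if hit_index is not None:
        if interior.exists:
            upto = states[: hit_index + 1]
            d_saddle = np.hypot(upto[:, 0] - interior.point[0], upto[:, 1] - interior.point[1])
            if d_saddle.min() < _SADDLE_GUARD:
                return "nonconvergent", None
        t_conv = float(times[hit_index])
        if hit_index > 0 and dense is not None:
            t_conv = _refine_crossing(
                params, dense, float(times[hit_index - 1]), t_conv, s.delta, s.clamp
            )
        return corner, t_conv

    fx, fy = states[-1]
    if interior.exists and math.hypot(fx - interior.point[0], fy - interior.point[1]) < s.delta:
        return "interior", None
    return "nonconvergent", None


def _refine_crossing(
    params: GameParameters,
    dense: Callable[[float], np.ndarray],
    t_lo: float,
    t_hi: float,
    delta: float,
    clamp: bool,
) -> float:
    """Bisect for the first time the convergence test passes."""
    for _ in range(60):
        if t_hi - t_lo < 1e-6:
            break
        mid = 0.5 * (t_lo + t_hi)
        x, y = dense(mid)
        if clamp:
            x = min(max(x, 0.0), 1.0)
            y = min(max(y, 0.0), 1.0)
        if _corner_reached(params, float(x), float(y), delta) is not None:
            t_hi = mid
        else:
            t_lo = mid
    return t_hi


def classify_outcome(traj: Trajectory, delta: float) -> str:
    """Label a trajectory's final state: a corner, "interior" or "nonconvergent".

    Uses a pointwise field tolerance of ``delta`` (the stricter ``delta**2``
    test is applied during integration, where the trajectory history makes
    slow saddle transits distinguishable).
    """
    if len(traj.states) == 0:
        raise ValueError("empty trajectory")
    x, y = traj.final_state
    corner = _corner_reached(traj.params, x, y, delta, field_tol=delta)
    if corner is not None:
        return corner
    interior = interior_equilibrium(traj.params)
    if interior.exists and math.hypot(x - interior.point[0], y - interior.point[1]) < delta:
        return "interior"
    return "nonconvergent"
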