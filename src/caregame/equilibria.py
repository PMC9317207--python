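"""Fixed points of the replicator system and their local stability.

The system always has the four corner fixed points O(0,0), A(0,1), B(1,0),
C(1,1) and, for some parameter values, an interior one E(x*, y*).  Each is
classified from the sign of the Jacobian determinant and trace: det > 0 and
tr < 0 is locally stable (an ESS), det > 0 and tr > 0 is unstable, det < 0
is a saddle, anything else is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .game_model import EPS, GameParameters, _check_state

__all__ = [
    "CORNERS",
    "Equilibrium",
    "RegimeReport",
    "interior_equilibrium",
    "jacobian",
    "det_trace_at",
    "classify_point",
    "classify_regime",
]

#: Corner fixed points by conventional label.
CORNERS = {"O": (0.0, 0.0), "A": (0.0, 1.0), "B": (1.0, 0.0), "C": (1.0, 1.0)}

_POINT_NAMES = ("O", "A", "B", "C", "E")


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its Jacobian determinant, trace and stability class."""

    name: str
    point: tuple[float, float]
    det: float
    tr: float
    stability: str  # "ESS" | "unstable" | "saddle" | "indeterminate"
    exists: bool = True


def jacobian(params: GameParameters, state) -> np.ndarray:
    """Jacobian of the replicator field at ``state`` (2x2 array)."""
    x, y = _check_state(state)
    a, b, c, d = params.reduced()
    return np.array(
        [
            [(1.0 - 2.0 * x) * (y * a + b), x * (1.0 - x) * a],
            [y * (1.0 - y) * c, (1.0 - 2.0 * y) * (x * c + d)],
        ]
    )


def classify_point(det: float, tr: float, eps: float = EPS) -> str:
    """Stability class from determinant/trace signs.

    A negative determinant is a saddle regardless of the trace (including
    the non-hyperbolic tr = 0 interior point).  Boundary sign patterns are
    reported as indeterminate rather than guessed.
    """
    if det < -eps:
        return "saddle"
    if det > eps:
        if tr < -eps:
            return "ESS"
        if tr > eps:
            return "unstable"
    return "indeterminate"


def interior_equilibrium(params: GameParameters, eps: float = EPS) -> Equilibrium:
    """The interior fixed point E(x*, y*) = (-d/c, -b/a), when it exists.

    ``exists`` is true only when both denominators are nonzero (beyond
    ``eps``) and the point lies strictly inside the open unit square;
    otherwise stability is indeterminate and det/tr are NaN.
    """
    a, b, c, d = params.reduced()
    if abs(a) <= eps or abs(c) <= eps:
        return Equilibrium("E", (np.nan, np.nan), np.nan, np.nan, "indeterminate", False)
    x_star = -d / c
    y_star = -b / a
    if not (eps < x_star < 1.0 - eps and eps < y_star < 1.0 - eps):
        return Equilibrium("E", (x_star, y_star), np.nan, np.nan, "indeterminate", False)
    det, tr = _closed_form_det_trace(params, "E")
    return Equilibrium("E", (x_star, y_star), det, tr, classify_point(det, tr, eps), True)


def _closed_form_det_trace(params: GameParameters, which: str) -> tuple[float, float]:
    p = params
    a, b, c, d = p.reduced()
    if which == "O":
        return b * d, b + d
    if which == "A":
        f1 = p.U1 + p.S1 - p.P1
        f2 = p.C2 - p.R2 - p.S1p
        return f1 * f2, f1 + f2
    if which == "B":
        f1 = p.P2 - p.U2 - p.S2
        f2 = p.R1 + p.P1 - p.C1
        return f1 * f2, f1 + f2
    if which == "C":
        f1 = p.U1 + p.S1 - p.P1
        f2 = p.R1 + p.P1 - p.C1
        return f1 * f2, p.C1 - p.R1 - p.U1 - p.S1
    if which == "E":
        num = (
            (p.P2 - p.U2 - p.S2)
            * (p.C2 - p.R2 - p.S1p)
            * (p.U1 + p.S1 - p.P1)
            * (p.R1 + p.P1 - p.C1)
        )
        return -num / (a * c), 0.0
    raise ValueError(f"unknown equilibrium label {which!r}")


def det_trace_at(params: GameParameters, which: str) -> tuple[float, float]:
    """Closed-form Jacobian determinant and trace at one of O, A, B, C, E.

    Requesting E when the interior point does not exist is an error.
    """
    if which not in _POINT_NAMES:
        raise ValueError(f"unknown equilibrium label {which!r}; expected one of {_POINT_NAMES}")
    if which == "E" and not interior_equilibrium(params).exists:
        raise ValueError("interior equilibrium does not exist for these parameters")
    return _closed_form_det_trace(params, which)


@dataclass(frozen=True)
class RegimeReport:
    """ESS membership, named care-model types, and the scenario number.

    ``care_model_types`` draws from {"health-led", "social-led",
    "bilateral", "none"}; "none" marks a stable no-integrated-service
    outcome (O is an ESS).  ``scenario`` (1-4) is set only when the
    bilateral corner C(1,1) is an ESS.
    """

    equilibria: tuple[Equilibrium, ...]
    ess_points: tuple[str, ...]
    care_model_types: frozenset[str]
    scenario: Optional[int]

    def equilibrium(self, name: str) -> Equilibrium:
        for eq in self.equilibria:
            if eq.name == name:
                return eq
        raise KeyError(name)


# Care-model names attached to each stable corner.
_CARE_MODEL = {"A": "health-led", "B": "social-led", "C": "bilateral", "O": "none"}


def classify_regime(params: GameParameters, eps: float = EPS) -> RegimeReport:
    """Classify all five candidate equilibria and name the resulting regime.

    When C(1,1) is an ESS the scenario number is assigned from the sign
    pair (U2+S2-P2, R2+S1p-C2) = (b, d): (-,-) -> 1, (-,+) -> 2,
    (+,-) -> 3, (+,+) -> 4.
    """
    eqs: list[Equilibrium] = []
    for name, point in CORNERS.items():
        det, tr = _closed_form_det_trace(params, name)
        eqs.append(Equilibrium(name, point, det, tr, classify_point(det, tr, eps)))
    eqs.append(interior_equilibrium(params, eps))

    ess = tuple(eq.name for eq in eqs if eq.stability == "ESS")
    types = frozenset(_CARE_MODEL[name] for name in ess if name in _CARE_MODEL)

    scenario: Optional[int] = None
    if "C" in ess:
        _, b, _, d = params.reduced()
        if b < -eps and d < -eps:
            scenario = 1
        elif b < -eps and d > eps:
            scenario = 2
        elif b > eps and d < -eps:
            scenario = 3
        elif b > eps and d > eps:
            scenario = 4
    return RegimeReport(
        equilibria=tuple(eqs), ess_points=ess, care_model_types=types, scenario=scenario
    )
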