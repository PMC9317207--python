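"""Area of the bilateral-cooperation basin and its parameter sensitivities.

Defined only in the bistable regime (scenario 1), where the unit square of
initial conditions splits into a basin converging to O(0,0) and one
converging to C(1,1).  The latter's area is approximated by the two
triangles cut off by the saddle E(x*, y*):

    S = 1/2 * (1 - x*) + 1/2 * (1 - y*) = 1 - (x* + y*)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .game_model import EPS, GameParameters, PARAM_NAMES
from .equilibria import interior_equilibrium

__all__ = [
    "SCENARIO1_TABLE_ORDER",
    "ScenarioError",
    "SensitivityRow",
    "require_scenario1",
    "scenario1_holds",
    "cooperation_basin_area",
    "area_sensitivity",
    "sensitivity_sign_table",
]

#: Row order of the sensitivity sign table.
SCENARIO1_TABLE_ORDER = ("R1", "R2", "P1", "P2", "C1", "C2", "U1", "U2", "S1", "S1p", "S2")


class ScenarioError(ValueError):
    """Raised when the bistable-regime (scenario 1) preconditions fail."""


def _scenario1_violations(params: GameParameters, eps: float = EPS) -> list[str]:
    p = params
    checks = (
        ("U1 + S1 > P1", p.U1 + p.S1 - p.P1),
        ("R1 + P1 > C1", p.R1 + p.P1 - p.C1),
        ("U2 + S2 < P2", p.P2 - p.U2 - p.S2),
        ("R2 + S1p < C2", p.C2 - p.R2 - p.S1p),
    )
    return [name for name, margin in checks if not margin > eps]


def scenario1_holds(params: GameParameters, eps: float = EPS) -> bool:
    """True iff the four bistable-regime sign conditions hold strictly."""
    return not _scenario1_violations(params, eps)


def require_scenario1(params: GameParameters, eps: float = EPS) -> None:
    """Raise :class:`ScenarioError` naming each failed scenario-1 condition."""
    bad = _scenario1_violations(params, eps)
    if bad:
        raise ScenarioError("scenario-1 condition(s) violated: " + "; ".join(bad))


def cooperation_basin_area(params: GameParameters) -> float:
    """Area of the set of initial conditions that evolve to C(1,1).

    Requires the scenario-1 conditions; under them the interior saddle
    always exists and the area lies strictly in (0, 1).
    """
    require_scenario1(params)
    eq = interior_equilibrium(params)
    if not eq.exists:
        raise ScenarioError("interior equilibrium does not exist")
    x_star, y_star = eq.point
    return 1.0 - 0.5 * (x_star + y_star)


# How each parameter enters x* = N/c and y* = M/a:
#   N = C2 - R2 - S1p,  c = R1 - R2 + P1 - S1p + C2 - C1
#   M = P2 - U2 - S2,   a = U1 - U2 + P2 - P1 + S1 - S2
# Values are (dN, dc) resp. (dM, da) per unit parameter increase.
_X_DEPS = {"R1": (0, 1), "R2": (-1, -1), "P1": (0, 1), "S1p": (-1, -1), "C1": (0, -1), "C2": (1, 1)}
_Y_DEPS = {"P2": (1, 1), "U2": (-1, -1), "S2": (-1, -1), "U1": (0, 1), "S1": (0, 1), "P1": (0, -1)}


@dataclass(frozen=True)
class SensitivityRow:
    """Partial derivative of the basin area with respect to one parameter."""

    parameter: str
    derivative: float
    sign: str  # "+" | "-" | "indeterminate"
    method: str
    globally_indeterminate: bool = False


def _closed_form_derivative(params: GameParameters, name: str) -> float:
    p = params
    a, b, c, d = p.reduced()
    n_x = p.C2 - p.R2 - p.S1p  # = -d
    m_y = p.P2 - p.U2 - p.S2  # = -b
    dS = 0.0
    if name in _X_DEPS:
        dN, dc = _X_DEPS[name]
        dS += -0.5 * (dN * c - n_x * dc) / (c * c)
    if name in _Y_DEPS:
        dM, da = _Y_DEPS[name]
        dS += -0.5 * (dM * a - m_y * da) / (a * a)
    return dS


def _finite_difference_derivative(params: GameParameters, name: str) -> float:
    value = getattr(params, name)
    h = 1e-6 * max(1.0, abs(value))
    lo = params.replace(**{name: value - h})
    hi = params.replace(**{name: value + h})
    for perturbed in (lo, hi):
        if not scenario1_holds(perturbed):
            raise ScenarioError(
                f"perturbing {name} by {h:g} exits the scenario-1 region; "
                "derivative undefined here"
            )
    return (cooperation_basin_area(hi) - cooperation_basin_area(lo)) / (2.0 * h)


def area_sensitivity(
    params: GameParameters, name: str, method: str = "closed_form", eps: float = EPS
) -> SensitivityRow:
    """Sensitivity of the basin area to one parameter.

    ``method`` is ``"closed_form"`` (quotient-rule partials of the two
    saddle coordinates) or ``"finite_difference"`` (central differences
    with relative step 1e-6).  P1's row is flagged globally indeterminate:
    its sign depends on where in the feasible region it is evaluated.
    """
    if name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {name!r}")
    require_scenario1(params)
    if not interior_equilibrium(params).exists:
        raise ScenarioError("interior equilibrium does not exist")
    if method == "closed_form":
        deriv = _closed_form_derivative(params, name)
    elif method == "finite_difference":
        deriv = _finite_difference_derivative(params, name)
    else:
        raise ValueError(f"unknown method {method!r}")
    if deriv > eps:
        sign = "+"
    elif deriv < -eps:
        sign = "-"
    else:
        sign = "indeterminate"
    return SensitivityRow(
        parameter=name,
        derivative=deriv,
        sign=sign,
        method=method,
        globally_indeterminate=(name == "P1"),
    )


def sensitivity_sign_table(
    params: GameParameters, method: str = "closed_form"
) -> list[SensitivityRow]:
    """One sensitivity row per parameter, in the conventional table order."""
    return [area_sensitivity(params, name, method=method) for name in SCENARIO1_TABLE_ORDER]
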