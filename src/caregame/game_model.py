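"""Model parameters, payoff matrix, expected payoffs and the replicator vector field.

The model is a two-population asymmetric game: elderly social care
organizations play "participation" with probability ``x`` and health care
organizations with probability ``y``.  Eleven nonnegative scalars determine
every payoff; the dynamics depend on them only through four reduced
coefficients (see :meth:`GameParameters.reduced`).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping, NamedTuple

import yaml

__all__ = [
    "PARAM_NAMES",
    "EPS",
    "DomainError",
    "ValidationError",
    "GameParameters",
    "ReducedCoefficients",
    "StrategyState",
    "ValidationReport",
    "PayoffTable",
    "ExpectedPayoffs",
    "validate_parameters",
    "payoff_matrix",
    "expected_payoffs",
    "replicator_field",
]

#: Canonical ordering of the 11 model parameters.
PARAM_NAMES = ("U1", "U2", "P1", "P2", "R1", "R2", "C1", "C2", "S1", "S2", "S1p")

#: Absolute tolerance used in every sign comparison against zero.
EPS = 1e-12

# Strict orderings assumed by the model: first must exceed second.
_ORDERINGS = (("U2", "U1"), ("P2", "P1"), ("R2", "R1"), ("C2", "C1"), ("S2", "S1"))


class ValidationError(ValueError):
    """Raised when a parameter set violates the model's assumptions in strict mode."""


class DomainError(ValueError):
    """Raised when a strategy state lies outside the unit square."""


class ReducedCoefficients(NamedTuple):
    """The four scalars through which the 11 raw parameters enter the dynamics.

    ``dx/dt = x(1-x)(y*a + b)`` and ``dy/dt = y(1-y)(x*c + d)``.
    """

    a: float
    b: float
    c: float
    d: float


@dataclass(frozen=True)
class GameParameters:
    """The 11 nonnegative payoff/cost/subsidy scalars of the model.

    Attributes
    ----------
    U1, U2
        Additional benefit to the social care organization under bilateral
        cooperation (U1) resp. when it provides health services itself (U2).
    P1, P2
        Social care organization's purchase/negotiation cost (P1) resp.
        own-provision cost (P2).
    R1, R2
        Additional income to the health care organization under bilateral
        cooperation (R1) resp. when it provides social care itself (R2).
    C1, C2
        Health care organization's additional operating cost under bilateral
        cooperation (C1) resp. own provision (C2).
    S1, S2
        Government subsidy to the social care organization: bilateral (S1)
        resp. social-care-led (S2).
    S1p
        Government subsidy to the health care organization in the
        health-care-led mode.
    """

    U1: float
    U2: float
    P1: float
    P2: float
    R1: float
    R2: float
    C1: float
    C2: float
    S1: float
    S2: float
    S1p: float

    def reduced(self) -> ReducedCoefficients:
        """Return the reduced coefficients ``(a, b, c, d)``."""
        return ReducedCoefficients(
            a=self.U1 - self.U2 + self.P2 - self.P1 + self.S1 - self.S2,
            b=self.U2 + self.S2 - self.P2,
            c=self.R1 - self.R2 + self.P1 - self.S1p + self.C2 - self.C1,
            d=self.R2 + self.S1p - self.C2,
        )

    def replace(self, **changes: float) -> "GameParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "GameParameters":
        """Build from a flat mapping; unknown or missing keys are errors."""
        keys = set(mapping)
        unknown = sorted(keys - set(PARAM_NAMES))
        missing = sorted(set(PARAM_NAMES) - keys)
        if unknown:
            raise ValidationError(f"unknown parameter keys: {', '.join(unknown)}")
        if missing:
            raise ValidationError(f"missing parameter keys: {', '.join(missing)}")
        return cls(**{name: float(mapping[name]) for name in PARAM_NAMES})

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "GameParameters":
        """Read a flat YAML or JSON mapping of the 11 parameter names."""
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValidationError(f"{path}: expected a flat mapping of parameter names")
        return cls.from_mapping(data)


@dataclass(frozen=True)
class StrategyState:
    """Pair of participation probabilities (social care x, health care y)."""

    x: float
    y: float

    def __iter__(self):
        return iter((self.x, self.y))


def _as_xy(state) -> tuple[float, float]:
    x, y = state
    return float(x), float(y)


def _check_state(state) -> tuple[float, float]:
    x, y = _as_xy(state)
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise DomainError(f"state ({x}, {y}) outside the unit square")
    return x, y


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_parameters`."""

    violations: tuple[str, ...]
    reduced: ReducedCoefficients

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_parameters(params: GameParameters, strict: bool = True) -> ValidationReport:
    """Check nonnegativity and the model's strict orderings.

    With ``strict=True`` (the default) any violation raises
    :class:`ValidationError` naming every violated condition; otherwise the
    violations are returned as warnings in the report.  The report always
    echoes the reduced coefficients.
    """
    violations: list[str] = []
    for name in PARAM_NAMES:
        value = getattr(params, name)
        if value < 0:
            violations.append(f"{name} >= 0 violated ({name} = {value})")
    for hi, lo in _ORDERINGS:
        if not getattr(params, hi) > getattr(params, lo):
            violations.append(
                f"{hi} > {lo} violated ({hi} = {getattr(params, hi)}, "
                f"{lo} = {getattr(params, lo)})"
            )
    report = ValidationReport(violations=tuple(violations), reduced=params.reduced())
    if strict and violations:
        raise ValidationError("; ".join(violations))
    return report


@dataclass(frozen=True)
class PayoffTable:
    """Per-profile payoffs; profiles ordered (PP, PN, NP, NN).

    P = participation, N = nonparticipation; the first letter is the social
    care organization's strategy.
    """

    social: tuple[float, float, float, float]
    health: tuple[float, float, float, float]


def payoff_matrix(params: GameParameters) -> PayoffTable:
    """The four strategy-profile payoff cells of the bimatrix game."""
    p = params
    return PayoffTable(
        social=(p.U1 + p.S1 - p.P1, p.U2 + p.S2 - p.P2, 0.0, 0.0),
        health=(p.R1 + p.P1 - p.C1, 0.0, p.R2 + p.S1p - p.C2, 0.0),
    )


class ExpectedPayoffs(NamedTuple):
    E11: float  # social care org, participation
    E12: float  # social care org, nonparticipation
    E21: float  # health care org, participation
    E22: float  # health care org, nonparticipation
    Ebar1: float  # social care org, population average
    Ebar2: float  # health care org, population average


def expected_payoffs(params: GameParameters, state) -> ExpectedPayoffs:
    """Expected payoffs of each pure strategy and the population averages."""
    x, y = _check_state(state)
    p = params
    E11 = y * (p.U1 + p.S1 - p.P1) + (1.0 - y) * (p.U2 + p.S2 - p.P2)
    E21 = x * (p.R1 + p.P1 - p.C1) + (1.0 - x) * (p.R2 + p.S1p - p.C2)
    return ExpectedPayoffs(E11=E11, E12=0.0, E21=E21, E22=0.0, Ebar1=x * E11, Ebar2=y * E21)


def replicator_field(params: GameParameters, state) -> tuple[float, float]:
    """Right-hand side (dx/dt, dy/dt) of the replicator system.

    Computed in reduced-coefficient form; identical to
    ``x(1-x)(E11-E12), y(1-y)(E21-E22)``.
    """
    x, y = _check_state(state)
    a, b, c, d = params.reduced()
    return x * (1.0 - x) * (y * a + b), y * (1.0 - y) * (x * c + d)
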