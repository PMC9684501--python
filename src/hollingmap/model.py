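"""Discrete predator-prey map with a Holling type-III functional response.

The map is the forward-Euler discretization (step size ``h``) of the planar
system

.. math::

    x' = a x - \\frac{b x^2 y}{e + x^2}, \\qquad
    y' = -c y + \\frac{b x^2 y}{e + x^2},

so one iteration sends ``(x, y)`` to

.. math::

    \\bigl( (1 + a h) x - \\frac{h b x^2 y}{e + x^2},\\;
            (1 - c h) y + \\frac{h b x^2 y}{e + x^2} \\bigr).

Here ``x`` and ``y`` are prey and predator densities, ``a`` the prey
intrinsic growth rate, ``b`` the predation coefficient, ``c`` the predator
death rate and ``e`` the half-saturation constant of the sigmoidal
(type-III) predation rate ``b x^2 / (e + x^2)``.

Besides the trivial extinction state at the origin, the map has a unique
coexistence (interior) fixed point whenever ``b > c``:

.. math::

    x^* = \\frac{c e}{\\sqrt{(b - c) c e}}, \\qquad
    y^* = \\frac{a e}{\\sqrt{(b - c) c e}}.

The raw Euler map is iterated as written: states are real-valued and are
never clipped to the non-negative quadrant, because the chaotic regimes of
interest live on the unmodified map.  Divergent orbits are reported via
:class:`DivergenceError` rather than silently repaired.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "FixedPointKind",
    "FixedPoint",
    "Jacobian2",
    "DivergenceError",
    "NoInteriorFixedPointError",
    "step",
    "functional_response",
    "interior_fixed_point",
    "origin_fixed_point",
    "jacobian",
    "orbit",
    "DIVERGENCE_LIMIT",
    "FIXED_POINT_ATOL",
    "FD_RTOL",
]

#: iteration aborts once |x| or |y| exceeds this bound (divergent orbit)
DIVERGENCE_LIMIT = 1e12

#: default absolute tolerance for fixed-point invariance checks
FIXED_POINT_ATOL = 1e-10

#: default relative tolerance when comparing analytic derivatives with
#: central finite differences
FD_RTOL = 1e-5


class DivergenceError(RuntimeError):
    """Raised when an orbit leaves the admissible numeric range.

    Attributes
    ----------
    index : int
        Iteration index at which the overflow was detected.
    """

    def __init__(self, index: int):
        self.index = index
        super().__init__(f"orbit diverged at iteration {index}")


class NoInteriorFixedPointError(ValueError):
    """Raised when the coexistence fixed point does not exist (``b <= c``)."""


class State(NamedTuple):
    """A population state: prey density ``x`` and predator density ``y``."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """The five positive model constants.

    Parameters
    ----------
    a : float
        Prey intrinsic growth rate (per unit time).
    b : float
        Predation coefficient (maximal per-capita predation rate).
    c : float
        Predator death rate.
    e : float
        Half-saturation constant of the type-III response.
    h : float
        Euler integration step size; acts as the principal bifurcation
        parameter.
    """

    a: float
    b: float
    c: float
    e: float
    h: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "e", "h"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be finite and > 0, got {value}")

    @property
    def has_interior_fixed_point(self) -> bool:
        """The coexistence state exists iff ``b > c``."""
        return self.b > self.c

    def replace(self, **kwargs) -> "ModelParams":
        fields = {k: getattr(self, k) for k in ("a", "b", "c", "e", "h")}
        fields.update(kwargs)
        return ModelParams(**fields)


class FixedPointKind(enum.Enum):
    ORIGIN = "origin"
    INTERIOR = "interior"


@dataclass(frozen=True)
class FixedPoint:
    state: State
    kind: FixedPointKind


@dataclass(frozen=True)
class Jacobian2:
    """Partial derivatives of the map at a state (dimensionless multipliers)."""

    j11: float
    j12: float
    j21: float
    j22: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.j11, self.j12], [self.j21, self.j22]], dtype=float)

    @property
    def trace(self) -> float:
        return self.j11 + self.j22

    @property
    def det(self) -> float:
        return self.j11 * self.j22 - self.j12 * self.j21


def functional_response(params: ModelParams, x: float) -> float:
    """Type-III per-predator predation rate ``b x^2 / (e + x^2)``."""
    return params.b * x * x / (params.e + x * x)


def step(params: ModelParams, s: State) -> State:
    """One iteration of the Euler map."""
    x, y = s
    predation = params.h * functional_response(params, x) * y
    return State(
        (1.0 + params.a * params.h) * x - predation,
        (1.0 - params.c * params.h) * y + predation,
    )


def origin_fixed_point() -> FixedPoint:
    return FixedPoint(State(0.0, 0.0), FixedPointKind.ORIGIN)


def interior_fixed_point(params: ModelParams) -> FixedPoint:
    """Coexistence fixed point ``(ce, ae) / sqrt((b-c)ce)``.

    Raises
    ------
    NoInteriorFixedPointError
        If ``b <= c`` (the radicand ``(b-c)ce`` is non-positive).
    """
    if not params.has_interior_fixed_point:
        raise NoInteriorFixedPointError(
            f"interior fixed point requires b > c (got b={params.b}, c={params.c})"
        )
    root = math.sqrt((params.b - params.c) * params.c * params.e)
    return FixedPoint(
        State(params.c * params.e / root, params.a * params.e / root),
        FixedPointKind.INTERIOR,
    )


def jacobian(params: ModelParams, s: State) -> Jacobian2:
    """Jacobian of the map at an arbitrary state.

    At the interior fixed point the entries simplify to
    ``j11 = 1 - ah(b-2c)/b``, ``j12 = -hc``, ``j21 = 2ah(b-c)/b`` and
    ``j22 = 1``; at the origin the matrix is diagonal ``(1+ah, 1-ch)``.
    Both follow from this general form.
    """
    a, b, c, e, h = params.a, params.b, params.c, params.e, params.h
    x, y = s
    denom = e + x * x
    mixed = 2.0 * b * e * h * x * y / denom**2
    return Jacobian2(
        j11=1.0 + a * h - mixed,
        j12=-h * b * x * x / denom,
        j21=mixed,
        j22=1.0 - c * h + h * b * x * x / denom,
    )


def orbit(
    params: ModelParams,
    init: State,
    n: int,
    transient: int = 0,
) -> np.ndarray:
    """Iterate the map and return the last ``n`` states as an ``(n, 2)`` array.

    The first ``transient`` iterates are discarded.  Raises
    :class:`DivergenceError` (carrying the failing iteration index) as soon
    as a coordinate exceeds :data:`DIVERGENCE_LIMIT` in magnitude.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if transient < 0:
        raise ValueError("transient must be non-negative")
    out = np.empty((n, 2), dtype=float)
    s = State(float(init[0]), float(init[1]))
    total = n + transient
    for i in range(total):
        s = step(params, s)
        if not (abs(s.x) < DIVERGENCE_LIMIT and abs(s.y) < DIVERGENCE_LIMIT):
            raise DivergenceError(i)
        if i >= transient:
            out[i - transient] = s
    return out
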