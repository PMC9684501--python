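"""Flip (period-doubling) bifurcation normal form at the coexistence point.

At a flip-critical step size (``h = h1`` or ``h1'``) the interior fixed
point has eigenvalues ``R1 = -1`` and ``k2 = 3 - h a(b-2c)/b``.  A linear
change of coordinates diagonalizing the Jacobian, followed by a
center-manifold reduction ``ybar = c1 xbar^2 + c2 xbar h* + ...``, leaves
the one-dimensional map

.. math::

    F: \\bar x \\mapsto -\\bar x + s_1 \\bar x^2 + s_2 \\bar x h_*
       + s_3 \\bar x^2 h_* + s_4 \\bar x h_*^2 + s_5 \\bar x^3 + \\dots

on the center manifold (``h*`` is the perturbation of the step size away
from criticality).  The two discriminatory quantities

.. math::

    \\Gamma_1 = s_2, \\qquad \\Gamma_2 = s_1^2 + s_5

decide the bifurcation: it is a genuine flip when both are nonzero, and
the emerging period-2 orbit is stable when ``\\Gamma_2 > 0``, unstable
when ``\\Gamma_2 < 0``.

The coefficients are evaluated literally from their closed forms at the
supplied ``h`` (with the perturbation ``h*`` set to 0); no symbolic
re-derivation is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

from .expansion import MapExpansion, map_expansion
from .model import ModelParams, State, interior_fixed_point, step
from .model import jacobian
from .stability import char_poly

__all__ = [
    "FlipVerdict",
    "FlipNormalFormResult",
    "NotAtCriticalityError",
    "DegenerateFlipError",
    "flip_coefficients",
    "taylor_check",
    "CRITICALITY_RTOL",
    "DEGENERACY_ATOL",
]

#: tolerance on F(-1)(h) (relative to the O(1) scale of the polynomial)
#: below which h counts as flip-critical
CRITICALITY_RTOL = 1e-6

#: |Gamma| below this absolute threshold is reported as degenerate
DEGENERACY_ATOL = 1e-10


class NotAtCriticalityError(ValueError):
    """The supplied step size is not a flip-critical value."""


class DegenerateFlipError(ArithmeticError):
    """``|k2| = 1``: the normal-form divisions ``1 +- k2`` break down."""


class FlipVerdict(enum.Enum):
    STABLE_PERIOD2 = "stable_period2"
    UNSTABLE_PERIOD2 = "unstable_period2"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class FlipNormalFormResult:
    expansion: MapExpansion
    k2: float
    c1: float
    c2: float
    c3: float
    s1: float
    s2: float
    s3: float
    s4: float
    s5: float
    gamma1: float
    gamma2: float
    verdict: FlipVerdict


def flip_coefficients(
    params: ModelParams,
    criticality_rtol: float = CRITICALITY_RTOL,
    degeneracy_atol: float = DEGENERACY_ATOL,
) -> FlipNormalFormResult:
    """Center-manifold flip coefficients and verdict at ``h = params.h``.

    ``params.h`` must be a flip-critical step size: the check is on the
    characteristic-polynomial residual ``F(-1)(h)`` (robust to how the
    caller obtained ``h``), scaled by the O(1) size of the polynomial.
    """
    cp = char_poly(jacobian(params, interior_fixed_point(params).state))
    residual = float(cp(-1.0).real)
    scale = 1.0 + abs(cp.T) + abs(cp.D)
    if abs(residual) > criticality_rtol * scale:
        raise NotAtCriticalityError(
            f"h={params.h} is not flip-critical: F(-1) = {residual:.3e}"
        )

    E = map_expansion(params)
    a, b, c, h = params.a, params.b, params.c, params.h
    k2 = 3.0 - h * a * (b - 2.0 * c) / b
    if abs(k2 - 1.0) < 1e-8 or abs(k2 + 1.0) < 1e-8:
        raise DegenerateFlipError(f"|k2| = 1 within tolerance (k2 = {k2})")

    E11, E12, E13, E14 = E.E11, E.E12, E.E13, E.E14
    E23, E24 = E.E23, E.E24
    P1, P2, P5, P6 = E.P1, E.P2, E.P5, E.P6

    c1 = (
        E12**2 * E24 + (1.0 + E11) * (E14 - E23) * E12 - E13 * (1.0 + E11) ** 2
    ) / (1.0 - k2**2)
    c2 = (
        P2 * (1.0 + E11) ** 2 - E12**2 * P5 - (1.0 + E11) * (P1 - P6) * E12
    ) / (E12 * (1.0 + k2) ** 2)
    c3 = 0.0

    s1 = (
        E11**2 * E13
        + ((-E14 + E23) * E12 - E13 * (-1.0 + k2)) * E11
        - E12**2 * E24
        + (E14 * k2 + E23) * E12
        - k2 * E13
    ) / (k2 + 1.0)
    s2 = (
        (E11 * (P6 - P1) + k2 * P1 + P6) * E12
        - P2 * (1.0 + E11) * (k2 - E11)
        - E12**2 * P5
    ) / (E12 * (k2 + 1.0))
    s3 = (
        -(E12**3) * (2.0 * E24 * c2 + E.P8)
        + (
            ((2.0 * E23 - 2.0 * E14) * c2 - E.P4 + E.P7) * E11
            + ((2.0 * E14 - E23) * c2 + E.P4) * k2
            - c1 * P5
            + c2 * E23
            + E.P7
        )
        * E12**2
        + (k2 - E11)
        * (
            (-2.0 * E13 * c2 - E.P3) * E11
            + E13 * c2 * k2
            - E13 * c2
            + (P1 - P6) * c1
            - E.P3
        )
        * E12
        + c1 * P2 * (k2 - E11) ** 2
    ) / (E12 * (k2 + 1.0))
    s4 = (
        (-(E12**2) * P5 + (P1 - P6) * (k2 - E11) * E12 + P2 * (k2 - E11) ** 2)
        * c2
    ) / (E12 * (k2 + 1.0))
    s5 = (
        (
            -2.0 * E12**2 * E24
            + ((2.0 * E14 - E23) * k2 + (2.0 * E23 - 2.0 * E14) * E11 + E23) * E12
            + E13 * (k2 - E11) * (k2 - 2.0 * E11 - 1.0)
        )
        * c1
    ) / (k2 + 1.0)

    gamma1 = s2
    gamma2 = s1**2 + s5
    if abs(gamma1) < degeneracy_atol or abs(gamma2) < degeneracy_atol:
        verdict = FlipVerdict.DEGENERATE
    elif gamma2 > 0:
        verdict = FlipVerdict.STABLE_PERIOD2
    else:
        verdict = FlipVerdict.UNSTABLE_PERIOD2

    return FlipNormalFormResult(
        expansion=E,
        k2=k2,
        c1=c1,
        c2=c2,
        c3=c3,
        s1=s1,
        s2=s2,
        s3=s3,
        s4=s4,
        s5=s5,
        gamma1=gamma1,
        gamma2=gamma2,
        verdict=verdict,
    )


def taylor_check(params: ModelParams, delta: float = 1e-5) -> float:
    """Max relative residual of E13/E14/E23/E24 vs central finite differences.

    Validates that the quadratic expansion coefficients really are the
    second-order Taylor coefficients of the translated map: the ``uv``
    coefficient is the mixed partial, the ``u^2`` coefficient half of the
    pure second ``x``-partial.
    """
    E = map_expansion(params)
    x0, y0 = E.x_star, E.y_star

    def f(u: float, v: float) -> Tuple[float, float]:
        s = step(params, State(x0 + u, y0 + v))
        return s.x - x0, s.y - y0

    # mixed partial d2/du dv via 4-point stencil
    fpp = f(delta, delta)
    fpm = f(delta, -delta)
    fmp = f(-delta, delta)
    fmm = f(-delta, -delta)
    mixed = [
        (fpp[i] - fpm[i] - fmp[i] + fmm[i]) / (4.0 * delta * delta) for i in (0, 1)
    ]
    # pure second partial d2/du2
    fp0 = f(delta, 0.0)
    fm0 = f(-delta, 0.0)
    f00 = f(0.0, 0.0)
    pure = [(fp0[i] - 2.0 * f00[i] + fm0[i]) / (delta * delta) for i in (0, 1)]

    pairs = [
        (E.E13, mixed[0]),
        (E.E23, mixed[1]),
        (E.E14, 0.5 * pure[0]),
        (E.E24, 0.5 * pure[1]),
    ]
    return max(
        abs(analytic - numeric) / max(1.0, abs(analytic))
        for analytic, numeric in pairs
    )
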