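"""Quadratic Taylor expansion of the map around the coexistence fixed point.

Translating the interior fixed point to the origin (``u = x - x*``,
``v = y - y*``) and expanding to second order gives

.. math::

    u \\mapsto \\hat E_{11} u + \\hat E_{12} v + \\hat E_{13} uv
              + \\hat E_{14} u^2 + \\hat P_1 u h_* + \\dots

with analogous ``\\hat E_{2k}`` / ``\\hat P_{5..8}`` terms in the second
component.  The ``E``-coefficients are the first and second partial
derivatives of the map (the ``uv`` coefficient is the mixed partial, the
``u^2`` coefficient is half the pure second partial; all ``v``-only second
derivatives vanish because the map is linear in ``y``).  The
``P``-coefficients are the same expressions differentiated once in the
step size, i.e. ``P_k = E_k / h`` term by term (with the constant parts of
``E11``/``E22`` removed).

Both bifurcation normal forms (flip and Neimark-Sacker) are built from
this single expansion, evaluated at whatever step size the caller supplies.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import ModelParams, interior_fixed_point

__all__ = ["MapExpansion", "map_expansion"]


@dataclass(frozen=True)
class MapExpansion:
    """Second-order expansion coefficients at the interior fixed point."""

    E11: float
    E12: float
    E13: float
    E14: float
    E21: float
    E22: float
    E23: float
    E24: float
    P1: float
    P2: float
    P3: float
    P4: float
    P5: float
    P6: float
    P7: float
    P8: float
    x_star: float
    y_star: float


def map_expansion(params: ModelParams) -> MapExpansion:
    """Evaluate the expansion at the interior fixed point with ``h = params.h``."""
    a, b, c, e, h = params.a, params.b, params.c, params.e, params.h
    x, y = interior_fixed_point(params).state
    d = x * x + e
    mixed = 2.0 * b * e * x * y / d**2          # d^2(predation)/dx dy / h
    cross = 2.0 * b * e * x / d**2              # mixed partial per predator
    curv = b * e * y * (-3.0 * x * x + e) / d**3  # half of d^2/dx^2
    resp = b * x * x / d
    return MapExpansion(
        E11=a * h + 1.0 - h * mixed,
        E12=-h * resp,
        E13=-h * cross,
        E14=-h * curv,
        E21=h * mixed,
        E22=1.0 - c * h + h * resp,
        E23=h * cross,
        E24=h * curv,
        P1=a - mixed,
        P2=-resp,
        P3=-cross,
        P4=-curv,
        P5=mixed,
        P6=resp - c,
        P7=cross,
        P8=curv,
        x_star=x,
        y_star=y,
    )
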