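"""Neimark-Sacker (discrete Hopf) bifurcation analysis at the coexistence point.

When ``b > 2c`` and the flip discriminant is negative, the interior fixed
point loses stability through a complex-conjugate eigenvalue pair crossing
the unit circle at ``h2 = (b-2c)/(2c(b-c))``.  With the step offset
``hbar`` the characteristic polynomial is ``R^2 - p R + q`` with

.. math::

    p = 2 + \\frac{a (h_2 + \\bar h)(2c - b)}{b}, \\qquad
    q = 1 + \\frac{2ac (h_2+\\bar h)^2 (b-c)}{b}
          + \\frac{a (h_2+\\bar h)(2c-b)}{b},

so ``|R| = sqrt(q)`` and the modulus crosses 1 transversally with slope
``ell = a(b-2c)/(2b)``.  Writing the critical eigenvalue ``R = m + i w``
and pushing the quadratic terms of the map through the real normal-form
coordinates gives the complex coefficients ``Phi20, Phi11, Phi02, Phi21``
and the first Lyapunov-type discriminatory quantity

.. math::

    \\Theta = -\\Bigl( \\mathrm{Re}\\bigl[ \\tfrac{(1-2R)\\bar R^2}{1-R}
        \\Phi_{11}\\Phi_{20} \\bigr] + \\tfrac12 |\\Phi_{11}|^2
        + |\\Phi_{02}|^2 - \\mathrm{Re}(R\\,\\Phi_{21}) \\Bigr).

(The overall sign follows the standard Wan/Kuznetsov convention, under
which ``Theta < 0`` means a supercritical bifurcation: an attracting
invariant closed curve is born for ``h`` just above ``h2``.  ``Theta > 0``
is subcritical with a repelling curve.)  For this map every third-order
partial of the transformed map vanishes, so ``Phi21 = 0`` identically.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Dict, Tuple

from .expansion import MapExpansion, map_expansion
from .model import ModelParams

__all__ = [
    "NSVerdict",
    "NSNormalFormResult",
    "RealEigenvalueError",
    "ns_char",
    "transversality",
    "resonance_check",
    "ns_theta",
    "RESONANCE_RTOL",
]

logger = logging.getLogger(__name__)

#: relative margin by which a(b-2c)^2 must differ from 4bc(b-c) and
#: 6bc(b-c) for the low-order resonance exclusion to hold
RESONANCE_RTOL = 1e-9


class RealEigenvalueError(ValueError):
    """The eigenvalues are real (``4q <= p^2``): no Neimark-Sacker pair."""


class NSVerdict(enum.Enum):
    SUPERCRITICAL_ATTRACTING = "supercritical_attracting"
    SUBCRITICAL_REPELLING = "subcritical_repelling"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class NSNormalFormResult:
    expansion: MapExpansion
    p0: float
    q0: float
    R: complex
    m: float
    omega: float
    ell: float
    resonance_ok: bool
    #: second partials of the transformed map; every third partial is 0
    d2: Dict[str, float]
    Phi20: complex
    Phi11: complex
    Phi02: complex
    Phi21: complex
    theta: float
    verdict: NSVerdict
    #: closed-form critical step (b-2c)/(2c(b-c)), for reference
    h2: float


def _pq(params: ModelParams, total_h: float) -> Tuple[float, float]:
    a, b, c = params.a, params.b, params.c
    p = 2.0 + a * total_h * (2.0 * c - b) / b
    q = 1.0 + 2.0 * a * c * total_h**2 * (b - c) / b + a * total_h * (2.0 * c - b) / b
    return p, q


def ns_char(
    params: ModelParams, hbar: float = 0.0
) -> Tuple[float, float, Tuple[complex, complex]]:
    """Characteristic data ``(p, q, (R, Rbar))`` at total step ``h + hbar``.

    ``R = p/2 + i sqrt(4q - p^2)/2`` (positive imaginary branch).  Raises
    :class:`RealEigenvalueError` outside the complex regime.
    """
    if params.b <= 2.0 * params.c:
        raise ValueError("Neimark-Sacker analysis requires b > 2c")
    p, q = _pq(params, params.h + hbar)
    disc = 4.0 * q - p * p
    if disc <= 0.0:
        raise RealEigenvalueError(
            f"eigenvalues are real at h={params.h + hbar} (4q - p^2 = {disc:.3e})"
        )
    root = math.sqrt(disc) / 2.0
    R = complex(p / 2.0, root)
    return p, q, (R, R.conjugate())


def transversality(params: ModelParams) -> float:
    """Slope ``d|R|/dh = a(b-2c)/(2b)`` of the eigenvalue modulus at ``h2``."""
    return params.a * (params.b - 2.0 * params.c) / (2.0 * params.b)


def resonance_check(params: ModelParams, rtol: float = RESONANCE_RTOL) -> bool:
    """Low-order resonance exclusion ``R^n != 1`` for ``n = 1..4``.

    Equivalent to ``a(b-2c)^2`` differing from both ``4bc(b-c)`` and
    ``6bc(b-c)``.
    """
    a, b, c = params.a, params.b, params.c
    lhs = a * (b - 2.0 * c) ** 2
    for target in (4.0 * b * c * (b - c), 6.0 * b * c * (b - c)):
        if abs(lhs - target) <= rtol * max(abs(lhs), abs(target)):
            return False
    return True


def ns_theta(params: ModelParams) -> NSNormalFormResult:
    """First Lyapunov-type quantity Theta and the bifurcation verdict.

    Theta is evaluated at the caller-supplied ``params.h`` (all of the
    expansion coefficients, ``m`` and ``omega`` use the same ``h``).  A
    warning is logged when ``h`` is more than 0.1% away from the closed
    form ``h2``, since the normal form is only exact on the critical set.
    """
    a, b, c = params.a, params.b, params.c
    h = params.h
    p0, q0, (R, _) = ns_char(params, 0.0)

    h2 = (b - 2.0 * c) / (2.0 * c * (b - c))
    if abs(h - h2) / h2 > 1e-3:
        logger.warning(
            "ns_theta evaluated at h=%g, %.2g%% away from the critical h2=%g",
            h,
            100.0 * abs(h - h2) / h2,
            h2,
        )

    resonance_ok = resonance_check(params)
    if not resonance_ok:
        logger.warning("low-order resonance condition fails; Theta unreliable")

    E = map_expansion(params)
    m = 1.0 - a * h * (b - 2.0 * c) / (2.0 * b)
    radicand = a * (8.0 * b * c * (b - c) - a * (b - 2.0 * c) ** 2)
    omega = h * math.sqrt(radicand) / (2.0 * b)

    E11, E12, E13, E14 = E.E11, E.E12, E.E13, E.E14
    E23, E24 = E.E23, E.E24
    fXX = 2.0 * (m - E11) * E13 + 2.0 * E12 * E14
    fXY = -omega * E13
    fYY = 0.0
    gXX = (2.0 / omega) * (
        (E14 - E23) * (m - E11) * E12 + (m - E11) ** 2 * E13 - E12**2 * E24
    )
    gXY = -(m - E11) * E13 + E12 * E23
    gYY = 0.0
    d2 = {
        "fXX": fXX, "fXY": fXY, "fYY": fYY,
        "gXX": gXX, "gXY": gXY, "gYY": gYY,
    }

    Phi20 = complex(fXX - fYY + 2.0 * gXY, gXX - gYY - 2.0 * fXY) / 8.0
    Phi11 = complex(fXX + fYY, gXX + gYY) / 4.0
    Phi02 = complex(fXX - fYY - 2.0 * gXY, gXX - gYY + 2.0 * fXY) / 8.0
    Phi21 = 0.0 + 0.0j  # all third partials vanish for this map

    if abs(R - 1.0) < 1e-12:
        raise ZeroDivisionError("R = 1: excluded by the resonance condition")
    first = ((1.0 - 2.0 * R) * R.conjugate() ** 2 / (1.0 - R) * Phi11 * Phi20).real
    theta = -(first + 0.5 * abs(Phi11) ** 2 + abs(Phi02) ** 2 - (R * Phi21).real)

    if theta < 0:
        verdict = NSVerdict.SUPERCRITICAL_ATTRACTING
    elif theta > 0:
        verdict = NSVerdict.SUBCRITICAL_REPELLING
    else:
        verdict = NSVerdict.DEGENERATE

    return NSNormalFormResult(
        expansion=E,
        p0=p0,
        q0=q0,
        R=R,
        m=m,
        omega=omega,
        ell=transversality(params),
        resonance_ok=resonance_ok,
        d2=d2,
        Phi20=Phi20,
        Phi11=Phi11,
        Phi02=Phi02,
        Phi21=Phi21,
        theta=theta,
        verdict=verdict,
        h2=h2,
    )
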