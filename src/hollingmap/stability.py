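"""Linear stability classification and critical step sizes.

A fixed point of the planar map is classified through the characteristic
polynomial of its Jacobian, written here in the trace/determinant
convention

.. math::  F(R) = R^2 - T R + D, \\qquad T = j_{11} + j_{22},\\; D = \\det J.

(Some sources write the same polynomial as ``R^2 + T R + D`` with
``T = -(j11+j22)``; this module standardizes on ``T = trace`` throughout.)
By the Jury criterion both roots lie inside the unit circle iff
``F(1) > 0``, ``F(-1) > 0`` and ``D < 1``.

At the interior fixed point the Jacobian reduces to closed form and the
boundary crossings become explicit in the step size ``h``:

* a real eigenvalue reaches ``-1`` (flip / period-doubling) at

  .. math:: h_1, h_1' = \\frac{(b-2c)a \\mp \\sqrt{a\\Delta}}{2ac(b-c)},
            \\quad \\Delta = (b-2c)^2 a - 8bc(b-c) \\ge 0,

* a complex pair crosses the unit circle (Neimark-Sacker) at

  .. math:: h_2 = \\frac{b-2c}{2c(b-c)}, \\qquad b > 2c.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .model import Jacobian2, ModelParams, interior_fixed_point, jacobian

__all__ = [
    "CharPoly2",
    "StabilityCategory",
    "StabilityVerdict",
    "CriticalSteps",
    "char_poly",
    "classify",
    "classify_origin",
    "classify_interior",
    "critical_steps",
    "UNIT_CIRCLE_TOL",
]

#: default tolerance on | |R| - 1 | below which a root counts as on the
#: unit circle (non-hyperbolic)
UNIT_CIRCLE_TOL = 1e-9


@dataclass(frozen=True)
class CharPoly2:
    """Quadratic characteristic polynomial ``R^2 - T R + D`` of a 2x2 matrix."""

    T: float
    D: float

    @property
    def eigenvalues(self) -> Tuple[complex, complex]:
        """Roots by the (complex-capable) quadratic formula."""
        disc = complex(self.T * self.T - 4.0 * self.D)
        root = disc ** 0.5
        r1 = (self.T + root) / 2.0
        r2 = (self.T - root) / 2.0
        return r1, r2

    def __call__(self, r: complex) -> complex:
        return r * r - self.T * r + self.D


class StabilityCategory(enum.Enum):
    SINK = "sink"
    SOURCE = "source"
    SADDLE = "saddle"
    NON_HYPERBOLIC = "non_hyperbolic"


@dataclass(frozen=True)
class StabilityVerdict:
    category: StabilityCategory
    eigenvalues: Tuple[complex, complex]
    #: some root sits at -1 (period-doubling candidate)
    flip_candidate: bool
    #: complex-conjugate roots on the unit circle (Neimark-Sacker candidate)
    ns_candidate: bool
    #: signed distances |R_i| - 1, so callers can apply their own threshold
    unit_distances: Tuple[float, float]
    #: which Theorem-style branch applied, when classification came from the
    #: interior fixed point (None otherwise)
    branch: Optional[str] = None


@dataclass(frozen=True)
class CriticalSteps:
    """Critical step sizes of the interior fixed point.

    ``h1``/``h1_prime`` (flip) exist only when the discriminant ``delta``
    is non-negative (and ``b > 2c``); ``h2`` (Neimark-Sacker) exists only
    when ``b > 2c``.  Missing values are ``None`` with the reason recorded.
    """

    delta: float
    h1: Optional[float]
    h1_prime: Optional[float]
    h2: Optional[float]
    reasons: Tuple[str, ...] = ()


def char_poly(J: Jacobian2) -> CharPoly2:
    return CharPoly2(T=J.trace, D=J.det)


def classify(cp: CharPoly2, tol: float = UNIT_CIRCLE_TOL) -> StabilityVerdict:
    """Topological type of a fixed point from its characteristic polynomial.

    Sink: both |R| < 1; source: both > 1; saddle: one on each side;
    non-hyperbolic when any |R| is within ``tol`` of 1, with candidate
    flags for a root at -1 (flip) and for complex-conjugate unit-modulus
    roots (Neimark-Sacker).
    """
    r1, r2 = cp.eigenvalues
    d1 = abs(r1) - 1.0
    d2 = abs(r2) - 1.0
    on_circle = (abs(d1) <= tol, abs(d2) <= tol)
    flip = any(
        on and abs(r + 1.0) <= 10.0 * max(tol, 1e-12)
        for on, r in zip(on_circle, (r1, r2))
    )
    ns = (
        all(on_circle)
        and abs(r1.imag) > tol
        and abs(r1 - r2.conjugate()) <= 10.0 * max(tol, 1e-12)
    )
    if any(on_circle):
        cat = StabilityCategory.NON_HYPERBOLIC
    elif d1 < 0 and d2 < 0:
        cat = StabilityCategory.SINK
    elif d1 > 0 and d2 > 0:
        cat = StabilityCategory.SOURCE
    else:
        cat = StabilityCategory.SADDLE
    return StabilityVerdict(
        category=cat,
        eigenvalues=(r1, r2),
        flip_candidate=flip,
        ns_candidate=ns,
        unit_distances=(d1, d2),
    )


def classify_origin(params: ModelParams, tol: float = UNIT_CIRCLE_TOL) -> StabilityVerdict:
    """Extinction state: eigenvalues are ``1 + ah`` and ``1 - ch`` exactly.

    Saddle for ``h < 2/c``, non-hyperbolic (flip candidate) at ``h = 2/c``,
    source for ``h > 2/c``.
    """
    cp = CharPoly2(T=(1.0 + params.a * params.h) + (1.0 - params.c * params.h),
                   D=(1.0 + params.a * params.h) * (1.0 - params.c * params.h))
    return classify(cp, tol=tol)


def _theorem_branch(params: ModelParams, cs: CriticalSteps) -> str:
    h = params.h
    if cs.delta >= 0:
        assert cs.h1 is not None and cs.h1_prime is not None
        if h < cs.h1:
            return "delta>=0, 0<h<h1"
        if h > cs.h1_prime:
            return "delta>=0, h>h1'"
        if math.isclose(h, cs.h1, rel_tol=1e-12) or math.isclose(h, cs.h1_prime, rel_tol=1e-12):
            return "delta>=0, h at a flip-critical step"
        return "delta>=0, h1<h<h1'"
    assert cs.h2 is not None
    if h < cs.h2:
        return "delta<0, 0<h<h2"
    if h > cs.h2:
        return "delta<0, h>h2"
    return "delta<0, h=h2"


def classify_interior(params: ModelParams, tol: float = UNIT_CIRCLE_TOL) -> StabilityVerdict:
    """Classify the coexistence fixed point (requires ``b > 2c``).

    The verdict is derived from the eigenvalues of the interior-fixed-point
    Jacobian; the parameter-region branch (sign of the flip discriminant
    and the ``h`` interval) is reported alongside for reference.
    """
    if params.b <= 2.0 * params.c:
        raise ValueError(
            f"interior classification requires b > 2c (got b={params.b}, c={params.c})"
        )
    fp = interior_fixed_point(params)
    verdict = classify(char_poly(jacobian(params, fp.state)), tol=tol)
    branch = _theorem_branch(params, critical_steps(params))
    return StabilityVerdict(
        category=verdict.category,
        eigenvalues=verdict.eigenvalues,
        flip_candidate=verdict.flip_candidate,
        ns_candidate=verdict.ns_candidate,
        unit_distances=verdict.unit_distances,
        branch=branch,
    )


def critical_steps(params: ModelParams) -> CriticalSteps:
    """Flip and Neimark-Sacker critical step sizes at the interior point.

    ``delta = (b-2c)^2 a - 8bc(b-c)`` is always reported.  ``h1 <= h1'``
    are the roots of ``F(-1)(h) = 0``; ``h2`` solves ``D(h) = 1``.
    """
    a, b, c = params.a, params.b, params.c
    delta = (b - 2.0 * c) ** 2 * a - 8.0 * b * c * (b - c)
    reasons = []
    h1 = h1_prime = h2 = None
    if b > 2.0 * c:
        h2 = (b - 2.0 * c) / (2.0 * c * (b - c))
    else:
        reasons.append("h2 undefined: requires b > 2c")
    if delta >= 0 and b > 2.0 * c:
        root = math.sqrt(a * delta)
        denom = 2.0 * a * c * (b - c)
        h1 = ((b - 2.0 * c) * a - root) / denom
        h1_prime = ((b - 2.0 * c) * a + root) / denom
    elif delta < 0:
        reasons.append("h1, h1' undefined: flip discriminant delta < 0")
    else:
        reasons.append("h1, h1' undefined: requires b > 2c")
    return CriticalSteps(
        delta=delta, h1=h1, h1_prime=h1_prime, h2=h2, reasons=tuple(reasons)
    )
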