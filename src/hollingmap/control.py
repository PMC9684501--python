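"""OGY feedback control of the chaotic map via the predator death rate.

The Ott-Grebogi-Yorke scheme stabilizes the (unstable) coexistence fixed
point by small state-dependent perturbations of an accessible parameter,
here the predator death rate ``c`` around its nominal value ``c0``:

.. math::

    c - c_0 = -K \\begin{pmatrix} x_n - x^* \\\\ y_n - y^* \\end{pmatrix},
    \\qquad K = [\\rho_1 \\; \\rho_2].

Linearizing around the fixed point gives ``z_{n+1} ~ (J - C K) z_n`` with
``J`` the fixed-point Jacobian and ``C = (0, \\Phi)^T`` the derivative of
the map in ``c``, where

.. math::

    \\Phi = -\\frac{a h \\sqrt{(b-c_0) c_0 e}}{(b-c_0) c_0}.

The pair is controllable (``[C : JC]`` has rank 2) whenever the interior
fixed point exists.  Closed-loop stability is the Jury criterion on the
characteristic polynomial of ``J - CK``; its three boundary conditions
(eigenvalue at -1, eigenvalue product 1, eigenvalue at +1) are straight
lines in the ``(rho1, rho2)`` gain plane whose enclosed triangle is the
candidate stabilizing-gain region.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .model import (
    DIVERGENCE_LIMIT,
    DivergenceError,
    Jacobian2,
    ModelParams,
    State,
    functional_response,
    interior_fixed_point,
    jacobian,
)
from .stability import CharPoly2, char_poly

__all__ = [
    "ControlSetup",
    "GainPair",
    "MarginalLineLabel",
    "MarginalLine",
    "GainIntervalReport",
    "UncontrollableError",
    "control_setup",
    "closed_loop",
    "marginal_lines",
    "stable_gain_interval",
    "controlled_orbit",
    "control_phase_sweep",
]


class UncontrollableError(ValueError):
    """The controllability matrix ``[C : JC]`` is rank deficient."""


@dataclass(frozen=True)
class GainPair:
    """Feedback gains multiplying ``(x - x*)`` and ``(y - y*)``."""

    rho1: float
    rho2: float


class MarginalLineLabel(enum.Enum):
    #: closed-loop eigenvalue at -1 (F(-1) = 0)
    H1_FLIP = "H1_flip"
    #: eigenvalue product equal to 1 (D = 1)
    H2_DET = "H2_det"
    #: closed-loop eigenvalue at +1 (F(1) = 0)
    H3_FOLD = "H3_fold"


@dataclass(frozen=True)
class MarginalLine:
    """A marginal-stability line ``alpha*rho1 + beta*rho2 + gamma = 0``."""

    label: MarginalLineLabel
    alpha: float
    beta: float
    gamma: float

    def __call__(self, rho1: float, rho2: float) -> float:
        return self.alpha * rho1 + self.beta * rho2 + self.gamma


@dataclass(frozen=True)
class ControlSetup:
    """Linearization of the controlled system at the target fixed point."""

    params: ModelParams
    c0: float
    delta: float
    target: State
    J: Jacobian2
    phi_c: float
    Cvec: Tuple[float, float]
    Tcheck: np.ndarray
    rank: int


@dataclass(frozen=True)
class GainIntervalReport:
    """Stabilizing ``rho2`` analysis at a fixed ``rho1``.

    ``rho2_flip_root`` / ``rho2_fold_root`` are the boundary-crossing
    roots of ``F(-1) = 0`` and ``F(1) = 0``; ``endpoint_interval`` is the
    open interval between them.  ``jury_interval`` is the exact stable set
    ``{F(1) > 0, F(-1) > 0, D < 1}``, which for this map can be strictly
    smaller; ``matches_endpoints`` flags whether the two agree.
    """

    rho1: float
    rho2_flip_root: float
    rho2_fold_root: float
    rho2_det_root: float
    endpoint_interval: Tuple[float, float]
    jury_interval: Optional[Tuple[float, float]]
    matches_endpoints: bool


def control_setup(
    params: ModelParams,
    c0: Optional[float] = None,
    delta: float = math.inf,
    rank_tol: float = 0.0,
) -> ControlSetup:
    """Build the OGY linearization at the interior fixed point.

    ``c0`` defaults to ``params.c``; the model is evaluated at ``c = c0``.
    ``delta`` is the admissible amplitude of the control perturbation
    (``c`` is clamped to ``(c0 - delta, c0 + delta)`` during controlled
    iteration when finite; by default no clamping).
    """
    if c0 is None:
        c0 = params.c
    p0 = params.replace(c=c0)
    if not p0.has_interior_fixed_point:
        raise ValueError("OGY setup requires b > c0 > 0")
    fp = interior_fixed_point(p0)
    J = jacobian(p0, fp.state)
    a, b, e, h = p0.a, p0.b, p0.e, p0.h
    root = math.sqrt((b - c0) * c0 * e)
    phi_c = -a * h * root / ((b - c0) * c0)
    Cvec = (0.0, phi_c)
    # controllability matrix [C : JC], built from its factors
    JC = J.as_array() @ np.array(Cvec)
    Tcheck = np.column_stack([np.array(Cvec), JC])
    det = Tcheck[0, 0] * Tcheck[1, 1] - Tcheck[0, 1] * Tcheck[1, 0]
    if abs(det) <= rank_tol:
        raise UncontrollableError(f"controllability matrix is singular (det={det})")
    return ControlSetup(
        params=p0,
        c0=c0,
        delta=delta,
        target=fp.state,
        J=J,
        phi_c=phi_c,
        Cvec=Cvec,
        Tcheck=Tcheck,
        rank=2,
    )


def closed_loop(setup: ControlSetup, gains: GainPair) -> Tuple[Jacobian2, CharPoly2]:
    """Closed-loop matrix ``J - CK`` and its characteristic polynomial.

    ``C = (0, phi)`` so only the second row is modified:
    ``(j21 - phi*rho1, j22 - phi*rho2)``.
    """
    J, phi = setup.J, setup.phi_c
    Jc = Jacobian2(
        j11=J.j11,
        j12=J.j12,
        j21=J.j21 - phi * gains.rho1,
        j22=J.j22 - phi * gains.rho2,
    )
    return Jc, char_poly(Jc)


def _poly_in_gains(setup: ControlSetup):
    """T and D of the closed loop as affine functions of (rho1, rho2).

    Returns coefficient triples ``(const, d/drho1, d/drho2)``.
    """
    J, phi = setup.J, setup.phi_c
    T = (J.trace, 0.0, -phi)
    D = (J.det, J.j12 * phi, -J.j11 * phi)
    return T, D


def marginal_lines(setup: ControlSetup) -> List[MarginalLine]:
    """The three marginal-stability lines in the gain plane.

    Each is normalized so the ``rho1`` coefficient equals ``|j12 * phi|``
    (the scale in which the determinant and fold lines are conventionally
    quoted).
    """
    T, D = _poly_in_gains(setup)
    lines = []
    # F(-1) = 1 + T + D = 0
    flip = (1.0 + T[0] + D[0], T[1] + D[1], T[2] + D[2])
    # D = 1
    det = (D[0] - 1.0, D[1], D[2])
    # F(1) = 1 - T + D = 0
    fold = (1.0 - T[0] + D[0], -T[1] + D[1], -T[2] + D[2])
    scale_target = abs(setup.J.j12 * setup.phi_c)
    for label, (gamma, alpha, beta) in (
        (MarginalLineLabel.H1_FLIP, flip),
        (MarginalLineLabel.H2_DET, det),
        (MarginalLineLabel.H3_FOLD, fold),
    ):
        if alpha == 0.0 and beta == 0.0:
            raise ValueError(f"degenerate marginal line {label}")
        if alpha != 0.0:
            factor = scale_target / alpha
        else:
            factor = 1.0
        lines.append(
            MarginalLine(label=label, alpha=alpha * factor, beta=beta * factor, gamma=gamma * factor)
        )
    return lines


def _root_in_rho2(coeffs: Tuple[float, float, float], rho1: float) -> float:
    const, a1, a2 = coeffs
    if a2 == 0.0:
        raise ZeroDivisionError("condition does not depend on rho2")
    return -(const + a1 * rho1) / a2


def stable_gain_interval(setup: ControlSetup, rho1: float) -> GainIntervalReport:
    """Exact Jury-stable ``rho2`` set at fixed ``rho1``, plus boundary roots.

    All three Jury conditions are affine in ``rho2``, so the stable set is
    the intersection of three half-lines: an interval, possibly empty
    (reported as ``None``).  The interval between the ``F(1)`` and
    ``F(-1)`` roots alone can be larger, since it ignores the determinant
    condition; both are returned.
    """
    T, D = _poly_in_gains(setup)
    f_minus = (1.0 + T[0] + D[0], T[1] + D[1], T[2] + D[2])   # F(-1) > 0
    f_plus = (1.0 - T[0] + D[0], -T[1] + D[1], -T[2] + D[2])  # F(1) > 0
    det = (D[0] - 1.0, D[1], D[2])                            # D - 1 < 0

    flip_root = _root_in_rho2(f_minus, rho1)
    fold_root = _root_in_rho2(f_plus, rho1)
    det_root = _root_in_rho2(det, rho1)

    lo, hi = -math.inf, math.inf
    for coeffs, want_positive in ((f_minus, True), (f_plus, True), (det, False)):
        const, a1, a2 = coeffs
        value_at_0 = const + a1 * rho1
        root = -(value_at_0) / a2
        increasing = a2 > 0
        # condition: value_at_0 + a2*rho2 > 0  (or < 0 when want_positive=False)
        if want_positive == increasing:
            lo = max(lo, root)
        else:
            hi = min(hi, root)
    jury: Optional[Tuple[float, float]] = (lo, hi) if lo < hi else None

    endpoints = (min(flip_root, fold_root), max(flip_root, fold_root))
    matches = jury is not None and math.isclose(jury[0], endpoints[0]) and math.isclose(
        jury[1], endpoints[1]
    )
    return GainIntervalReport(
        rho1=rho1,
        rho2_flip_root=flip_root,
        rho2_fold_root=fold_root,
        rho2_det_root=det_root,
        endpoint_interval=endpoints,
        jury_interval=jury,
        matches_endpoints=matches,
    )


def controlled_step(setup: ControlSetup, gains: GainPair, s: State) -> State:
    """One iteration of the OGY-controlled map.

    The effective death rate ``c = c0 - rho1 (x - x*) - rho2 (y - y*)`` is
    clamped into ``(c0 - delta, c0 + delta)`` when ``delta`` is finite.
    """
    params = setup.params
    x, y = s
    xs, ys = setup.target
    c_eff = setup.c0 - gains.rho1 * (x - xs) - gains.rho2 * (y - ys)
    if math.isfinite(setup.delta):
        c_eff = min(max(c_eff, setup.c0 - setup.delta), setup.c0 + setup.delta)
    predation = params.h * functional_response(params, x) * y
    return State(
        (1.0 + params.a * params.h) * x - predation,
        (1.0 - c_eff * params.h) * y + predation,
    )


def controlled_orbit(
    setup: ControlSetup,
    gains: GainPair,
    init: State,
    n: int,
    transient: int = 0,
) -> np.ndarray:
    """Iterate the controlled map; same contract as :func:`hollingmap.model.orbit`."""
    if n <= 0:
        raise ValueError("n must be positive")
    if transient < 0:
        raise ValueError("transient must be non-negative")
    out = np.empty((n, 2), dtype=float)
    s = State(float(init[0]), float(init[1]))
    for i in range(n + transient):
        s = controlled_step(setup, gains, s)
        if not (abs(s.x) < DIVERGENCE_LIMIT and abs(s.y) < DIVERGENCE_LIMIT):
            raise DivergenceError(i)
        if i >= transient:
            out[i - transient] = s
    return out


def control_phase_sweep(
    setup: ControlSetup,
    rho1: float,
    rho2_values,
    init: State,
    n_keep: int = 100,
    transient: int = 500,
):
    """Bifurcation-diagram data over the gain ``rho2`` (fixed ``rho1``).

    For each ``rho2`` the controlled orbit is run and the post-transient
    samples recorded; a diverging orbit is flagged and the sweep continues.
    Returns a pandas DataFrame with columns
    ``rho2, sample_index, x, y, diverged``.
    """
    import pandas as pd

    records = []
    for rho2 in rho2_values:
        gains = GainPair(rho1=rho1, rho2=float(rho2))
        try:
            pts = controlled_orbit(setup, gains, init, n_keep, transient)
        except DivergenceError:
            records.append((float(rho2), -1, math.nan, math.nan, True))
            continue
        for k, (x, y) in enumerate(pts):
            records.append((float(rho2), k, x, y, False))
    return pd.DataFrame(
        records, columns=["rho2", "sample_index", "x", "y", "diverged"]
    )
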