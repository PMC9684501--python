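"""Orbit-based diagnostics: bifurcation sweeps, Lyapunov exponents, portraits.

These are the numerical-experiment counterparts of the analytical modules:
sweeping a single parameter while recording post-transient orbit samples
traces out bifurcation diagrams (period-doubling cascades, invariant-curve
bands, chaotic windows); the maximal Lyapunov exponent, estimated by
propagating a unit tangent vector through the orbit's Jacobians with
per-step renormalization, diagnoses chaos (positive exponent) and
cross-checks the linear theory (in a stable regime it equals the log
spectral radius of the fixed-point Jacobian).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .model import (
    DIVERGENCE_LIMIT,
    DivergenceError,
    ModelParams,
    State,
    interior_fixed_point,
    jacobian,
    orbit,
    step,
)

__all__ = [
    "SweepSpec",
    "LyapunovResult",
    "bifurcation_sweep",
    "local_amplification",
    "max_lyapunov",
    "phase_portrait",
    "count_attractor_points",
    "DEFAULT_INIT_OFFSET",
]

#: default offset from the fixed point used for the "fixed_point_offset"
#: initial-condition policy
DEFAULT_INIT_OFFSET = (1e-3, 1e-3)


@dataclass(frozen=True)
class SweepSpec:
    """Parameterization of a single-parameter bifurcation sweep.

    ``init`` is either an explicit state or the string
    ``"fixed_point_offset"``, meaning the interior fixed point (recomputed
    at every grid value) plus :data:`DEFAULT_INIT_OFFSET`.  ``policy``
    selects whether each grid point restarts from ``init`` (default;
    reproducible, no hysteresis) or continues from the previous grid
    point's final state.
    """

    vary: Literal["a", "b", "c", "e", "h"]
    lo: float
    hi: float
    n_points: int
    transient: int = 1000
    n_keep: int = 64
    init: Union[State, str] = "fixed_point_offset"
    policy: Literal["restart", "continue"] = "restart"
    seed: Optional[int] = None
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("sweep range must satisfy lo < hi")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.n_keep < 1:
            raise ValueError("n_keep must be >= 1")

    def grid(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)


@dataclass(frozen=True)
class LyapunovResult:
    """Maximal Lyapunov exponent estimate (natural log per iterate)."""

    lambda_max: float
    n_used: int
    diverged: bool


def _initial_state(params: ModelParams, spec: SweepSpec, rng) -> State:
    if isinstance(spec.init, str):
        if spec.init != "fixed_point_offset":
            raise ValueError(f"unknown init policy {spec.init!r}")
        fp = interior_fixed_point(params).state
        s = State(fp.x + DEFAULT_INIT_OFFSET[0], fp.y + DEFAULT_INIT_OFFSET[1])
    else:
        s = State(float(spec.init[0]), float(spec.init[1]))
    if spec.jitter > 0.0 and rng is not None:
        dx, dy = rng.normal(scale=spec.jitter, size=2)
        s = State(s.x + dx, s.y + dy)
    return s


def bifurcation_sweep(params: ModelParams, spec: SweepSpec) -> pd.DataFrame:
    """Post-transient orbit samples at each grid value of the varied parameter.

    Returns a DataFrame with columns ``param, sample_index, x, y,
    diverged``; a diverging grid point contributes a single flagged row
    and the sweep continues.
    """
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else None
    records = []
    carry: Optional[State] = None
    for value in spec.grid():
        p = params.replace(**{spec.vary: float(value)})
        if spec.policy == "continue" and carry is not None:
            init = carry
        else:
            init = _initial_state(p, spec, rng)
        try:
            pts = orbit(p, init, spec.n_keep, spec.transient)
        except DivergenceError:
            records.append((float(value), -1, math.nan, math.nan, True))
            carry = None
            continue
        carry = State(*pts[-1])
        for k, (x, y) in enumerate(pts):
            records.append((float(value), k, x, y, False))
    return pd.DataFrame(records, columns=["param", "sample_index", "x", "y", "diverged"])


def local_amplification(params: ModelParams, spec: SweepSpec) -> pd.DataFrame:
    """Denser sweep over a sub-range; identical orbit policy as the parent."""
    return bifurcation_sweep(params, spec)


def max_lyapunov(
    params: ModelParams,
    init: State,
    n: int = 20000,
    transient: int = 1000,
) -> LyapunovResult:
    """Maximal Lyapunov exponent by tangent-vector renormalization.

    A unit tangent vector is propagated by the Jacobian along the orbit
    and renormalized each step; ``lambda_max`` is the mean log growth
    factor over ``n`` post-transient iterates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = State(float(init[0]), float(init[1]))
    v = np.array([1.0, 0.0])
    log_sum = 0.0
    used = 0
    for i in range(transient + n):
        J = jacobian(params, s).as_array()
        s = step(params, s)
        if not (abs(s.x) < DIVERGENCE_LIMIT and abs(s.y) < DIVERGENCE_LIMIT):
            return LyapunovResult(lambda_max=math.nan, n_used=used, diverged=True)
        v = J @ v
        norm = float(np.hypot(v[0], v[1]))
        if norm == 0.0:
            return LyapunovResult(lambda_max=-math.inf, n_used=used, diverged=False)
        v /= norm
        if i >= transient:
            log_sum += math.log(norm)
            used += 1
    return LyapunovResult(lambda_max=log_sum / used, n_used=used, diverged=False)


def phase_portrait(
    params: ModelParams,
    init: State,
    n: int,
    transient: int = 0,
) -> pd.DataFrame:
    """Orbit samples formatted as an (x, y) scatter table."""
    pts = orbit(params, init, n, transient)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})


def count_attractor_points(samples: np.ndarray, decimals: int = 6) -> int:
    """Number of distinct attractor points after rounding to ``decimals``.

    Used to detect period-doubling onsets in sweep columns: a period-k
    orbit yields k distinct values, a quasi-periodic band many more.
    """
    return len(np.unique(np.round(np.asarray(samples, dtype=float), decimals)))
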