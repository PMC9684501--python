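# Methods

## The map and its fixed points

The package analyzes the planar map

    x' = (1 + ah)x − hbx²y/(e + x²)
    y' = (1 − ch)y + hbx²y/(e + x²)

obtained by Euler discretization of a predator–prey system with a Holling
type-III functional response. The conversion efficiency of captured prey
into predators is taken as 1 (it rescales `y` and is not a free
parameter). States are real-valued densities and are iterated exactly as
written — no clipping to the positive quadrant — because the chaotic
regimes of interest live on the unmodified map; an orbit is declared
divergent (with the failing iteration index) once a coordinate exceeds
1e12 in magnitude.

Fixed points: the origin (extinction), and the coexistence point
`x* = ce/√((b−c)ce)`, `y* = ae/√((b−c)ce)` iff `b > c`. At the
coexistence point the per-predator predation rate equals `c` exactly,
which reduces the Jacobian to

    j11 = 1 − ah(b−2c)/b,  j12 = −hc,  j21 = 2ah(b−c)/b,  j22 = 1.

## Stability conventions

All classification goes through the characteristic polynomial in the
trace convention `F(R) = R² − TR + D`, `T = j11 + j22`, `D = det J`.
(Sources that write `R² + TR + D` with `T = −trace` describe the same
polynomial; reported coefficient pairs are always `(−T, D)` so printed
equations of the form `R² + 1.38805R + 0.97224` can be compared
directly.) The Jury conditions `F(1) > 0`, `F(−1) > 0`, `D < 1`
characterize a sink. Classification is done from the eigenvalue moduli,
not from enumerated parameter-region inequalities: the region branch
(discriminant sign and `h`-interval) is reported alongside for reference
but never drives the verdict. A root counts as on the unit circle when
`||R| − 1| ≤ 1e-9` (overridable); the signed distances `|Rᵢ| − 1` are
returned so callers can apply their own threshold.

Critical step sizes at the coexistence point, with
`Δ = (b−2c)²a − 8bc(b−c)`:

* flip: `h₁, h₁′ = [(b−2c)a ∓ √(aΔ)] / (2ac(b−c))` (require `b > 2c`,
  `Δ ≥ 0`); these are exactly the roots of `F(−1)(h) = 0`. The side
  condition is the discriminant `Δ ≥ 0` itself — an algebraically
  simplified variant sometimes quoted (`a(b−2c) > 8bc`) does not make the
  radicand real and is not used.
* Neimark–Sacker: `h₂ = (b−2c)/(2c(b−c))` (require `b > 2c`), the root of
  `D(h) = 1`.

## Flip normal form

At `h = h₁` the eigenvalues are `−1` and `k₂ = 3 − h₁a(b−2c)/b`. The
quadratic Taylor expansion of the translated map (coefficients Ê, and
their step-size derivatives P̂) is evaluated at the coexistence point;
the center-manifold reduction gives `ȳ = c₁x̄² + c₂x̄h* (+ 0·h*²)` and a
one-dimensional map with coefficients `s₁…s₅`, from which

    Γ₁ = s₂,   Γ₂ = s₁² + s₅.

`Γ₁, Γ₂ ≠ 0` certify a genuine flip; `Γ₂ > 0` means the period-2 orbit is
stable. All coefficients are evaluated literally from their closed forms
at the supplied `h` with the perturbation `h* = 0` — no symbolic
re-derivation — and the "at criticality" precondition is checked on the
residual `F(−1)(h)` (relative tolerance 1e-6 against the O(1) scale of
the polynomial) rather than on `h` itself, so it is robust to how the
caller obtained the critical step. `|k₂ ± 1| < 1e-8` is rejected as
degenerate (the reduction divides by `1 ± k₂`); `|Γ| < 1e-10` is reported
as degenerate since all worked cases have `Γ` of order 1. The expansion
is validated against second-order finite differences of the map
(`taylor_check`), and the `(Ê11, Ê12, Ê21, Ê22)` block is checked to have
spectrum `{−1, k₂}`.

## Neimark–Sacker normal form

With total step `h₂ + h̄`, the characteristic data are

    p = 2 + a(h₂+h̄)(2c−b)/b
    q = 1 + 2ac(h₂+h̄)²(b−c)/b + a(h₂+h̄)(2c−b)/b

and `R = p/2 + i√(4q−p²)/2` (positive-imaginary branch; `|R| = √q`). The
modulus crosses 1 with slope `ℓ = a(b−2c)/(2b) > 0` (transversality), and
low-order resonances `Rⁿ = 1 (n ≤ 4)` are excluded iff `a(b−2c)²` differs
from `4bc(b−c)` and `6bc(b−c)` (relative margin 1e-9). Writing
`R = m + iω` with `m = 1 − ah(b−2c)/(2b)`,
`ω = h√(a(8bc(b−c) − a(b−2c)²))/(2b)`, the quadratic terms of the map in
normal-form coordinates give the second partials (all third partials
vanish for this map, so `Φ₂₁ = 0`), the complex coefficients
`Φ₂₀, Φ₁₁, Φ₀₂`, and the first Lyapunov-type quantity

    Θ = −( Re[(1−2R)R̄²/(1−R) · Φ₁₁Φ₂₀] + ½|Φ₁₁|² + |Φ₀₂|² − Re(RΦ₂₁) ).

The overall sign follows the standard Wan/Kuznetsov convention, under
which `Θ < 0` is supercritical: an attracting invariant closed curve
exists for `h` just above `h₂`. (The bracketed expression is sometimes
quoted without the leading minus while its numerical values are reported
with it; this implementation fixes the convention by the dynamical
meaning, verified by direct iteration: just past `h₂` orbits settle onto
a positive-radius bounded annulus.)

`Θ` is evaluated at the caller-supplied `h` — the Ê coefficients, `m` and
`ω` all use that same `h` — because the tabulated reference values
demonstrably do so; a warning is logged when `h` deviates from `h₂` by
more than 0.1%, since the normal form is only exact on the critical set.

## OGY control

The death rate `c` is the accessible parameter, perturbed around its
nominal `c₀` by the feedback law `c − c₀ = −ρ₁(x−x*) − ρ₂(y−y*)`. The
linearization uses the coexistence-point Jacobian `J` (at `c = c₀`) and
`C = (0, Φ)` with `Φ = −ah√((b−c₀)c₀e)/((b−c₀)c₀)` (equal to `−h·y*`,
which a central-difference oracle confirms). The controllability matrix
`[C : JC]` is built from its factors and is nonsingular whenever the
coexistence point exists. The closed loop `J − CK` modifies only the
second row, `(j21 − Φρ₁, j22 − Φρ₂)`; its characteristic polynomial is
affine in the gains, so each Jury boundary — eigenvalue at −1
(`H1_flip`), eigenvalue product 1 (`H2_det`), eigenvalue at +1
(`H3_fold`) — is a straight line `αρ₁ + βρ₂ + γ = 0` in the gain plane.
Lines are normalized so the `ρ₁` coefficient equals `|j12·Φ|`, the scale
in which such lines are conventionally quoted.

At fixed `ρ₁` the stable `ρ₂` set is computed exactly as the intersection
of the three affine half-line conditions; it is reported together with
the `F(±1) = 0` boundary roots because the interval between those roots
alone ignores the determinant condition and can be strictly larger —
for the worked control example it is (the package flags the mismatch
rather than choosing one). Controlled simulation iterates the full
nonlinear map with the state-dependent `c`; an optional amplitude bound
`δ` clamps the effective `c` into `(c₀−δ, c₀+δ)` (default ∞, i.e. no
clamp, matching the uncl amped feedback law).

## Diagnostics

Bifurcation sweeps iterate the map on a uniform grid of one parameter,
discard a transient, and record the kept samples; per-point divergence is
flagged and the sweep continues. The default initial-condition policy
restarts every grid point at the coexistence point plus (1e-3, 1e-3) —
reproducible and hysteresis-free; a warm-start ("continue") policy is
available, and optional seeded Gaussian jitter of the initial condition
is recorded in the spec. Identical spec and seed give byte-identical
tables. The maximal Lyapunov exponent propagates one unit tangent vector
through the orbit Jacobians with per-step renormalization (transient 1000
and 20000 iterates by default) and is cross-checked against the log
spectral radius of the fixed-point Jacobian in sink regimes (agreement to
1e-3). Attractor cardinality (for onset detection) counts distinct kept
samples after rounding — 6 decimals by default; onset-bracketing tests
use 4 decimals because critical slowing near a flip leaves residuals of
order 1e-5 after a few thousand transient steps.

Problem sizes used by the test suite and acceptance checks — 500-point
sweeps with 2000-step transients, 20000–30000-iterate Lyapunov runs,
5000-step controlled orbits — were chosen as the smallest sizes at which
the measured quantities are stable to well within the asserted
tolerances.

## Known limitations and caveats

* The flip and Neimark–Sacker reductions are quadratic/cubic-order normal
  forms at the coexistence point only; the flip at the origin (`h = 2/c`)
  and period-k orbits (k > 1) are not analyzed.
* `Θ` away from the critical set is a heuristic evaluation (see warning
  above): at a working point 12% below `h₂` it reproduces a reference
  value only to about 1%.
* On this map the invariant-curve onset observed by direct iteration
  coincides with the closed-form `h₂` (e.g. 3.75 for `b=0.5, c=0.1`);
  sweeps configured exactly at `h = h₂` sit on the critical set, where
  the fixed point is only weakly (algebraically) attracting and Lyapunov
  exponents are 0 to estimator resolution — parameter scans along other
  axes at that exact `h` are degenerate by construction.
* The exact Jury-stable gain set of the control example is a strict
  subset of the interval between the `F(±1)` boundary roots; users who
  take the latter as "the" stable interval will include gains with
  `|R₁R₂| > 1`.
* No basin-of-attraction or rotation-number computation; figure
  reproduction from sweeps is qualitative (onsets and attractor
  cardinality), not bitwise.
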