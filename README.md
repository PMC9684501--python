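# hollingmap

Stability, bifurcation and chaos-control analysis of a discrete-time
predator–prey map with a Holling type-III functional response.

## The model

Prey density `x` and predator density `y` evolve under the forward-Euler
discretization (step size `h`) of

```
x' = a·x − b·x²·y/(e + x²)
y' = −c·y + b·x²·y/(e + x²)
```

so one iteration of the map is

```
x_{n+1} = (1 + a·h)·x_n − h·b·x_n²·y_n/(e + x_n²)
y_{n+1} = (1 − c·h)·y_n + h·b·x_n²·y_n/(e + x_n²)
```

with prey growth rate `a`, predation coefficient `b`, predator death rate
`c` and half-saturation constant `e` (all positive). The sigmoidal
(type-III) predation rate `b·x²/(e + x²)` is the standard form for
predators that switch targets at low prey density.

Besides the extinction state at the origin, the map has a unique
coexistence fixed point `(x*, y*) = (ce, ae)/√((b−c)ce)` whenever `b > c`.
The package provides, in closed form and numerically:

* **Stability classification** of both fixed points via the Jury
  conditions on the characteristic polynomial `F(R) = R² − T·R + D`
  (sink / source / saddle / non-hyperbolic), with the critical step sizes
  `h₁, h₁′` (flip, eigenvalue −1) and `h₂ = (b−2c)/(2c(b−c))`
  (Neimark–Sacker, complex pair on the unit circle).
* **Flip normal form**: the center-manifold reduction at `h = h₁` and the
  discriminatory quantities `Γ₁ = s₂` and `Γ₂ = s₁² + s₅`; the emerging
  period-2 orbit is stable iff `Γ₂ > 0`.
* **Neimark–Sacker normal form**: critical eigenvalue `R = m + iω`,
  transversality `ℓ = a(b−2c)/(2b)`, low-order resonance exclusion, the
  complex coefficients `Φ₂₀, Φ₁₁, Φ₀₂, Φ₂₁` and the first Lyapunov-type
  quantity `Θ` (supercritical — attracting invariant curve — iff `Θ < 0`).
* **OGY chaos control** using the death rate `c` as the accessible
  parameter: linearization `(J, C)`, controllability, the closed-loop
  matrix `J − CK` for gains `K = [ρ₁ ρ₂]`, the three marginal-stability
  lines in the gain plane and the exact Jury-stable gain set, plus
  controlled-orbit simulation.
* **Diagnostics**: bifurcation-diagram sweeps over any parameter, maximal
  Lyapunov exponents (tangent-vector renormalization) and phase portraits.

## Worked example

The parameter set `a=4, b=2, c=0.1, e=0.7` has its flip bifurcation at
`h₁ = 0.5926274349`:

```
$ hollingmap flip --a 4 --b 2 --c 0.1 --e 0.7
{
  ...
  "k2": 0.86654123436,
  "gamma1": -3.3748015748,
  "gamma2": 0.267544150994,
  "verdict": "stable_period2",
  "h": 0.592627434731
}
```

`gamma1 ≠ 0` confirms a genuine flip at `h₁`, and `gamma2 > 0` means the
period-2 orbit born there is stable: just past `h₁` the populations settle
into a two-year-type oscillation around the coexistence state, the first
step of the period-doubling cascade to chaos visible in an `h`-sweep
(`hollingmap sweep --vary h --min 0.58 --max 0.8875 ...`).

For `a=1.5, b=0.5, c=0.1, e=2` the instability is oscillatory instead:

```
$ hollingmap neimark-sacker --a 1.5 --b 0.5 --c 0.1 --e 2 --h 3.7328
{
  ...
  "theta": -0.395115389385,
  "verdict": "supercritical_attracting",
  "h2": 3.75
}
```

`Θ < 0`: past the critical step size an attracting invariant closed curve
surrounds the fixed point — prey and predator densities cycle
quasi-periodically. And the chaotic regime of `a=9, b=2, c=0.25, e=0.5,
h=0.5` is stabilized by OGY feedback:

```
$ hollingmap control-region --preset example3_control
{
  "c0": 0.25,
  "J": [[-2.375, -0.125], [7.875, 1.0]],
  "phi_c": -4.81070235442,
  ...
  "gain_interval": {
    "rho1": 1.55,
    "rho2_flip_root": -0.12601469994,
    "rho2_fold_root": 0.118036115063,
    "jury_interval": [-0.127658472287, -0.12601469994],
    "matches_endpoints": false
  }
}
```

At `ρ₁ = 1.55` the eigenvalue-at-±1 boundary roots are
`ρ₂ = −0.1260146999` and `0.1180361151`, but the full Jury criterion
(including the determinant condition) stabilizes only the narrow interval
`(−0.12766, −0.12601)` — the package reports both and flags the
difference.

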