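# Methods

## Model

The package integrates the extended Kierstead–Slobodkin (KiSS)
reaction–diffusion equation

    u_t = D ∇²u + τ u^α

for a population density `u ≥ 0` (sign-indefinite initial data are allowed
and arise in the benchmark problems) on an interval `[lo, hi]` or a square,
with homogeneous Dirichlet ("absorbing") boundaries by default.  Parameters:

| parameter | meaning | units | constraint |
|---|---|---|---|
| `D` | diffusion coefficient | length²/time | `D > 0` |
| `τ` | growth rate | 1/time | `τ ≥ 0` |
| `α` | critical exponent | — | `α > 0` |

For `α = 1` the sine-series solution on `[0, l]` is

    u(x,t) = Σ aₙ sin(nπx/l) exp[(τ − D n²π²/l²) t],
    aₙ = (2/l) ∫₀ˡ u₀(x) sin(nπx/l) dx,

whose slowest mode changes sign of growth at the critical patch size
`l* = π√(D/τ)`.  Note the `D` in the exponent: the series is only
consistent with the governing equation and with the threshold formula when
the diffusion coefficient multiplies `n²π²/l²`.  For `τ = 0` the
free-space limits are the heat kernel `exp(−x²/4Dt)/√(4πDt)` (point
release; peak decays as `1/√(4πDt)`, unit mass) and the error-function
front `(1/√π)∫_{x/√(4Dt)}^{l} e^{−ξ²} dξ`.  No closed forms exist for
`α ≠ 1`; those regimes are validated by self-convergence and by an
independent implicit (Radau) integration of the same semidiscretization in
the test suite.

`α ≥ 1` is assumed in practice (the paper-scale experiments use α ∈ {1,2});
for non-integer `α` the nodewise power is computed as `sign(u)|u|^α` so
that transiently negative nodal values never produce complex arithmetic.

## Spatial discretization

*Grid rule.*  Dirichlet grids place `N` nodes including both endpoints,
`h = (hi − lo)/(N − 1)`; the endpoints are pinned to zero and excluded from
the unknown vector.  Periodic grids follow the FFT convention
`h = (hi − lo)/N` with the right endpoint identified with the left; the
node count would otherwise be inconsistent with the spectral symbol.
`N ≥ 7` is required for Dirichlet grids (the five-point stencil needs two
interior neighbours on each side of every unknown).

*Fourth-order differences.*  The Laplacian is the five-point stencil
`(−1, 16, −30, 16, −1)/(12h²)`.  At the walls the stencil reaches one ghost
node, filled by odd reflection through the wall (`u₋₁ = −u₁`); for profiles
vanishing at the wall this closure preserves fourth-order accuracy (the
odd extension of such a profile is smooth through the boundary).  The 1-D
operator is a dense symmetric matrix on the interior unknowns and is
diagonalized once (`scipy.linalg.eigh`); the 2-D operator is the Kronecker
sum `A⊗I + I⊗B` of the per-axis matrices and is never materialized — all
exponential weights act in the tensor eigenbasis
`Ũ = Vₓᵀ U V_y`, at the cost of two small dense matrix products per
transform.

*Collocation.*  Periodic problems use the Fourier symbol `−Dk²`,
`k = 2πj/L`; Dirichlet problems can opt into sine collocation (DST-I, the
discrete odd extension) with the exact continuous symbol `−D(nπ/L)²`.
Default pairing: `fd4 ↔ dirichlet0`, `spectral ↔ periodic`.

## Time integration

All schemes act in the modal basis of the spatial operator, where `e^{Lh}`
is a per-mode scalar; the nonlinear term is evaluated nodewise in physical
space, with a transform round-trip per evaluation.

*ETDRK4* (Cox–Matthews).  Stages

    a  = E2·u + Q·F(u,t)
    b  = E2·u + Q·F(a,t+h/2)
    c  = E2·a + Q·(2F(b,t+h/2) − F(u,t))
    u⁺ = E·u + W_u·F(u) + 2·W_ab·(F(a)+F(b)) + W_c·F(c)

with `E = e^{Lh}`, `E2 = e^{Lh/2}`, `Q = (E2−I)/L` and the three bracket
weights `[−4−z+e^z(4−3z+z²)]/z³`, `[2+z+e^z(−2+z)]/z³`,
`[−4−3z−z²+e^z(4−z)]/z³` (each scaled by `h`, `z = Lh`).  Two conventions
matter and are fixed here deliberately: the `c` stage advances from `a`
(not from `u`), and the `/z³` denominator applies to each bracket.  Both
choices are confirmed by the symbolic expansion of the resulting
amplification factor, which reproduces the published fourth-order series
coefficients (247/2880, 61/720, 7/640, 19/11520) exactly — the variant
that advances `c` from `u` does not.  The consistency weights are
`(h/6, h/3, h/3, h/6)`, the classical RK4 profile; `W_ab` is stored as the
single bracket (limit `h/6`) and applied with the explicit factor two.

*φ-weight evaluation.*  The brackets suffer catastrophic cancellation as
`z → 0` (they are `O(1)` differences of `O(z⁻³)` terms).  For `|z| <
0.5` each weight is evaluated as the mean of its closed form over 32
points of a unit circle centred at `z` — the trapezoidal rule on a circle
is spectrally accurate for these entire functions, and the mean-value
property makes the average equal the desired value at the centre.  The
cutoff and point count are configuration-exposed (`numerics.contour_cutoff`,
`numerics.contour_points`).  Both branches agree to better than 1e−12
relative, and against a 50-digit reference on `|z| ≤ 1`.  The higher
φ-functions (`φ_k`, `k ≤ 6`) needed by the multistep weights use the same
contour device with a wider cutoff of 2.0, because the downward recurrence
`φ_{k+1} = (φ_k − 1/k!)/z` amplifies roundoff by `1/|z|` per level.

*Exponential multistep comparators.*  ETDM4/5/6 are the exponential
Adams–Bashforth schemes of orders 4–6,

    u_{n+1} = e^{hL} u_n + h Σ_{k<p} γ_k(hL) ∇^k F_n,

with `γ_k(z) = ∫₀¹ e^{(1−s)z} s(s+1)…(s+k−1)/k! ds` expressed through
φ-functions and `∇^k` the backward differences of the stored nonlinear
evaluations.  ETDADAMS4 is the algebraically identical order-4 scheme in
Lagrange form (weights attached to past values directly); it is kept as an
independent code path because the source material names both without
defining a distinction.  Startup states come from ETDRK4 at the same step;
for the order-5/6 schemes each startup interval is subdivided into
`m ≈ 2/√k` ETDRK4 substeps so the `O(k⁵)` startup error cannot cap the
measured order (this pushes it to `O(k⁷)`).

*Driver.*  `integrate` takes `round(T/k)` equal steps (a non-integral
`T/k` is rejected; there is no partial final step), records per-step
diagnostics (total mass `Σu·h` per axis, min, max) and snapshots at
requested times on the step grid, and halts with a blow-up flag and the
last valid time if the state exceeds `1e10` in max-norm or goes
non-finite — relevant because `α > 1` admits genuine finite-time blow-up.
There is no randomness anywhere in the integration; identical
configurations produce byte-identical diagnostics.

## Stability analysis

Applying ETDRK4 to `u' = gu + λu` with the `g` part in `L` and the `λ`
part in `F` gives the one-step growth ratio `r(x, y)`, `x = λh`, `y = gh`,
a quartic polynomial in `x` with entire coefficients `g_i(y)`.  The
module evaluates `r` by running the stage recurrence directly —
independent of the integrator's code path — with its own small-argument
branch (truncated φ-series, 30 terms, cutoff `|y| < 0.8`).  Facts used as
anchors: `r(0, y) = e^y`; `r(x, 0)` is the RK4 polynomial
`1 + x + x²/2 + x³/6 + x⁴/24`; and `r(−y, y) = 1` exactly (the weights
collapse to `φ₁` on the stationary line `λ + g = 0`).

`series_coefficients` expands the same recurrence symbolically (sympy) into
exact rationals.  The `x⁰` and `x¹` profiles both expand `e^y`; a numeric
bivariate Cauchy-integral extraction (FFT on small circles) independently
confirms every coefficient up to `x⁴y³`.

`trace_boundary` solves `r(x, y) = e^{iθ}` for fixed real `y ≤ 0` by
quartic root-finding (the `g_i(y)` evaluated in closed form, not by the
truncated series), following the branch continuous in `θ` seeded from the
root nearest the origin.  Because the quartic's roots permute as `e^{iθ}`
winds the unit circle, the branch generally closes only after several
2π loops (four, for the values studied); `θ` is continued until closure
and each root is Newton-polished so the residual `||r| − 1|` stays below
1e−10.  The enclosed area (shoelace) of the traced curve for `y = 0`
matches a brute-force area fill of the classical RK4 stability region to
three digits, and the areas grow monotonically along
`y = 0, −3.5, −5, −7, −9, −11`.

## Benchmarks and error reporting

The accuracy metric is the relative root-sum-square error
`‖L₂‖ = √(Σ(eⱼ−cⱼ)²/Σeⱼ²)` over the interior nodes.  For the nonlinear
benchmark (`D = τ = 0.5`, `α = 2`, `u₀ = sin 2πx` on `[−1,1]`, `N = 200`,
`T = 1`) no closed form exists, so the reference is ETDRK4 on the same
spatial grid at `k_ref = 1/8192`; the policy and `k_ref` are recorded in
every report.  Using the same grid for reference and computed solution
cancels the spatial error exactly, so the table measures pure
time-integration error; the reference's own time error (≈1e−13) is
negligible against the coarsest asserted row.  With this policy the
computed errors at `k = 1/32` and `1/64` land within 15% of the published
table values, and the log–log slope over `k ∈ {1/32, 1/64, 1/256}` is
4.0 to within ±0.05.  At `k = 1/256` the published value sits about 2×
above the scheme's own fourth-order trend (the published inter-row ratios
drop below 4ᵖ there), which is the signature of an error floor in the
unstated published reference; the computed error — confirmed to five
digits by an independent implicit Radau integration — is therefore treated
as bounded above by the published number rather than matched two-sidedly.
Wall-clock times are logged (`cpu_s`) for cost-vs-accuracy comparisons but
are hardware-dependent and never asserted.

The patch-size sweep integrates the linear model from the slowest sine
mode on `[0, l]` for a grid of patch lengths and reports the measured
growth rate `log(max|u(T)|/max|u(0)|)/T`, whose analytic value
`τ − Dπ²/l²` is affine in `1/l²`; the threshold estimate interpolates the
rate linearly in `1/l²` across the sign-change bracket and recovers `l*`
to ~1e−9 at `N = 200`, `k = 1e−3`.

Problem sizes used by the default test and acceptance runs — `N = 200` in
1-D, `N ≤ 48` in 2-D, reference step `1/8192`, sweeps of ≤ 6 patch
lengths at 5000 steps each — keep the whole suite under a minute on one
CPU while leaving every asserted quantity far from its tolerance.

## Numerical edge cases and conventions

* `z = 0` (and any `|z|` below the cutoff) is handled by the contour
  average — no division by zero, exact limits `Q → h/2`, brackets → `h/6`.
* Cross-implementation agreement between `etdrk4_step` and the stability
  module's `r(x, y)` is asserted at 1e−13 relative to `max(1, |r|)`: `r`
  crosses zero inside the sampled parameter square, and where `|r| ~ 1e−6`
  while the stage terms are `O(10)` no two independent double-precision
  evaluations can agree to 1e−13 in the plain relative sense (the plain
  bound is additionally asserted wherever `|r| ≥ 1e−2`).
* Snapshot text files store 17 significant digits, so write → read
  round-trips are bit-exact.
* The catalog formula `sinc(√((x/π)² + (y/π)²))` uses the normalized
  convention `sinc(z) = sin(πz)/(πz)` and hence equals `sin(r)/r` in the
  plain radius `r`; the related entry `sin_radial` is read literally as
  `sin(r/π)`.  The damped-cosine entry is
  `cos(x)cos(y)·exp(−√(x²+y²)/4)`.

## Known limitations

* Uniform tensor grids only; no adaptive refinement, no Neumann/Robin
  closures beyond the odd-reflection Dirichlet rule, no adaptive time
  stepping, and no Krylov φ-evaluation for operators without an accessible
  eigenbasis.
* The 2-D finite-difference path assumes the same node count and bounds on
  both axes (the benchmark geometries are square).
* Closed-form solutions are available only for `α = 1` and `τ = 0`;
  everything else is validated by convergence and cross-implementation
  checks, not against exact solutions.
* The dense eigendecomposition of the 1-D FD operator costs `O(N³)` once
  per (grid, D) pair — fine for the `N ≤ 10³` regimes targeted here, but
  the sine/Fourier collocation path is preferable for much larger grids.
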