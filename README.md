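# kiss-sim

Simulation toolkit for the extended Kierstead–Slobodkin (KiSS)
reaction–diffusion model of population growth on a bounded patch,

```
u_t = D ∇²u + τ uᵅ,        u = 0 on the patch boundary,
```

where `u(x, t)` is the organism density, `D > 0` the diffusion (dispersal)
coefficient, `τ ≥ 0` the growth rate and `α > 0` the critical exponent
(`α = 1` is the classical linear KiSS model; `α > 1` adds a
super-exponential growth term that admits finite-time blow-up).  The model
was originally devised to explain red-tide plankton blooms, and its central
ecological question — *how large must a habitat patch be for the population
to persist?* — has the sharp answer `l* = π√(D/τ)` in the linear case:
below this critical patch size diffusion through the absorbing boundary
outpaces growth and the population dies out; above it the population
blooms.

The package is aimed at modellers who want to study the nonlinear regime
numerically with high-order machinery:

* **Space**: fourth-order central differences (five-point stencil, dense on
  the interior unknowns with an odd-reflection Dirichlet closure; a
  Kronecker-sum tensor form in 2-D) or Fourier/sine collocation, in 1-D and
  2-D.
* **Time**: the fourth-order exponential time differencing Runge–Kutta
  scheme of Cox–Matthews (ETDRK4), with its φ-function weights evaluated by
  the Kassam–Trefethen contour average near the origin, plus exponential
  Adams–Bashforth multistep comparators of orders 4–6 (ETDM4/5/6,
  ETDADAMS4).
* **Theory**: the linear model's sine-series solution, the heat-kernel and
  error-function limits of the diffusion-only model, the critical-patch
  criterion, and the full linear stability analysis of ETDRK4 — its
  amplification factor `r(x, y)` on `u' = gu + λu` (`x = λh`, `y = gh`),
  the exact bivariate series of `r`, and traced stability-region boundaries
  `|r| = 1`.

## Worked example: the critical patch size

```python
import math
from kiss_sim import KissModel, critical_length
from kiss_sim.experiments import patch_size_sweep

model = KissModel(D=1.0, tau=1.0, alpha=1.0)
print("critical patch size l* =", critical_length(model))

table, lstar = patch_size_sweep(model, (2.8, 3.0, 3.2, 3.4),
                                T=3.0, k=5e-3, N=100)
print(table.to_string(index=False))
print("empirical threshold:", lstar)
```

prints

```
critical patch size l* = 3.141592653589793
  l  indicator  blowup
2.8  -0.258878   False
3.0  -0.096623   False
3.2   0.036171   False
3.4   0.146228   False
empirical threshold: 3.1415926358932493
```

The *indicator* column is the measured exponential growth rate
`log(max|u(T)| / max|u(0)|) / T` of the slowest sine mode on a patch of
length `l`; its analytic value is `τ − Dπ²/l²`.  The sign flips between
`l = 3.0` and `l = 3.2`, and interpolating the rate linearly in `1/l²`
recovers the analytic threshold `π ≈ 3.14159` to nine digits: simulated
populations persist exactly on patches larger than `π√(D/τ)`.

## Command line

```sh
kiss-sim run -c config.yaml            # one simulation (snapshots, CSV, JSON)
kiss-sim converge -c config.yaml --schemes ETDRK4,ETDM4 --ks 0.03125,0.015625
kiss-sim stability --y 0 --y -3.5 --y -5 --ntheta 512
kiss-sim patchsize -c config.yaml --l-grid 2.8,3.0,3.2,3.4
```

A minimal config:

```yaml
model:  {D: 0.5, tau: 0.5, alpha: 2}
domain: {dim: 1, lo: -1.0, hi: 1.0, N: 200, bc: dirichlet0}
time:   {k: 0.00390625, T: 1.0}
ic:     {name: sin2pix}
```

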