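"""Linear stability analysis of ETDRK4.

The scheme is applied to the scalar two-parameter problem u' = g u + lambda u
with the g-part treated exactly and the lambda-part through the nonlinear
machinery.  With x = lambda*h and y = g*h the one-step growth ratio
r(x, y) = u_{n+1}/u_n is a quartic polynomial in x whose coefficients are
entire functions of y.  This module evaluates r directly (independently of
the integrator code path), expands it as an exact bivariate Taylor series,
and traces the stability-region boundaries |r| = 1 in the complex x plane
for fixed real y <= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "amplification_factor",
    "AmplificationSeries",
    "series_coefficients",
    "StabilityCurve",
    "trace_boundary",
]

_SERIES_TERMS = 30
_SERIES_CUTOFF = 0.8


def _phi_series(z: np.ndarray, k: int, terms: int = _SERIES_TERMS) -> np.ndarray:
    """phi_k(z) = sum_{j>=0} z^j / (j+k)! by truncated Taylor series (Horner).

    Converges to full double precision for |z| <~ 1 with 30 terms; used as
    the small-argument branch, deliberately independent of the contour
    evaluation in the integrator module.
    """
    acc = np.zeros_like(z)
    for j in range(terms, -1, -1):
        acc = acc * z + 1.0 / math.factorial(j + k)
    return acc


def _stage_quantities(y: np.ndarray):
    """E, E2, q, w1, w2, w3 at y (h = 1), cancellation-free near 0.

    The bracket weights are the phi-combinations
    w1 = phi1 - 3 phi2 + 4 phi3, w2 = phi2 - 2 phi3, w3 = -phi2 + 4 phi3,
    and q = (e^{y/2} - 1)/y = phi1(y/2)/2.
    """
    ya = np.asarray(y)
    E = np.exp(ya)
    E2 = np.exp(ya / 2.0)
    small = np.abs(ya) < _SERIES_CUTOFF
    q = np.empty_like(E)
    w1 = np.empty_like(E)
    w2 = np.empty_like(E)
    w3 = np.empty_like(E)
    if np.any(small):
        zs = ya[small]
        p1, p2, p3 = (_phi_series(zs, k) for k in (1, 2, 3))
        q[small] = 0.5 * _phi_series(zs / 2.0, 1)
        w1[small] = p1 - 3.0 * p2 + 4.0 * p3
        w2[small] = p2 - 2.0 * p3
        w3[small] = -p2 + 4.0 * p3
    if np.any(~small):
        z = ya[~small]
        ez, ez2, z3 = np.exp(z), np.exp(z / 2.0), z**3
        q[~small] = (ez2 - 1.0) / z
        w1[~small] = (-4.0 - z + ez * (4.0 - 3.0 * z + z * z)) / z3
        w2[~small] = (2.0 + z + ez * (-2.0 + z)) / z3
        w3[~small] = (-4.0 - 3.0 * z - z * z + ez * (4.0 - z)) / z3
    return E, E2, q, w1, w2, w3


def amplification_factor(x, y):
    """One-step growth ratio r(x, y) of ETDRK4 on u' = g u + lambda u.

    Computed by running the stage recurrence on the scalar problem with
    u_n = 1 (the nonlinear term is F(u) = lambda u, so every stage is a
    polynomial in x).  r(0, y) = e^y exactly; r(x, 0) is the classical RK4
    polynomial 1 + x + x^2/2 + x^3/6 + x^4/24.
    """
    xa = np.asarray(x, dtype=complex)
    ya = np.asarray(y, dtype=complex)
    xa, ya = np.broadcast_arrays(xa, ya)
    E, E2, q, w1, w2, w3 = _stage_quantities(ya)
    a = E2 + xa * q
    b = E2 + xa * q * a
    c = E2 * a + xa * q * (2.0 * b - 1.0)
    r = E + xa * w1 + 2.0 * xa * w2 * (a + b) + xa * w3 * c
    if np.isrealobj(np.asarray(x)) and np.isrealobj(np.asarray(y)):
        r = r.real
    if np.isscalar(x) and np.isscalar(y):
        return complex(r) if np.iscomplexobj(r) else float(r)
    return r


def _g_coefficients(y: float):
    """Exact (closed-form) quartic coefficients g0..g4 of r(., y)."""
    E, E2, q, w1, w2, w3 = _stage_quantities(np.asarray([y], dtype=float))
    E, E2, q, w1, w2, w3 = (float(v[0]) for v in (E, E2, q, w1, w2, w3))
    g0 = E
    g1 = w1 + 4.0 * w2 * E2 + w3 * E2 * E2
    g2 = 2.0 * w2 * q * (1.0 + E2) + w3 * q * (3.0 * E2 - 1.0)
    g3 = 2.0 * w2 * q * q + 2.0 * w3 * q * q * E2
    g4 = 2.0 * w3 * q**3
    return g0, g1, g2, g3, g4


# ---------------------------------------------------------------------------
# exact bivariate Taylor series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmplificationSeries:
    """Exact rational Taylor coefficients of r(x, y) about (0, 0).

    ``g[i][j]`` (sympy Rational) is the coefficient of x^i y^j, i = 0..4,
    j = 0..max_y_order.  g[0] is the series of e^y; at y = 0 the x-profile
    is the RK4 polynomial (1, 1, 1/2, 1/6, 1/24).
    """

    g: tuple
    max_y_order: int

    def coeff(self, i: int, j: int):
        """Coefficient of x^i y^j as an exact sympy Rational."""
        return self.g[i][j]


def series_coefficients(max_y_order: int = 3) -> AmplificationSeries:
    """Symbolically expand the ETDRK4 stage recurrence about (0, 0).

    Builds r(x, y) from the exact stage expressions (E = e^y, E2 = e^{y/2},
    q = (E2-1)/y, bracket weights over y^3) and returns its bivariate
    Taylor coefficients as exact rationals.
    """
    if max_y_order < 3:
        raise ValueError("max_y_order must be >= 3")
    import sympy as sp

    x, y = sp.symbols("x y")
    E = sp.exp(y)
    E2 = sp.exp(y / 2)
    q = (E2 - 1) / y
    w1 = (-4 - y + E * (4 - 3 * y + y**2)) / y**3
    w2 = (2 + y + E * (-2 + y)) / y**3
    w3 = (-4 - 3 * y - y**2 + E * (4 - y)) / y**3
    a = E2 + x * q
    b = E2 + x * q * a
    c = E2 * a + x * q * (2 * b - 1)
    r = E + x * w1 + 2 * x * w2 * (a + b) + x * w3 * c
    poly = sp.Poly(sp.expand(r), x)
    gs = []
    for i in range(5):
        gi = sp.together(poly.coeff_monomial(x**i))
        ser = sp.series(gi, y, 0, max_y_order + 1).removeO()
        ser = sp.expand(ser)
        gs.append(tuple(sp.Rational(sp.nsimplify(ser.coeff(y, j)))
                        for j in range(max_y_order + 1)))
    return AmplificationSeries(g=tuple(gs), max_y_order=max_y_order)


# ---------------------------------------------------------------------------
# stability-region boundaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StabilityCurve:
    """Closed boundary |r(x, y)| = 1 in the complex x plane for fixed y."""

    y: float
    theta: np.ndarray
    x: np.ndarray  # complex boundary points

    def area(self) -> float:
        """Enclosed area by the shoelace formula."""
        xr, xi = self.x.real, self.x.imag
        return 0.5 * abs(
            float(np.sum(xr[:-1] * xi[1:] - xr[1:] * xi[:-1]))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta": self.theta, "re_x": self.x.real, "im_x": self.x.imag}
        )


def trace_boundary(y: float, n_theta: int = 512) -> StabilityCurve:
    """Trace the stability boundary by solving r(x, y) = e^{i theta}.

    For each theta the quartic sum_i g_i(y) x^i - e^{i theta} = 0 is solved
    with the g_i evaluated from the closed-form stage expressions (exact in
    y, not the truncated series); the branch continuous in theta, seeded
    from the root nearest the origin at theta = 0, is followed.  Because the
    quartic's roots permute as e^{i theta} winds around the unit circle, the
    branch may need several 2*pi loops before it returns to its seed; theta
    is continued (``n_theta`` samples per loop, up to 8 loops) until the
    curve closes.  Each root is polished by Newton iteration so the residual
    ||r| - 1| stays below 1e-10.
    """
    if y > 0:
        raise ValueError(f"trace_boundary expects y <= 0, got {y}")
    if n_theta < 64:
        raise ValueError(f"n_theta must be >= 64, got {n_theta}")
    g = _g_coefficients(float(y))
    # np.roots expects descending powers
    base = np.array([g[4], g[3], g[2], g[1], g[0]], dtype=complex)
    dcoef = np.array([4 * g[4], 3 * g[3], 2 * g[2], g[1]], dtype=complex)
    dtheta = 2.0 * math.pi / n_theta

    def solve_at(th: float, prev: complex | None) -> complex:
        coef = base.copy()
        coef[-1] -= np.exp(1j * th)
        roots = np.roots(coef)
        if prev is None:
            pick = roots[np.argmin(np.abs(roots))]
        else:
            pick = roots[np.argmin(np.abs(roots - prev))]
            if abs(pick - prev) > 0.25 * (1.0 + abs(prev)):
                raise RuntimeError(
                    f"stability-boundary branch jump at theta={th:.4f} "
                    f"(|dx|={abs(pick - prev):.3g})"
                )
        for _ in range(3):  # Newton polish
            df = np.polyval(dcoef, pick)
            if df == 0:
                break
            pick = pick - np.polyval(coef, pick) / df
        return pick

    thetas = [0.0]
    xs = [solve_at(0.0, None)]
    max_steps = 8 * n_theta
    for i in range(1, max_steps + 1):
        th = i * dtheta
        pick = solve_at(th, xs[-1])
        thetas.append(th)
        xs.append(pick)
        if i >= n_theta and i % n_theta == 0 and abs(pick - xs[0]) < 1e-8:
            break
    else:
        raise RuntimeError(
            f"stability boundary at y={y} did not close within 8 loops"
        )
    return StabilityCurve(y=float(y), theta=np.asarray(thetas), x=np.asarray(xs))
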