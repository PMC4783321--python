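"""Extended Kierstead-Slobodkin (KiSS) model definition and analytic limits.

The model is the reaction-diffusion equation

    u_t = D laplacian(u) + tau * u**alpha

for a population density u on a bounded patch with absorbing (homogeneous
Dirichlet) boundaries.  D is the diffusion coefficient (length^2/time), tau
the intrinsic growth rate (1/time) and alpha the critical exponent; alpha = 1
recovers the classical linear KiSS model, for which the sine-series solution
and the critical patch size pi*sqrt(D/tau) are available in closed form.
These analytic limits serve as oracles for the numerical machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.special import erf

__all__ = [
    "KissModel",
    "InitialCondition",
    "AnalyticLinearSolution",
    "fourier_sine_coefficients",
    "linear_kiss_series",
    "critical_length",
    "heat_kernel_solution",
    "step_front_solution",
    "catalog_ic",
    "load_ic_file",
    "CATALOG",
]


@dataclass(frozen=True)
class KissModel:
    """The physics triple (D, tau, alpha).

    Parameters
    ----------
    D : float
        Diffusion coefficient, length^2/time.  Strictly positive.
    tau : float
        Growth rate, 1/time.  Non-negative; tau = 0 is pure diffusion.
    alpha : float
        Critical exponent of the growth term tau*u**alpha.  Strictly
        positive; alpha = 1 is the linear model.
    """

    D: float
    tau: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValueError(f"diffusion coefficient D must be > 0, got {self.D}")
        if self.tau < 0:
            raise ValueError(f"growth rate tau must be >= 0, got {self.tau}")
        if not (self.alpha > 0):
            raise ValueError(f"critical exponent alpha must be > 0, got {self.alpha}")


def critical_length(model: KissModel) -> float:
    """Critical patch size l* = pi*sqrt(D/tau) of the linear (alpha=1) model.

    On a Dirichlet patch of length l the slowest sine mode grows like
    exp[(tau - D pi^2/l^2) t]; it decays for l < l* and grows for l > l*,
    so l* is the minimal domain on which the population persists.

    Raises
    ------
    ValueError
        If tau == 0 (pure diffusion always decays; no finite threshold).
    """
    if model.tau == 0:
        raise ValueError("critical length undefined for tau = 0 (no growth)")
    return math.pi * math.sqrt(model.D / model.tau)


# ---------------------------------------------------------------------------
# linear-model sine series
# ---------------------------------------------------------------------------


def fourier_sine_coefficients(
    u0: Callable[[np.ndarray], np.ndarray],
    l: float,
    M: int,
    n_quad: int = 2049,
) -> np.ndarray:
    """Sine-series coefficients a_n = (2/l) * int_0^l u0(x) sin(n pi x / l) dx.

    Quadrature is composite Simpson on ``n_quad`` uniformly spaced points
    (refinable; the default resolves smooth catalog inputs to ~1e-10).

    Returns an array ``a`` with ``a[n-1]`` the coefficient of sin(n pi x/l),
    n = 1..M.
    """
    if l <= 0:
        raise ValueError(f"interval length l must be > 0, got {l}")
    if M < 1:
        raise ValueError(f"truncation order M must be >= 1, got {M}")
    if n_quad < 5:
        raise ValueError("n_quad must be >= 5")
    x = np.linspace(0.0, l, n_quad)
    vals = np.asarray(u0(x), dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"initial condition evaluates non-finite at node x={x[i]!r} (index {i})"
        )
    n = np.arange(1, M + 1)
    # integrand matrix (M, n_quad)
    sines = np.sin(np.outer(n, x) * (math.pi / l))
    return (2.0 / l) * simpson(sines * vals, x=x, axis=1)


@dataclass(frozen=True)
class AnalyticLinearSolution:
    """Truncated sine-series solution of the linear KiSS model on [0, l].

    u(x, t) = sum_{n=1}^{M} a_n sin(n pi x / l) exp[(tau - D n^2 pi^2 / l^2) t]

    Note the growth exponent carries the diffusion coefficient D: this is the
    only form consistent with the threshold l ≷ pi*sqrt(D/tau).
    """

    coefficients: np.ndarray
    model: KissModel
    l: float

    def __post_init__(self) -> None:
        a = np.asarray(self.coefficients, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("coefficients must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(a)):
            raise ValueError("coefficients must be finite")
        if self.l <= 0:
            raise ValueError(f"l must be > 0, got {self.l}")
        object.__setattr__(self, "coefficients", a)

    @property
    def M(self) -> int:
        return self.coefficients.size

    def growth_exponents(self) -> np.ndarray:
        """Per-mode rates tau - D n^2 pi^2 / l^2, n = 1..M."""
        n = np.arange(1, self.M + 1)
        return self.model.tau - self.model.D * (n * math.pi / self.l) ** 2

    @classmethod
    def from_ic(
        cls,
        u0: Callable[[np.ndarray], np.ndarray],
        model: KissModel,
        l: float,
        M: int = 64,
        n_quad: int = 2049,
    ) -> "AnalyticLinearSolution":
        a = fourier_sine_coefficients(u0, l, M, n_quad=n_quad)
        return cls(coefficients=a, model=model, l=l)


def linear_kiss_series(
    x: np.ndarray | float, t: float, sol: AnalyticLinearSolution
) -> np.ndarray | float:
    """Evaluate the truncated linear-model series at positions x and time t."""
    if t < 0:
        raise ValueError(f"time t must be >= 0, got {t}")
    xa = np.asarray(x, dtype=float)
    n = np.arange(1, sol.M + 1)
    modes = np.sin(np.multiply.outer(xa, n) * (math.pi / sol.l))
    amps = sol.coefficients * np.exp(sol.growth_exponents() * t)
    out = modes @ amps
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# diffusion-only (tau = 0) closed forms
# ---------------------------------------------------------------------------


def heat_kernel_solution(
    x: np.ndarray | float, t: float, D: float
) -> np.ndarray | float:
    """Free-space heat kernel exp(-x^2/(4 D t)) / sqrt(4 pi D t).

    Solution of u_t = D u_xx from a unit point release at the origin; the
    peak height decays as 1/sqrt(4 pi D t) and total mass stays 1.
    """
    if t <= 0:
        raise ValueError(f"heat kernel requires t > 0, got {t}")
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    xa = np.asarray(x, dtype=float)
    out = np.exp(-(xa**2) / (4.0 * D * t)) / math.sqrt(4.0 * math.pi * D * t)
    return float(out) if np.isscalar(x) else out


def step_front_solution(
    x: np.ndarray | float, t: float, D: float, l: float = math.inf
) -> np.ndarray | float:
    """Diffusing front (1/sqrt(pi)) * int_{x/sqrt(4Dt)}^{l} exp(-xi^2) d xi.

    Solution of pure diffusion from a unit step of material initially
    occupying x < 0; evaluated through the error function.  ``l`` is the
    upper limit of the similarity integral (``inf`` gives the classical
    complementary-error-function front).
    """
    if t <= 0:
        raise ValueError(f"step front requires t > 0, got {t}")
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    xa = np.asarray(x, dtype=float)
    lo = xa / math.sqrt(4.0 * D * t)
    hi = 1.0 if math.isinf(l) else erf(l)
    out = 0.5 * (hi - erf(lo))
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# initial-condition catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InitialCondition:
    """A named initial density profile.

    ``evaluator`` maps grid coordinates to density values: for 1-D it is
    called as f(x); for 2-D as f(x, y) with broadcastable arrays.  ``dim``
    is 1, 2, or 0 meaning either (dimension-agnostic formulas).
    """

    name: str
    evaluator: Callable[..., np.ndarray]
    params: dict = field(default_factory=dict)
    dim: int = 0

    def __call__(self, *coords: np.ndarray) -> np.ndarray:
        if self.dim and len(coords) != self.dim:
            raise ValueError(
                f"initial condition {self.name!r} is {self.dim}-D, "
                f"got {len(coords)} coordinate arrays"
            )
        return np.asarray(self.evaluator(*coords), dtype=float)

    @classmethod
    def from_callable(
        cls, f: Callable[..., np.ndarray], name: str = "custom", dim: int = 0
    ) -> "InitialCondition":
        return cls(name=name, evaluator=f, dim=dim)


def _radial(x, y):
    return np.sqrt(np.asarray(x, dtype=float) ** 2 + np.asarray(y, dtype=float) ** 2)


def _make_sin2pix(params):
    return InitialCondition("sin2pix", lambda x: np.sin(2.0 * math.pi * x), params, dim=1)


def _make_sinc_radial(params):
    # sinc(sqrt((x/pi)^2+(y/pi)^2)) with sinc(z) = sin(pi z)/(pi z)
    # simplifies to sin(r)/r, r = sqrt(x^2+y^2); value 1 at the origin.
    def f(x, y):
        r = _radial(x, y)
        return np.sinc(r / math.pi)

    return InitialCondition("sinc_radial", f, params, dim=2)


def _make_coscos_exp(params):
    def f(x, y):
        return np.cos(x) * np.cos(y) * np.exp(-_radial(x, y) / 4.0)

    return InitialCondition("coscos_exp", f, params, dim=2)


def _make_exp_trig_sum(params):
    c = math.exp(0.1)

    def f(x, y):
        return c * (np.cos(x) + np.sin(y))

    return InitialCondition("exp_trig_sum", f, params, dim=2)


def _make_sin_radial(params):
    def f(x, y):
        return np.sin(_radial(x, y) / math.pi)

    return InitialCondition("sin_radial", f, params, dim=2)


def _make_gaussian_bump(params):
    amp = float(params.get("amp", 1.0))
    sigma = float(params.get("sigma", 1.0))
    center = params.get("center", 0.0)
    if sigma <= 0:
        raise ValueError("gaussian_bump requires sigma > 0")

    def f(*coords):
        if len(coords) == 1:
            d2 = (np.asarray(coords[0], dtype=float) - center) ** 2
        else:
            cx, cy = (center, center) if np.isscalar(center) else center
            d2 = (np.asarray(coords[0], float) - cx) ** 2 + (
                np.asarray(coords[1], float) - cy
            ) ** 2
        return amp * np.exp(-d2 / (2.0 * sigma**2))

    return InitialCondition("gaussian_bump", f, dict(params), dim=0)


def _make_delta_like(params):
    # heat kernel already diffused for a short time t0: a sharply peaked,
    # unit-mass stand-in for a point release that the grid can resolve.
    t0 = float(params.get("t0", 0.01))
    D = float(params.get("D", 1.0))
    if t0 <= 0 or D <= 0:
        raise ValueError("delta_like requires t0 > 0 and D > 0")

    def f(*coords):
        if len(coords) == 1:
            return heat_kernel_solution(np.asarray(coords[0], float), t0, D)
        r2 = np.asarray(coords[0], float) ** 2 + np.asarray(coords[1], float) ** 2
        return np.exp(-r2 / (4.0 * D * t0)) / (4.0 * math.pi * D * t0)

    return InitialCondition("delta_like", f, dict(params), dim=0)


CATALOG = {
    "sin2pix": _make_sin2pix,
    "sinc_radial": _make_sinc_radial,
    "coscos_exp": _make_coscos_exp,
    "exp_trig_sum": _make_exp_trig_sum,
    "sin_radial": _make_sin_radial,
    "gaussian_bump": _make_gaussian_bump,
    "delta_like": _make_delta_like,
}


def catalog_ic(name: str, params: dict | None = None) -> InitialCondition:
    """Look up a named initial condition from the catalog.

    Catalog entries: sin2pix (1-D), sinc_radial, coscos_exp, exp_trig_sum,
    sin_radial (2-D), gaussian_bump, delta_like (either dimension, with
    parameters).
    """
    if name not in CATALOG:
        raise KeyError(
            f"unknown initial condition {name!r}; catalog: {sorted(CATALOG)}"
        )
    return CATALOG[name](params or {})


# ---------------------------------------------------------------------------
# file-based initial conditions
# ---------------------------------------------------------------------------

_IC_HEADER = "# kiss-ic v1"


def load_ic_file(path, grid=None) -> InitialCondition:
    """Read tabulated initial data: two columns (x, u) or three (x, y, u).

    The file must start with the header line ``# kiss-ic v1``.  If ``grid``
    is given, the tabulated coordinates must match the grid nodes exactly
    (within 1e-12 of the spacing).
    """
    with open(path) as fh:
        first = fh.readline().strip()
    if first != _IC_HEADER:
        raise ValueError(f"{path}: missing header {_IC_HEADER!r} (got {first!r})")
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, got shape {data.shape}")
    dim = data.shape[1] - 1
    if dim == 1:
        xs, us = data[:, 0], data[:, 1]
        order = np.argsort(xs)
        xs, us = xs[order], us[order]
        if grid is not None:
            _check_nodes(xs, grid.axes[0], path)

        def f(x):
            return np.interp(np.asarray(x, float), xs, us)

        return InitialCondition(name=f"file:{path}", evaluator=f, dim=1)
    # 2-D: rows are (x, y, u) on the tensor grid
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    if xs.size * ys.size != data.shape[0]:
        raise ValueError(f"{path}: 2-D data does not form a tensor grid")
    if grid is not None:
        _check_nodes(xs, grid.axes[0], path)
        _check_nodes(ys, grid.axes[1], path)
    u = np.full((xs.size, ys.size), np.nan)
    ix = np.searchsorted(xs, data[:, 0])
    iy = np.searchsorted(ys, data[:, 1])
    u[ix, iy] = data[:, 2]
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator((xs, ys), u, bounds_error=False, fill_value=0.0)

    def f2(x, y):
        xb, yb = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float))
        pts = np.stack([xb.ravel(), yb.ravel()], axis=-1)
        return interp(pts).reshape(xb.shape)

    return InitialCondition(name=f"file:{path}", evaluator=f2, dim=2)


def _check_nodes(file_nodes: np.ndarray, grid_nodes: np.ndarray, path) -> None:
    if file_nodes.size != grid_nodes.size or not np.allclose(
        file_nodes, grid_nodes, atol=1e-12 * max(1.0, np.ptp(grid_nodes))
    ):
        raise ValueError(f"{path}: tabulated nodes do not match the grid nodes")
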