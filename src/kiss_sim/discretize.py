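"""Spatial discretization: grids and semidiscrete systems u' = Lu + F(u,t).

Two discretizations of the Laplacian are provided:

* fourth-order central differences (five-point stencil
  (-1, 16, -30, 16, -1)/(12 h^2)) with an odd-reflection Dirichlet closure,
  in 1-D as a dense operator on the interior unknowns and in 2-D as a
  Kronecker-sum tensor pair that is never materialized;
* Fourier collocation for periodic domains (diagonal symbol -D k^2) and its
  discrete-sine-transform counterpart for Dirichlet domains.

Every operator exposes a modal basis in which it is diagonal (eigenbasis for
finite differences, transform space for collocation); the exponential
integrators work entirely in that basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import scipy.fft as sfft
from scipy.linalg import eigh

from .model import InitialCondition, KissModel

__all__ = [
    "GridSpec",
    "Grid",
    "build_grid",
    "LinearOperator",
    "fd4_laplacian_1d",
    "fd4_laplacian_2d",
    "spectral_symbol",
    "sine_spectral_laplacian",
    "SemilinearSystem",
    "assemble_system",
]

BoundaryKind = Literal["dirichlet0", "periodic"]

_MIN_N = {"dirichlet0": 7, "periodic": 4}


@dataclass(frozen=True)
class GridSpec:
    """Domain bounds, node count per axis and boundary kind.

    ``N`` counts nodes per axis *including* endpoints for Dirichlet grids.
    Periodic grids use the FFT convention: N nodes with the right endpoint
    identified with the left one, h = (hi - lo)/N.
    """

    dim: int
    lo: float
    hi: float
    N: int
    bc: BoundaryKind = "dirichlet0"

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError(f"dim must be 1 or 2, got {self.dim}")
        if not self.hi > self.lo:
            raise ValueError(f"need hi > lo, got [{self.lo}, {self.hi}]")
        if self.bc not in _MIN_N:
            raise ValueError(f"unknown bc {self.bc!r}; use dirichlet0 or periodic")
        if self.N < _MIN_N[self.bc]:
            raise ValueError(
                f"N={self.N} too small for bc={self.bc!r}: the five-point FD4 "
                f"stencil needs N >= {_MIN_N['dirichlet0']} for dirichlet0; "
                f"periodic needs N >= {_MIN_N['periodic']}"
            )


@dataclass(frozen=True)
class Grid:
    """Realized grid: node coordinates per axis plus spacing."""

    spec: GridSpec
    axes: tuple[np.ndarray, ...]
    h: float

    @property
    def dim(self) -> int:
        return self.spec.dim

    @property
    def bc(self) -> str:
        return self.spec.bc

    def interior_axes(self) -> tuple[np.ndarray, ...]:
        """Coordinates of the unknowns: interior nodes for Dirichlet, all
        nodes for periodic."""
        if self.bc == "dirichlet0":
            return tuple(ax[1:-1] for ax in self.axes)
        return self.axes

    def meshgrid(self, interior: bool = False) -> tuple[np.ndarray, ...]:
        axes = self.interior_axes() if interior else self.axes
        if self.dim == 1:
            return (axes[0],)
        return tuple(np.meshgrid(axes[0], axes[1], indexing="ij"))

    def evaluate_ic(self, ic: InitialCondition | Callable) -> np.ndarray:
        """Sample an initial condition on the unknown nodes."""
        return np.asarray(ic(*self.meshgrid(interior=True)), dtype=float)


def build_grid(spec: GridSpec) -> Grid:
    """Build the grid for a spec.

    Dirichlet: x_i = lo + i h, i = 0..N-1, h = (hi-lo)/(N-1), endpoints
    included (and held at zero).  Periodic: h = (hi-lo)/N, nodes 0..N-1,
    the right endpoint omitted.  2-D grids are tensor products of the same
    1-D rule on each axis.
    """
    if spec.bc == "dirichlet0":
        h = (spec.hi - spec.lo) / (spec.N - 1)
        ax = spec.lo + h * np.arange(spec.N)
    else:
        h = (spec.hi - spec.lo) / spec.N
        ax = spec.lo + h * np.arange(spec.N)
    axes = (ax,) * spec.dim
    return Grid(spec=spec, axes=axes, h=h)


# ---------------------------------------------------------------------------
# linear operators with a diagonalizing modal basis
# ---------------------------------------------------------------------------


class LinearOperator:
    """A spatial operator D*Laplacian together with a modal basis in which
    it acts diagonally.

    Attributes
    ----------
    eigenvalues : ndarray
        The modal spectrum, same shape as a modal state.  All entries are
        real and <= 0 for the diffusion operators built here (plus tau on
        no axis -- growth enters through the nonlinear term).
    """

    eigenvalues: np.ndarray
    shape: tuple[int, ...]

    def to_modal(self, u: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def from_modal(self, m: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def apply(self, u: np.ndarray) -> np.ndarray:
        """Apply the operator to a physical-space state."""
        return self.from_modal(self.eigenvalues * self.to_modal(u))


class DiagonalOperator(LinearOperator):
    """Operator already diagonal in physical space (e.g. scalar tests)."""

    def __init__(self, eigenvalues: np.ndarray):
        self.eigenvalues = np.asarray(eigenvalues, dtype=float)
        self.shape = self.eigenvalues.shape

    def to_modal(self, u):
        return np.asarray(u)

    def from_modal(self, m):
        return np.asarray(m)


def _fd4_dirichlet_matrix(n_interior: int, h: float) -> np.ndarray:
    """Dense FD4 Laplacian on interior unknowns with odd-reflection ghosts.

    Endpoints are held at zero and excluded; ghost values outside the wall
    are the odd reflection of the interior (u_{-1} = -u_1), which keeps
    fourth-order accuracy for profiles vanishing at the wall.
    """
    if n_interior < 5:
        raise ValueError("need at least 5 interior nodes for the FD4 stencil")
    w = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / (12.0 * h * h)
    A = np.zeros((n_interior, n_interior))
    # interior index i is grid node i+1; nodes 0 and n_interior+1 are the
    # walls (pinned to 0); nodes -1 and n_interior+2 are ghosts, filled by
    # odd reflection through the wall: v_{-1} = -v_1, v_{N} = -v_{N-2}.
    for i in range(n_interior):
        for off, wt in zip(range(-2, 3), w):
            j = i + off  # interior index of the touched node
            if 0 <= j < n_interior:
                A[i, j] += wt
            elif j == -2:
                A[i, 0] -= wt  # ghost mirrors the first interior node
            elif j == n_interior + 1:
                A[i, n_interior - 1] -= wt
            # j == -1 / n_interior: wall nodes, value 0
    return A


class Fd4Dirichlet1D(LinearOperator):
    """Dense FD4 operator on the interior unknowns of a 1-D Dirichlet grid,
    diagonalized once by a symmetric eigendecomposition."""

    def __init__(self, grid: Grid, scale: float = 1.0):
        if grid.bc != "dirichlet0" or grid.dim != 1:
            raise ValueError("Fd4Dirichlet1D requires a 1-D dirichlet0 grid")
        self.grid = grid
        self.h = grid.h
        self.scale = scale
        self.matrix = scale * _fd4_dirichlet_matrix(grid.spec.N - 2, grid.h)
        w, V = eigh(self.matrix)
        self.eigenvalues = w
        self._V = V
        self.shape = (grid.spec.N - 2,)

    def to_modal(self, u):
        return self._V.T @ u

    def from_modal(self, m):
        return self._V @ m

    def apply(self, u):
        return self.matrix @ u


class Fd4Dirichlet2D(LinearOperator):
    """Kronecker sum A (x) I + I (x) B of per-axis FD4 operators.

    States are (Nx-2, Ny-2) arrays; the full N^2 x N^2 matrix is never
    formed.  Modal transforms apply the per-axis eigenvector matrices on
    each index.
    """

    def __init__(self, grid: Grid, scale: float = 1.0):
        if grid.bc != "dirichlet0" or grid.dim != 2:
            raise ValueError("Fd4Dirichlet2D requires a 2-D dirichlet0 grid")
        self.grid = grid
        self.h = grid.h
        self.scale = scale
        n = grid.spec.N - 2
        self.ax_matrix = scale * _fd4_dirichlet_matrix(n, grid.h)
        w, V = eigh(self.ax_matrix)
        self._w = w
        self._V = V
        self.eigenvalues = w[:, None] + w[None, :]
        self.shape = (n, n)

    def to_modal(self, u):
        return self._V.T @ u @ self._V

    def from_modal(self, m):
        return self._V @ m @ self._V.T

    def apply(self, u):
        return self.ax_matrix @ u + u @ self.ax_matrix.T


class Spectral1D(LinearOperator):
    """Fourier collocation Laplacian -D k^2 on a periodic 1-D grid."""

    def __init__(self, grid: Grid, scale: float = 1.0):
        if grid.bc != "periodic" or grid.dim != 1:
            raise ValueError("Spectral1D requires a 1-D periodic grid")
        self.grid = grid
        self.h = grid.h
        self.scale = scale
        N = grid.spec.N
        L = grid.spec.hi - grid.spec.lo
        k = 2.0 * math.pi * sfft.fftfreq(N, d=L / N)
        self.eigenvalues = -scale * k**2
        self.shape = (N,)

    def to_modal(self, u):
        return sfft.fft(u)

    def from_modal(self, m):
        return sfft.ifft(m).real


class Spectral2D(LinearOperator):
    """Fourier collocation Laplacian on a periodic 2-D tensor grid."""

    def __init__(self, grid: Grid, scale: float = 1.0):
        if grid.bc != "periodic" or grid.dim != 2:
            raise ValueError("Spectral2D requires a 2-D periodic grid")
        self.grid = grid
        self.h = grid.h
        self.scale = scale
        N = grid.spec.N
        L = grid.spec.hi - grid.spec.lo
        k = 2.0 * math.pi * sfft.fftfreq(N, d=L / N)
        self.eigenvalues = -scale * (k[:, None] ** 2 + k[None, :] ** 2)
        self.shape = (N, N)

    def to_modal(self, u):
        return sfft.fft2(u)

    def from_modal(self, m):
        return sfft.ifft2(m).real


class SineSpectral(LinearOperator):
    """Sine-collocation Laplacian for Dirichlet problems (odd periodic
    extension via DST-I); exact continuous symbol -D (n pi / L)^2."""

    def __init__(self, grid: Grid, scale: float = 1.0):
        if grid.bc != "dirichlet0":
            raise ValueError("SineSpectral requires a dirichlet0 grid")
        self.grid = grid
        self.h = grid.h
        self.scale = scale
        n_int = grid.spec.N - 2
        L = grid.spec.hi - grid.spec.lo
        k = math.pi * np.arange(1, n_int + 1) / L
        lam = -scale * k**2
        self._dim = grid.dim
        if grid.dim == 1:
            self.eigenvalues = lam
            self.shape = (n_int,)
        else:
            self.eigenvalues = lam[:, None] + lam[None, :]
            self.shape = (n_int, n_int)

    def to_modal(self, u):
        if self._dim == 1:
            return sfft.dst(u, type=1, norm="ortho")
        return sfft.dstn(u, type=1, norm="ortho")

    def from_modal(self, m):
        if self._dim == 1:
            return sfft.idst(m, type=1, norm="ortho")
        return sfft.idstn(m, type=1, norm="ortho")


def fd4_laplacian_1d(grid: Grid, scale: float = 1.0) -> LinearOperator:
    """FD4 Laplacian (times ``scale``) on a 1-D grid; dense on interior
    unknowns for Dirichlet, circulant (applied spectrally exactly) is not
    offered here -- periodic grids use :func:`spectral_symbol`."""
    if grid.bc == "periodic":
        return _Fd4Periodic1D(grid, scale)
    return Fd4Dirichlet1D(grid, scale)


class _Fd4Periodic1D(LinearOperator):
    """Cyclic FD4 stencil on a periodic grid, diagonal in Fourier space."""

    def __init__(self, grid: Grid, scale: float = 1.0):
        self.grid = grid
        self.h = grid.h
        self.scale = scale
        N = grid.spec.N
        theta = 2.0 * math.pi * np.arange(N) / N
        # symbol of (-1,16,-30,16,-1)/(12h^2)
        self.eigenvalues = (
            scale
            * (-30.0 + 32.0 * np.cos(theta) - 2.0 * np.cos(2.0 * theta))
            / (12.0 * grid.h**2)
        )
        self.shape = (N,)

    def to_modal(self, u):
        return sfft.fft(u)

    def from_modal(self, m):
        return sfft.ifft(m).real


def fd4_laplacian_2d(grid: Grid, scale: float = 1.0) -> LinearOperator:
    """Tensor (Kronecker-sum) FD4 Laplacian on a 2-D Dirichlet grid."""
    if grid.dim != 2:
        raise ValueError("fd4_laplacian_2d requires a 2-D grid")
    if grid.bc != "dirichlet0":
        raise ValueError("2-D FD4 is built for dirichlet0; use spectral_symbol "
                         "for periodic grids")
    return Fd4Dirichlet2D(grid, scale)


def spectral_symbol(grid: Grid, scale: float = 1.0) -> LinearOperator:
    """Diagonal Fourier symbol -D k^2 of the Laplacian on a periodic grid."""
    if grid.bc != "periodic":
        raise ValueError(
            "spectral_symbol requires periodic bc; for dirichlet0 use the "
            "sine-transform option (sine_spectral_laplacian)"
        )
    return Spectral1D(grid, scale) if grid.dim == 1 else Spectral2D(grid, scale)


def sine_spectral_laplacian(grid: Grid, scale: float = 1.0) -> LinearOperator:
    """Sine-collocation Laplacian for Dirichlet grids (odd extension)."""
    return SineSpectral(grid, scale)


# ---------------------------------------------------------------------------
# semilinear system
# ---------------------------------------------------------------------------


@dataclass
class SemilinearSystem:
    """The split system u' = L u + F(u, t) after spatial discretization.

    ``L`` carries the diffusion; ``F`` is evaluated nodewise in physical
    space (for transform-based operators the integrator moves states
    between modal and physical space around each F evaluation).
    """

    L: LinearOperator
    F: Callable[[np.ndarray, float], np.ndarray]
    grid: Grid | None = None
    model: KissModel | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.L.shape


def _power_nonlinearity(model: KissModel) -> Callable[[np.ndarray, float], np.ndarray]:
    tau, alpha = model.tau, model.alpha
    if tau == 0.0:
        return lambda u, t: np.zeros_like(u)
    if alpha == 1.0:
        return lambda u, t: tau * u
    if float(alpha).is_integer():
        a = int(alpha)
        return lambda u, t: tau * u**a
    # non-integer power of a possibly negative density: keep arithmetic real
    # with the odd extension sign(u)|u|^alpha
    return lambda u, t: tau * np.sign(u) * np.abs(u) ** alpha


def assemble_system(
    model: KissModel,
    grid: Grid,
    disc: Literal["fd4", "spectral"] = "fd4",
) -> SemilinearSystem:
    """Build u' = L u + F(u,t) with L = D*Laplacian and F(u) = tau*u^alpha.

    Pairings: fd4 works on dirichlet0 grids (1-D dense / 2-D tensor) and
    periodic 1-D grids; spectral uses the Fourier symbol on periodic grids
    and the sine transform on dirichlet0 grids.
    """
    if disc == "fd4":
        if grid.dim == 1:
            L = fd4_laplacian_1d(grid, scale=model.D)
        else:
            L = fd4_laplacian_2d(grid, scale=model.D)
    elif disc == "spectral":
        if grid.bc == "periodic":
            L = spectral_symbol(grid, scale=model.D)
        else:
            L = sine_spectral_laplacian(grid, scale=model.D)
    else:
        raise ValueError(f"unknown discretization {disc!r}; use fd4 or spectral")
    return SemilinearSystem(
        L=L,
        F=_power_nonlinearity(model),
        grid=grid,
        model=model,
        meta={"disc": disc, "bc": grid.bc, "grid_rule": "endpoints" if grid.bc == "dirichlet0" else "fft"},
    )
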