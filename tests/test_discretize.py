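"""Grids, FD4/spectral Laplacians and semidiscrete system assembly."""

import math

import numpy as np
import pytest

from kiss_sim import KissModel
from kiss_sim.discretize import (
    GridSpec,
    assemble_system,
    build_grid,
    fd4_laplacian_1d,
    fd4_laplacian_2d,
    sine_spectral_laplacian,
    spectral_symbol,
)
from kiss_sim.etd import etdrk4_coefficients, etdrk4_step


def brute_force_fd4(N: int, h: float) -> np.ndarray:
    """Independent dense construction in grid-node space: loop the stencil
    over nodes 1..N-2, pin the walls (nodes 0, N-1) to zero, and fill the
    ghosts by odd reflection: v[-1] = -v[1], v[N] = -v[N-2]."""
    n = N - 2
    A = np.zeros((n, n))
    w = [-1.0, 16.0, -30.0, 16.0, -1.0]
    for node in range(1, N - 1):
        for off, wt in zip(range(-2, 3), w):
            nb = node + off
            if nb == -1:
                A[node - 1, 0] -= wt
            elif nb == N:
                A[node - 1, n - 1] -= wt
            elif nb in (0, N - 1):
                continue  # wall value 0
            else:
                A[node - 1, nb - 1] += wt
    return A / (12.0 * h * h)


class TestBuildGrid:
    def test_dirichlet_convention(self):
        g = build_grid(GridSpec(dim=1, lo=-1.0, hi=1.0, N=201))
        assert g.h == pytest.approx(0.01)
        assert g.axes[0][0] == -1.0 and g.axes[0][-1] == pytest.approx(1.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="N >= 7"):
            GridSpec(dim=1, lo=0.0, hi=1.0, N=5)

    def test_2d_tensor(self):
        g = build_grid(GridSpec(dim=2, lo=-10.0, hi=10.0, N=101))
        assert g.h == pytest.approx(0.2)
        assert g.axes[0].size == g.axes[1].size == 101

    def test_periodic_uses_fft_convention(self):
        g = build_grid(GridSpec(dim=1, lo=-math.pi, hi=math.pi, N=64, bc="periodic"))
        assert g.h == pytest.approx(2 * math.pi / 64)
        assert g.axes[0][-1] == pytest.approx(math.pi - g.h)


class TestFd4Dirichlet:
    def test_exact_on_quadratic_deep_interior(self, grid1d):
        L = fd4_laplacian_1d(grid1d)
        x = grid1d.interior_axes()[0]
        out = L.apply(x**2)
        # rows >= 2 away from each wall see the pure stencil
        np.testing.assert_allclose(out[2:-2], 2.0, rtol=1e-11)

    def test_interior_stencil_rows_sum_to_zero(self, grid1d):
        L = fd4_laplacian_1d(grid1d)
        rows = L.matrix[2:-2].sum(axis=1)
        np.testing.assert_allclose(rows, 0.0, atol=1e-9 / grid1d.h**2)

    def test_fourth_order_convergence_on_sine(self):
        errs = []
        for N in (101, 201):
            g = build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=N))
            x = g.interior_axes()[0]
            L = fd4_laplacian_1d(g)
            err = np.abs(L.apply(np.sin(math.pi * x)) + math.pi**2 * np.sin(math.pi * x))
            errs.append(err.max())
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0  # ~16x per halving of h

    @pytest.mark.parametrize("N", [11, 21, 51])
    def test_matches_brute_force_construction(self, N):
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=N))
        L = fd4_laplacian_1d(g)
        np.testing.assert_allclose(L.matrix, brute_force_fd4(N, g.h), rtol=1e-13)

    def test_eigenvalues_real_negative(self):
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=21))
        L = fd4_laplacian_1d(g)
        w = np.linalg.eigvals(L.matrix)
        assert np.abs(w.imag).max() < 1e-9
        assert w.real.max() < 0


class TestFd4TwoD:
    def test_exact_on_quadratic(self, grid2d):
        L = fd4_laplacian_2d(grid2d)
        X, Y = grid2d.meshgrid(interior=True)
        out = L.apply(X**2 + Y**2)
        np.testing.assert_allclose(out[2:-2, 2:-2], 4.0, rtol=1e-10)

    def test_tensor_identity(self, grid2d):
        L = fd4_laplacian_2d(grid2d)
        x = grid2d.interior_axes()[0]
        f = np.sin(2 * x)
        g = np.cos(x) * x
        U = np.outer(f, g)
        A = L.ax_matrix
        expected = np.outer(A @ f, g) + np.outer(f, A @ g)
        np.testing.assert_allclose(L.apply(U), expected, rtol=1e-12, atol=1e-9)

    def test_kronecker_eigen_consistency(self, grid2d):
        # modal action on a product eigenvector = summed axis eigenvalues
        L = fd4_laplacian_2d(grid2d)
        i, j = 3, 5
        u = np.outer(L._V[:, i], L._V[:, j])
        np.testing.assert_allclose(
            L.apply(u), (L._w[i] + L._w[j]) * u, atol=1e-9
        )

    def test_mixed_bc_unsupported(self):
        g = build_grid(GridSpec(dim=2, lo=0.0, hi=1.0, N=16, bc="periodic"))
        with pytest.raises(ValueError, match="spectral_symbol"):
            fd4_laplacian_2d(g)


class TestSpectral:
    def test_constant_maps_to_zero(self):
        g = build_grid(GridSpec(dim=1, lo=-math.pi, hi=math.pi, N=64, bc="periodic"))
        L = spectral_symbol(g)
        np.testing.assert_allclose(L.apply(np.ones(64)), 0.0, atol=1e-12)

    def test_exact_on_resolved_mode(self):
        g = build_grid(GridSpec(dim=1, lo=-math.pi, hi=math.pi, N=64, bc="periodic"))
        D = 2.5
        L = spectral_symbol(g, scale=D)
        x = g.axes[0]
        np.testing.assert_allclose(L.apply(np.sin(x)), -D * np.sin(x), atol=1e-12)

    def test_symbol_nonpositive(self):
        g = build_grid(GridSpec(dim=2, lo=0.0, hi=2.0, N=32, bc="periodic"))
        assert spectral_symbol(g).eigenvalues.max() <= 0.0

    def test_dirichlet_directed_to_sine_transform(self, grid1d):
        with pytest.raises(ValueError, match="sine-transform"):
            spectral_symbol(grid1d)

    def test_sine_spectral_eigenmode(self, grid1d):
        L = sine_spectral_laplacian(grid1d, scale=1.0)
        x = grid1d.interior_axes()[0]
        u = np.sin(3 * math.pi * x)
        np.testing.assert_allclose(L.apply(u), -9 * math.pi**2 * u, rtol=1e-10)


class TestAssemble:
    def test_nonlinearity_vanishes_at_zero(self, grid1d):
        sys_ = assemble_system(KissModel(D=1.0, tau=0.5, alpha=2.0), grid1d)
        u = np.zeros(grid1d.spec.N - 2)
        np.testing.assert_array_equal(sys_.F(u, 0.0), 0.0)

    def test_tau_zero_is_pure_diffusion(self, grid1d):
        sys_ = assemble_system(KissModel(D=1.0, tau=0.0), grid1d)
        u = np.linspace(-1, 1, grid1d.spec.N - 2)
        np.testing.assert_array_equal(sys_.F(u, 0.0), 0.0)

    def test_alpha_one_linear_slope(self, grid1d):
        sys_ = assemble_system(KissModel(D=1.0, tau=0.7), grid1d)
        u = np.linspace(-1, 1, grid1d.spec.N - 2)
        np.testing.assert_allclose(sys_.F(u, 0.0), 0.7 * u)

    def test_noninteger_alpha_stays_real_on_negative_values(self, grid1d):
        sys_ = assemble_system(KissModel(D=1.0, tau=1.0, alpha=1.5), grid1d)
        out = sys_.F(np.array([-4.0, 0.0, 4.0]), 0.0)
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, [-8.0, 0.0, 8.0])

    def test_one_step_reproduces_linear_growth_factor(self):
        # alpha = 1 single sine mode with the sine-spectral operator: the
        # mode is an exact eigenvector, so one ETDRK4 step must match
        # exp[(tau - D pi^2/l^2) h] to the scheme's O(h^5) accuracy.
        model = KissModel(D=1.0, tau=1.0, alpha=1.0)
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=65))
        sys_ = assemble_system(model, g, disc="spectral")
        x = g.interior_axes()[0]
        u = np.sin(math.pi * x)
        h = 0.01
        coeffs = etdrk4_coefficients(sys_.L, h)
        u1 = sys_.L.from_modal(
            etdrk4_step(sys_, sys_.L.to_modal(u), 0.0, h, coeffs)
        )
        factor = math.exp((1.0 - math.pi**2) * h)
        np.testing.assert_allclose(u1, factor * u, rtol=1e-8)

    def test_unknown_disc_rejected(self, grid1d):
        with pytest.raises(ValueError, match="fd4 or spectral"):
            assemble_system(KissModel(D=1.0, tau=1.0), grid1d, disc="fem")
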