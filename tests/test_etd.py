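"""Exponential integrators: phi weights, ETDRK4, multistep comparators."""

import math

import numpy as np
import pytest

from kiss_sim import KissModel, critical_length
from kiss_sim.discretize import (
    DiagonalOperator,
    GridSpec,
    SemilinearSystem,
    assemble_system,
    build_grid,
)
from kiss_sim.etd import (
    SCHEMES,
    etd_multistep_step,
    etdrk4_coefficients,
    etdrk4_step,
    integrate,
    multistep_state,
    phi_functions,
    phi_weights,
)


def scalar_square_system() -> SemilinearSystem:
    """u' = u^2 (L = 0), u0 = 1, exact u(t) = 1/(1-t)."""
    return SemilinearSystem(L=DiagonalOperator(np.zeros(1)), F=lambda u, t: u**2)


class TestPhiWeights:
    def test_limits_at_zero_without_division(self):
        E, E2, Q, Wu, Wab, Wc = phi_weights(0.0, h=2.0)
        assert (E, E2) == (1.0, 1.0)
        assert Q == pytest.approx(1.0)  # h/2
        for w in (Wu, Wab, Wc):
            assert w == pytest.approx(2.0 / 6.0, rel=1e-14)

    def test_contour_and_direct_branches_agree(self):
        # z = -10 is far outside the contour region; force both branches
        direct = phi_weights(-10.0, h=1.0, cutoff=0.5)
        contoured = phi_weights(-10.0, h=1.0, cutoff=20.0)
        for d, c in zip(direct, contoured):
            assert c == pytest.approx(d, rel=1e-12)

    def test_matches_extended_precision_series(self):
        # mpmath (50 digits) as the independent oracle on |z| <= 1
        import mpmath as mp

        mp.mp.dps = 50
        for z in (-1.0, -0.3, 0.2, 1.0, -0.05):
            zm = mp.mpf(z)
            ez = mp.e**zm
            q = float(((mp.e ** (zm / 2)) - 1) / zm)
            b1 = float((-4 - zm + ez * (4 - 3 * zm + zm**2)) / zm**3)
            b2 = float((2 + zm + ez * (-2 + zm)) / zm**3)
            b3 = float((-4 - 3 * zm - zm**2 + ez * (4 - zm)) / zm**3)
            E, E2, Q, Wu, Wab, Wc = phi_weights(z, h=1.0)
            assert Q == pytest.approx(q, rel=1e-12)
            assert Wu == pytest.approx(b1, rel=1e-12)
            assert Wab == pytest.approx(b2, rel=1e-12)
            assert Wc == pytest.approx(b3, rel=1e-12)

    def test_phi_functions_series_oracle(self):
        import mpmath as mp

        mp.mp.dps = 50
        z = np.array([-0.2, -1.5, -8.0, 0.3])
        got = phi_functions(z, 6)
        for j, zj in enumerate(z):
            acc = mp.e ** mp.mpf(zj)
            for k in range(1, 7):
                acc = (acc - 1 / mp.factorial(k - 1)) / mp.mpf(zj)
                assert got[k - 1, j] == pytest.approx(float(acc), rel=1e-11)


class TestEtdrk4Coefficients:
    def test_scalar_zero_operator(self):
        c = etdrk4_coefficients(DiagonalOperator(np.zeros(3)), h=0.5)
        np.testing.assert_allclose(c.E, 1.0)
        np.testing.assert_allclose(c.Q, 0.25)
        np.testing.assert_allclose(c.W_u, 0.5 / 6.0)

    def test_scalar_bracket_value(self):
        # L = -1, h = 1: W_u = [-4-(-1)+e^{-1}(4+3+1)]/(-1)^3 = 3 - 8/e
        c = etdrk4_coefficients(DiagonalOperator(np.array([-1.0])), h=1.0)
        assert c.W_u[0] == pytest.approx(3.0 - 8.0 / math.e, rel=1e-13)

    def test_tensor_weights_match_summed_eigenvalues(self):
        g = build_grid(GridSpec(dim=2, lo=0.0, hi=1.0, N=9))
        sys_ = assemble_system(KissModel(D=1.0, tau=0.0), g)
        L = sys_.L
        h = 0.01
        c = etdrk4_coefficients(L, h)
        i, j = 2, 4
        lam = L._w[i] + L._w[j]
        _, _, _, Wu, _, _ = phi_weights(h * lam, h=h)
        assert c.W_u[i, j] == pytest.approx(Wu, rel=1e-12)

    def test_rejects_nonpositive_step(self):
        with pytest.raises(ValueError, match="h must be > 0"):
            etdrk4_coefficients(DiagonalOperator(np.zeros(1)), h=0.0)


class TestEtdrk4Step:
    def test_pure_linear_is_exact_exponential(self):
        lam = np.array([-3.0, -1.0, -0.25])
        L = DiagonalOperator(lam)
        sys_ = SemilinearSystem(L=L, F=lambda u, t: np.zeros_like(u))
        h = 0.37
        c = etdrk4_coefficients(L, h)
        u = np.array([1.0, 2.0, -1.5])
        u1 = etdrk4_step(sys_, u, 0.0, h, c)
        np.testing.assert_allclose(u1, np.exp(lam * h) * u, rtol=1e-14)

    def test_matches_stability_amplification(self, rng):
        from kiss_sim.stability import amplification_factor

        n = 256
        x = -5.0 * rng.random(n)
        y = -5.0 * rng.random(n)
        L = DiagonalOperator(y)  # h = 1 so y = g*h directly
        sys_ = SemilinearSystem(L=L, F=lambda u, t: x * u)
        c = etdrk4_coefficients(L, h=1.0)
        got = etdrk4_step(sys_, np.ones(n), 0.0, 1.0, c)
        np.testing.assert_allclose(got, amplification_factor(x, y), rtol=1e-13)

    def test_fourth_order_on_riccati(self):
        # u' = u^2, u(0)=1, exact 1/(1-t): global error at t=1/2 drops ~16x
        sys_ = scalar_square_system()
        errs = []
        for h in (1 / 64, 1 / 128):
            res = integrate(sys_, np.ones(1), 0.5, h)
            errs.append(abs(res.final[0] - 2.0))
        ratio = errs[0] / errs[1]
        assert 12.0 < ratio < 20.0


class TestMultistep:
    @pytest.mark.parametrize("name", ["ETDM4", "ETDM5", "ETDM6", "ETDADAMS4"])
    def test_pure_linear_is_exact(self, name):
        lam = np.array([-2.0, -0.5])
        L = DiagonalOperator(lam)
        sys_ = SemilinearSystem(L=L, F=lambda u, t: np.zeros_like(u))
        res = integrate(sys_, np.array([1.0, -1.0]), 1.0, 0.125, scheme=name)
        np.testing.assert_allclose(
            res.final, np.exp(lam) * np.array([1.0, -1.0]), rtol=1e-12
        )

    @pytest.mark.parametrize(
        "name, hs, expected_order, tol",
        [
            ("ETDM4", (1 / 64, 1 / 128, 1 / 256, 1 / 512), 4.0, 0.4),
            ("ETDADAMS4", (1 / 64, 1 / 128, 1 / 256, 1 / 512), 4.0, 0.4),
            ("ETDM5", (1 / 32, 1 / 64, 1 / 128, 1 / 256), 5.0, 0.5),
        ],
    )
    def test_measured_order_on_riccati(self, name, hs, expected_order, tol):
        sys_ = scalar_square_system()
        errs = []
        for h in hs:
            n = round(0.5 / h)
            res = integrate(sys_, np.ones(1), n * h, h, scheme=name)
            errs.append(abs(res.final[0] - 1.0 / (1.0 - n * h)))
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert order == pytest.approx(expected_order, abs=tol)

    def test_etdm6_order_on_logistic(self):
        # u' = -u + u^2, u0 = 1/2, exact u(t) = 1/(1 + e^t): the linear part
        # exercises the exponential weights; errors at h = 1/256 sit on the
        # roundoff floor, so the order is fitted over the clean range
        sys_ = SemilinearSystem(
            L=DiagonalOperator(np.array([-1.0])), F=lambda u, t: u**2
        )
        hs = (1 / 32, 1 / 64, 1 / 128)
        errs = []
        for h in hs:
            res = integrate(sys_, np.array([0.5]), 1.0, h, scheme="ETDM6")
            errs.append(abs(res.final[0] - 1.0 / (1.0 + math.e)))
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert order == pytest.approx(6.0, abs=0.5)

    def test_insufficient_history_reported(self):
        sys_ = scalar_square_system()
        st = multistep_state("ETDM4", sys_.L, 0.1)
        st.push(sys_.L.to_modal(np.ones(1)))
        with pytest.raises(ValueError, match="startup"):
            etd_multistep_step(sys_, st, np.ones(1), 0.0)


class TestIntegrate:
    def test_subcritical_patch_decays(self):
        model = KissModel(D=1.0, tau=1.0)
        l = 0.8 * critical_length(model)
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=l, N=80))
        sys_ = assemble_system(model, g)
        u0 = np.sin(math.pi * g.interior_axes()[0] / l)
        res = integrate(sys_, u0, 2.0, 0.01)
        assert np.abs(res.final).max() < np.abs(res.snapshots[0]).max()

    def test_supercritical_patch_grows(self):
        model = KissModel(D=1.0, tau=1.0)
        l = 1.3 * critical_length(model)
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=l, N=80))
        sys_ = assemble_system(model, g)
        u0 = np.sin(math.pi * g.interior_axes()[0] / l)
        res = integrate(sys_, u0, 2.0, 0.01)
        assert np.abs(res.final).max() > np.abs(res.snapshots[0]).max()

    def test_pure_diffusion_energy_decays(self):
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=60))
        sys_ = assemble_system(KissModel(D=1.0, tau=0.0), g)
        x = g.interior_axes()[0]
        ts = [round(i * 0.01, 10) for i in range(21)]
        res = integrate(sys_, x * (1 - x), 0.2, 0.01, snapshot_times=ts)
        energy = [float(np.sum(u**2)) * g.h for u in res.snapshots]
        assert all(b <= a + 1e-14 for a, b in zip(energy, energy[1:]))

    def test_blowup_detected_with_last_valid_time(self):
        sys_ = scalar_square_system()
        res = integrate(sys_, np.ones(1), 2.0, 0.01, blowup_threshold=1e6)
        assert res.blowup
        assert res.t_blowup is not None and 0.9 < res.t_blowup < 1.1

    def test_non_integral_step_count_rejected(self):
        sys_ = scalar_square_system()
        with pytest.raises(ValueError, match="integer step count"):
            integrate(sys_, np.ones(1), 1.005, 0.01)

    def test_snapshot_off_grid_rejected(self):
        sys_ = scalar_square_system()
        with pytest.raises(ValueError, match="step grid"):
            integrate(sys_, np.ones(1), 0.5, 0.01, snapshot_times=[0.015])

    def test_diagnostics_are_finite_and_aligned(self):
        g = build_grid(GridSpec(dim=1, lo=0.0, hi=1.0, N=30))
        sys_ = assemble_system(KissModel(D=0.5, tau=0.5, alpha=2.0), g)
        res = integrate(sys_, np.sin(math.pi * g.interior_axes()[0]), 0.1, 0.01)
        d = res.diagnostics
        assert list(d.columns) == ["step", "t", "mass", "min", "max"]
        assert len(d) == 11
        assert np.all(np.isfinite(d[["mass", "min", "max"]].to_numpy()))
        assert np.all(np.diff(d["t"]) > 0)
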