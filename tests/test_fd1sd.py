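"""Single-distance phase-only inversion: cost, regularizer, optimizer contract."""

import numpy as np
import pytest

from fdphase.fd1sd import (
    BoundsSpec,
    _cost_and_grad_scaled,
    derived_optics,
    edge_barrier,
    fit_fd1sd,
    phase_residual_cost,
)
from fdphase.forward_diffusion import FDContext, flux_phase
from fdphase.spectra import (
    EIGHT_WAVELENGTHS,
    TWO_WAVELENGTHS,
    ChromophoreSet,
    ScatterLaw,
    absorption_spectrum,
    scattering_spectrum,
)

TRUTH8 = np.array([60.0, 25.0, 8.5, 24.2, 1.611])


def forward_phases(table, theta, wavelengths, rho):
    c = ChromophoreSet(theta[0], theta[1], theta[2] if len(theta) == 5 else 0.0, 0.75)
    sl = ScatterLaw(theta[-2], theta[-1], 500.0)
    mu_a = absorption_spectrum(c, table, wavelengths)
    mu_s = scattering_spectrum(sl, wavelengths)
    return flux_phase(mu_a, mu_s, FDContext(110e6, 1.37, rho))


class TestEdgeBarrier:
    def test_zero_at_midpoints(self):
        b = BoundsSpec.for_mode("eight_wavelength", alpha=1.0)
        assert edge_barrier(b.center, b) == 0.0

    def test_equals_alpha_at_a_bound(self):
        b = BoundsSpec.for_mode("eight_wavelength", alpha=1.0)
        theta = b.center.copy()
        theta[0] = b.upper[0]
        assert edge_barrier(theta, b) == pytest.approx(1.0, rel=1e-14)
        theta[0] = b.lower[0]
        assert edge_barrier(theta, b) == pytest.approx(1.0, rel=1e-14)

    def test_half_width_excursion_arithmetic(self):
        """HbO bounds (30, 90): c = 60, h = 30; HbO = 75 with alpha = 2 adds 0.5."""
        b = BoundsSpec.for_mode(
            "eight_wavelength",
            alpha={"hbo": 2.0, "hb": 0.0, "cco_redox": 0.0, "a": 0.0, "b": 0.0},
        )
        theta = b.center.copy()
        theta[0] = 75.0
        assert edge_barrier(theta, b) == pytest.approx(2.0 * 0.25, rel=1e-14)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            BoundsSpec(
                names=("hbo",), lower=np.array([5.0]), upper=np.array([5.0]),
                alpha=np.array([1.0]),
            )


class TestPhaseResidualCost:
    def test_inverse_crime_cost_is_zero(self, table):
        wl = np.array(EIGHT_WAVELENGTHS)
        phases = forward_phases(table, TRUTH8, wl, 2.0)
        b = BoundsSpec.for_mode("eight_wavelength", alpha=0.0)
        cost = phase_residual_cost(
            TRUTH8, phases, FDContext(110e6, 1.37, 2.0), table, b, wl
        )
        assert cost < 1e-28

    def test_zero_measurement_cost_is_sum_of_model_phases_squared(self, table):
        wl = np.array(EIGHT_WAVELENGTHS)
        b = BoundsSpec.for_mode("eight_wavelength", alpha=0.0)
        model = forward_phases(
            table, np.concatenate([b.center[:3], b.center[3:]]), wl, 2.0
        )
        cost = phase_residual_cost(
            b.center, np.zeros(8), FDContext(110e6, 1.37, 2.0), table, b, wl
        )
        assert cost == pytest.approx(float(np.sum(model**2)), rel=1e-12)

    def test_hand_set_residuals(self, table):
        """Residuals (0.01, -0.02) rad at two wavelengths cost 5e-4."""
        wl = np.array(TWO_WAVELENGTHS)
        theta4 = np.array([60.0, 25.0, 24.2, 1.611])
        model = forward_phases(table, theta4, wl, 2.0)
        b = BoundsSpec.for_mode("two_wavelength", alpha=0.0)
        cost = phase_residual_cost(
            theta4, model - np.array([0.01, -0.02]),
            FDContext(110e6, 1.37, 2.0), table, b, wl,
        )
        assert cost == pytest.approx(5e-4, rel=1e-10)

    def test_wavelength_phase_count_mismatch_rejected(self, table):
        b = BoundsSpec.for_mode("eight_wavelength", alpha=0.0)
        with pytest.raises(ValueError):
            phase_residual_cost(
                b.center, np.zeros(3), FDContext(110e6, 1.37, 2.0), table, b,
                np.array(EIGHT_WAVELENGTHS),
            )


class TestGradient:
    def test_complex_step_gradient_matches_finite_differences(self, table):
        rng = np.random.default_rng(5)
        wl = np.array(EIGHT_WAVELENGTHS)
        b = BoundsSpec.for_mode("eight_wavelength", alpha=1e-3)
        meas = forward_phases(table, TRUTH8, wl, 2.0) + 0.01
        ctx = FDContext(110e6, 1.37, 2.0)
        for _ in range(3):
            u = rng.uniform(-0.8, 0.8, 5)
            _, g = _cost_and_grad_scaled(u, meas, b, wl, ctx, table, 0.75, 500.0)
            eps = 1e-6
            for j in range(5):
                up, um = u.copy(), u.copy()
                up[j] += eps
                um[j] -= eps
                fp, _ = _cost_and_grad_scaled(up, meas, b, wl, ctx, table, 0.75, 500.0)
                fm, _ = _cost_and_grad_scaled(um, meas, b, wl, ctx, table, 0.75, 500.0)
                assert g[j] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5)


class TestFitFd1sd:
    def test_noiseless_inverse_crime_recovery(self, table):
        """Clean 8-wavelength phases: concentrations within 1%, tiny residual."""
        wl = np.array(EIGHT_WAVELENGTHS)
        phases = forward_phases(table, TRUTH8, wl, 2.0)
        res = fit_fd1sd(phases, wl, rho=2.0, mode="eight_wavelength", table=table)
        for name, truth in zip(("hbo", "hb", "cco_redox"), TRUTH8[:3]):
            assert abs(res.theta[name] - truth) / truth < 0.01
        assert res.data_term < 1e-12

    def test_fixed_initializations_agree(self, table):
        """Midpoint start vs truth+20% start land on the same solution."""
        wl = np.array(EIGHT_WAVELENGTHS)
        phases = forward_phases(table, TRUTH8, wl, 2.0)
        r1 = fit_fd1sd(phases, wl, rho=2.0, mode="eight_wavelength", table=table)
        r2 = fit_fd1sd(
            phases, wl, rho=2.0, mode="eight_wavelength", table=table,
            x0=TRUTH8 * 1.2,
        )
        for name in ("hbo", "hb", "cco_redox", "a", "b"):
            assert abs(r1.theta[name] - r2.theta[name]) / abs(r1.theta[name]) < 0.005

    def test_two_wavelength_mode_has_no_cco(self, table):
        wl = np.array(TWO_WAVELENGTHS)
        phases = forward_phases(table, np.array([60.0, 25.0, 24.2, 1.611]), wl, 2.0)
        res = fit_fd1sd(phases, wl, rho=2.0, mode="two_wavelength", table=table)
        assert "cco_redox" not in res.theta
        assert res.mode == "two_wavelength"

    def test_bounds_respected_and_cost_decomposition(self, table):
        wl = np.array(EIGHT_WAVELENGTHS)
        rng = np.random.default_rng(0)
        phases = forward_phases(table, TRUTH8, wl, 2.0) + rng.normal(0, 0.02, 8)
        b = BoundsSpec.for_mode("eight_wavelength", alpha=1e-3)
        res = fit_fd1sd(phases, wl, rho=2.0, mode="eight_wavelength", table=table, bounds=b)
        for j, name in enumerate(b.names):
            assert b.lower[j] <= res.theta[name] <= b.upper[j]
        assert res.final_cost == pytest.approx(res.data_term + res.reg_term, rel=1e-12)

    def test_objective_never_increases_from_start(self, table):
        wl = np.array(EIGHT_WAVELENGTHS)
        rng = np.random.default_rng(1)
        phases = forward_phases(table, TRUTH8, wl, 2.0) + rng.normal(0, 0.01, 8)
        b = BoundsSpec.for_mode("eight_wavelength", alpha=1e-4)
        res = fit_fd1sd(phases, wl, rho=2.0, mode="eight_wavelength", table=table, bounds=b)
        start_cost = phase_residual_cost(
            b.center, np.mod(phases, 2 * np.pi), FDContext(110e6, 1.37, 2.0),
            table, b, wl,
        )
        assert res.final_cost <= start_cost

    def test_out_of_range_phases_wrapped_with_warning(self, table):
        wl = np.array(EIGHT_WAVELENGTHS)
        phases = forward_phases(table, TRUTH8, wl, 2.0)
        with pytest.warns(UserWarning, match="wrapped"):
            res = fit_fd1sd(
                phases + 2 * np.pi, wl, rho=2.0, mode="eight_wavelength", table=table
            )
        assert abs(res.theta["hbo"] - 60.0) / 60.0 < 0.01

    def test_nonfinite_phases_rejected(self, table):
        wl = np.array(TWO_WAVELENGTHS)
        with pytest.raises(ValueError):
            fit_fd1sd(np.array([0.3, np.nan]), wl, rho=2.0, mode="two_wavelength")


class TestDerivedOptics:
    def test_truth_parameters_reproduce_generating_optics(self, table):
        wl = np.array(EIGHT_WAVELENGTHS)
        phases = forward_phases(table, TRUTH8, wl, 2.0)
        res = fit_fd1sd(phases, wl, rho=2.0, mode="eight_wavelength", table=table)
        optics = derived_optics(res, wl, table=table)
        c = ChromophoreSet(60.0, 25.0, 8.5, 0.75)
        np.testing.assert_allclose(
            optics.mu_a, absorption_spectrum(c, table, wl), rtol=1e-3
        )
        np.testing.assert_allclose(
            optics.mu_s_prime,
            scattering_spectrum(ScatterLaw(24.2, 1.611), wl),
            rtol=5e-3,
        )

    def test_delegates_to_spectral_closed_forms(self, table):
        """Arbitrary theta: derived optics equal independent recomputation."""
        wl = np.array(EIGHT_WAVELENGTHS)
        from fdphase.fd1sd import FitResult

        res = FitResult(
            theta={"hbo": 45.0, "hb": 30.0, "cco_redox": 4.0, "a": 20.0, "b": 1.2},
            final_cost=0.0, data_term=0.0, reg_term=0.0, n_iterations=0,
            converged=True, rho=2.0, mode="eight_wavelength",
        )
        optics = derived_optics(res, wl, table=table)
        eps = table.epsilon_at(wl)
        expected_mu_a = eps @ np.array([45.0, 30.0, 4.0]) + 0.75 * table.water_at(wl)
        np.testing.assert_allclose(optics.mu_a, expected_mu_a, rtol=1e-12)
        np.testing.assert_allclose(
            optics.mu_s_prime, 20.0 * (wl / 500.0) ** -1.2, rtol=1e-12
        )
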