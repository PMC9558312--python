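"""TI scans, correction-potential fits, and free-energy quadrature."""

import numpy as np
import pytest

from cphmd.calibration import (
    GridSpec,
    TiScanResult,
    fit_vmm,
    make_simplex_grid,
    ti_free_energy,
    ti_scan,
)
from cphmd.constants import COULOMB
from cphmd.dynamics import RunPotentials
from cphmd.errors import ConfigurationError, CphmdError
from cphmd.fixtures import FixtureSpec, make_fixture
from cphmd.lambda_potentials import VmmPolynomial, vmm_eval

MOBILE_SPEC = FixtureSpec(
    kind="shifted_site", pKa_refs=(4.0,), mobile_environment=True,
    environment_charges=[((1.0, 0.0, 0.0), 0.05), ((0.0, 1.2, 0.0), -0.04)],
)


class TestTiScan:
    def test_frozen_fixture_gradient_is_closed_form(self, shifted_site):
        """No atomic motion: the mean gradient is exactly f dq q_env / d."""
        scan = ti_scan(shifted_site, per_point_steps=500, seed=0)
        expected = COULOMB * (-1.0) * 0.05 / 1.0
        assert np.allclose(scan.mean_gradients, expected, rtol=1e-12)
        assert np.all(scan.stderr == 0.0)

    def test_lambda_independent_system_gives_zero_gradient(self, ideal_site):
        scan = ti_scan(ideal_site, per_point_steps=500, seed=0)
        assert np.allclose(scan.mean_gradients, 0.0)

    def test_grid_extends_beyond_physical_range(self, shifted_site):
        scan = ti_scan(shifted_site, per_point_steps=500, seed=0)
        assert scan.grid.min() < 0.0 and scan.grid.max() > 1.0

    def test_below_minimum_steps_refused_in_strict_mode(self, shifted_site):
        with pytest.raises(ConfigurationError):
            ti_scan(shifted_site, per_point_steps=100, seed=0)
        with pytest.warns(UserWarning):
            ti_scan(shifted_site, per_point_steps=100, seed=0, strict=False)

    def test_replicas_with_different_seeds_agree(self):
        """Two independent scans agree within 3 pooled SEM per point."""
        system = make_fixture(MOBILE_SPEC)
        grid = np.array([[-0.1], [0.5], [1.1]])
        a = ti_scan(system, grid=grid, per_point_steps=4000, seed=21, sample_interval=100)
        b = ti_scan(system, grid=grid, per_point_steps=4000, seed=99, sample_interval=100)
        pooled = np.sqrt(a.stderr**2 + b.stderr**2)
        assert np.all(np.abs(a.mean_gradients - b.mean_gradients) < 3 * pooled)

    def test_multisite_grid_respects_simplex_window(self):
        grid = make_simplex_grid(2, GridSpec())
        lam0 = 1.0 - grid.sum(axis=1)
        assert lam0.min() >= -0.1 - 1e-9
        assert lam0.max() <= 1.1 + 1e-9


class TestFitVmm:
    def test_exact_recovery_of_fifth_order_gradients(self):
        rng = np.random.default_rng(7)
        true = VmmPolynomial.from_1d_coefficients(rng.uniform(-5, 5, 5))
        grid = np.arange(-0.1, 1.1001, 0.05)[:, None]
        _, grads = vmm_eval(grid, true)
        scan = TiScanResult(grid=grid, mean_gradients=-grads, stderr=np.zeros_like(grads))
        poly, report = fit_vmm(scan, order=5)
        _, gfit = vmm_eval(grid, poly)
        assert np.max(np.abs(gfit - grads)) < 1e-8
        assert report.max_residual < 1e-8

    def test_nested_model_higher_coefficients_vanish(self):
        """Quadratic data fitted at order 5: cubic+ coefficients are zero."""
        true = VmmPolynomial.from_1d_coefficients([1.5, -2.0])
        grid = np.arange(-0.1, 1.1001, 0.05)[:, None]
        _, grads = vmm_eval(grid, true)
        scan = TiScanResult(grid=grid, mean_gradients=-grads, stderr=np.zeros_like(grads))
        poly, _ = fit_vmm(scan, order=5)
        high = poly.coefficients[poly.exponents[:, 0] > 2]
        assert np.max(np.abs(high)) < 1e-8

    def test_noise_calibration_fitting_error_below_half_kj(self):
        """Gaussian noise sigma=0.3 kJ/mol on the gradients: the fitting
        error (RMS residual) stays below 0.5 kJ/mol, and the fitted curve
        tracks the clean truth over the physical range to 0.5 kJ/mol, in
        at least 95% of 100 seeded repeats."""
        rng = np.random.default_rng(123)
        base = VmmPolynomial.from_1d_coefficients([2.0, -7.0, 4.0, 1.0, -0.5])
        grid = np.arange(-0.1, 1.1001, 0.05)[:, None]
        _, grads = vmm_eval(grid, base)
        interior = (grid[:, 0] >= 0.0) & (grid[:, 0] <= 1.0)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            noisy = -grads + rng.normal(0.0, 0.3, grads.shape)
            scan = TiScanResult(
                grid=grid, mean_gradients=noisy, stderr=np.full_like(grads, 0.3)
            )
            poly, report = fit_vmm(scan, order=5)
            _, gfit = vmm_eval(grid, poly)
            truth_err = np.max(np.abs(gfit - grads)[interior])
            if report.rms_residual <= 0.5 and truth_err <= 0.5:
                ok += 1
        assert ok >= 95

    def test_underdetermined_fit_rejected(self):
        grid = np.array([[-0.1], [0.5], [1.1]])
        scan = TiScanResult(
            grid=grid, mean_gradients=np.zeros_like(grid), stderr=np.zeros_like(grid)
        )
        with pytest.raises(ConfigurationError):
            fit_vmm(scan, order=5)

    def test_eighth_order_two_dimensional_fit(self):
        """Three-state correction: order 8 in two free coordinates."""
        rng = np.random.default_rng(17)
        true = VmmPolynomial(arity=2, order=3)
        true.coefficients = rng.uniform(-2, 2, true.n_terms)
        grid = make_simplex_grid(2, GridSpec())
        _, grads = vmm_eval(grid, true)
        scan = TiScanResult(grid=grid, mean_gradients=-grads, stderr=np.zeros_like(grads))
        poly, report = fit_vmm(scan)       # defaults to order 8 for arity 2
        assert poly.order == 8
        _, gfit = vmm_eval(grid, poly)
        assert np.max(np.abs(gfit - grads)) < 1e-7


class TestTiFreeEnergy:
    def grid_scan(self, values):
        grid = np.arange(-0.1, 1.1001, 0.05)[:, None]
        g = np.full_like(grid, values) if np.isscalar(values) else values
        return TiScanResult(grid=grid, mean_gradients=g, stderr=np.zeros_like(grid))

    def test_zero_gradients_zero_free_energy(self):
        dg, err = ti_free_energy(self.grid_scan(0.0))
        assert dg == 0.0 and err == 0.0

    def test_constant_gradient_integrates_to_itself(self):
        dg, _ = ti_free_energy(self.grid_scan(-3.2))
        assert dg == pytest.approx(-3.2, rel=1e-12)

    def test_frozen_pair_fixture_matches_end_state_energies(self, shifted_site):
        """TI over the frozen pair equals E(lambda=1) - E(lambda=0)."""
        from cphmd import electrostatics as es
        from cphmd.model import interpolated_charges

        scan = ti_scan(shifted_site, per_point_steps=500, seed=0)
        dg, _ = ti_free_energy(scan)
        e0 = es.coulomb(shifted_site, interpolated_charges(shifted_site, [1.0, 0.0])).energy
        e1 = es.coulomb(shifted_site, interpolated_charges(shifted_site, [0.0, 1.0])).energy
        assert dg == pytest.approx(e1 - e0, abs=1e-6)

    def test_gap_in_grid_rejected(self):
        grid = np.array([[-0.1], [0.0], [0.5], [1.0], [1.1]])
        scan = TiScanResult(
            grid=grid, mean_gradients=np.zeros_like(grid), stderr=np.zeros_like(grid)
        )
        with pytest.raises(CphmdError):
            ti_free_energy(scan)
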