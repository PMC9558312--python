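"""Integration, thermostats, and the analytic constraint solver."""

import numpy as np
import pytest

from cphmd.constants import KB
from cphmd.dynamics import (
    ConstraintSet,
    IntegratorSpec,
    RunPotentials,
    build_constraints,
    run_lambda_dynamics,
    run_md,
    solve_constraints,
    vrescale,
)
from cphmd.errors import ConfigurationError
from cphmd.fixtures import FixtureSpec, make_fixture
from cphmd.lambda_potentials import VmmPolynomial
from cphmd.model import total_charge


class TestConstraintSolver:
    def test_satisfied_constraints_are_identity(self, his_like):
        cset = build_constraints(his_like)
        lam = np.array([0.2, 0.5, 0.3])
        vel = np.array([0.1, -0.3, 0.2])
        lam2, vel2 = solve_constraints(lam, vel, cset)
        assert np.linalg.norm(lam2 - lam) < 1e-14
        # velocity projection removes only the constraint-normal component
        assert abs(vel2.sum()) < 1e-14

    def test_three_state_uniform_shift(self, his_like):
        """Equal masses: the correction is a uniform shift by (sum-1)/3."""
        cset = build_constraints(his_like)
        lam, _ = solve_constraints(
            np.array([0.5, 0.4, 0.3]), np.zeros(3), cset
        )
        assert np.allclose(lam, np.array([0.5, 0.4, 0.3]) - 0.2 / 3)

    def test_buffers_absorb_titration_charge(self, buffered_site):
        """Moving along the constraint manifold, a site-charge change of
        delta is compensated by -delta/10 on each of the 10 buffers."""
        cset = build_constraints(buffered_site)
        start = buffered_site.lambda_vector()
        # propose a titration displacement and project back onto the manifold
        prop = start.copy()
        prop[0] -= 0.4
        prop[1] += 0.4
        lam, _ = solve_constraints(prop, np.zeros_like(prop), cset)
        dq_site = (lam[1] - start[1]) * (-1.0)  # site charge change
        dq_buffer = (lam[-1] - start[-1]) * buffered_site.buffers.charge_span
        # each buffer compensates -delta/10; all ten together -delta
        assert dq_buffer == pytest.approx(-dq_site / 10, rel=1e-9)
        assert total_charge(buffered_site, lam) == pytest.approx(
            total_charge(buffered_site, start), abs=1e-10
        )

    def test_charge_constraint_without_buffers_is_singular(self, ideal_site):
        with pytest.raises(ConfigurationError):
            build_constraints(ideal_site, charge_constraint=True)


class TestVRescale:
    def test_no_coupling_limit_leaves_velocities_unchanged(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((4, 3))
        out = vrescale(v, np.ones(3), 300.0, None, 0.002, rng)
        assert np.array_equal(out, v)

    def test_fixed_seed_reproducible(self):
        v = np.random.default_rng(1).standard_normal((4, 3))
        a = vrescale(v, np.ones(3), 300.0, 2.0, 0.002, np.random.default_rng(7))
        b = vrescale(v, np.ones(3), 300.0, 2.0, 0.002, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_equipartition_on_ideal_site(self, ideal_site):
        """<K> per constrained lambda pair = kB T / 2 (one free DOF)."""
        spec = IntegratorSpec(n_steps=150_000, seed=2, lambda_output_interval=0.5)
        traj = run_lambda_dynamics(
            ideal_site, RunPotentials(pH=4.0), spec, n_walkers=16, record_kinetic=True
        )
        kin = traj.kinetic[:, 50:]
        target = 0.5 * KB * 300.0
        per_walker = kin.mean(axis=1)
        sem = per_walker.std(ddof=1) / np.sqrt(len(per_walker))
        assert abs(per_walker.mean() - target) < 3 * max(sem, 1e-3)


class TestLeapfrog:
    def test_zero_forces_zero_velocities_state_unchanged(self, ideal_site):
        spec = IntegratorSpec(
            n_steps=100, lambda_thermostat=None, seed=0, lambda_output_interval=0.002
        )
        pots = RunPotentials(bias=None, pH=None, include_coulomb=False)
        init = np.array([[1.0, 0.0]])
        traj = run_lambda_dynamics(
            ideal_site, pots, spec, n_walkers=1, initial_lambdas=init
        )
        # no potential terms act; initial velocity is the only motion source,
        # so freeze it by setting temperature via a zero-variance draw:
        # instead verify the frozen path explicitly
        traj2 = run_lambda_dynamics(
            ideal_site, pots, spec, n_walkers=1, initial_lambdas=init, frozen=True
        )
        assert np.allclose(traj2.lambdas[0, -1], init[0])

    def test_harmonic_oscillator_period(self, ideal_site):
        """V = k t^2 / 2 on the titration coordinate.

        Under the simplex constraint both lambda particles move, so the
        effective inertia is 2 m_lambda and the period is
        2 pi sqrt(2 m / k).
        """
        k = 100.0
        pots = RunPotentials(
            bias=None,
            pH=None,
            vmm=[VmmPolynomial.from_1d_coefficients([0.0, 0.5 * k])],
            include_coulomb=False,
        )
        spec = IntegratorSpec(
            n_steps=40_000, dt=0.001, lambda_thermostat=None, seed=1,
            lambda_output_interval=0.001,
        )
        init = np.array([[0.7, 0.3]])
        traj = run_lambda_dynamics(
            ideal_site, pots, spec, n_walkers=1, initial_lambdas=init
        )
        x = traj.lambdas[0, :, 1]
        x = x - x.mean()
        up = np.where(np.diff(np.sign(x)) > 0)[0]
        period = np.diff(up * 0.001).mean()
        expected = 2 * np.pi * np.sqrt(2 * 5.0 / k)
        assert period == pytest.approx(expected, rel=0.01)

    def test_nve_energy_drift_small(self):
        """Thermostats off: total energy drift below 0.01 kJ/mol per ps."""
        spec = FixtureSpec(
            kind="shifted_site", pKa_refs=(4.0,), mobile_environment=True,
            environment_charges=[((1.0, 0.0, 0.0), 0.05), ((0.0, 1.2, 0.0), -0.04)],
        )
        system = make_fixture(spec)
        ispec = IntegratorSpec(
            n_steps=10_000, dt=0.001, atom_thermostat=None, lambda_thermostat=None,
            seed=5, lambda_output_interval=0.01,
        )
        _, (_, energies) = run_md(system, ispec, RunPotentials(pH=4.0), record_energy=True)
        times = np.arange(len(energies)) * 0.01
        drift_per_ps = abs(np.polyfit(times, energies, 1)[0])
        assert drift_per_ps < 0.01

    def test_simplex_and_charge_conserved_along_trajectory(self, buffered_site):
        spec = IntegratorSpec(n_steps=20_000, seed=3, lambda_output_interval=0.1)
        traj = run_lambda_dynamics(
            buffered_site, RunPotentials(pH=4.0), spec, n_walkers=2
        )
        sl = buffered_site.dof_slices()[0]
        sums = traj.lambdas[:, :, sl].sum(axis=2)
        assert np.max(np.abs(sums - 1.0)) < 1e-9
        charges = [
            total_charge(buffered_site, traj.lambdas[w, f])
            for w in range(2)
            for f in range(0, traj.lambdas.shape[1], 7)
        ]
        assert max(charges) - min(charges) < 1e-9

    def test_fixed_seed_trajectories_bit_identical(self, ideal_site):
        spec = IntegratorSpec(n_steps=5_000, seed=11, lambda_output_interval=0.1)
        a = run_lambda_dynamics(ideal_site, RunPotentials(pH=4.0), spec, n_walkers=3)
        b = run_lambda_dynamics(ideal_site, RunPotentials(pH=4.0), spec, n_walkers=3)
        assert np.array_equal(a.lambdas, b.lambdas)
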