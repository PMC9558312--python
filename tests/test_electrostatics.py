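"""Coulomb kernels, per-atom potentials, and the two interpolation schemes."""

import numpy as np
import pytest

from cphmd.constants import COULOMB
from cphmd import electrostatics as es
from cphmd.errors import (
    ConfigurationError,
    ContractViolationError,
    SingularityError,
)
from cphmd.model import (
    Atom,
    ElectrostaticsSpec,
    LambdaGroup,
    TitratableSystem,
    interpolated_charges,
)
from conftest import random_multisite_system


def pair_system(r=1.0, q1=1.0, q2=1.0, spec=None):
    atoms = [
        Atom(id=0, position=np.zeros(3), q_A=q1),
        Atom(id=1, position=np.array([r, 0.0, 0.0]), q_A=q2),
    ]
    return TitratableSystem(atoms=atoms, electrostatics=spec or ElectrostaticsSpec())


class TestCoulomb:
    def test_unit_pair_at_one_nm(self):
        res = es.coulomb(pair_system())
        assert res.energy == pytest.approx(COULOMB, rel=1e-12)

    def test_forces_sum_to_zero(self):
        rng = np.random.default_rng(0)
        s = random_multisite_system(rng, n_sites=3, n_env=5)
        res = es.coulomb(s)
        assert np.max(np.abs(res.atom_forces.sum(axis=0))) < 1e-9

    def test_force_matches_position_finite_difference(self):
        s = pair_system(r=0.8, q1=0.5, q2=-0.7)
        res = es.coulomb(s)
        h = 1e-7
        for d in range(3):
            s.atoms[0].position[d] += h
            ep = es.coulomb(s).energy
            s.atoms[0].position[d] -= 2 * h
            em = es.coulomb(s).energy
            s.atoms[0].position[d] += h
            assert res.atom_forces[0, d] == pytest.approx(-(ep - em) / (2 * h), rel=1e-5)

    def test_phi_is_charge_derivative_of_energy(self):
        rng = np.random.default_rng(1)
        s = random_multisite_system(rng)
        q = interpolated_charges(s)
        res = es.coulomb(s, q)
        h = 1e-6
        for i in range(s.n_atoms):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            fd = (es.coulomb(s, qp).energy - es.coulomb(s, qm).energy) / (2 * h)
            assert res.phi[i] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_coincident_atoms_raise(self):
        s = pair_system(r=1e-8)
        with pytest.raises(SingularityError):
            es.coulomb(s)

    def test_cutoff_beyond_half_box_rejected(self):
        with pytest.raises(ConfigurationError):
            ElectrostaticsSpec(scheme="plain", cutoff=2.0, box=3.0)

    def test_reaction_field_energy_continuous_at_cutoff(self):
        spec = ElectrostaticsSpec(scheme="reaction-field", cutoff=1.1, eps_r=2.5)
        just_in = es.coulomb(pair_system(r=1.0999, spec=spec)).energy
        just_out = es.coulomb(pair_system(r=1.1001, spec=spec)).energy
        assert just_out == 0.0
        assert abs(just_in) < 0.02  # kernel tends to zero at the cutoff

    def test_minimum_image_periodicity(self):
        spec = ElectrostaticsSpec(box=3.0)
        near = es.coulomb(pair_system(r=0.4, spec=spec)).energy
        wrapped = es.coulomb(pair_system(r=2.6, spec=spec)).energy
        assert near == pytest.approx(wrapped, rel=1e-12)


class TestLambdaGradients:
    def test_zero_delta_charge_gives_zero_gradient(self):
        g = LambdaGroup.two_state([0], [0.3], [0.3], 4.0)
        s = TitratableSystem(
            atoms=[
                Atom(id=0, position=np.zeros(3), group_id=0),
                Atom(id=1, position=np.array([1.0, 0, 0]), q_A=0.5),
            ],
            groups=[g],
        )
        res = es.coulomb(s)
        grads = es.lambda_gradients_charge_interp(s, res)
        assert np.allclose(grads[0], 0.0)

    def test_single_pair_closed_form(self):
        """One site + one fixed charge: gradient is f*dq*q_env/r."""
        g = LambdaGroup.two_state([0], [0.0], [-1.0], 4.0)
        g.set_lambdas([0.6, 0.4])
        s = TitratableSystem(
            atoms=[
                Atom(id=0, position=np.zeros(3), group_id=0),
                Atom(id=1, position=np.array([0.8, 0, 0]), q_A=0.25),
            ],
            groups=[g],
        )
        res = es.coulomb(s)
        grads = es.lambda_gradients_charge_interp(s, res)
        assert grads[0][1] == pytest.approx(COULOMB * (-1.0) * 0.25 / 0.8, rel=1e-12)
        assert grads[0][0] == pytest.approx(0.0, abs=1e-12)

    def test_gradient_matches_constrained_finite_difference(self):
        """dq-form gradients are derivatives along the simplex direction."""
        rng = np.random.default_rng(7)
        s = random_multisite_system(rng, n_sites=3)
        res = es.coulomb(s)
        grads = es.lambda_gradients_charge_interp(s, res)
        h = 1e-6
        vec = s.lambda_vector()
        for gi, sl in enumerate(s.dof_slices()):
            vp, vm = vec.copy(), vec.copy()
            vp[sl.start + 1] += h
            vp[sl.start] -= h
            vm[sl.start + 1] -= h
            vm[sl.start] += h
            ep = es.coulomb(s, interpolated_charges(s, vp)).energy
            em = es.coulomb(s, interpolated_charges(s, vm)).energy
            fd = (ep - em) / (2 * h)
            assert grads[gi][1] - grads[gi][0] == pytest.approx(fd, rel=1e-6, abs=1e-6)

    def test_stale_phi_rejected(self):
        rng = np.random.default_rng(9)
        s = random_multisite_system(rng)
        res = es.coulomb(s)
        lam = s.groups[0].lambdas
        s.groups[0].set_lambdas([lam[0] - 0.05, lam[1] + 0.05])
        with pytest.raises(ContractViolationError):
            es.lambda_gradients_charge_interp(s, res)


class TestPotentialInterpolation:
    def test_no_sites_identical_to_plain_coulomb(self):
        s = pair_system(q1=0.4, q2=-0.2)
        oracle = es.potential_interp_oracle(s)
        assert oracle.energy == pytest.approx(es.coulomb(s).energy, rel=1e-12)
        assert oracle.n_evaluations == 0

    def test_two_sites_need_four_evaluations(self):
        rng = np.random.default_rng(3)
        s = random_multisite_system(rng, n_sites=2)
        assert es.potential_interp_oracle(s).n_evaluations == 4

    def test_multisite_group_rejected(self, his_like):
        with pytest.raises(ConfigurationError):
            es.potential_interp_oracle(his_like)

    def test_inter_group_and_environment_terms_identical(self):
        """Outside the intra-group term the two schemes agree exactly."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            s = random_multisite_system(
                rng,
                n_sites=int(rng.integers(1, 4)),
                n_atoms_per_site=int(rng.integers(1, 3)),
                n_env=int(rng.integers(0, 4)),
            )
            ci_energy = es.coulomb(s).energy
            oracle = es.potential_interp_oracle(s)
            disc = es.scheme_discrepancy(s) if any(
                len(g.atom_ids) >= 2 for g in s.groups
            ) else np.zeros(len(s.groups))
            # total difference is fully explained by the intra-group term
            assert oracle.energy - ci_energy == pytest.approx(disc.sum(), abs=1e-10)

    def test_intra_group_discrepancy_hand_derived(self):
        """Two-atom group, swap charges, r = 0.5 nm, lambda = 1/2."""
        g = LambdaGroup.two_state([0, 1], [1.0, 0.0], [0.0, 1.0], 4.0)
        g.set_lambdas([0.5, 0.5])
        s = TitratableSystem(
            atoms=[
                Atom(id=0, position=np.zeros(3), group_id=0),
                Atom(id=1, position=np.array([0.5, 0, 0]), group_id=0),
            ],
            groups=[g],
        )
        disc = es.scheme_discrepancy(s)
        assert disc[0] == pytest.approx(-COULOMB * 0.25 / 0.5, rel=1e-9)

    def test_discrepancy_vanishes_at_end_states(self):
        g = LambdaGroup.two_state([0, 1], [0.7, -0.3], [0.1, -0.9], 4.0)
        s = TitratableSystem(
            atoms=[
                Atom(id=0, position=np.zeros(3), group_id=0),
                Atom(id=1, position=np.array([0.6, 0, 0]), group_id=0),
            ],
            groups=[g],
        )
        for lam in (0.0, 1.0):
            s.groups[0].set_lambdas([1 - lam, lam])
            assert es.scheme_discrepancy(s)[0] == pytest.approx(0.0, abs=1e-10)


def test_quadratic_form_reproduces_coulomb_everywhere(buffered_site):
    H, g, c = es.quadratic_form(buffered_site)
    rng = np.random.default_rng(5)
    for _ in range(10):
        t = rng.uniform(-0.1, 1.1)
        lam_buf = rng.uniform(0, 1)
        vec = np.array([1 - t, t, lam_buf])
        e_direct = es.coulomb(buffered_site, interpolated_charges(buffered_site, vec)).energy
        e_quad = 0.5 * vec @ H @ vec + g @ vec + c
        assert e_quad == pytest.approx(e_direct, rel=1e-12, abs=1e-12)
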