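"""Pairwise Coulomb energies, forces, potentials, and lambda-gradients.

Two interpolation schemes are provided:

*charge interpolation* (the production path) — partial charges are
linear in lambda, so one electrostatic evaluation yields the energy, the
atomic forces, and, through the per-atom electrostatic potential
``Phi(R_i, lambda)``, the gradients with respect to every titration
coordinate;

*potential interpolation* (an independent oracle) — the end-state
Hamiltonians are mixed linearly, which requires two full electrostatic
evaluations per titratable site.  The two schemes coincide for
group-environment and inter-group interactions and differ only in the
intra-group term, which is quadratic in lambda under charge
interpolation but linear under potential interpolation.

The engine is a desk-scale O(N^2) direct sum with an optional
minimum-image cubic box and an optional reaction-field kernel
(eps_RF = infinity), standing in for the mesh Ewald treatment of
production MD codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB
from .errors import ConfigurationError, ContractViolationError, SingularityError
from .model import TitratableSystem, interpolated_charges

__all__ = [
    "ElectrostaticsResult",
    "coulomb",
    "lambda_gradients_charge_interp",
    "potential_interp_oracle",
    "scheme_discrepancy",
    "quadratic_form",
]

_MIN_SEPARATION = 1e-6  # nm


@dataclass
class ElectrostaticsResult:
    """Energy, forces, per-atom potentials of one electrostatic evaluation."""

    energy: float
    atom_forces: np.ndarray          # (N, 3), kJ/(mol nm)
    phi: np.ndarray                  # (N,), kJ/(mol e): dE/dq_i
    n_evaluations: int = 1
    charges: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class PotentialInterpResult:
    """Energy and lambda-gradients from the potential-interpolation oracle."""

    energy: float
    gradients: np.ndarray            # dV/dlambda per (2-state) group
    n_evaluations: int


def _pair_geometry(system: TitratableSystem):
    """Displacements, distances and the validity mask for all pairs."""
    pos = system.positions
    spec = system.electrostatics
    d = pos[:, None, :] - pos[None, :, :]
    if spec.box is not None:
        d -= spec.box * np.round(d / spec.box)
    r = np.sqrt((d**2).sum(axis=2))
    n = len(pos)
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < _MIN_SEPARATION):
        raise SingularityError("coincident atoms (separation < 1e-6 nm)")
    return d, r, off


def _kernel(system: TitratableSystem, r: np.ndarray, mask: np.ndarray):
    """Pair kernel k(r) and its radial derivative on valid pairs.

    plain:           k = 1 / (eps_r r)
    reaction field:  k = (1/r + r^2/(2 rc^3) - 3/(2 rc)) / eps_r, r < rc
    """
    spec = system.electrostatics
    k = np.zeros_like(r)
    dk = np.zeros_like(r)
    within = mask.copy()
    if spec.cutoff is not None:
        within &= r < spec.cutoff
    rr = np.where(within, r, 1.0)
    if spec.scheme == "plain":
        k[within] = (1.0 / rr[within]) / spec.eps_r
        dk[within] = (-1.0 / rr[within] ** 2) / spec.eps_r
    else:
        rc = spec.cutoff
        k[within] = (1.0 / rr[within] + rr[within] ** 2 / (2 * rc**3) - 3.0 / (2 * rc)) / spec.eps_r
        dk[within] = (-1.0 / rr[within] ** 2 + rr[within] / rc**3) / spec.eps_r
    return k, dk


def coulomb(system: TitratableSystem, charges=None) -> ElectrostaticsResult:
    """One full electrostatic evaluation at the given per-atom charges.

    ``phi[i] = dE/dq_i`` is the electrostatic potential at atom i due to
    all other atoms, the central quantity of the charge-interpolation
    lambda-gradients.  Forces obey Newton's third law exactly.
    """
    if charges is None:
        charges = interpolated_charges(system)
    q = np.asarray(charges, dtype=float)
    if q.shape != (system.n_atoms,):
        raise ConfigurationError("charge vector length mismatch")
    d, r, off = _pair_geometry(system)
    k, dk = _kernel(system, r, off)
    phi = COULOMB * (k @ q)
    energy = 0.5 * float(q @ phi)
    # F_i = -dE/dr_i = f q_i sum_j q_j (-dk/dr) * unit(i - j)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(off[..., None], d / np.where(r[..., None] == 0, 1.0, r[..., None]), 0.0)
    fmag = -COULOMB * dk * np.outer(q, q)
    forces = (fmag[..., None] * unit).sum(axis=1)
    return ElectrostaticsResult(
        energy=energy, atom_forces=forces, phi=phi, n_evaluations=1, charges=q.copy()
    )


def lambda_gradients_charge_interp(
    system: TitratableSystem, result: ElectrostaticsResult
) -> list[np.ndarray]:
    """Per-coordinate Coulomb gradients from one evaluation's potentials.

    For each group, ``grad[k] = sum_{i in group} dq_i^{(k)} Phi(R_i)``
    with ``dq^{(k)}`` the charge difference of state k relative to the
    shared reference state (for a two-state site this is the familiar
    ``dq = q_B - q_A`` on the titration coordinate, and exactly zero on
    the reference coordinate).

    Raises :class:`ContractViolationError` if the charges the evaluation
    was run with no longer match the system's current lambda values.
    """
    current = interpolated_charges(system)
    if result.charges.size == 0 or not np.allclose(result.charges, current, atol=1e-12):
        raise ContractViolationError(
            "electrostatic potentials are stale: charges changed since evaluation"
        )
    grads = []
    for g in system.groups:
        idx = [system.atom_index(a) for a in g.atom_ids]
        phi_g = result.phi[idx]
        grads.append(
            np.array([float(g.delta_charges(k) @ phi_g) for k in range(g.n_states)])
        )
    return grads


def _charges_with_group_state(system: TitratableSystem, gi: int, state: int) -> np.ndarray:
    """Interpolated charges with group ``gi`` clamped to end state ``state``."""
    q = interpolated_charges(system)
    g = system.groups[gi]
    for aid, qa in zip(g.atom_ids, g.state_charges[state]):
        q[system.atom_index(aid)] = qa
    return q


def _intra_group_energy(system: TitratableSystem, gi: int, charges: np.ndarray) -> float:
    """Coulomb energy among the member atoms of one group only."""
    g = system.groups[gi]
    idx = np.array([system.atom_index(a) for a in g.atom_ids])
    if len(idx) < 2:
        return 0.0
    d, r, off = _pair_geometry(system)
    k, _ = _kernel(system, r, off)
    sub = k[np.ix_(idx, idx)]
    qg = charges[idx]
    return 0.5 * COULOMB * float(qg @ sub @ qg)


def potential_interp_oracle(system: TitratableSystem) -> PotentialInterpResult:
    """Energy and lambda-gradients by linear mixing of end-state Hamiltonians.

    Supports chemically uncoupled sites only (two-state groups).  The
    energy replaces each group's quadratic intra-group charge product by
    the linear mixture of end-state intra energies; the gradient for a
    group is the difference of two full evaluations with that group
    clamped to its end states (all other groups at interpolated
    charges), hence 2 * N_sites evaluations in total.
    """
    for g in system.groups:
        if g.n_states != 2:
            raise ConfigurationError(
                "potential interpolation supports two-state (uncoupled) groups only"
            )
    base = coulomb(system)
    energy = base.energy
    for gi, g in enumerate(system.groups):
        lam = g.lambdas[g.titration_index]
        e_mix = _intra_group_energy(system, gi, base.charges)
        e_a = _intra_group_energy(system, gi, _charges_with_group_state(system, gi, 0))
        e_b = _intra_group_energy(system, gi, _charges_with_group_state(system, gi, 1))
        energy += (1.0 - lam) * e_a + lam * e_b - e_mix
    grads = np.zeros(len(system.groups))
    n_eval = 0
    for gi in range(len(system.groups)):
        e_a = coulomb(system, _charges_with_group_state(system, gi, 0)).energy
        e_b = coulomb(system, _charges_with_group_state(system, gi, 1)).energy
        n_eval += 2
        grads[gi] = e_b - e_a
    return PotentialInterpResult(energy=energy, gradients=grads, n_evaluations=n_eval)


def scheme_discrepancy(system: TitratableSystem) -> np.ndarray:
    """Intra-group energy difference, potential- minus charge-interpolation.

    Zero at the end states for every group; generally nonzero at interior
    lambda because the intra-group term is linear in lambda under
    potential interpolation but quadratic under charge interpolation.
    """
    if not any(len(g.atom_ids) >= 2 for g in system.groups):
        raise ConfigurationError(
            "scheme discrepancy requires a group with at least two member atoms"
        )
    q_now = interpolated_charges(system)
    out = np.zeros(len(system.groups))
    for gi, g in enumerate(system.groups):
        lam = g.lambdas[1] if g.n_states == 2 else None
        if g.n_states != 2:
            raise ConfigurationError("scheme discrepancy defined for two-state groups")
        e_mix = _intra_group_energy(system, gi, q_now)
        e_a = _intra_group_energy(system, gi, _charges_with_group_state(system, gi, 0))
        e_b = _intra_group_energy(system, gi, _charges_with_group_state(system, gi, 1))
        out[gi] = (1.0 - lam) * e_a + lam * e_b - e_mix
    return out


def quadratic_form(system: TitratableSystem):
    """Exact lambda-dependence of the Coulomb energy for frozen atoms.

    Charges are affine in the lambda DOF vector d (group coordinates in
    group-major order, buffer lambda last), so the energy is the
    quadratic form

        E(d) = 1/2 d^T H d + g^T d + c,      grad = H d + g.

    Used by the fast frozen-atom lambda sampler, the TI scan, and the
    quadrature oracle; it reproduces :func:`coulomb` exactly.
    """
    n = system.n_atoms
    K = system.n_lambda_dofs
    # affine charge map q(d) = q0 + C d
    q0 = np.array([a.q_A for a in system.atoms], dtype=float)
    C = np.zeros((n, K))
    for sl, g in zip(system.dof_slices(), system.groups):
        for k in range(g.n_states):
            for aid, qs in zip(g.atom_ids, g.state_charges[k]):
                i = system.atom_index(aid)
                C[i, sl.start + k] = qs
                q0[i] = 0.0
    if system.buffers is not None:
        for aid in system.buffers.atom_ids:
            i = system.atom_index(aid)
            q0[i] = system.buffers.q_min
            C[i, K - 1] = system.buffers.charge_span
    d, r, off = _pair_geometry(system)
    kmat, _ = _kernel(system, r, off)
    G = COULOMB * kmat
    H = C.T @ G @ C
    g = C.T @ G @ q0
    c = 0.5 * float(q0 @ G @ q0)
    return H, g, c
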