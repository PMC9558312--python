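"""Time integration of atoms and lambda-particles with holonomic constraints.

Two entry points:

:func:`run_lambda_dynamics`
    a batched frozen-atom sampler: many independent walkers (one per
    pH value and replica) evolve their lambda coordinates on the exact
    quadratic Coulomb form plus the analytic lambda potentials.  This is
    the statistical workhorse for titration campaigns.

:func:`run_md` / :func:`md_step`
    full coupled leapfrog dynamics of atoms and lambda particles for a
    single system, used for energy-conservation checks and calibration
    scans with mobile atoms.

Both apply the same closed-form constraint solver: the simplex
constraint sum_k lambda_{i,k} = 1 per group and, with buffers, one
global charge-neutrality row.  All constraints are linear in the lambda
variables, so the mass-weighted least-squares (Lagrange) correction is
analytic; no iterative SHAKE is needed.  Velocity components along the
constraint normals are removed as in standard holonomic treatments.

Temperatures are maintained by the stochastic velocity-rescaling
(v-rescale) thermostat, with separate pools for atoms and lambdas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, LN10
from .errors import ConfigurationError, IntegrationBlowupError, ParameterError
from .lambda_potentials import (
    BiasSpec,
    VmmPolynomial,
    _step,
    _step_deriv,
    bias_potential,
    vmm_eval,
)
from .model import TitratableSystem, interpolated_charges
from . import electrostatics as es
from . import _kernels

__all__ = [
    "IntegratorSpec",
    "ConstraintSet",
    "build_constraints",
    "solve_constraints",
    "vrescale",
    "RunPotentials",
    "LambdaTrajectory",
    "run_lambda_dynamics",
    "MDState",
    "md_step",
    "run_md",
    "total_potential_energy",
]


@dataclass
class IntegratorSpec:
    """Leapfrog integrator and thermostat settings.

    ``dt`` in ps (default 2 fs); thermostat couples are ``(T in K, tau in
    ps)`` or ``None`` to disable (NVE).  ``lambda_output_interval`` is
    the spacing of recorded lambda frames in ps.
    """

    dt: float = 0.002
    n_steps: int = 1000
    atom_thermostat: tuple[float, float] | None = (300.0, 0.5)
    lambda_thermostat: tuple[float, float] | None = (300.0, 2.0)
    seed: int = 0
    lambda_output_interval: float = 1.0
    freeze_atoms: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        for th in (self.atom_thermostat, self.lambda_thermostat):
            if th is not None and th[1] <= 0:
                raise ParameterError("thermostat time constant must be positive")

    @property
    def output_stride(self) -> int:
        return max(1, int(round(self.lambda_output_interval / self.dt)))


@dataclass
class ConstraintSet:
    """Linear constraints J d = c on the lambda DOF vector d.

    ``masses`` are the fictitious masses of the DOFs; the correction is
    the mass-weighted least-squares (minimum kinetic-energy) projection
    via closed-form Lagrange multipliers.
    """

    jacobian: np.ndarray            # (m, K)
    targets: np.ndarray             # (m,)
    masses: np.ndarray              # (K,)
    tolerance: float = 1e-10
    _proj: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        J = np.atleast_2d(np.asarray(self.jacobian, dtype=float))
        self.jacobian = J
        self.targets = np.asarray(self.targets, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if J.shape[0] != self.targets.size or J.shape[1] != self.masses.size:
            raise ConfigurationError("constraint shape mismatch")
        minv = 1.0 / self.masses
        gram = J @ (minv[:, None] * J.T)
        if np.linalg.matrix_rank(gram, tol=1e-10) < J.shape[0]:
            raise ConfigurationError(
                "singular constraint system (e.g. charge constraint without "
                "buffer capacity)"
            )
        #: A such that correction = -(J d - c) @ A.T restores J d = c
        self._proj = (minv[:, None] * J.T) @ np.linalg.inv(gram)

    @property
    def n_constraints(self) -> int:
        return self.jacobian.shape[0]

    def residual(self, d: np.ndarray) -> np.ndarray:
        return d @ self.jacobian.T - self.targets

    def project_positions(self, d: np.ndarray) -> np.ndarray:
        return d - self.residual(d) @ self._proj.T

    def project_velocities(self, v: np.ndarray) -> np.ndarray:
        return v - (v @ self.jacobian.T) @ self._proj.T


def build_constraints(
    system: TitratableSystem, charge_constraint: bool | None = None
) -> ConstraintSet:
    """Simplex rows per group plus, with buffers, the charge row.

    The charge row fixes ``sum_k Q_k lambda_k + N_buf dq_buf lambda_buf``
    at its initial value, where Q_k is the total charge of group state k,
    so the total interpolated system charge is conserved exactly.
    """
    K = system.n_lambda_dofs
    rows, targets = [], []
    for sl, g in zip(system.dof_slices(), system.groups):
        row = np.zeros(K)
        row[sl] = 1.0
        rows.append(row)
        targets.append(g.constrained_sum)
    if charge_constraint is None:
        charge_constraint = system.buffers is not None
    if charge_constraint:
        row = np.zeros(K)
        titrates = False
        for sl, g in zip(system.dof_slices(), system.groups):
            qs = g.state_charges.sum(axis=1)
            row[sl] = qs
            titrates |= bool(np.ptp(qs) > 0)
        if system.buffers is not None:
            row[K - 1] = system.buffers.n_buffers * system.buffers.charge_span
        elif titrates:
            raise ConfigurationError(
                "charge constraint without buffer capacity would freeze titration"
            )
        rows.append(row)
        targets.append(float(row @ system.lambda_vector()))
    if not rows:
        raise ConfigurationError("no constraints to build")
    return ConstraintSet(
        jacobian=np.vstack(rows), targets=np.array(targets), masses=system.lambda_masses()
    )


def solve_constraints(lambdas, velocities, constraints: ConstraintSet):
    """Project lambda values and velocities onto the constraint manifold.

    Accepts single vectors (K,) or batches (B, K); returns the corrected
    pair.  For already-satisfied constraints this is the identity to
    machine precision.
    """
    d = np.asarray(lambdas, dtype=float)
    v = np.asarray(velocities, dtype=float)
    d_new = constraints.project_positions(d)
    v_new = constraints.project_velocities(v)
    return d_new, v_new


def vrescale(velocities, masses, T_target, tau, dt, rng, n_dof=None):
    """Stochastic velocity rescaling (canonical-sampling thermostat).

    ``velocities`` is (K,) or a batch (B, K); each batch row is an
    independent walker with its own rescaling factor.  ``n_dof`` is the
    number of unconstrained degrees of freedom in the pool (defaults to
    the number of velocity components).  ``tau=None`` or infinite means
    no coupling: velocities are returned unchanged.
    """
    v = np.asarray(velocities, dtype=float)
    if tau is None or not np.isfinite(tau):
        return v.copy()
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    m = np.asarray(masses, dtype=float)
    nf = v2.shape[1] if n_dof is None else int(n_dof)
    if nf < 1:
        return v.copy()
    kin = 0.5 * (m * v2**2).sum(axis=1)
    kin = np.maximum(kin, 1e-300)
    kbar = 0.5 * nf * KB * T_target
    c = np.exp(-dt / tau)
    B = v2.shape[0]
    r1 = rng.standard_normal(B)
    s = rng.chisquare(nf - 1, size=B) if nf > 1 else np.zeros(B)
    alpha2 = (
        c
        + (1.0 - c) * kbar * (r1**2 + s) / (nf * kin)
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * kbar / (nf * kin))
    )
    out = v2 * np.sqrt(np.maximum(alpha2, 0.0))[:, None]
    return out[0] if single else out


@dataclass
class RunPotentials:
    """The analytic lambda-potential terms active during a run.

    ``vmm`` holds one (possibly None) correction polynomial per group.
    ``pH`` may be a scalar or, in batched runs, an array with one value
    per walker.  Any term can be switched off, e.g. for TI scans where
    only the force-field gradient is integrated.
    """

    bias: BiasSpec | None = field(default_factory=BiasSpec)
    vmm: list[VmmPolynomial | None] = field(default_factory=list)
    pH: float | np.ndarray | None = None
    k1: float = 100.0
    x0: float = 0.25
    include_coulomb: bool = True

    def vmm_for(self, gi: int) -> VmmPolynomial | None:
        return self.vmm[gi] if gi < len(self.vmm) else None


def _ph_delta_g_matrix(system: TitratableSystem, pots: RunPotentials, B: int) -> np.ndarray:
    """Per-walker, per-DOF end-state free energies ln10 kT (pKa_k - pH)."""
    K = system.n_lambda_dofs
    dg = np.zeros((B, K))
    if pots.pH is None:
        return dg
    pH = np.broadcast_to(np.asarray(pots.pH, dtype=float), (B,))
    kT = KB * system.temperature
    for sl, g in zip(system.dof_slices(), system.groups):
        for k in range(1, g.n_states):
            pka = g.reference_pKas[k]
            if pka is not None:
                dg[:, sl.start + k] = LN10 * kT * (pka - pH)
    return dg


@dataclass
class LambdaTrajectory:
    """Recorded lambda time series for a batch of walkers.

    ``lambdas`` has shape (n_walkers, n_frames, K); metadata identify
    each walker's pH and replica index.
    """

    times: np.ndarray
    lambdas: np.ndarray
    names: list[str]
    pH: np.ndarray | None = None
    replica: np.ndarray | None = None
    seed: int | None = None
    kinetic: np.ndarray | None = None

    @property
    def n_walkers(self) -> int:
        return self.lambdas.shape[0]


def _group_mask(system: TitratableSystem) -> np.ndarray:
    """Boolean mask of lambda DOFs that belong to titration coordinates."""
    K = system.n_lambda_dofs
    mask = np.zeros(K, dtype=bool)
    for sl in system.dof_slices():
        mask[sl] = True
    return mask


def run_lambda_dynamics(
    system: TitratableSystem,
    potentials: RunPotentials,
    spec: IntegratorSpec,
    n_walkers: int = 1,
    initial_lambdas: np.ndarray | None = None,
    replica: np.ndarray | None = None,
    record_kinetic: bool = False,
    frozen: bool = False,
) -> LambdaTrajectory:
    """Batched leapfrog lambda-dynamics with frozen atoms.

    All walkers share the system geometry; the Coulomb term enters
    through the exact quadratic form in the lambda DOFs.  With
    ``frozen=True`` the lambdas are held at their initial values and only
    recorded (used by TI scans on frozen-atom systems).

    Initial lambda velocities are Maxwell-Boltzmann at the lambda
    temperature, projected onto the constraint manifold; the whole run is
    reproducible from ``spec.seed`` alone.
    """
    K = system.n_lambda_dofs
    B = int(n_walkers)
    rng = np.random.default_rng(spec.seed)
    constraints = build_constraints(system)
    masses = system.lambda_masses()
    nf = K - constraints.n_constraints
    if nf < 1 and not frozen:
        raise ConfigurationError("no free lambda degrees of freedom")

    if initial_lambdas is None:
        lam = np.tile(system.lambda_vector(), (B, 1))
    else:
        lam = np.array(initial_lambdas, dtype=float).reshape(B, K)
    lam, _ = solve_constraints(lam, np.zeros_like(lam), constraints)

    T_l, tau_l = (
        spec.lambda_thermostat if spec.lambda_thermostat is not None else (system.temperature, None)
    )
    vel = rng.standard_normal((B, K)) * np.sqrt(KB * T_l / masses)
    vel = constraints.project_velocities(vel)

    gmask = _group_mask(system)
    dg = _ph_delta_g_matrix(system, potentials, B)
    have_ph = np.any(dg != 0.0)
    H = g_lin = None
    if potentials.include_coulomb and system.n_atoms > 0:
        H, g_lin, _ = es.quadratic_form(system)
        if not (np.any(H) or np.any(g_lin)):
            H = g_lin = None
    slices = system.dof_slices()
    vmm_list = [potentials.vmm_for(gi) for gi in range(len(system.groups))]
    have_vmm = any(p is not None and p.n_terms and np.any(p.coefficients) for p in vmm_list)
    bias = potentials.bias

    stride = spec.output_stride
    n_frames = spec.n_steps // stride
    frames = np.empty((n_frames, B, K))
    kin_frames = np.empty((n_frames, B)) if record_kinetic else None
    times = (np.arange(n_frames) + 1) * stride * spec.dt

    dt = spec.dt
    frame = 0
    use_fast = (
        _kernels.HAVE_NUMBA
        and not frozen
        and not record_kinetic
        and not have_vmm
        and spec.n_steps % stride == 0
    )
    if use_fast:
        from scipy.special import expit

        k1, x0 = potentials.k1, potentials.x0
        snorm = 0.5 * (expit(k1 * (1 - x0)) + expit(k1 * x0)) - 0.5 * (
            expit(-k1 * x0) + expit(-k1 * (1 - x0))
        )
        use_thermo = spec.lambda_thermostat is not None
        cth = np.exp(-dt / tau_l) if use_thermo else 1.0
        kbar = 0.5 * nf * KB * T_l
        Hk = H if H is not None else np.zeros((K, K))
        gk = g_lin if g_lin is not None else np.zeros(K)
        barrier = bias.barrier if bias is not None else 0.0
        chunk = stride * max(1, 8192 // stride)
        done = 0
        while done < spec.n_steps:
            n = min(chunk, spec.n_steps - done)
            if use_thermo:
                r1 = rng.standard_normal((n, B))
                schi = (
                    rng.chisquare(nf - 1, size=(n, B)) if nf > 1 else np.zeros((n, B))
                )
            else:
                r1 = np.zeros((n, B))
                schi = np.zeros((n, B))
            frame = _kernels.lambda_chunk(
                lam, vel, masses, Hk, gk, H is not None, barrier, gmask, dg,
                k1, x0, snorm, constraints.jacobian, constraints._proj,
                constraints.targets, dt, cth, kbar, float(nf), r1, schi,
                use_thermo, frames, stride, frame,
            )
            done += n
            if not np.all(np.isfinite(lam)) or np.any(np.abs(lam) > 1e3):
                raise IntegrationBlowupError("lambda dynamics diverged", step=done)
        return LambdaTrajectory(
            times=times,
            lambdas=frames.transpose(1, 0, 2),
            names=system.lambda_names(),
            pH=np.broadcast_to(np.asarray(potentials.pH, dtype=float), (B,)).copy()
            if potentials.pH is not None
            else None,
            replica=replica,
            seed=spec.seed,
        )
    for step in range(spec.n_steps):
        if not frozen:
            grad = np.zeros((B, K))
            if H is not None:
                grad += lam @ H.T + g_lin
            if have_vmm:
                for sl, poly in zip(slices, vmm_list):
                    if poly is None or not np.any(poly.coefficients):
                        continue
                    _, gv = vmm_eval(lam[:, sl][:, 1:], poly)
                    grad[:, sl.start + 1 : sl.stop] += gv
            if bias is not None and bias.barrier != 0.0:
                lg = lam[:, gmask]
                grad[:, gmask] += 32.0 * bias.barrier * lg * (1.0 - lg) * (1.0 - 2.0 * lg)
            if have_ph:
                grad += dg * _step_deriv(lam, potentials.k1, potentials.x0)
            vel += dt * (-grad) / masses
            new = constraints.project_positions(lam + dt * vel)
            vel = (new - lam) / dt
            lam = new
            if spec.lambda_thermostat is not None:
                vel = vrescale(vel, masses, T_l, tau_l, dt, rng, n_dof=nf)
        if (step + 1) % stride == 0:
            frames[frame] = lam
            if record_kinetic:
                kin_frames[frame] = 0.5 * (masses * vel**2).sum(axis=1)
            frame += 1
            if not np.all(np.isfinite(lam)) or np.any(np.abs(lam) > 1e3):
                raise IntegrationBlowupError("lambda dynamics diverged", step=step)
    return LambdaTrajectory(
        times=times,
        lambdas=frames.transpose(1, 0, 2),
        names=system.lambda_names(),
        pH=np.broadcast_to(np.asarray(potentials.pH, dtype=float), (B,)).copy()
        if potentials.pH is not None
        else None,
        replica=replica,
        seed=spec.seed,
        kinetic=kin_frames.T if record_kinetic else None,
    )


# ---------------------------------------------------------------------------
# Full coupled atom + lambda dynamics (single system)
# ---------------------------------------------------------------------------


@dataclass
class MDState:
    """Positions/velocities of atoms and lambda particles at one instant."""

    positions: np.ndarray
    velocities: np.ndarray
    lambdas: np.ndarray
    lambda_velocities: np.ndarray
    reference_positions: np.ndarray
    step: int = 0

    @classmethod
    def initialize(
        cls, system: TitratableSystem, rng: np.random.Generator,
        atom_T: float | None = None, lambda_T: float | None = None,
        constraints: ConstraintSet | None = None,
    ) -> "MDState":
        pos = system.positions.copy()
        amass = np.array([a.mass for a in system.atoms])
        aT = system.temperature if atom_T is None else atom_T
        lT = system.temperature if lambda_T is None else lambda_T
        vel = rng.standard_normal(pos.shape) * np.sqrt(KB * aT / amass)[:, None]
        lam = system.lambda_vector()
        lmass = system.lambda_masses()
        lvel = rng.standard_normal(lam.shape) * np.sqrt(KB * lT / lmass)
        if constraints is not None:
            lam, lvel = solve_constraints(lam, lvel, constraints)
        return cls(
            positions=pos, velocities=vel, lambdas=lam, lambda_velocities=lvel,
            reference_positions=pos.copy(),
        )


def _lambda_coulomb_gradient(system: TitratableSystem, result) -> np.ndarray:
    """Full K-vector of Coulomb lambda-gradients from one evaluation."""
    from .electrostatics import lambda_gradients_charge_interp

    K = system.n_lambda_dofs
    grad = np.zeros(K)
    grads = lambda_gradients_charge_interp(system, result)
    for sl, gvec in zip(system.dof_slices(), grads):
        grad[sl] = gvec
    if system.buffers is not None:
        idx = [system.atom_index(a) for a in system.buffers.atom_ids]
        grad[K - 1] = system.buffers.charge_span * float(result.phi[idx].sum())
    return grad


def _analytic_lambda_gradient(
    system: TitratableSystem, lam: np.ndarray, pots: RunPotentials
) -> np.ndarray:
    K = system.n_lambda_dofs
    grad = np.zeros(K)
    dg = _ph_delta_g_matrix(system, pots, 1)[0]
    if np.any(dg != 0.0):
        grad += dg * _step_deriv(lam, pots.k1, pots.x0)
    if pots.bias is not None and pots.bias.barrier != 0.0:
        mask = _group_mask(system)
        _, db = bias_potential(lam[mask], pots.bias)
        grad[mask] += db
    for gi, sl in enumerate(system.dof_slices()):
        poly = pots.vmm_for(gi)
        if poly is not None and np.any(poly.coefficients):
            _, gv = vmm_eval(lam[sl][1:], poly)
            grad[sl.start + 1 : sl.stop] += gv
    return grad


def _atom_forces(system: TitratableSystem, state: MDState, pots: RunPotentials):
    system_positions_backup = None
    # positions live in state; write through to atoms for the evaluators
    for a, p in zip(system.atoms, state.positions):
        a.position = p
    system.set_lambda_vector(state.lambdas)
    q = interpolated_charges(system)
    res = es.coulomb(system, q) if pots.include_coulomb else None
    forces = res.atom_forces.copy() if res is not None else np.zeros_like(state.positions)
    ks = np.array([a.restraint_k for a in system.atoms])
    if np.any(ks > 0):
        forces -= ks[:, None] * (state.positions - state.reference_positions)
    return forces, res


def md_step(
    system: TitratableSystem,
    state: MDState,
    spec: IntegratorSpec,
    pots: RunPotentials,
    constraints: ConstraintSet,
    rng: np.random.Generator,
) -> MDState:
    """One leapfrog step of the coupled atom + lambda dynamics.

    Atomic and lambda forces come from a single electrostatic evaluation
    (charge interpolation); constraints are re-established after the
    position update and the velocity components along the constraint
    gradients are removed.  Thermostats (if enabled) act after the step,
    separately on the atom and lambda pools.
    """
    dt = spec.dt
    amass = np.array([a.mass for a in system.atoms])
    lmass = system.lambda_masses()

    forces, res = _atom_forces(system, state, pots)
    lgrad = _analytic_lambda_gradient(system, state.lambdas, pots)
    if res is not None:
        lgrad += _lambda_coulomb_gradient(system, res)
    if not (np.all(np.isfinite(forces)) and np.all(np.isfinite(lgrad))):
        raise IntegrationBlowupError("non-finite forces", step=state.step)

    if spec.freeze_atoms:
        new_pos, new_vel = state.positions, np.zeros_like(state.velocities)
    else:
        new_vel = state.velocities + dt * forces / amass[:, None]
        new_pos = state.positions + dt * new_vel

    lvel = state.lambda_velocities + dt * (-lgrad) / lmass
    new_lam = constraints.project_positions(state.lambdas + dt * lvel)
    lvel = (new_lam - state.lambdas) / dt

    if spec.atom_thermostat is not None and not spec.freeze_atoms:
        T, tau = spec.atom_thermostat
        new_vel = vrescale(
            new_vel.ravel(), np.repeat(amass, 3), T, tau, dt, rng
        ).reshape(new_vel.shape)
    if spec.lambda_thermostat is not None:
        T, tau = spec.lambda_thermostat
        nf = len(new_lam) - constraints.n_constraints
        lvel = vrescale(lvel, lmass, T, tau, dt, rng, n_dof=nf)

    return MDState(
        positions=new_pos,
        velocities=new_vel,
        lambdas=new_lam,
        lambda_velocities=lvel,
        reference_positions=state.reference_positions,
        step=state.step + 1,
    )


def total_potential_energy(
    system: TitratableSystem, state: MDState, pots: RunPotentials
) -> float:
    """Potential energy of the coupled system (for conservation checks)."""
    for a, p in zip(system.atoms, state.positions):
        a.position = p
    system.set_lambda_vector(state.lambdas)
    e = 0.0
    if pots.include_coulomb:
        e += es.coulomb(system).energy
    ks = np.array([a.restraint_k for a in system.atoms])
    if np.any(ks > 0):
        dr = state.positions - state.reference_positions
        e += 0.5 * float((ks * (dr**2).sum(axis=1)).sum())
    lam = state.lambdas
    dgrow = _ph_delta_g_matrix(system, pots, 1)[0]
    if np.any(dgrow != 0.0):
        e += float((dgrow * _step(lam, pots.k1, pots.x0)).sum())
    if pots.bias is not None:
        mask = _group_mask(system)
        vb, _ = bias_potential(lam[mask], pots.bias)
        e += float(np.sum(vb))
    for gi, sl in enumerate(system.dof_slices()):
        poly = pots.vmm_for(gi)
        if poly is not None and np.any(poly.coefficients):
            v, _ = vmm_eval(lam[sl][1:], poly)
            e += float(v)
    return e


def run_md(
    system: TitratableSystem,
    spec: IntegratorSpec,
    pots: RunPotentials,
    record_energy: bool = False,
):
    """Run coupled dynamics; returns (trajectory, states_summary).

    The lambda trajectory is recorded at ``spec.lambda_output_interval``.
    With ``record_energy`` the total (kinetic + potential) energy is
    recorded at the same interval, for NVE drift checks.
    """
    rng = np.random.default_rng(spec.seed)
    constraints = build_constraints(system)
    orig_positions = system.positions.copy()
    orig_lambdas = system.lambda_vector().copy()
    aT = spec.atom_thermostat[0] if spec.atom_thermostat else system.temperature
    lT = spec.lambda_thermostat[0] if spec.lambda_thermostat else system.temperature
    state = MDState.initialize(system, rng, atom_T=aT, lambda_T=lT, constraints=constraints)
    if spec.freeze_atoms:
        state.velocities[:] = 0.0
    stride = spec.output_stride
    frames, times, energies = [], [], []
    amass = np.array([a.mass for a in system.atoms])
    lmass = system.lambda_masses()
    for step in range(spec.n_steps):
        state = md_step(system, state, spec, pots, constraints, rng)
        if (step + 1) % stride == 0:
            frames.append(state.lambdas.copy())
            times.append((step + 1) * spec.dt)
            if record_energy:
                kin = 0.5 * float((amass[:, None] * state.velocities**2).sum())
                kin += 0.5 * float((lmass * state.lambda_velocities**2).sum())
                energies.append(kin + total_potential_energy(system, state, pots))
    for a, p in zip(system.atoms, orig_positions):
        a.position = p.copy()
    system.set_lambda_vector(orig_lambdas)
    traj = LambdaTrajectory(
        times=np.array(times),
        lambdas=np.array(frames)[None, ...] if frames else np.zeros((1, 0, system.n_lambda_dofs)),
        names=system.lambda_names(),
        pH=np.array([pots.pH]) if np.isscalar(pots.pH) else None,
        seed=spec.seed,
    )
    return traj, (state, np.array(energies) if record_energy else None)
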